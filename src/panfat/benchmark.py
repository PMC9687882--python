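"""The standard synthetic segmentation benchmark.

Builds multi-slice synthetic stacks, LSC-preprocesses every water slice into
a schematic image, and splits stacks 80:20 into training and test sets —
always by stack, never by slice, so no subject leaks across the split. Used
by the test suite and the acceptance script; the sizes are arguments so the
same machinery scales from smoke tests to the full benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import NOMINAL_FRAME
from .superpixel import LSCParams, lsc_segment, schematic_map
from .synthetic import generate_stack
from .types import SuperpixelMap


@dataclass
class BenchmarkSlice:
    water: np.ndarray
    schematic: np.ndarray
    gt_mask: np.ndarray
    spmap: SuperpixelMap
    stack_id: int


@dataclass
class Benchmark:
    slices: list[BenchmarkSlice] = field(default_factory=list)
    train_stacks: list[int] = field(default_factory=list)
    test_stacks: list[int] = field(default_factory=list)

    def _subset(self, stack_ids):
        return [s for s in self.slices if s.stack_id in stack_ids]

    @property
    def train(self) -> list[BenchmarkSlice]:
        return self._subset(set(self.train_stacks))

    @property
    def test(self) -> list[BenchmarkSlice]:
        return self._subset(set(self.test_stacks))


def density_scaled_superpixels(shape, nominal: int = 2500) -> int:
    """Superpixel count keeping the nominal 512x512 density on other frames."""
    h, w = shape
    k = int(round(nominal * (h * w) / NOMINAL_FRAME**2))
    return max(16, min(k, h * w // 4))


def build_benchmark(n_stacks: int = 25, n_slices: int = 8, shape=(128, 128),
                    fat_fraction: float = 8.0, r: float = 0.25,
                    n_superpixels: int | None = None, noise_sd: float = 1.5,
                    test_fraction: float = 0.2, seed: int = 0) -> Benchmark:
    """Generate stacks, preprocess each slice, and split by stack (80:20)."""
    rng = np.random.default_rng(seed)
    k = n_superpixels or density_scaled_superpixels(shape)
    params = LSCParams(n_superpixels=k, r=r)
    bench = Benchmark()
    for sid in range(n_stacks):
        stack = generate_stack(n_slices=n_slices, shape=shape,
                               fat_fraction=fat_fraction, noise_sd=noise_sd,
                               seed=int(rng.integers(0, 2**31 - 1)))
        for pair in stack.slices:
            spmap = lsc_segment(pair.water, params)
            schem = schematic_map(pair.water, spmap)
            bench.slices.append(BenchmarkSlice(
                water=pair.water.data, schematic=schem.values,
                gt_mask=pair.gt_mask, spmap=spmap, stack_id=sid))
    order = rng.permutation(n_stacks)
    n_test = max(1, int(round(test_fraction * n_stacks)))
    bench.test_stacks = sorted(int(i) for i in order[:n_test])
    bench.train_stacks = sorted(int(i) for i in order[n_test:])
    return bench
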
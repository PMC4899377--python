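"""Bundled example data.

The glass-fiber strength data: 63 breaking strengths of 1.5 cm glass
fibres measured at the UK National Physical Laboratory (measurement
units not recorded in the source).  A classical left-skewed benchmark
for lifetime/strength distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import SampleVector

__all__ = ["DatasetHandle", "load_glass_fiber"]

_GLASS_FIBER = (
    0.55, 0.74, 0.77, 0.81, 0.84, 0.93, 1.04, 1.11, 1.13, 1.24, 1.25, 1.27,
    1.28, 1.29, 1.30, 1.36, 1.39, 1.42, 1.48, 1.48, 1.49, 1.49, 1.50, 1.50,
    1.51, 1.52, 1.53, 1.54, 1.55, 1.55, 1.58, 1.59, 1.60, 1.61, 1.61, 1.61,
    1.61, 1.62, 1.62, 1.63, 1.64, 1.66, 1.66, 1.66, 1.67, 1.68, 1.68, 1.69,
    1.70, 1.70, 1.73, 1.76, 1.76, 1.77, 1.78, 1.81, 1.82, 1.84, 1.84, 1.89,
    2.00, 2.01, 2.24,
)


@dataclass(frozen=True)
class DatasetHandle:
    name: str
    sample: SampleVector
    source: str

    @property
    def values(self) -> np.ndarray:
        return self.sample.values


def load_glass_fiber() -> DatasetHandle:
    """The 63 glass-fibre strengths, in their published order."""
    return DatasetHandle(
        name="glass_fiber",
        sample=SampleVector(np.array(_GLASS_FIBER)),
        source="UK National Physical Laboratory; strengths of 1.5 cm glass fibres "
               "(Smith & Naylor benchmark data)",
    )
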
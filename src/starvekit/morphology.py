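"""Spherocylinder cell volumes and per-volume normalization.

Starved rod-shaped cells are modeled as a cylinder of width w capped by two
hemispheres, V = pi*(w/2)^2*(l - w) + 4/3*pi*(w/2)^3.  Population volume is
the mean of per-cell volumes (not the volume of the mean cell, which would
underestimate skewed samples); its uncertainty combines the sampling
standard error with a 5% relative instrument error in quadrature.
Maintenance rate and recycling yield are normalized per mean cell volume
with relative errors added in quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import GrowthCondition

#: relative instrument error of volume determination
INSTRUMENT_REL_ERR = 0.05
#: minimum cells for a reliable population average
MIN_SAMPLE = 200


@dataclass(frozen=True)
class CellSizeSample:
    """Per-cell lengths and widths (um) of one growth condition."""

    lengths: tuple
    widths: tuple
    condition: GrowthCondition | None = None

    def __post_init__(self):
        l = np.asarray(self.lengths, float)
        w = np.asarray(self.widths, float)
        if l.shape != w.shape or l.ndim != 1:
            raise ValueError("lengths and widths must be 1-D, equal length")
        if np.any(w <= 0) or np.any(l < w):
            raise ValueError("invalid rod geometry: need l >= w > 0 per cell")
        object.__setattr__(self, "lengths", tuple(float(v) for v in l))
        object.__setattr__(self, "widths", tuple(float(v) for v in w))


@dataclass(frozen=True)
class VolumeStat:
    """Population mean cell volume (um^3) with standard error."""

    mean_volume: float
    se: float
    n: int = 0


def cell_volume(l: float, w: float) -> float:
    """Volume (um^3) of a rod of length l, width w (um), spherocylinder."""
    if not (l >= w > 0):
        raise ValueError("invalid rod geometry: need l >= w > 0")
    r = w / 2.0
    return math.pi * r**2 * (l - w) + 4.0 / 3.0 * math.pi * r**3


def sample_volume(sample: CellSizeSample,
                  instrument_rel_err: float = INSTRUMENT_REL_ERR) -> VolumeStat:
    """Mean per-cell volume of a sample, with sampling + instrument error."""
    n = len(sample.lengths)
    if n < MIN_SAMPLE:
        warnings.warn(f"undersized sample: {n} cells < {MIN_SAMPLE}",
                      stacklevel=2)
    vols = np.array([cell_volume(l, w)
                     for l, w in zip(sample.lengths, sample.widths)])
    mean = float(np.mean(vols))
    sampling_se = float(np.std(vols, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    se = math.hypot(sampling_se, instrument_rel_err * mean)
    return VolumeStat(mean, se, n)


def normalize_by_volume(value: float, value_se: float,
                        vol: VolumeStat) -> tuple[float, float]:
    """Divide a condition-level quantity by mean cell volume.

    Relative errors of numerator and denominator add in quadrature.
    """
    if vol.mean_volume <= 0:
        raise ValueError("mean volume must be positive")
    ratio = value / vol.mean_volume
    rel = math.hypot(
        value_se / value if value != 0 else 0.0,
        vol.se / vol.mean_volume,
    )
    return ratio, abs(ratio) * rel
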
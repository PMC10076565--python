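"""First-order intensity-histogram features of the plaque ROI.

Computed on the pre-contrast T1 wall annulus at the most-stenotic section.
Mean, median, SD (sample, n−1), minimum and maximum are taken on the raw
intensities; entropy is Shannon entropy in bits over an equal-width
histogram spanning the per-sample min–max range (default 256 bins, the
common radiomics convention, bounding entropy at 8 bits); the coefficient
of variation is SD/mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .geometry import LesionStack, rasterize_wall_roi


class HistogramError(ValueError):
    pass


@dataclass(frozen=True)
class HistogramFeatures:
    mean: float
    median: float
    sd: float
    minimum: float
    maximum: float
    entropy: float      # bits
    cv: float           # dimensionless

    def as_dict(self, prefix: str = "hist_") -> dict:
        return {prefix + k: v for k, v in asdict(self).items()}


def first_order_features(
    intensities: np.ndarray, n_bins: int = 256
) -> HistogramFeatures:
    """First-order features of an intensity sample.

    The sample must be non-empty with a strictly positive mean (the
    coefficient of variation is otherwise undefined).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise HistogramError("empty intensity sample")
    if n_bins < 2:
        raise HistogramError("n_bins must be >= 2")
    mean = float(x.mean())
    if mean <= 0:
        raise HistogramError("cv undefined: sample mean must be > 0")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        p = counts[counts > 0] / x.size
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0  # constant sample: a single occupied bin
    return HistogramFeatures(
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        minimum=lo,
        maximum=hi,
        entropy=entropy,
        cv=sd / mean,
    )


def stenotic_site_features(
    stack: LesionStack, n_bins: int = 256, weighting: str = "t1_pre"
) -> HistogramFeatures:
    """Histogram features of the stenotic-site wall ROI on pre-contrast T1."""
    ny, nx = stack.grid_shape[1:]
    idx = rasterize_wall_roi(stack.stenotic, (ny, nx), stack.voxel_spacing)
    z = stack.stenotic.slice_index
    values = stack.volumes[weighting][z, idx[:, 0], idx[:, 1]]
    return first_order_features(values, n_bins=n_bins)
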
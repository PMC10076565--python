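"""Plaque-level quantitative indices from a segmented lesion stack.

All indices follow the conventional vessel-wall-MRI definitions:

* stenosis (%)           = (D_n − D_s) / D_n × 100, D_n the mean of the
                           proximal and distal reference lumen diameters
* plaque burden (%)      = (1 − MLA / VA_s) × 100 at the most-stenotic site
* remodeling ratio (%)   = VA_s / VA_n × 100, VA_n the mean reference
                           vessel area
* eccentricity index (%) = (Wall_max − Wall_min) / Wall_max × 100
* enhancement ratio (%)  = [(S_plaque_post / S_gm_post) /
                            (S_plaque_pre  / S_gm_pre) − 1] × 100,
                           computed at the stenotic site and over the
                           whole plaque
* plaque volume (mm³)    = Σ_slices (outer area − lumen area) × spacing
* IPH                    = any sufficiently large connected wall region
                           whose pre-contrast T1 signal exceeds 150% of
                           adjacent muscle

Effective diameters are circular-equivalent diameters of the lumen areas.
Negative stenosis (compensatory dilation) is retained and flagged rather
than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .geometry import (
    CrossSection,
    GeometryError,
    LesionStack,
    effective_diameter,
    polygon_area,
    rasterize_wall_roi,
    wall_thickness_extrema,
)


class MorphometryError(ValueError):
    """Raised when an index cannot be computed; names the failing index."""


IPH_THRESHOLD = 1.5          # strict: signal ratio must exceed 150%
IPH_MIN_COMPONENT = 3        # voxels


@dataclass
class PlaqueMeasurements:
    """The full per-plaque feature record."""

    mla: float
    va_s: float
    wa_s: float
    d_s: float
    d_proximal: float
    d_distal: float
    va_proximal: float
    va_distal: float
    wall_max: float
    wall_min: float
    stenosis_pct: float
    plaque_burden_pct: float
    remodeling_ratio_pct: float
    eccentricity_index_pct: float
    enhancement_ratio_stenosis_pct: float
    enhancement_ratio_whole_pct: float
    plaque_volume: float
    iph: bool
    s_plaque_pre: float
    s_plaque_post: float
    s_whole_pre: float
    s_whole_post: float
    s_gm_pre: float
    s_gm_post: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = ";".join(self.flags)
        return d


def stenosis_percent(d_s: float, d_proximal: float, d_distal: float) -> float:
    """Diameter stenosis relative to the mean reference diameter, percent."""
    if min(d_s, d_proximal, d_distal) <= 0:
        raise MorphometryError("stenosis: all diameters must be > 0")
    d_n = 0.5 * (d_proximal + d_distal)
    return (d_n - d_s) / d_n * 100.0


def plaque_burden(mla: float, va_s: float) -> float:
    """Wall occupancy of the vessel at the most-stenotic site, percent."""
    if va_s <= 0:
        raise MorphometryError("plaque burden: vessel area must be > 0")
    if mla < 0 or mla > va_s:
        raise MorphometryError(
            f"plaque burden: MLA {mla} outside [0, VA={va_s}]"
        )
    return (1.0 - mla / va_s) * 100.0


def remodeling_ratio(va_s: float, va_proximal: float, va_distal: float) -> float:
    """Stenotic-site vessel area over the mean reference vessel area, percent."""
    if min(va_s, va_proximal, va_distal) <= 0:
        raise MorphometryError("remodeling ratio: all areas must be > 0")
    va_n = 0.5 * (va_proximal + va_distal)
    return va_s / va_n * 100.0


def eccentricity_index(wall_max: float, wall_min: float) -> float:
    """Relative spread of wall thickness, percent; 0 for concentric walls."""
    if wall_max <= 0 or wall_min < 0 or wall_max < wall_min:
        raise MorphometryError(
            "eccentricity index requires wall_max >= wall_min > 0"
        )
    return (wall_max - wall_min) / wall_max * 100.0


def enhancement_ratio(
    s_plaque_pre: float,
    s_plaque_post: float,
    s_gm_pre: float,
    s_gm_post: float,
) -> float:
    """Gray-matter-normalized post/pre contrast signal gain, percent."""
    signals = (s_plaque_pre, s_plaque_post, s_gm_pre, s_gm_post)
    if min(signals) <= 0:
        raise MorphometryError("enhancement ratio: all signals must be > 0")
    return ((s_plaque_post / s_gm_post) / (s_plaque_pre / s_gm_pre) - 1.0) * 100.0


def plaque_volume(stack: LesionStack) -> float:
    """Wall area accumulated over every whole-plaque slice × spacing, mm³."""
    return float(
        sum(s.wall_area * s.slice_spacing for s in stack.whole_plaque)
    )


def detect_iph(
    t1_pre: np.ndarray,
    wall_mask: np.ndarray,
    muscle_values: np.ndarray,
    threshold: float = IPH_THRESHOLD,
    min_component_size: int = IPH_MIN_COMPONENT,
) -> bool:
    """Intraplaque hemorrhage rule on pre-contrast T1.

    Connected components of wall voxels individually exceeding
    ``threshold × mean(muscle)`` are evaluated; IPH is called when any
    component of at least ``min_component_size`` voxels has a mean signal
    strictly above the threshold.
    """
    muscle_values = np.asarray(muscle_values, dtype=float)
    if muscle_values.size == 0 or wall_mask.sum() == 0:
        raise MorphometryError("IPH: empty plaque or muscle sample")
    muscle_mean = float(muscle_values.mean())
    if muscle_mean <= 0:
        raise MorphometryError("IPH: muscle signal must be > 0")
    hot = wall_mask & (t1_pre > threshold * muscle_mean)
    labels, n_components = ndimage.label(hot)
    for k in range(1, n_components + 1):
        component = labels == k
        if component.sum() < min_component_size:
            continue
        if float(t1_pre[component].mean()) > threshold * muscle_mean:
            return True
    return False


def _section_diameters(section: CrossSection) -> float:
    return effective_diameter(polygon_area(section.lumen))


def measure_plaque(
    stack: LesionStack, n_thickness_samples: int = 256
) -> PlaqueMeasurements:
    """Populate the full feature record from a lesion stack.

    Deterministic for fixed input; failures are re-raised naming the index
    that could not be computed.
    """
    flags: list[str] = []

    def _step(name: str, fn, *args):
        try:
            return fn(*args)
        except (GeometryError, MorphometryError, KeyError) as exc:
            raise MorphometryError(f"{name}: {exc}") from exc

    mla = _step("mla", polygon_area, stack.stenotic.lumen)
    va_s = _step("va_s", polygon_area, stack.stenotic.outer_wall)
    wa_s = va_s - mla
    d_s = _step("d_s", effective_diameter, mla)
    d_proximal = _step("d_proximal", _section_diameters, stack.proximal_ref)
    d_distal = _step("d_distal", _section_diameters, stack.distal_ref)
    va_proximal = _step("va_proximal", polygon_area, stack.proximal_ref.outer_wall)
    va_distal = _step("va_distal", polygon_area, stack.distal_ref.outer_wall)
    wall_max, wall_min = _step(
        "wall_thickness", wall_thickness_extrema, stack.stenotic,
        n_thickness_samples,
    )

    stenosis = _step("stenosis", stenosis_percent, d_s, d_proximal, d_distal)
    if stenosis < 0:
        flags.append("negative_stenosis")
    burden = _step("plaque_burden", plaque_burden, mla, va_s)
    remodeling = _step(
        "remodeling_ratio", remodeling_ratio, va_s, va_proximal, va_distal
    )
    eccentricity = _step("eccentricity_index", eccentricity_index, wall_max, wall_min)
    volume = _step("plaque_volume", plaque_volume, stack)
    if volume <= 0:
        flags.append("degenerate_volume")

    ny, nx = stack.grid_shape[1:]
    sten_idx = _step(
        "stenotic_roi", rasterize_wall_roi, stack.stenotic, (ny, nx),
        stack.voxel_spacing,
    )
    z = stack.stenotic.slice_index

    def _slice_mean(weighting: str) -> float:
        return float(stack.volumes[weighting][z, sten_idx[:, 0], sten_idx[:, 1]].mean())

    s_plaque_pre = _step("s_plaque_pre", _slice_mean, "t1_pre")
    s_plaque_post = _step("s_plaque_post", _slice_mean, "t1_post")
    wall = _step("wall_mask", stack.wall_mask)
    s_whole_pre = float(stack.volumes["t1_pre"][wall].mean())
    s_whole_post = float(stack.volumes["t1_post"][wall].mean())
    s_gm_pre = float(stack.roi_values("t1_pre", stack.gray_matter_roi).mean())
    s_gm_post = float(stack.roi_values("t1_post", stack.gray_matter_roi).mean())

    er_stenosis = _step(
        "enhancement_ratio_stenosis", enhancement_ratio,
        s_plaque_pre, s_plaque_post, s_gm_pre, s_gm_post,
    )
    er_whole = _step(
        "enhancement_ratio_whole", enhancement_ratio,
        s_whole_pre, s_whole_post, s_gm_pre, s_gm_post,
    )
    iph = _step(
        "iph", detect_iph,
        stack.volumes["t1_pre"], wall, stack.roi_values("t1_pre", stack.muscle_roi),
    )

    return PlaqueMeasurements(
        mla=mla, va_s=va_s, wa_s=wa_s, d_s=d_s,
        d_proximal=d_proximal, d_distal=d_distal,
        va_proximal=va_proximal, va_distal=va_distal,
        wall_max=wall_max, wall_min=wall_min,
        stenosis_pct=stenosis, plaque_burden_pct=burden,
        remodeling_ratio_pct=remodeling,
        eccentricity_index_pct=eccentricity,
        enhancement_ratio_stenosis_pct=er_stenosis,
        enhancement_ratio_whole_pct=er_whole,
        plaque_volume=volume, iph=iph,
        s_plaque_pre=s_plaque_pre, s_plaque_post=s_plaque_post,
        s_whole_pre=s_whole_pre, s_whole_post=s_whole_post,
        s_gm_pre=s_gm_pre, s_gm_post=s_gm_post,
        flags=tuple(flags),
    )
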
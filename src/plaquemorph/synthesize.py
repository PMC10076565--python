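"""Synthetic cohorts, plaque geometries and intensity volumes.

Three generators make the whole pipeline testable without patient data:

* :func:`generate_cohort` draws per-patient covariate/feature tables whose
  group distributions default to the published culprit / non-culprit
  calibration (truncated normals for continuous features, Bernoulli for
  binary covariates, a right-skewed discrete distribution for NIHSS).
* :func:`generate_plaque_stack` builds a straight tubular vessel with an
  eccentric crescent-shaped wall thickening across several slices, renders
  T2 / pre- / post-contrast T1 volumes on a 0.5 mm isotropic grid, and
  returns exact construction ground truth for every morphometric index.
  The ground truth is computed by dense brute-force evaluation of the
  continuous radius functions (independent of the polygon/shapely
  measurement path).
* :func:`simulate_second_reader` perturbs contours with radial Gaussian
  noise to emulate a second human reader for agreement studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import norm, truncnorm

from . import calibration as cal
from .geometry import (
    Contour,
    CrossSection,
    GeometryError,
    LesionStack,
    rasterize_wall_roi,
)


class SpecError(ValueError):
    """Invalid or infeasible generator specification."""


class AdmissibilityError(SpecError):
    """Parameter combination violating the <50% stenosis admission rule."""


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Distributional specification of one plaque group."""

    n: int
    continuous: dict[str, tuple[float, float]]
    binary: dict[str, float]
    age: tuple[float, float] = (58.5, 12.6)
    nihss_decay: float = 0.8
    nihss_max: int = 18

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SpecError(f"group size must be > 0, got {self.n}")
        for name, (mean, sd) in self.continuous.items():
            if sd <= 0:
                raise SpecError(f"{name}: sd must be > 0")
            lo, hi = cal.TRUNCATION_BOUNDS.get(name, cal.DEFAULT_TRUNCATION)
            mass = norm.cdf((hi - mean) / sd) - norm.cdf((lo - mean) / sd)
            if mass < 1e-6:
                raise SpecError(
                    f"{name}: truncation bounds [{lo}, {hi}] leave no mass "
                    f"around mean {mean} (sd {sd})"
                )
        for name, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{name}: prevalence must be in [0, 1]")
        if not 0.0 < self.nihss_decay < 1.0 or self.nihss_max < 0:
            raise SpecError("invalid NIHSS distribution parameters")


def default_culprit_spec() -> GroupSpec:
    return GroupSpec(
        n=cal.N_CULPRIT,
        continuous={k: v[0] for k, v in cal.CONTINUOUS_FEATURES.items()},
        binary={k: v[0] for k, v in cal.BINARY_COVARIATES.items()},
        age=cal.AGE[0],
        nihss_decay=0.82,
        nihss_max=cal.NIHSS_CULPRIT["range"][1],
    )


def default_nonculprit_spec() -> GroupSpec:
    return GroupSpec(
        n=cal.N_NONCULPRIT,
        continuous={k: v[1] for k, v in cal.CONTINUOUS_FEATURES.items()},
        binary={k: v[1] for k, v in cal.BINARY_COVARIATES.items()},
        age=cal.AGE[1],
        nihss_decay=0.40,
        nihss_max=cal.NIHSS_NONCULPRIT["range"][1],
    )


def _nihss_pmf(decay: float, k_max: int) -> np.ndarray:
    p = decay ** np.arange(k_max + 1)
    return p / p.sum()


def _truncnorm_params(name: str, mean: float, sd: float):
    lo, hi = cal.TRUNCATION_BOUNDS.get(name, cal.DEFAULT_TRUNCATION)
    return (lo - mean) / sd, (hi - mean) / sd


def _draw_group(
    spec: GroupSpec,
    label: str,
    rng: np.random.Generator,
    correlation: pd.DataFrame | None,
) -> pd.DataFrame:
    names = list(spec.continuous)
    k = len(names)
    # Gaussian copula: identity correlation unless the caller supplies one
    corr = np.eye(k)
    if correlation is not None:
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if a in correlation.index and b in correlation.columns:
                    corr[i, j] = correlation.loc[a, b]
        if not np.all(np.linalg.eigvalsh(corr) > -1e-10):
            raise SpecError("correlation matrix is not positive semidefinite")
    z = rng.multivariate_normal(np.zeros(k), corr, size=spec.n,
                                method="cholesky")
    u = norm.cdf(z)
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        mean, sd = spec.continuous[name]
        a, b = _truncnorm_params(name, mean, sd)
        # clip away exact 0/1 quantiles to keep ppf finite
        q = np.clip(u[:, j], 1e-12, 1 - 1e-12)
        data[name] = truncnorm.ppf(q, a, b, loc=mean, scale=sd)
    data["age"] = rng.normal(spec.age[0], spec.age[1], size=spec.n)
    for name, p in spec.binary.items():
        data[name] = (rng.random(spec.n) < p).astype(int)
    pmf = _nihss_pmf(spec.nihss_decay, spec.nihss_max)
    data["nihss"] = rng.choice(len(pmf), size=spec.n, p=pmf)
    df = pd.DataFrame(data)
    df.insert(0, "label", label)
    return df


def generate_cohort(
    culprit_spec: GroupSpec | None = None,
    nonculprit_spec: GroupSpec | None = None,
    seed: int = 0,
    correlation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw a labelled case-control cohort table, reproducible per seed."""
    culprit_spec = culprit_spec or default_culprit_spec()
    nonculprit_spec = nonculprit_spec or default_nonculprit_spec()
    rng = np.random.default_rng(seed)
    df = pd.concat(
        [
            _draw_group(culprit_spec, "culprit", rng, correlation),
            _draw_group(nonculprit_spec, "non-culprit", rng, correlation),
        ],
        ignore_index=True,
    )
    df.insert(0, "patient_id", [f"P{i:04d}" for i in range(len(df))])
    return df


# --------------------------------------------------------------------------
# plaque geometry + intensity volumes
# --------------------------------------------------------------------------

@dataclass
class SyntheticPlaqueParams:
    """Construction parameters of one synthetic plaque.

    The vessel is a straight tube along z.  The lumen radius narrows toward
    the stenotic slice by ``stenosis_fraction``; the outer wall carries a
    crescent-shaped thickening of angular width ``angular_extent`` whose
    peak adds ``plaque_thickness`` to the baseline wall.
    """

    lumen_radius: float = 1.3          # reference lumen radius, mm
    stenosis_fraction: float = 0.2     # diameter reduction at the stenotic site
    base_wall_thickness: float = 0.3   # mm, concentric wall everywhere
    plaque_thickness: float = 1.2      # mm added at the crescent peak
    angular_extent: float = 0.7 * 2 * np.pi  # radians
    plaque_center_angle: float = 0.0
    n_slices: int = 7                  # plaque length in slices
    slice_spacing: float = 0.5         # mm
    enhancement_pct: float = 40.0      # constructed whole-plaque ER
    wall_signal_mean: float = 119.0    # pre-contrast T1 wall signal, a.u.
    noise_sd: float = 5.0              # intensity noise, a.u.
    iph: bool = False
    n_vertices: int = 96
    grid_size: int = 32
    voxel_spacing: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.stenosis_fraction:
            raise SpecError("stenosis_fraction must be >= 0")
        if self.stenosis_fraction >= 0.5:
            raise AdmissibilityError(
                f"stenosis_fraction {self.stenosis_fraction} implies >=50% "
                "stenosis; only non-stenotic plaques are admissible"
            )
        if self.plaque_thickness < 0 or self.base_wall_thickness <= 0:
            raise SpecError("wall thicknesses must be positive")
        if not 0.0 < self.angular_extent < 2 * np.pi:
            raise SpecError("angular_extent must be in (0, 2*pi)")
        if self.n_slices < 1:
            raise SpecError("n_slices must be >= 1")
        outer_max = (
            self.lumen_radius + self.base_wall_thickness + self.plaque_thickness
        )
        fov_half = (self.grid_size - 8) * self.voxel_spacing / 2
        if outer_max >= fov_half:
            raise SpecError("vessel does not fit the grid with ROI margins")


def sample_plaque_params(
    rng: np.random.Generator, **overrides
) -> SyntheticPlaqueParams:
    """Draw one plaque's construction parameters from the study population.

    Ranges are chosen so that the resulting morphometric dispersions match
    the published culprit-cohort spread (e.g. minimum wall thickness SD
    ≈ 0.17 mm, eccentricity-index SD ≈ 9.7 percentage points) while every
    draw stays non-stenotic and resolvable on the 0.5 mm grid.
    """
    params = dict(
        lumen_radius=float(rng.uniform(1.1, 1.6)),
        base_wall_thickness=float(rng.uniform(0.3, 0.9)),
        plaque_thickness=float(rng.uniform(0.6, 1.6)),
        angular_extent=float(rng.uniform(0.45, 0.8)) * 2 * np.pi,
        plaque_center_angle=float(rng.uniform(0.0, 2 * np.pi)),
        stenosis_fraction=float(rng.uniform(0.1, 0.35)),
        enhancement_pct=float(rng.uniform(15.0, 45.0)),
    )
    params.update(overrides)
    return SyntheticPlaqueParams(**params)


GM_SIGNAL = 100.0
MUSCLE_SIGNAL = 100.0
BACKGROUND_SIGNAL = 60.0
LUMEN_SIGNAL = 40.0
IPH_FACTOR = 1.7  # hot-spot signal relative to muscle when the flag is set


def _angular_bump(theta: np.ndarray, center: float, extent: float) -> np.ndarray:
    delta = np.angle(np.exp(1j * (theta - center)))
    bump = 0.5 * (1.0 + np.cos(2 * np.pi * delta / extent))
    return np.where(np.abs(delta) <= extent / 2, bump, 0.0)


def _outer_radius(
    theta: np.ndarray, lumen_r: float, params: SyntheticPlaqueParams,
    z_bump: float,
) -> np.ndarray:
    ang = _angular_bump(theta, params.plaque_center_angle, params.angular_extent)
    return lumen_r + params.base_wall_thickness + \
        params.plaque_thickness * z_bump * ang


def _circle(center: np.ndarray, radius: float, n: int) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    return center + radius * np.column_stack([np.cos(theta), np.sin(theta)])


def _dense_ground_truth(params: SyntheticPlaqueParams, z_bumps: np.ndarray,
                        lumen_radii: np.ndarray, stenotic_local: int) -> dict:
    """Brute-force morphometric ground truth from the continuous radii."""
    n_dense = 8192
    theta = 2 * np.pi * np.arange(n_dense) / n_dense
    outer_areas = []
    for z_bump, r in zip(z_bumps, lumen_radii):
        R = _outer_radius(theta, r, params, z_bump)
        outer_areas.append(0.5 * float(np.mean(R**2)) * 2 * np.pi)
    outer_areas = np.asarray(outer_areas)
    lumen_areas = np.pi * lumen_radii**2

    r_s = lumen_radii[stenotic_local]
    R_s = _outer_radius(theta, r_s, params, z_bumps[stenotic_local])
    outer_pts = np.column_stack([R_s * np.cos(theta), R_s * np.sin(theta)])
    lumen_theta = 2 * np.pi * np.arange(2048) / 2048
    lumen_pts = r_s * np.column_stack(
        [np.cos(lumen_theta), np.sin(lumen_theta)]
    )
    dists, _ = cKDTree(outer_pts).query(lumen_pts)
    wall_max, wall_min = float(dists.max()), float(dists.min())

    r0 = params.lumen_radius
    va_ref = np.pi * (r0 + params.base_wall_thickness) ** 2
    mla = float(lumen_areas[stenotic_local])
    va_s = float(outer_areas[stenotic_local])
    d_s, d_ref = 2 * r_s, 2 * r0
    d_n = d_ref
    return {
        "mla": mla,
        "va_s": va_s,
        "wa_s": va_s - mla,
        "d_s": d_s,
        "d_proximal": d_ref,
        "d_distal": d_ref,
        "va_proximal": va_ref,
        "va_distal": va_ref,
        "wall_max": wall_max,
        "wall_min": wall_min,
        "stenosis_pct": (d_n - d_s) / d_n * 100.0,
        "plaque_burden_pct": (1.0 - mla / va_s) * 100.0,
        "remodeling_ratio_pct": va_s / va_ref * 100.0,
        "eccentricity_index_pct": (wall_max - wall_min) / wall_max * 100.0,
        "enhancement_ratio_stenosis_pct": params.enhancement_pct,
        "enhancement_ratio_whole_pct": params.enhancement_pct,
        "plaque_volume": float(
            ((outer_areas - lumen_areas) * params.slice_spacing).sum()
        ),
        "iph": params.iph,
    }


def generate_plaque_stack(
    params: SyntheticPlaqueParams | None = None, seed: int = 0
) -> tuple[LesionStack, dict]:
    """Build a lesion stack plus its construction ground truth.

    Returns ``(stack, ground_truth)`` where ``ground_truth`` maps
    morphometric field names to their analytically constructed values.
    """
    params = params or SyntheticPlaqueParams()
    rng = np.random.default_rng(seed)
    L = params.n_slices
    nz = L + 4
    G = params.grid_size
    sp = params.voxel_spacing
    center = np.array([(G // 2) * sp, (G // 2) * sp])  # (x, y) mm

    mid = (L - 1) / 2.0
    local = np.arange(L)
    zeta = (local - mid) / (mid + 1.0)
    z_bumps = np.cos(np.pi * zeta / 2.0) ** 2
    stenotic_local = int(round(mid))
    lumen_radii = params.lumen_radius * (
        1.0 - params.stenosis_fraction * z_bumps
    )

    def _section(slice_index: int, lumen_r: float, z_bump: float) -> CrossSection:
        theta = 2 * np.pi * np.arange(params.n_vertices) / params.n_vertices
        R = _outer_radius(theta, lumen_r, params, z_bump)
        outer = center + np.column_stack([R * np.cos(theta), R * np.sin(theta)])
        return CrossSection(
            slice_index=slice_index,
            lumen=Contour(_circle(center, lumen_r, params.n_vertices), "lumen"),
            outer_wall=Contour(outer, "outer_wall"),
            slice_spacing=params.slice_spacing,
        )

    r0 = params.lumen_radius
    proximal = _section(0, r0, 0.0)
    distal = _section(nz - 1, r0, 0.0)
    plaque_sections = tuple(
        _section(j + 2, lumen_radii[j], z_bumps[j]) for j in range(L)
    )
    stenotic = plaque_sections[stenotic_local]
    gap_sections = (_section(1, r0, 0.0), _section(nz - 2, r0, 0.0))

    # ---- intensity volumes ----------------------------------------------
    t2 = np.full((nz, G, G), BACKGROUND_SIGNAL)
    t1_pre = np.full((nz, G, G), BACKGROUND_SIGNAL)
    xs = np.arange(G) * sp
    gx, gy = np.meshgrid(xs, xs)  # gx: x per column, gy: y per row

    all_sections = (proximal, distal) + plaque_sections + gap_sections
    for section in all_sections:
        z = section.slice_index
        lumen_mask = shapely.contains_xy(
            section.lumen.polygon, gx.ravel(), gy.ravel()
        ).reshape(G, G)
        idx = rasterize_wall_roi(section, (G, G), sp)
        t2[z][lumen_mask] = LUMEN_SIGNAL
        t1_pre[z][lumen_mask] = LUMEN_SIGNAL
        t2[z, idx[:, 0], idx[:, 1]] = 90.0
        t1_pre[z, idx[:, 0], idx[:, 1]] = params.wall_signal_mean + \
            rng.normal(0.0, params.noise_sd, size=len(idx))

    # reference ROIs: constant blocks clear of the vessel
    gm_block = np.array(
        [(z, r, c) for z in range(nz) for r in range(2, 5) for c in range(2, 5)]
    )
    muscle_block = np.array(
        [(z, r, c) for z in range(nz) for r in range(2, 5)
         for c in range(G - 5, G - 2)]
    )
    for vol in (t2, t1_pre):
        vol[gm_block[:, 0], gm_block[:, 1], gm_block[:, 2]] = GM_SIGNAL
        vol[muscle_block[:, 0], muscle_block[:, 1], muscle_block[:, 2]] = \
            MUSCLE_SIGNAL

    # IPH hot spot: a small connected mid-wall block at the crescent peak
    if params.iph:
        idx = rasterize_wall_roi(stenotic, (G, G), sp)
        mid_wall_r = lumen_radii[stenotic_local] + (
            params.base_wall_thickness + params.plaque_thickness
        ) / 2.0
        target = center + mid_wall_r * np.array(
            [np.cos(params.plaque_center_angle), np.sin(params.plaque_center_angle)]
        )
        xy = np.column_stack([idx[:, 1] * sp, idx[:, 0] * sp])
        seed_voxel = idx[np.argmin(np.linalg.norm(xy - target, axis=1))]
        z = stenotic.slice_index
        in_block = (
            (np.abs(idx[:, 0] - seed_voxel[0]) <= 1)
            & (np.abs(idx[:, 1] - seed_voxel[1]) <= 1)
        )
        hot = idx[in_block]
        t1_pre[z, hot[:, 0], hot[:, 1]] = IPH_FACTOR * MUSCLE_SIGNAL

    # post-contrast: wall voxels gain the constructed enhancement factor
    t1_post = t1_pre.copy()
    factor = 1.0 + params.enhancement_pct / 100.0
    for section in all_sections:
        z = section.slice_index
        idx = rasterize_wall_roi(section, (G, G), sp)
        t1_post[z, idx[:, 0], idx[:, 1]] = (
            t1_pre[z, idx[:, 0], idx[:, 1]] * factor
            + rng.normal(0.0, params.noise_sd, size=len(idx))
        )

    stack = LesionStack(
        stenotic=stenotic,
        proximal_ref=proximal,
        distal_ref=distal,
        whole_plaque=plaque_sections,
        volumes={"t2": t2, "t1_pre": t1_pre, "t1_post": t1_post},
        gray_matter_roi=gm_block,
        muscle_roi=muscle_block,
        voxel_spacing=sp,
    )
    truth = _dense_ground_truth(params, z_bumps, lumen_radii, stenotic_local)
    return stack, truth


# --------------------------------------------------------------------------
# second reader
# --------------------------------------------------------------------------

@dataclass
class ReaderNoiseSpec:
    """Measurement noise of a simulated second reader.

    Contour error is a radial Gaussian field with marginal standard
    deviation ``contour_sd`` built from low-order Fourier harmonics —
    human tracing error is smooth along the boundary, not independent
    per vertex.
    """

    contour_sd: float = 0.05    # radial contour perturbation, mm
    intensity_sd: float = 0.0   # intensity re-measurement noise, a.u.
    n_harmonics: int = 4        # highest angular order of the error field
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.contour_sd < 0 or self.intensity_sd < 0:
            raise SpecError("noise sds must be >= 0")
        if self.n_harmonics < 0:
            raise SpecError("n_harmonics must be >= 0")


def _perturb_contour(
    contour: Contour, sd: float, n_harmonics: int, rng: np.random.Generator
) -> Contour:
    v = contour.vertices
    centroid = v.mean(axis=0)
    rel = v - centroid
    radii = np.linalg.norm(rel, axis=1)
    units = rel / radii[:, None]
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    # band-limited radial Gaussian field, Var = sd^2 at every angle
    m = n_harmonics
    coef = rng.standard_normal(2 * m + 1)
    eps = coef[0] * np.ones_like(theta)
    for k in range(1, m + 1):
        eps += coef[2 * k - 1] * np.cos(k * theta) \
            + coef[2 * k] * np.sin(k * theta)
    eps *= sd / np.sqrt(m + 1)
    return Contour(centroid + (radii + eps)[:, None] * units,
                   label=contour.label)


def simulate_second_reader(
    stack: LesionStack, noise: ReaderNoiseSpec
) -> LesionStack:
    """Re-derive a lesion stack as a noisy second reader would draw it.

    A zero-noise spec returns a stack with identical measurements.
    Perturbations producing invalid contour nesting are resampled up to
    ``noise.max_retries`` times before raising.
    """
    rng = np.random.default_rng(noise.seed)
    if noise.contour_sd == 0 and noise.intensity_sd == 0:
        return stack

    def _perturb_section(section: CrossSection) -> CrossSection:
        for _ in range(noise.max_retries):
            try:
                return CrossSection(
                    slice_index=section.slice_index,
                    lumen=_perturb_contour(
                        section.lumen, noise.contour_sd,
                        noise.n_harmonics, rng,
                    ),
                    outer_wall=_perturb_contour(
                        section.outer_wall, noise.contour_sd,
                        noise.n_harmonics, rng,
                    ),
                    slice_spacing=section.slice_spacing,
                )
            except GeometryError:
                continue
        raise GeometryError(
            f"slice {section.slice_index}: could not produce a valid "
            f"perturbed section in {noise.max_retries} tries"
        )

    by_index = {s.slice_index: _perturb_section(s) for s in stack.whole_plaque}
    volumes = stack.volumes
    if noise.intensity_sd > 0:
        volumes = {
            k: v + rng.normal(0.0, noise.intensity_sd, size=v.shape)
            for k, v in volumes.items()
        }
    return dataclasses.replace(
        stack,
        stenotic=by_index[stack.stenotic.slice_index],
        proximal_ref=_perturb_section(stack.proximal_ref),
        distal_ref=_perturb_section(stack.distal_ref),
        whole_plaque=tuple(by_index[s.slice_index] for s in stack.whole_plaque),
        volumes=volumes,
    )
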
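"""Synthetic ground truth for the OCTA pipeline, in two tiers.

**Image tier** — vascular-network phantoms: trees of sine-perturbed
branches grown from roots around the grid center, rasterized at a known
vessel width.  The generator records each branch's analytic arc length
and chord, so measured vessel density and tortuosity can be validated
against geometric ground truth.

**Cohort tier** — per-eye metric tables with the statistical structure
reported for anterior ischemic optic neuropathy: five groups (arteritic
AAION, non-arteritic NAION, their contralateral eyes, healthy controls),
group-level VD/VT means and SDs, and a focal-VD / global-VT quadrant
defect pattern (diseased eyes lose VD only in affected quadrants but VT
everywhere, with affected quadrants worst).  Visual-field defect flags
concord with the affected quadrants up to a configurable flip
probability.  The absolute VT scale of the clinical tables is treated as
a cohort-level parameter only: it comes from a proprietary analysis
script whose formula is not reconstructable, so image-tier validation
never targets those magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .angio_io import (
    GROUPS,
    QUADRANT_PLEXUSES,
    QUADRANTS,
    AngioImage,
    EyeRecord,
    ValidationError,
    map_vf_defects_to_retinal_quadrants,
)
from .vessel_metrics import BinaryMap

__all__ = [
    "NetworkParams",
    "NoiseParams",
    "CohortParams",
    "TruthBranch",
    "generate_network",
    "render_angio",
    "generate_cohort",
    "default_cohort_params",
]


# ---------------------------------------------------------------------------
# Image tier
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """Geometry of a synthetic vascular-network phantom."""

    image_size_px: int = 256
    n_roots: int = 8
    branching_depth: int = 3
    branch_length_mean_px: float = 45.0
    branch_length_sd_px: float = 10.0
    tortuosity_amplitude_px: float = 4.0
    tortuosity_wavelength_px: float = 60.0
    vessel_width_px: int = 3
    # realistic peripapillary angiograms occupy roughly a third of the field
    target_vessel_fraction: float | None = 0.35

    def __post_init__(self) -> None:
        if self.image_size_px <= 0 or self.n_roots <= 0 or self.branching_depth < 1:
            raise ValidationError("image size, roots and depth must be positive")
        if self.vessel_width_px < 1 or self.tortuosity_amplitude_px < 0:
            raise ValidationError("width >= 1 and amplitude >= 0 required")
        if self.target_vessel_fraction is not None and self.target_vessel_fraction > 0.9:
            raise ValidationError("target_vessel_fraction > 0.9 is infeasible")


@dataclass
class NoiseParams:
    """Additive imaging noise for rendering phantoms as angiograms."""

    background_level: float = 0.2
    speckle_sd: float = 0.05
    blur_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.background_level < 1 or self.speckle_sd < 0 or self.blur_sigma_px < 0:
            raise ValidationError("invalid noise parameters")
        if self.background_level + 3 * self.speckle_sd >= 1:
            raise ValidationError("vessel signal not separable from background")


@dataclass
class TruthBranch:
    """Ground truth for one continuous branch curve."""

    points: np.ndarray  # (n, 2) float (row, col) samples along the curve
    arc_length: float
    chord_length: float
    depth: int

    @property
    def tortuosity(self) -> float:
        return self.arc_length / self.chord_length


def _sine_branch(
    start: np.ndarray,
    direction: float,
    length: float,
    amplitude: float,
    wavelength: float,
    n_samples: int = 400,
) -> TruthBranch:
    """A straight segment perturbed by a perpendicular sine wave.

    The sine vanishes at both ends (integer half-periods are fitted into
    the branch length) so consecutive branches connect continuously.  Arc
    length is computed by dense polyline quadrature on the analytic curve.
    """
    t = np.linspace(0.0, length, n_samples)
    k_half = max(1, round(2.0 * length / wavelength))  # half-periods fitted
    phase = k_half * math.pi * t / length
    offset = amplitude * np.sin(phase)
    u = np.array([math.cos(direction), math.sin(direction)])  # (drow, dcol)
    v = np.array([-u[1], u[0]])
    pts = start[None, :] + t[:, None] * u[None, :] + offset[:, None] * v[None, :]
    seg = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
    return TruthBranch(
        points=pts,
        arc_length=float(seg.sum()),
        chord_length=float(np.hypot(*(pts[-1] - pts[0]))),
        depth=0,
    )


def _grow_tree(
    rng: np.random.Generator, params: NetworkParams, root: np.ndarray, heading: float
) -> list[TruthBranch]:
    branches: list[TruthBranch] = []
    stack = [(root, heading, 1)]
    while stack:
        start, direction, depth = stack.pop()
        length = max(
            10.0, rng.normal(params.branch_length_mean_px, params.branch_length_sd_px)
        )
        br = _sine_branch(
            start, direction, length,
            params.tortuosity_amplitude_px, params.tortuosity_wavelength_px,
        )
        br.depth = depth
        branches.append(br)
        if depth < params.branching_depth:
            end = br.points[-1]
            for sign in (-1.0, 1.0):
                child_dir = direction + sign * rng.uniform(0.35, 0.75)
                stack.append((end.copy(), child_dir, depth + 1))
    return branches


def _rasterize(
    branches: Sequence[TruthBranch], size: int, width_px: int
) -> np.ndarray:
    canvas = np.zeros((size, size), dtype=bool)
    for br in branches:
        ij = np.round(br.points).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
        canvas[ij[ok, 0], ij[ok, 1]] = True
    if width_px > 1:
        r = width_px // 2
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        canvas = ndimage.binary_dilation(canvas, structure=(yy**2 + xx**2) <= r**2)
    return canvas


def generate_network(
    params: NetworkParams, seed: int
) -> tuple[BinaryMap, list[TruthBranch], float]:
    """Grow a synthetic vascular network with analytic ground truth.

    Returns the rasterized binary truth map, the list of continuous
    branch curves (each with exact arc and chord lengths), and the
    achieved vessel-pixel fraction.  Trees are grown from roots placed on
    a circle around the grid center and oriented outward; when
    ``target_vessel_fraction`` is set, trees are added until the fraction
    is reached (within 0.02).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    size = params.image_size_px
    center = np.array([size / 2.0, size / 2.0])
    radius = size * 0.12

    def new_tree(i: int) -> list[TruthBranch]:
        ang = rng.uniform(0, 2 * math.pi)
        root = center + radius * np.array([math.sin(ang), math.cos(ang)])
        return _grow_tree(rng, params, root, ang + rng.normal(0.0, 0.2))

    branches: list[TruthBranch] = []
    for i in range(params.n_roots):
        branches.extend(new_tree(i))
    truth = _rasterize(branches, size, params.vessel_width_px)

    if params.target_vessel_fraction is not None:
        target = params.target_vessel_fraction
        guard = 0
        while truth.mean() < target - 0.005 and guard < 500:
            branches.extend(new_tree(guard))
            truth = _rasterize(branches, size, params.vessel_width_px)
            guard += 1
        if truth.mean() < target - 0.02:
            raise ValidationError(
                f"could not reach vessel fraction {target}; got {truth.mean():.3f}"
            )
    return BinaryMap(truth, provenance="synthetic_truth"), branches, float(truth.mean())


def render_angio(
    truth: BinaryMap,
    noise: NoiseParams,
    seed: int,
    scan_size_mm: float = 4.5,
    plexus: str = "RPC",
    laterality: str = "OD",
    patient_id: str = "synthetic",
    group: str = "CONTROL",
    quality_index: int = 90,
) -> AngioImage:
    """Render a truth map as a noisy grayscale angiogram.

    Vessel pixels start at intensity 1.0 and background at
    ``background_level``; Gaussian speckle and optional blur are applied
    and the result is clipped to [0, 1].  Deterministic per seed.
    """
    if not truth.pixels.any():
        raise ValidationError("truth map has no vessel pixels")
    rng = np.random.default_rng(seed)
    img = np.where(truth.pixels, 1.0, noise.background_level)
    if noise.speckle_sd > 0:
        img = img + rng.normal(0.0, noise.speckle_sd, img.shape)
    if noise.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, noise.blur_sigma_px)
    img = np.clip(img, 0.0, 1.0)
    h, w = img.shape
    return AngioImage(
        pixels=img,
        scan_size_mm=scan_size_mm,
        plexus=plexus,
        laterality=laterality,
        disc_center=(h // 2, w // 2),
        quality_index=quality_index,
        patient_id=patient_id,
        group=group,
    )


# ---------------------------------------------------------------------------
# Cohort tier
# ---------------------------------------------------------------------------

# Group-level metric means and SDs (clinical study values).  Keys are the
# flattened metric names of the EyeRecord table.
GROUP_METRICS: dict[str, dict[str, tuple[float, float]]] = {
    "AAION": {
        "vd_RPC": (0.37, 0.01), "vd_SCP": (0.36, 0.02), "vd_DCP": (0.28, 0.01),
        "vd_CC": (0.47, 0.03),
        "vt_RPC": (4.56, 0.38), "vt_SCP": (3.81, 0.38), "vt_DCP": (4.43, 0.30),
    },
    "NAION": {
        "vd_RPC": (0.40, 0.01), "vd_SCP": (0.39, 0.02), "vd_DCP": (0.28, 0.01),
        "vd_CC": (0.48, 0.03),
        "vt_RPC": (5.11, 0.42), "vt_SCP": (4.27, 0.42), "vt_DCP": (4.97, 0.34),
    },
    "CONTRA_AAION": {
        "vd_RPC": (0.44, 0.01), "vd_SCP": (0.42, 0.01), "vd_DCP": (0.39, 0.01),
        "vd_CC": (0.52, 0.03),
        "vt_RPC": (7.77, 0.23), "vt_SCP": (8.36, 0.30), "vt_DCP": (6.94, 0.24),
    },
    "CONTRA_NAION": {
        "vd_RPC": (0.44, 0.00), "vd_SCP": (0.42, 0.01), "vd_DCP": (0.39, 0.02),
        "vd_CC": (0.53, 0.02),
        "vt_RPC": (7.61, 0.20), "vt_SCP": (8.37, 0.42), "vt_DCP": (7.08, 0.25),
    },
    "CONTROL": {
        "vd_RPC": (0.45, 0.01), "vd_SCP": (0.43, 0.01), "vd_DCP": (0.40, 0.02),
        "vd_CC": (0.55, 0.03),
        "vt_RPC": (7.71, 0.39), "vt_SCP": (8.43, 0.26), "vt_DCP": (7.06, 0.23),
    },
}

# Quadrant-level sub-analysis distributions: (mean, sd) per stratum.
# Diseased eyes lose VD focally (unaffected quadrants near normal) but VT
# globally (unaffected quadrants already reduced).
QUADRANT_METRICS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "AAION": {
        "affected": {
            "vd_RPC": (0.29, 0.04), "vd_SCP": (0.27, 0.04),
            "vt_RPC": (3.8, 0.4), "vt_SCP": (2.8, 0.8),
        },
        "unaffected": {
            "vd_RPC": (0.44, 0.01), "vd_SCP": (0.44, 0.02),
            "vt_RPC": (4.6, 0.8), "vt_SCP": (4.8, 0.8),
        },
    },
    "NAION": {
        "affected": {
            "vd_RPC": (0.36, 0.01), "vd_SCP": (0.33, 0.04),
            "vt_RPC": (4.6, 0.7), "vt_SCP": (3.4, 0.5),
        },
        "unaffected": {
            "vd_RPC": (0.44, 0.01), "vd_SCP": (0.43, 0.01),
            "vt_RPC": (5.5, 0.7), "vt_SCP": (5.2, 0.8),
        },
    },
}

# Global RNFL thickness (µm) per group; quadrant-level focal model below.
RNFL_GLOBAL: dict[str, tuple[float, float]] = {
    "AAION": (74.0, 15.0),
    "NAION": (85.0, 16.0),
    "CONTRA_AAION": (115.0, 10.0),
    "CONTRA_NAION": (115.0, 10.0),
    "CONTROL": (115.0, 10.0),
}
RNFL_QUADRANT = {
    "normal": (105.0, 10.0),
    "affected": {"AAION": (65.0, 12.0), "NAION": (75.0, 12.0)},
}

BCVA_LOGMAR: dict[str, tuple[float, float]] = {
    "AAION": (0.6, 0.2),
    "NAION": (0.3, 0.3),
    "CONTRA_AAION": (0.0, 0.0),
    "CONTRA_NAION": (0.0, 0.0),
    "CONTROL": (0.0, 0.0),
}

SD_FLOOR = 0.005  # printed SDs are rounded to 2 decimals; 0.00 means < 0.005
VD_WITHIN_EYE_SD = 0.02  # quadrant-to-quadrant VD variation within one eye


@dataclass
class CohortParams:
    """Parameters of the synthetic per-eye cohort."""

    group_metrics: dict = field(default_factory=lambda: GROUP_METRICS)
    quadrant_metrics: dict = field(default_factory=lambda: QUADRANT_METRICS)
    rnfl_global: dict = field(default_factory=lambda: RNFL_GLOBAL)
    bcva: dict = field(default_factory=lambda: BCVA_LOGMAR)
    affected_quadrant_counts: dict = field(
        default_factory=lambda: {"AAION": (1, 2), "NAION": (1, 1)}
    )
    vf_concordance: float = 0.95
    n_per_group: int = 15
    vd_within_eye_sd: float = VD_WITHIN_EYE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.vf_concordance <= 1:
            raise ValidationError("vf_concordance must be in [0, 1]")
        if self.n_per_group < 2:
            raise ValidationError("statistics need n_per_group >= 2")


def default_cohort_params(seed: int = 0, n_per_group: int = 15) -> CohortParams:
    """Cohort defaults from the study's summary tables (15 eyes/group)."""
    return CohortParams(seed=seed, n_per_group=n_per_group)


def _sd(sd: float) -> float:
    return max(sd, SD_FLOOR)


def _trunc01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def generate_cohort(params: CohortParams | None = None) -> list[EyeRecord]:
    """Draw a synthetic five-group cohort of EyeRecords.

    Group-level metrics are Normal(mean, SD) draws (VD truncated to
    [0, 1]).  Diseased eyes receive 1–2 affected retinal quadrants;
    quadrant metrics use a hierarchical model: an eye-level stratum mean
    drawn from the configured (mean, SD), plus independent within-eye
    quadrant noise (SD ``vd_within_eye_sd`` for VD, the stratum SD for
    VT), so that per-eye means keep the configured between-eye SD.
    Visual-field flags are the affected set mapped to field space, each
    flag flipped independently with probability 1 − vf_concordance.
    Deterministic per (params, seed).
    """
    params = params or default_cohort_params()
    rng = np.random.default_rng(params.seed)
    records: list[EyeRecord] = []
    for group in GROUPS:
        gm = params.group_metrics[group]
        for i in range(params.n_per_group):
            rec = _draw_eye(rng, params, group, i)
            records.append(rec)
    return records


def _draw_eye(
    rng: np.random.Generator, params: CohortParams, group: str, idx: int
) -> EyeRecord:
    gm = params.group_metrics[group]
    diseased = group in ("AAION", "NAION")
    laterality = "OD" if idx % 2 == 0 else "OS"

    vd = {p: _trunc01(rng.normal(*_mean_sd(gm[f"vd_{p}"]))) for p in ("RPC", "SCP", "DCP", "CC")}
    vt = {p: max(rng.normal(*_mean_sd(gm[f"vt_{p}"])), 1.0) for p in ("RPC", "SCP", "DCP")}

    if diseased:
        lo, hi = params.affected_quadrant_counts[group]
        n_aff = int(rng.integers(lo, hi + 1))
        affected = set(rng.choice(len(QUADRANTS), size=n_aff, replace=False))
        affected = {QUADRANTS[k] for k in affected}
    else:
        affected = set()

    quadrant_vd: dict[tuple[str, str], float] = {}
    quadrant_vt: dict[tuple[str, str], float] = {}
    for plexus in QUADRANT_PLEXUSES:
        if diseased:
            qm = params.quadrant_metrics[group]
            strata = {
                True: (qm["affected"][f"vd_{plexus}"], qm["affected"][f"vt_{plexus}"]),
                False: (qm["unaffected"][f"vd_{plexus}"], qm["unaffected"][f"vt_{plexus}"]),
            }
        else:
            base = (
                (gm[f"vd_{plexus}"], gm[f"vt_{plexus}"])
            )
            strata = {False: base, True: base}
        # eye-level stratum means, then within-eye quadrant noise
        lvl = {
            aff: (
                rng.normal(*_mean_sd(vdm)),
                rng.normal(*_mean_sd(vtm)),
            )
            for aff, (vdm, vtm) in strata.items()
        }
        for q in QUADRANTS:
            aff = q in affected
            vdl, vtl = lvl[aff]
            vt_sd = _sd(strata[aff][1][1])
            quadrant_vd[(plexus, q)] = _trunc01(
                vdl + rng.normal(0.0, params.vd_within_eye_sd)
            )
            quadrant_vt[(plexus, q)] = max(vtl + rng.normal(0.0, vt_sd), 1.0)

    # RNFL: focal thinning in affected quadrants, near-normal elsewhere
    rnfl = {}
    for q in QUADRANTS:
        if q in affected:
            mu, sd = RNFL_QUADRANT["affected"][group]
        else:
            mu, sd = RNFL_QUADRANT["normal"]
        rnfl[q] = max(rng.normal(mu, sd), 1.0)
    rnfl["global"] = max(rng.normal(*_mean_sd(params.rnfl_global[group])), 1.0)

    # VF flags: affected retinal set mapped to field space, then flipped
    retinal_flags = {q: q in affected for q in QUADRANTS}
    vf = map_vf_defects_to_retinal_quadrants(retinal_flags, laterality)  # involution
    if diseased:
        vf = {
            q: (not v) if rng.random() > params.vf_concordance else v
            for q, v in vf.items()
        }
    else:
        vf = {q: False for q in QUADRANTS}

    mu_b, sd_b = params.bcva[group]
    bcva = max(rng.normal(mu_b, sd_b), 0.0) if sd_b > 0 else mu_b

    return EyeRecord(
        patient_id=f"{group}_{idx:03d}",
        group=group,
        laterality=laterality,
        quality_index=int(rng.integers(75, 100)),
        bcva_logmar=bcva,
        rnfl_um=rnfl,
        vf_defect=vf,
        vd=vd,
        vt=vt,
        quadrant_vd=quadrant_vd,
        quadrant_vt=quadrant_vt,
    )


def _mean_sd(ms: tuple[float, float]) -> tuple[float, float]:
    return ms[0], _sd(ms[1])
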
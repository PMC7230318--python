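"""Cohort statistics for the quantitative OCTA analysis.

Implements the study's statistical battery: one-way ANOVA with
Bonferroni-corrected pairwise comparisons of the group-level VD/VT
metrics, normative 2-SD impairment classification of quadrant metrics,
the affected/unaffected-quadrant sub-analysis, and Kendall tau-b
concordance between visual-field defects and quadrant impairment.

The pairwise test defaults to Welch's t (group SDs differ several-fold);
an SPSS-style pooled-variance Bonferroni post hoc (t on the ANOVA MSW
with N − k degrees of freedom) is available via ``method="pooled"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .angio_io import (
    GROUPS,
    QUADRANT_PLEXUSES,
    QUADRANTS,
    EyeRecord,
    ValidationError,
    map_vf_defects_to_retinal_quadrants,
)

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "ConcordanceResult",
    "GroupComparisonReport",
    "TABLE1_PAIRS",
    "TABLE2_COMPARISONS",
    "one_way_anova",
    "pairwise_bonferroni",
    "normative_limits",
    "classify_impaired_quadrants",
    "kendall_tau",
    "vf_concordance_analysis",
    "subgroup_report",
]

GROUP_METRIC_NAMES = (
    "vd_RPC", "vd_SCP", "vd_DCP", "vd_CC", "vt_RPC", "vt_SCP", "vt_DCP",
)
QUADRANT_METRIC_NAMES = ("vd_RPC", "vd_SCP", "vt_RPC", "vt_SCP", "rnfl")

# The seven pairwise comparisons of the group-level table.
TABLE1_PAIRS = (
    ("AAION", "NAION"),
    ("AAION", "CONTROL"),
    ("NAION", "CONTROL"),
    ("AAION", "CONTRA_AAION"),
    ("NAION", "CONTRA_NAION"),
    ("CONTRA_AAION", "CONTROL"),
    ("CONTRA_NAION", "CONTROL"),
)

# The eight comparison rows of the quadrant sub-analysis table:
# (group-or-pair, stratum_a, stratum_b)
TABLE2_COMPARISONS = (
    ("AAION", "affected", "unaffected"),
    ("AAION", "affected", "controls"),
    ("AAION", "unaffected", "controls"),
    ("NAION", "affected", "unaffected"),
    ("NAION", "affected", "controls"),
    ("NAION", "unaffected", "controls"),
    ("AAION_vs_NAION", "affected", "affected"),
    ("AAION_vs_NAION", "unaffected", "unaffected"),
)


class DegenerateStatisticError(ValueError):
    """The requested statistic is undefined on this input."""


@dataclass
class GroupSummary:
    group: str
    metric: str
    n: int
    mean: float
    sd: float


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    metric: str
    raw_p: float
    adjusted_p: float
    significant_at: float = 0.05

    @property
    def significant(self) -> bool:
        return self.adjusted_p < self.significant_at


@dataclass
class ConcordanceResult:
    pair: str
    tau: float
    p: float
    n_pairs: int


@dataclass
class GroupComparisonReport:
    """Group-level and quadrant-level summary of a cohort analysis."""

    summaries: list[GroupSummary]
    pairwise: list[PairwiseComparison]
    quadrant_strata: pd.DataFrame  # parameter x stratum means +/- SD
    quadrant_pairwise: list[PairwiseComparison]
    concordance: list[ConcordanceResult]

    def to_dict(self) -> dict:
        return {
            "summaries": [vars(s) for s in self.summaries],
            "pairwise": [
                {k: v for k, v in vars(p).items()} for p in self.pairwise
            ],
            "quadrant_strata": self.quadrant_strata.to_dict(orient="records"),
            "quadrant_pairwise": [vars(p) for p in self.quadrant_pairwise],
            "concordance": [vars(c) for c in self.concordance],
        }

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=_json_default)
        table1 = pd.DataFrame([vars(s) for s in self.summaries]).pivot(
            index="group", columns="metric", values="mean"
        )
        sds = pd.DataFrame([vars(s) for s in self.summaries]).pivot(
            index="group", columns="metric", values="sd"
        )
        styled = table1.round(4).astype(str) + " ± " + sds.round(4).astype(str)
        pw = pd.DataFrame([vars(p) for p in self.pairwise])
        pw["stars"] = pw["adjusted_p"].map(_stars)
        pwp = pw.pivot(index=["group_a", "group_b"], columns="metric", values="adjusted_p")
        pd.concat([styled, pwp.map(lambda p: format(p, ".4g"))]).to_csv(
            out_dir / "table1_style.csv"
        )
        qt = self.quadrant_strata.copy()
        qpw = pd.DataFrame([vars(p) for p in self.quadrant_pairwise])
        qpw["stars"] = qpw["adjusted_p"].map(_stars)
        qt.to_csv(out_dir / "table2_style.csv", index=False)
        qpw.to_csv(out_dir / "table2_pvalues.csv", index=False, float_format="%.4g")


def _stars(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across k groups.

    F = MSB/MSW with (k − 1, N − k) degrees of freedom.  Raises
    :class:`DegenerateStatisticError` when every value is identical
    (within-group variance zero).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateStatisticError("all values identical; F undefined")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def pairwise_bonferroni(
    groups: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] = TABLE1_PAIRS,
    alpha: float = 0.05,
    metric: str = "",
    method: str = "welch",
) -> list[PairwiseComparison]:
    """Bonferroni-corrected pairwise two-sample tests.

    ``method="welch"`` runs Welch's unequal-variance t per pair;
    ``method="pooled"`` runs the SPSS-style post hoc t on the pooled
    within-group variance of *all* supplied groups (df = N − k).  The
    adjusted p is min(1, raw_p × m) with m = number of pairs tested.
    """
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValidationError(f"unknown group label in pair ({a}, {b})")
    m = len(pairs)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if method == "pooled":
        k = len(arrays)
        n_total = sum(len(a) for a in arrays.values())
        msw = sum((len(a) - 1) * np.var(a, ddof=1) for a in arrays.values()) / (
            n_total - k
        )
    out = []
    for a, b in pairs:
        if method == "welch":
            raw = float(stats.ttest_ind(arrays[a], arrays[b], equal_var=False).pvalue)
        elif method == "pooled":
            se = math.sqrt(msw * (1 / len(arrays[a]) + 1 / len(arrays[b])))
            if se == 0:
                raise DegenerateStatisticError("zero pooled variance")
            t = (arrays[a].mean() - arrays[b].mean()) / se
            raw = float(2 * stats.t.sf(abs(t), n_total - k))
        else:
            raise ValidationError(f"unknown method {method!r}")
        out.append(
            PairwiseComparison(
                group_a=a, group_b=b, metric=metric,
                raw_p=raw, adjusted_p=min(1.0, raw * m), significant_at=alpha,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Normative classification
# ---------------------------------------------------------------------------

def _quadrant_value(rec: EyeRecord, metric: str, q: str) -> float:
    if metric == "rnfl":
        return rec.rnfl_um[q]
    kind, plexus = metric.split("_")
    table = rec.quadrant_vd if kind == "vd" else rec.quadrant_vt
    return table[(plexus, q)]


def normative_limits(
    controls: Sequence[EyeRecord], k_sd: float = 2.0
) -> dict[str, dict[str, float]]:
    """Lower normative limit (control mean − k·SD) per metric and quadrant.

    Covers quadrant-level VD and VT for RPC/SCP plus RNFL thickness;
    needs at least 5 control eyes.
    """
    if len(controls) < 5:
        raise ValidationError("need >= 5 control eyes for normative limits")
    limits: dict[str, dict[str, float]] = {}
    for metric in QUADRANT_METRIC_NAMES:
        limits[metric] = {}
        for q in QUADRANTS:
            try:
                vals = np.array([_quadrant_value(r, metric, q) for r in controls])
            except KeyError as exc:
                raise ValidationError(f"metric {metric!r} missing from controls") from exc
            limits[metric][q] = float(vals.mean() - k_sd * vals.std(ddof=1))
    return limits


def classify_impaired_quadrants(
    record: EyeRecord, limits: Mapping[str, Mapping[str, float]]
) -> dict[tuple[str, str], bool]:
    """Flag (metric, quadrant) impaired iff value < the normative limit.

    The comparison is strict; a value exactly at the limit is normal.
    """
    out = {}
    for metric, per_q in limits.items():
        for q, lim in per_q.items():
            out[(metric, q)] = bool(_quadrant_value(record, metric, q) < lim)
    return out


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def kendall_tau(x: Sequence, y: Sequence, pair: str = "") -> ConcordanceResult:
    """Kendall tau-b (tie-corrected) with a two-sided p-value.

    Binary quadrant indicators are tie-heavy, so the b variant is used.
    SciPy enumerates the exact null for small tie-free samples and falls
    back to the normal approximation otherwise.  Zero variance in either
    vector leaves tau undefined and raises.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y) or len(x) < 2:
        raise ValidationError("x and y must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("zero variance; tau undefined")
    res = stats.kendalltau(x, y)
    return ConcordanceResult(pair=pair, tau=float(res.statistic), p=float(res.pvalue), n_pairs=len(x))


def vf_concordance_analysis(
    records: Sequence[EyeRecord],
    limits: Mapping[str, Mapping[str, float]],
    metrics: Sequence[str] = ("rnfl", "vd_RPC", "vt_RPC"),
) -> list[ConcordanceResult]:
    """Pooled per-quadrant concordance between VF defects and impairment.

    For every diseased eye (AAION/NAION) and each of its four quadrants,
    pairs the retina-mapped visual-field defect flag with the normative
    impairment flag, pools pairs across eyes, and reports Kendall tau-b
    per metric.  A metric whose impairment flags have no variance (e.g.
    tortuosity reduced in every quadrant of every eye) yields tau = NaN.
    """
    diseased = [r for r in records if r.group in ("AAION", "NAION")]
    if not diseased:
        raise ValidationError("no diseased eyes with VF flags")
    results = []
    for metric in metrics:
        xs, ys = [], []
        for rec in diseased:
            retinal_vf = map_vf_defects_to_retinal_quadrants(rec.vf_defect, rec.laterality)
            flags = classify_impaired_quadrants(rec, {metric: limits[metric]})
            for q in QUADRANTS:
                xs.append(int(retinal_vf[q]))
                ys.append(int(flags[(metric, q)]))
        try:
            res = kendall_tau(xs, ys, pair=f"VF_vs_{metric}")
        except DegenerateStatisticError:
            res = ConcordanceResult(
                pair=f"VF_vs_{metric}", tau=math.nan, p=math.nan, n_pairs=len(xs)
            )
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _stratum_eye_means(
    records: Sequence[EyeRecord], group: str, stratum: str, metric: str
) -> np.ndarray:
    """Per-eye mean of a quadrant metric over one stratum of quadrants.

    For diseased eyes the stratum is the eye's affected / unaffected
    visual-field quadrant set (mapped to retina); controls contribute all
    four quadrants.
    """
    vals = []
    for rec in records:
        if rec.group != group:
            continue
        if group == "CONTROL":
            qs = list(QUADRANTS)
        else:
            retinal = map_vf_defects_to_retinal_quadrants(rec.vf_defect, rec.laterality)
            qs = [q for q in QUADRANTS if retinal[q] == (stratum == "affected")]
        if qs:
            vals.append(float(np.mean([_quadrant_value(rec, metric, q) for q in qs])))
    return np.array(vals)


def subgroup_report(
    records: Sequence[EyeRecord],
    limits: Mapping[str, Mapping[str, float]] | None = None,
    alpha: float = 0.05,
    method: str = "welch",
) -> GroupComparisonReport:
    """Build the full group-level + quadrant-level comparison report.

    Group-level: means ± SD for every group × metric and the seven-pair
    Bonferroni battery per metric.  Quadrant-level: affected/unaffected
    stratum means for AAION/NAION vs controls with the eight comparison
    rows (Bonferroni family = 8 per metric, per-eye stratum means as the
    unit of analysis).  Also runs the VF concordance analysis.
    """
    present = {r.group for r in records}
    missing = set(GROUPS) - present
    if missing:
        raise ValidationError(f"missing groups: {sorted(missing)}")
    by_group = {g: [r for r in records if r.group == g] for g in GROUPS}

    summaries: list[GroupSummary] = []
    pairwise: list[PairwiseComparison] = []
    for metric in GROUP_METRIC_NAMES:
        samples = {
            g: np.array([_metric_value(r, metric) for r in by_group[g]]) for g in GROUPS
        }
        for g in GROUPS:
            summaries.append(
                GroupSummary(
                    group=g, metric=metric, n=len(samples[g]),
                    mean=float(samples[g].mean()), sd=float(samples[g].std(ddof=1)),
                )
            )
        pairwise.extend(
            pairwise_bonferroni(samples, TABLE1_PAIRS, alpha, metric, method)
        )

    # quadrant sub-analysis
    strata_rows = []
    quadrant_pairwise: list[PairwiseComparison] = []
    qmetrics = ("vd_RPC", "vd_SCP", "vt_RPC", "vt_SCP")
    strata_samples: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for metric in qmetrics:
        samples = {}
        for g in ("AAION", "NAION"):
            for s in ("affected", "unaffected"):
                samples[f"{g}:{s}"] = _stratum_eye_means(records, g, s, metric)
        samples["controls"] = _stratum_eye_means(records, "CONTROL", "all", metric)
        strata_samples[metric] = samples
        row = {"parameter": metric}
        for key, arr in samples.items():
            row[key] = f"{arr.mean():.4f} ± {arr.std(ddof=1):.4f}" if len(arr) > 1 else ""
        strata_rows.append(row)
        m = len(TABLE2_COMPARISONS)
        for who, sa, sb in TABLE2_COMPARISONS:
            if who == "AAION_vs_NAION":
                a, b = samples[f"AAION:{sa}"], samples[f"NAION:{sb}"]
                label_a, label_b = f"AAION:{sa}", f"NAION:{sb}"
            else:
                a = samples[f"{who}:{sa}"]
                b = samples[f"{who}:{sb}"] if sb != "controls" else samples["controls"]
                label_a, label_b = f"{who}:{sa}", f"{who}:{sb}" if sb != "controls" else "controls"
            raw = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            quadrant_pairwise.append(
                PairwiseComparison(
                    group_a=label_a, group_b=label_b, metric=metric,
                    raw_p=raw, adjusted_p=min(1.0, raw * m), significant_at=alpha,
                )
            )

    if limits is None:
        limits = normative_limits(by_group["CONTROL"])
    concordance = vf_concordance_analysis(records, limits)

    return GroupComparisonReport(
        summaries=summaries,
        pairwise=pairwise,
        quadrant_strata=pd.DataFrame(strata_rows),
        quadrant_pairwise=quadrant_pairwise,
        concordance=concordance,
    )


def _metric_value(rec: EyeRecord, metric: str) -> float:
    kind, plexus = metric.split("_")
    return rec.vd[plexus] if kind == "vd" else rec.vt[plexus]
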
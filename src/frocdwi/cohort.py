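"""Per-lesion summarisation and benign-vs-malignant cohort statistics.

The analysis mirrors the standard imaging-biomarker workflow: each
lesion is reduced to the arithmetic mean of every fitted parameter over
its ROI voxels; groups are compared with the Mann–Whitney U test;
diagnostic performance is quantified by the area under the ROC curve
with a DeLong 95% confidence interval; and per-parameter AUCs are
compared against the ADC reference with the paired DeLong test for
correlated ROC curves.  A size stratification (default 10 mm maximal
in-plane diameter) repeats the analysis in the small- and large-lesion
subgroups.

Orientation: diffusivity-like parameters score malignancy with LOWER
values (malignant lesions restrict diffusion).  Every ROC is
auto-oriented so AUC >= 0.5 and the direction is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .fitting import ParameterMaps

__all__ = [
    "MALIGNANT",
    "BENIGN",
    "PARAMETER_ORDER",
    "LesionRecord",
    "GroupComparison",
    "ROCResult",
    "AUCComparison",
    "CohortAnalysis",
    "summarize_lesion",
    "build_lesion_records",
    "group_compare",
    "roc_auc",
    "compare_aucs",
    "run_cohort_analysis",
]

MALIGNANT = "malignant"
BENIGN = "benign"

#: Canonical reporting order: FROC parameters, ADC reference, IVIM extension.
PARAMETER_ORDER = ("d_froc", "beta_froc", "mu_froc", "d_app", "d_ivim", "f_ivim")


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: identifier, histopathology label, maximal in-plane
    diameter (mm) and the per-parameter ROI-mean summaries."""

    lesion_id: int
    label: str
    size_mm: float
    summaries: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.label not in (MALIGNANT, BENIGN):
            raise AnalysisError(
                f"lesion {self.lesion_id}: label must be "
                f"'{MALIGNANT}' or '{BENIGN}', got {self.label!r}"
            )
        if not self.size_mm > 0:
            raise AnalysisError(
                f"lesion {self.lesion_id}: size_mm must be > 0, got {self.size_mm}"
            )
        for k, v in self.summaries.items():
            if not np.isfinite(v):
                raise AnalysisError(
                    f"lesion {self.lesion_id}: non-finite summary for {k!r}"
                )


def summarize_lesion(
    maps: ParameterMaps | Iterable[ParameterMaps],
    roi: np.ndarray,
    lesion_id: int,
) -> dict[str, float]:
    """Arithmetic mean of each parameter over the lesion's valid ROI voxels.

    ``roi`` is an integer label image; voxels with ``roi == lesion_id``
    and a valid fit contribute.  An empty or fully-invalid ROI raises an
    error naming the lesion.
    """
    if isinstance(maps, ParameterMaps):
        maps = [maps]
    roi = np.asarray(roi)
    in_roi = roi == lesion_id
    if not in_roi.any():
        raise AnalysisError(f"lesion {lesion_id}: ROI contains no voxels")
    out: dict[str, float] = {}
    for pm in maps:
        sel = in_roi & pm.valid
        if not sel.any():
            raise AnalysisError(
                f"lesion {lesion_id}: no valid {pm.model} fit inside the ROI"
            )
        for name, arr in pm.maps.items():
            out[name] = float(arr[sel].mean())
    return out


def build_lesion_records(
    maps: ParameterMaps | Iterable[ParameterMaps],
    roi: np.ndarray,
    lesion_table: pd.DataFrame,
) -> list[LesionRecord]:
    """Assemble LesionRecords from fitted maps plus a lesion table with
    columns ``lesion_id``, ``label``, ``size_mm``."""
    maps = [maps] if isinstance(maps, ParameterMaps) else list(maps)
    records = []
    for row in lesion_table.itertuples(index=False):
        summaries = summarize_lesion(maps, roi, int(row.lesion_id))
        records.append(
            LesionRecord(
                lesion_id=int(row.lesion_id),
                label=str(row.label),
                size_mm=float(row.size_mm),
                summaries=summaries,
            )
        )
    return records


def _split(values: Sequence[float], labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise AnalysisError(
            f"values ({values.shape}) and labels ({labels.shape}) differ in length"
        )
    pos = values[labels == MALIGNANT]
    neg = values[labels == BENIGN]
    return pos, neg


@dataclass(frozen=True)
class GroupComparison:
    """Mann–Whitney comparison of one parameter between groups, with the
    per-group median and quartiles (linear-interpolation percentiles)."""

    parameter: str
    n_malignant: int
    n_benign: int
    median_malignant: float
    q25_malignant: float
    q75_malignant: float
    median_benign: float
    q25_benign: float
    q75_benign: float
    U: float
    p: float
    method: str


def group_compare(
    values: Sequence[float],
    labels: Sequence[str],
    parameter: str = "",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test of malignant vs benign summaries.

    U is the statistic for the malignant group with midrank tie
    handling.  The p-value is exact when n1*n2 <= 400 and the data are
    tie-free, otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    pos, neg = _split(values, labels)
    if pos.size == 0 or neg.size == 0:
        raise AnalysisError(
            f"group_compare({parameter!r}): both groups must be non-empty "
            f"(malignant n={pos.size}, benign n={neg.size})"
        )
    pooled = np.concatenate([pos, neg])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pos.size * neg.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    q_pos = np.percentile(pos, [25, 50, 75])
    q_neg = np.percentile(neg, [25, 50, 75])
    return GroupComparison(
        parameter=parameter,
        n_malignant=int(pos.size),
        n_benign=int(neg.size),
        median_malignant=float(q_pos[1]),
        q25_malignant=float(q_pos[0]),
        q75_malignant=float(q_pos[2]),
        median_benign=float(q_neg[1]),
        q25_benign=float(q_neg[0]),
        q75_benign=float(q_neg[2]),
        U=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method=method,
    )


# ---------------------------------------------------------------------------
# DeLong machinery for AUC variance and paired AUC comparison.
# Structural components ("placement values") per class give the AUC as a
# two-sample U-statistic and its (co)variance estimate.
# ---------------------------------------------------------------------------

def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation placement values V10 (positives) and V01
    (negatives), computed via midranks."""
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)  # midranks over pooled sample
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def _auc_concordance(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the midrank Mann–Whitney estimator (ties count 1/2)."""
    return _placements(pos, neg)[0]


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong 95% CI.  ``orientation`` records which direction
    of the raw score indicates malignancy ('lower' for diffusivity-like
    parameters, 'higher' otherwise); the AUC refers to the oriented
    score and is always >= 0.5."""

    parameter: str
    auc: float
    ci_low: float
    ci_high: float
    orientation: str
    variance: float


def roc_auc(
    values: Sequence[float],
    labels: Sequence[str],
    parameter: str = "",
    orientation: str | None = None,
) -> ROCResult:
    """ROC area with DeLong 95% confidence interval.

    The AUC equals the midrank Mann–Whitney concordance estimator.  If
    ``orientation`` is None the sign is auto-selected so AUC >= 0.5 and
    the chosen direction is recorded.
    """
    pos, neg = _split(values, labels)
    if pos.size == 0 or neg.size == 0:
        raise AnalysisError(
            f"roc_auc({parameter!r}): both classes must be present"
        )
    if orientation is None:
        auc_higher = _auc_concordance(pos, neg)
        orientation = "higher" if auc_higher >= 0.5 else "lower"
    if orientation not in ("higher", "lower"):
        raise AnalysisError(f"orientation must be 'higher' or 'lower', got {orientation!r}")
    sign = 1.0 if orientation == "higher" else -1.0
    auc, v10, v01 = _placements(sign * pos, sign * neg)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    half = 1.959963984540054 * np.sqrt(var)
    return ROCResult(
        parameter=parameter,
        auc=float(auc),
        ci_low=float(max(0.0, min(auc - half, auc))),
        ci_high=float(min(1.0, max(auc + half, auc))),
        orientation=orientation,
        variance=float(var),
    )


@dataclass(frozen=True)
class AUCComparison:
    """Paired comparison of two ROC curves on the same lesions."""

    parameter_a: str
    parameter_b: str
    auc_a: float
    auc_b: float
    area_difference: float
    p: float
    method: str


def compare_aucs(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: Sequence[str],
    parameter_a: str = "A",
    parameter_b: str = "B",
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCComparison:
    """Two-sided paired test of AUC_A - AUC_B for correlated ROC curves.

    Both score vectors must be defined on the same lesions.  Each score
    is auto-oriented (AUC >= 0.5) before the comparison, matching how
    the individual ROC curves are reported.  ``method`` is 'delong'
    (default) or 'bootstrap' (stratified lesion resampling, intended for
    tiny subgroups where the DeLong variance is fragile).
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    labels = np.asarray(labels)
    if not (values_a.shape == values_b.shape == labels.shape):
        raise AnalysisError(
            "compare_aucs: score vectors and labels must be paired "
            f"(lengths {values_a.size}, {values_b.size}, {labels.size})"
        )
    ra = roc_auc(values_a, labels, parameter_a)
    rb = roc_auc(values_b, labels, parameter_b)
    sa = values_a if ra.orientation == "higher" else -values_a
    sb = values_b if rb.orientation == "higher" else -values_b
    pos_mask = labels == MALIGNANT
    pa, na = sa[pos_mask], sa[~pos_mask]
    pb, nb = sb[pos_mask], sb[~pos_mask]
    auc_a, v10a, v01a = _placements(pa, na)
    auc_b, v10b, v01b = _placements(pb, nb)
    diff = auc_a - auc_b

    if method == "delong":
        m, n = pa.size, na.size
        var = 0.0
        if m > 1:
            s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
            var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        if n > 1:
            s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
            var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        if var <= 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            z = diff / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        m, n = pa.size, na.size
        diffs = np.empty(n_boot)
        for i in range(n_boot):
            ip = rng.integers(0, m, m)
            ineg = rng.integers(0, n, n)
            diffs[i] = _auc_concordance(pa[ip], na[ineg]) - _auc_concordance(
                pb[ip], nb[ineg]
            )
        sd = diffs.std(ddof=1)
        if sd == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(diff) / sd))
    else:
        raise AnalysisError(f"unknown method {method!r}; use 'delong' or 'bootstrap'")
    return AUCComparison(
        parameter_a=parameter_a,
        parameter_b=parameter_b,
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        area_difference=float(diff),
        p=min(float(p), 1.0),
        method=method,
    )


@dataclass
class CohortAnalysis:
    """Full benign-vs-malignant results: per subgroup ('all',
    'le_threshold', 'gt_threshold') and per parameter, the group
    comparison, ROC result and paired AUC comparison against the ADC
    reference.  ``not_computable`` lists subgroup/parameter entries that
    could not be evaluated (e.g. a subgroup missing one class)."""

    size_threshold_mm: float
    reference: str
    comparisons: dict[str, dict[str, GroupComparison]] = field(default_factory=dict)
    rocs: dict[str, dict[str, ROCResult]] = field(default_factory=dict)
    auc_vs_reference: dict[str, dict[str, AUCComparison]] = field(default_factory=dict)
    not_computable: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy results table: one row per (subgroup, parameter)."""
        rows = []
        for sub, comps in self.comparisons.items():
            for param, gc in comps.items():
                roc = self.rocs[sub][param]
                cmp_ = self.auc_vs_reference[sub].get(param)
                rows.append(
                    {
                        "subgroup": sub,
                        "parameter": param,
                        "n_malignant": gc.n_malignant,
                        "n_benign": gc.n_benign,
                        "median_malignant": gc.median_malignant,
                        "q25_malignant": gc.q25_malignant,
                        "q75_malignant": gc.q75_malignant,
                        "median_benign": gc.median_benign,
                        "q25_benign": gc.q25_benign,
                        "q75_benign": gc.q75_benign,
                        "U": gc.U,
                        "p_mannwhitney": gc.p,
                        "auc": roc.auc,
                        "ci_low": roc.ci_low,
                        "ci_high": roc.ci_high,
                        "orientation": roc.orientation,
                        "auc_diff_vs_ref": (
                            np.nan if cmp_ is None else cmp_.area_difference
                        ),
                        "p_vs_ref": np.nan if cmp_ is None else cmp_.p,
                    }
                )
        return pd.DataFrame(rows)


def run_cohort_analysis(
    records: Sequence[LesionRecord],
    size_threshold_mm: float = 10.0,
    reference: str = "d_app",
    parameters: Sequence[str] | None = None,
) -> CohortAnalysis:
    """Benign-vs-malignant comparison for every parameter, with
    lesion-size stratification.

    For each parameter present in the records' summaries this computes
    the Mann–Whitney group comparison, ROC/AUC with 95% CI, and the
    paired DeLong comparison against the reference parameter (the ADC,
    ``d_app``); the same analysis is repeated for lesions with maximal
    in-plane diameter above and at-or-below ``size_threshold_mm``.
    Subgroups missing a class are recorded as not computable rather than
    aborting.
    """
    if not size_threshold_mm > 0:
        raise AnalysisError(f"size threshold must be > 0, got {size_threshold_mm}")
    records = list(records)
    labels_all = np.array([r.label for r in records])
    if (labels_all == MALIGNANT).sum() < 2 or (labels_all == BENIGN).sum() < 2:
        raise AnalysisError("need at least 2 lesions per class overall")
    if parameters is None:
        available = set(records[0].summaries)
        parameters = [p for p in PARAMETER_ORDER if p in available]
        parameters += sorted(available - set(parameters) - {"d_star_ivim", "s0"})
    sizes = np.array([r.size_mm for r in records])
    subgroups = {
        "all": np.ones(len(records), dtype=bool),
        "le_threshold": sizes <= size_threshold_mm,
        "gt_threshold": sizes > size_threshold_mm,
    }
    out = CohortAnalysis(size_threshold_mm=size_threshold_mm, reference=reference)
    for sub, sel in subgroups.items():
        sub_records = [r for r, s in zip(records, sel) if s]
        sub_labels = labels_all[sel]
        if (sub_labels == MALIGNANT).sum() == 0 or (sub_labels == BENIGN).sum() == 0:
            out.not_computable[sub] = (
                f"subgroup {sub!r} has {int((sub_labels == MALIGNANT).sum())} "
                f"malignant and {int((sub_labels == BENIGN).sum())} benign lesions"
            )
            continue
        out.comparisons[sub] = {}
        out.rocs[sub] = {}
        out.auc_vs_reference[sub] = {}
        ref_values = np.array([r.summaries[reference] for r in sub_records])
        for param in parameters:
            values = np.array([r.summaries[param] for r in sub_records])
            out.comparisons[sub][param] = group_compare(values, sub_labels, param)
            out.rocs[sub][param] = roc_auc(values, sub_labels, param)
            if param != reference:
                out.auc_vs_reference[sub][param] = compare_aucs(
                    values, ref_values, sub_labels, param, reference
                )
    return out
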
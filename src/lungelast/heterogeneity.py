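"""Heterogeneity indices and group statistics for lobar elasticity.

Interlobar heterogeneity is summarized by the Elasticity Heterogeneity
Index (EHI). With E_max the maximum per-lobe percent of parenchymal
voxels in the 1-3 kPa diseased-tissue band and E~max the mean of the
other lobes' percentages,

    EHI = | 1 - (100 - E_max) / (100 - E~max) |

so EHI = 0 means total homogeneity and larger values mean the most
diseased lobe stands out more. Intralobar heterogeneity is the
coefficient of variation (CV, sample SD as a percent of the mean) and
the non-uniformity index NU = (E95 - mean) / mean of each lobe's
elasticity distribution. Group contrasts use an F-test for variance
equality to choose between pooled and Welch two-sample t-tests, with a
Mann-Whitney U option as the nonparametric robustness check.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .masking import LobarDistribution, lobar_values, parenchyma_mask
from .phantom import BIOMARKER_BAND, LOBE_LABELS, PARENCHYMA_HU_THRESHOLD

logger = logging.getLogger(__name__)

SEVERITY_GROUPS = ("none", "mild", "moderate_severe", "copd_unknown")


# --------------------------------------------------------------------------
# Per-lobe indices
# --------------------------------------------------------------------------

def percent_in_band(
    dist: LobarDistribution,
    lo: float = BIOMARKER_BAND[0],
    hi: float = BIOMARKER_BAND[1],
) -> float:
    """Percent of lobe voxels with elasticity in [lo, hi] kPa (inclusive)."""
    if dist.is_empty:
        raise ValueError(f"lobe {dist.lobe_label} has no parenchymal voxels")
    v = dist.values
    return 100.0 * float(np.count_nonzero((v >= lo) & (v <= hi))) / dist.n


@dataclass(frozen=True)
class DiseasedPercentages:
    """Per-lobe percent of voxels in the diseased biomarker band."""

    percents: tuple[float, ...]  # one per lobe, NaN for empty lobes
    band_lo: float = BIOMARKER_BAND[0]
    band_hi: float = BIOMARKER_BAND[1]

    def __post_init__(self) -> None:
        for p in self.percents:
            if not math.isnan(p) and not 0.0 <= p <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


def ehi(diseased: DiseasedPercentages | "list[float]") -> float:
    """Elasticity Heterogeneity Index over the lobar diseased percentages.

    Empty lobes (NaN) are dropped; at least two lobes with data are
    required. The maximal percentage serves as E_max (tie-invariant: only
    its value enters); the remaining lobes' mean is E~max. The degenerate
    case E~max = 100 yields 0 when E_max = 100 as well (all lung fully
    diseased is homogeneous) and is an error otherwise.
    """
    if isinstance(diseased, DiseasedPercentages):
        percents = diseased.percents
    else:
        percents = tuple(diseased)
    vals = np.asarray([p for p in percents if not math.isnan(p)], dtype=float)
    if len(vals) < 2:
        raise ValueError("EHI requires at least two lobes with data")
    i_max = int(np.argmax(vals))
    e_max = float(vals[i_max])
    e_rest = float(np.mean(np.delete(vals, i_max)))
    if e_rest == 100.0:
        if e_max == 100.0:
            return 0.0
        raise ValueError(
            "EHI undefined: non-maximal lobes are fully diseased "
            "(E~max = 100) while E_max < 100"
        )
    return abs(1.0 - (100.0 - e_max) / (100.0 - e_rest))


def coefficient_of_variation(dist: LobarDistribution) -> float:
    """Sample SD as a percent of the mean of a lobar distribution."""
    if dist.n < 2:
        raise ValueError("CV requires at least two values")
    if dist.mean <= 0:
        raise ValueError("CV requires a positive mean")
    return 100.0 * dist.sd / dist.mean


def non_uniformity(dist: LobarDistribution) -> float:
    """Non-uniformity index: (95th percentile - mean) / mean."""
    if dist.n < 2:
        raise ValueError("NU requires at least two values")
    if dist.mean <= 0:
        raise ValueError("NU requires a positive mean")
    return (dist.p95 - dist.mean) / dist.mean


# --------------------------------------------------------------------------
# Two-group comparisons
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-sample contrast: F-test for variances, then the mean test."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    f_statistic: float
    f_pvalue: float
    test_type: str       # t_equal_var | t_welch | mann_whitney
    statistic: float
    pvalue: float
    alpha: float = 0.05
    metric: str = ""
    group_a: str = ""
    group_b: str = ""


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test with the larger-variance group in the numerator."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0, 1.0
    if va >= vb:
        num_v, den_v, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num_v, den_v, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    if den_v == 0.0:
        return float("inf"), 0.0
    f = num_v / den_v
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return float(f), p


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    method: str = "auto",
) -> GroupComparison:
    """Compare two groups of values with the study's test procedure.

    ``method='auto'``: a two-sided F-test on the variances decides between
    the pooled-variance t-test (F-test p >= alpha) and Welch's t-test.
    ``method='mann_whitney'`` runs the two-sided rank-sum test instead.
    Identical groups are a degenerate identity (statistic 0, p = 1) even
    below the usual n >= 2 requirement.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method not in ("auto", "t_equal_var", "t_welch", "mann_whitney"):
        raise ValueError(f"unknown method {method!r}")
    identical = (
        len(a) == len(b)
        and np.array_equal(np.sort(a), np.sort(b))
    )
    if (len(a) < 2 or len(b) < 2) and not identical:
        raise ValueError("each group needs at least 2 values")
    sd_a = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    sd_b = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    if identical:
        f_stat, f_p = 1.0, 1.0
        test_type = "t_equal_var" if method in ("auto", "t_equal_var") else method
        stat, p = 0.0, 1.0
    else:
        f_stat, f_p = _variance_f_test(a, b)
        if method == "auto":
            test_type = "t_equal_var" if f_p >= alpha else "t_welch"
        else:
            test_type = method
        if test_type == "mann_whitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            if sd_a == 0.0 and sd_b == 0.0:
                # zero variance, different means: infinitely significant
                stat = math.copysign(math.inf, float(np.mean(a) - np.mean(b)))
                p = 0.0
            else:
                res = stats.ttest_ind(a, b, equal_var=test_type == "t_equal_var")
                stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        n_a=len(a), n_b=len(b),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        sd_a=sd_a, sd_b=sd_b,
        f_statistic=f_stat, f_pvalue=f_p,
        test_type=test_type, statistic=stat, pvalue=p,
        alpha=alpha,
    )


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# --------------------------------------------------------------------------
# Tumor-lobe contrast
# --------------------------------------------------------------------------

@dataclass
class TumorContrast:
    tumor_lobes: tuple[int, ...]
    tumor_mean: float            # pooled voxels across tumor lobes, kPa
    other_mean: float            # mean of the non-tumor lobar means, kPa
    absolute_difference: float   # kPa
    relative_difference: float   # percent of the all-lobe mean
    pvalue: float                # per-subject two-sample test, tumor vs rest
    tumor_lobe_is_stiffest: bool


def tumor_contrast(
    lobar: list[LobarDistribution],
    tumor_lobes,
) -> TumorContrast:
    """Contrast the tumor-bearing lobe(s) against the non-cancerous lobes.

    The tumor side pools voxels across its lobes; the other side is the
    mean of the non-tumor lobar means. The relative difference is taken
    against the mean of all five lobar means. Ties in the stiffest-lobe
    flag resolve to False (the tumor lobe must be strictly stiffest).
    """
    tumor_lobes = tuple(sorted(set(int(t) for t in tumor_lobes)))
    if not 1 <= len(tumor_lobes) <= 2:
        raise ValueError("expected 1-2 tumor-bearing lobes")
    for t in tumor_lobes:
        if t not in LOBE_LABELS:
            raise ValueError(f"invalid tumor lobe label {t}")
    by_label = {d.lobe_label: d for d in lobar}
    others = [
        d for d in lobar
        if d.lobe_label not in tumor_lobes and not d.is_empty
    ]
    if not others:
        raise ValueError("no non-tumor lobe with data to contrast against")
    tumor_values = np.concatenate(
        [by_label[t].values for t in tumor_lobes if not by_label[t].is_empty]
    ) if any(not by_label[t].is_empty for t in tumor_lobes) else np.empty(0)
    if len(tumor_values) == 0:
        raise ValueError("tumor-bearing lobes have no parenchymal voxels")
    tumor_mean = float(np.mean(tumor_values))
    other_means = [d.mean for d in others]
    other_mean = float(np.mean(other_means))
    all_means = [d.mean for d in lobar if not d.is_empty]
    grand = float(np.mean(all_means))
    absolute = abs(tumor_mean - other_mean)
    relative = absolute / grand * 100.0 if grand > 0 else float("nan")
    other_values = np.concatenate([d.values for d in others])
    p = compare_groups(tumor_values, other_values).pvalue
    tumor_lobe_means = [
        by_label[t].mean for t in tumor_lobes if not by_label[t].is_empty
    ]
    stiffest = max(tumor_lobe_means) > max(other_means)
    return TumorContrast(
        tumor_lobes=tumor_lobes,
        tumor_mean=tumor_mean,
        other_mean=other_mean,
        absolute_difference=absolute,
        relative_difference=relative,
        pvalue=p,
        tumor_lobe_is_stiffest=bool(stiffest),
    )


# --------------------------------------------------------------------------
# Subject-level report
# --------------------------------------------------------------------------

@dataclass
class HeterogeneityReport:
    """All heterogeneity metrics for one subject."""

    subject_id: str
    severity: str                       # none | mild | moderate_severe | copd_unknown
    lobar_means: tuple[float, ...]      # kPa per lobe (NaN for empty lobes)
    whole_lung_mean: float              # kPa, over all masked voxels
    diseased: DiseasedPercentages
    ehi: float
    cv: tuple[float, ...]               # percent per lobe
    nu: tuple[float, ...]               # dimensionless per lobe
    tumor: TumorContrast | None = None

    def to_dict(self) -> dict:
        out = {
            "subject_id": self.subject_id,
            "severity": self.severity,
            "lobar_means_kpa": list(self.lobar_means),
            "whole_lung_mean_kpa": self.whole_lung_mean,
            "percent_diseased": list(self.diseased.percents),
            "band_kpa": [self.diseased.band_lo, self.diseased.band_hi],
            "ehi": self.ehi,
            "cv_percent": list(self.cv),
            "nu": list(self.nu),
        }
        if self.tumor is not None:
            out["tumor_contrast"] = {
                "tumor_lobes": list(self.tumor.tumor_lobes),
                "absolute_difference_kpa": self.tumor.absolute_difference,
                "relative_difference_percent": self.tumor.relative_difference,
                "pvalue": self.tumor.pvalue,
                "tumor_lobe_is_stiffest": self.tumor.tumor_lobe_is_stiffest,
            }
        return out


def subject_report(
    elasticity: np.ndarray,
    hu_exhale: np.ndarray,
    lobe_labels: np.ndarray,
    subject_id: str = "subject",
    severity: str = "none",
    tumor_lobes=None,
    threshold_hu: float = PARENCHYMA_HU_THRESHOLD,
    band: tuple[float, float] = BIOMARKER_BAND,
) -> HeterogeneityReport:
    """Compute every heterogeneity metric for one elasticity map."""
    if severity not in SEVERITY_GROUPS:
        raise ValueError(
            f"severity must be one of {SEVERITY_GROUPS}, got {severity!r}"
        )
    pmask = parenchyma_mask(hu_exhale, lobe_labels, threshold_hu)
    lobar = lobar_values(elasticity, pmask, lobe_labels)
    percents = tuple(
        percent_in_band(d, *band) if not d.is_empty else float("nan")
        for d in lobar
    )
    diseased = DiseasedPercentages(percents, band[0], band[1])
    cv = tuple(
        coefficient_of_variation(d) if d.n >= 2 else float("nan")
        for d in lobar
    )
    nu = tuple(
        non_uniformity(d) if d.n >= 2 else float("nan") for d in lobar
    )
    masked = np.asarray(elasticity)[pmask.mask]
    tumor = (
        tumor_contrast(lobar, tumor_lobes) if tumor_lobes else None
    )
    return HeterogeneityReport(
        subject_id=subject_id,
        severity=severity,
        lobar_means=tuple(d.mean for d in lobar),
        whole_lung_mean=float(np.mean(masked)) if len(masked) else float("nan"),
        diseased=diseased,
        ehi=ehi(diseased),
        cv=cv,
        nu=nu,
        tumor=tumor,
    )


# --------------------------------------------------------------------------
# Cohort-level report
# --------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Cohort tables: group summaries and all pairwise comparisons."""

    lobar_elasticity: pd.DataFrame   # group x lobe mean +/- sd (kPa)
    ehi_summary: pd.DataFrame        # per-group EHI mean +/- sd
    cv_summary: pd.DataFrame         # pooled-lobe CV mean +/- sd per group
    cv_histogram: pd.DataFrame       # 10-point bins of pooled-lobe CVs
    nu_summary: pd.DataFrame         # per-group per-lobe NU mean +/- sd
    comparisons: pd.DataFrame        # pairwise group tests per metric


def _summary(values: np.ndarray) -> tuple[float, float, int]:
    v = values[~np.isnan(values)]
    mean = float(np.mean(v)) if len(v) else float("nan")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
    return mean, sd, len(v)


def cohort_report(
    subjects: list[HeterogeneityReport],
    alpha: float = 0.05,
    holm: bool = False,
    cv_bin_width: float = 10.0,
) -> CohortReport:
    """Aggregate subject reports into the cohort tables and group tests.

    Subjects labelled ``copd_unknown`` enter only the pooled all-COPD
    versus no-COPD contrast, not the named severity groups. Pairwise
    comparisons cover whole-lung mean elasticity, EHI (both per subject)
    and pooled-lobe CV for every pair of named groups; ``holm=True`` adds
    Holm-adjusted p-values (raw p-values are always reported).
    """
    if not subjects:
        raise ValueError("empty cohort")
    named = [g for g in ("none", "mild", "moderate_severe")
             if any(s.severity == g for s in subjects)]

    def of_group(g: str) -> list[HeterogeneityReport]:
        return [s for s in subjects if s.severity == g]

    rows = []
    for g in named:
        for li, lb in enumerate(LOBE_LABELS):
            vals = np.asarray([of_group(g)[i].lobar_means[li]
                               for i in range(len(of_group(g)))])
            mean, sd, n = _summary(vals)
            rows.append({"group": g, "lobe": lb, "mean_kpa": mean,
                         "sd_kpa": sd, "n": n})
    lobar_df = pd.DataFrame(rows)

    ehi_rows, cv_rows, cvh_frames, nu_rows = [], [], [], []
    pooled_cv: dict[str, np.ndarray] = {}
    for g in named:
        grp = of_group(g)
        mean, sd, n = _summary(np.asarray([s.ehi for s in grp]))
        ehi_rows.append({"group": g, "mean_ehi": mean, "sd_ehi": sd, "n": n})
        cvs = np.asarray([c for s in grp for c in s.cv if not math.isnan(c)])
        pooled_cv[g] = cvs
        mean, sd, n = _summary(cvs)
        cv_rows.append({"group": g, "mean_cv_percent": mean,
                        "sd_cv_percent": sd, "n_lobes": n})
        if len(cvs):
            top = max(100.0, float(np.ceil(cvs.max() / cv_bin_width))
                      * cv_bin_width)
            edges = np.arange(0.0, top + cv_bin_width, cv_bin_width)
            counts, _ = np.histogram(cvs, bins=edges)
            cvh_frames.append(pd.DataFrame({
                "group": g, "bin_lo": edges[:-1], "bin_hi": edges[1:],
                "count": counts,
            }))
        for li, lb in enumerate(LOBE_LABELS):
            mean, sd, n = _summary(np.asarray([s.nu[li] for s in grp]))
            nu_rows.append({"group": g, "lobe": lb, "mean_nu": mean,
                            "sd_nu": sd, "n": n})

    metrics = {
        "whole_lung_elasticity": lambda s: s.whole_lung_mean,
        "ehi": lambda s: s.ehi,
    }
    comp_rows = []
    for metric, getter in metrics.items():
        for ga, gb in itertools.combinations(named, 2):
            va = np.asarray([getter(s) for s in of_group(ga)])
            vb = np.asarray([getter(s) for s in of_group(gb)])
            comp_rows.append(_comparison_row(metric, ga, gb, va, vb, alpha))
    for ga, gb in itertools.combinations(named, 2):
        comp_rows.append(_comparison_row(
            "pooled_lobe_cv", ga, gb, pooled_cv[ga], pooled_cv[gb], alpha
        ))
    # all-COPD (mild + moderate_severe + copd_unknown) vs no COPD
    copd = [s for s in subjects if s.severity != "none"]
    none_grp = of_group("none")
    if copd and none_grp:
        for metric, getter in metrics.items():
            va = np.asarray([getter(s) for s in copd])
            vb = np.asarray([getter(s) for s in none_grp])
            comp_rows.append(
                _comparison_row(metric, "all_copd", "none", va, vb, alpha)
            )
    comp_df = pd.DataFrame(comp_rows)
    if holm and len(comp_df):
        comp_df["pvalue_holm"] = holm_correction(comp_df["pvalue"].to_numpy())

    return CohortReport(
        lobar_elasticity=lobar_df,
        ehi_summary=pd.DataFrame(ehi_rows),
        cv_summary=pd.DataFrame(cv_rows),
        cv_histogram=(
            pd.concat(cvh_frames, ignore_index=True)
            if cvh_frames else pd.DataFrame()
        ),
        nu_summary=pd.DataFrame(nu_rows),
        comparisons=comp_df,
    )


def _comparison_row(metric, ga, gb, va, vb, alpha) -> dict:
    base = {"metric": metric, "group_a": ga, "group_b": gb,
            "n_a": len(va), "n_b": len(vb)}
    try:
        c = compare_groups(va, vb, alpha=alpha)
    except ValueError as exc:
        logger.warning("skipping %s %s vs %s: %s", metric, ga, gb, exc)
        return {**base, "f_statistic": float("nan"), "f_pvalue": float("nan"),
                "test_type": "skipped", "statistic": float("nan"),
                "pvalue": float("nan")}
    return {**base, "f_statistic": c.f_statistic, "f_pvalue": c.f_pvalue,
            "test_type": c.test_type, "statistic": c.statistic,
            "pvalue": c.pvalue}
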
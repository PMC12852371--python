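"""Agreement and evaluation statistics for paired measurements and masks.

ICC (two-way model, absolute agreement, single measure) with 95% CI,
Bland–Altman bias and limits of agreement with a proportional-bias check,
volumetric/surface overlap metrics (DSC, surface Dice, HD95), Cohen's kappa,
paired t / Wilcoxon timing comparisons, and grade-table tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy import ndimage
from sklearn.metrics import cohen_kappa_score

from .labelmap import CANONICAL_SCHEMA, LabelMap, LabelSchema

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "icc_absolute_agreement",
    "bland_altman",
    "mask_overlap_metrics",
    "cohens_kappa",
    "paired_time_test",
    "grade_table_test",
    "agreement_table",
]


@dataclass
class PairedMeasurements:
    """One metric measured by two methods on the same subjects.

    Missing values are removed pairwise at construction; the number of
    dropped pairs is recorded in ``n_dropped``.
    """

    subjects: np.ndarray
    method_a: np.ndarray
    method_b: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a, dtype=float)
        b = np.asarray(self.method_b, dtype=float)
        s = np.asarray(self.subjects)
        if not (len(a) == len(b) == len(s)):
            raise ValueError("subjects, method_a, method_b must have equal length")
        keep = ~(np.isnan(a) | np.isnan(b))
        self.n_dropped = int(np.count_nonzero(~keep))
        self.subjects, self.method_a, self.method_b = s[keep], a[keep], b[keep]
        if len(self.method_a) < 3:
            raise ValueError("need at least 3 complete pairs")

    @property
    def n(self) -> int:
        return len(self.method_a)


@dataclass
class AgreementResult:
    """ICC and Bland–Altman summary for one metric."""

    icc: float
    icc_ci: tuple[float, float]
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    proportional_bias_p: float
    n: int = 0


def _two_way_mean_squares(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the two-way subject x rater ANOVA."""
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc_absolute_agreement(
    data: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Single-measure ICC, two-way model, absolute agreement — ICC(A,1).

    ``(MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))`` from the
    two-way ANOVA decomposition, with the F-based confidence interval of
    McGraw & Wong.  Raises on zero between-subject variance, where the ICC
    is undefined.
    """
    a, b = data.method_a, data.method_b
    n, k = data.n, 2
    msr, msc, mse = _two_way_mean_squares(a, b)
    scale = max(np.var(np.concatenate([a, b])), 1.0)
    if msr < 1e-12 * scale:
        raise ValueError("no between-subject variance: ICC undefined")
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # F-based CI (McGraw & Wong case 2A,1)
    if mse <= 0:
        return float(icc), (float(icc), float(icc))
    f3c = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * icc * f3c + n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    vd = (n - 1) * k**2 * icc**2 * f3c**2 + (
        n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr
    )
    return float(icc), (float(lower), float(upper))


def bland_altman(data: PairedMeasurements) -> AgreementResult:
    """Bias, limits of agreement, and a proportional-bias slope test.

    Differences are ``a − b``; LOA = bias ± 1.96·SD (sample SD, n−1).  The
    proportional-bias p-value is the slope test of the differences regressed
    on the pair means.
    """
    d = data.method_a - data.method_b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    means = (data.method_a + data.method_b) / 2.0
    if np.ptp(means) == 0 or np.allclose(d, d[0]):
        prop_p = 1.0
    else:
        prop_p = float(stats.linregress(means, d).pvalue)
    icc, ci = np.nan, (np.nan, np.nan)
    try:
        icc, ci = icc_absolute_agreement(data)
    except ValueError:
        pass
    return AgreementResult(
        icc=icc, icc_ci=ci, bias=bias, sd_diff=sd, loa=loa,
        proportional_bias_p=prop_p, n=data.n,
    )


_CONN6 = ndimage.generate_binary_structure(3, 1)


def _surface_points(lm: LabelMap, mask: np.ndarray) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask, structure=_CONN6)
    return lm.index_to_physical(np.argwhere(boundary))


def mask_overlap_metrics(
    a: LabelMap,
    b: LabelMap,
    structure: str | int,
    tolerance: float = 1.0,
    schema: LabelSchema = CANONICAL_SCHEMA,
) -> tuple[float, float, float]:
    """(DSC, surface Dice, HD95 mm) between one structure in two label maps.

    Surface distances use voxel-center positions of the 6-connected boundary
    layer.  Surface Dice is the symmetrized fraction of boundary points
    within ``tolerance`` mm of the other boundary; HD95 is the 95th
    percentile of the pooled symmetric surface distances.
    """
    if a.voxels.shape != b.voxels.shape or not np.allclose(a.spacing, b.spacing):
        raise ValueError("label maps must share the same grid and spacing")
    code = schema[structure] if isinstance(structure, str) else int(structure)
    ma, mb = a.voxels == code, b.voxels == code
    if not ma.any() and not mb.any():
        raise ValueError("both masks are empty")
    inter = np.count_nonzero(ma & mb)
    dsc = 2.0 * inter / (np.count_nonzero(ma) + np.count_nonzero(mb))
    pa, pb = _surface_points(a, ma), _surface_points(b, mb)
    if len(pa) == 0 or len(pb) == 0:
        return float(dsc), 0.0, float("inf")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    surface_dice = (
        np.count_nonzero(d_ab <= tolerance) + np.count_nonzero(d_ba <= tolerance)
    ) / (len(pa) + len(pb))
    hd95 = float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    return float(dsc), float(surface_dice), hd95


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa, κ = (p_o − p_e)/(1 − p_e), for two categorical raters."""
    a, b = list(ratings_a), list(ratings_b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length rating lists of length >= 2")
    if len(set(a) | set(b)) < 2:
        raise ValueError("kappa undefined: only one category present")
    return float(cohen_kappa_score(a, b))


@dataclass
class PairedTestResult:
    test: str
    statistic: float
    pvalue: float
    flags: list[str] = field(default_factory=list)


def paired_time_test(
    times_a, times_b, method: str = "auto", alpha: float = 0.05
) -> PairedTestResult:
    """Paired comparison of per-case times (or any paired measurements).

    ``method='auto'`` runs a Shapiro–Wilk normality check on the differences
    and selects the paired t-test (normal) or the Wilcoxon signed-rank test
    (exact where scipy supports it) otherwise; 't' and 'wilcoxon' force a
    branch.  All-zero differences are reported as p = 1 with a flag.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need equal-length samples with n >= 5")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult("wilcoxon", 0.0, 1.0, ["all_differences_zero"])
    if method == "auto":
        method = "t" if stats.shapiro(d).pvalue >= alpha else "wilcoxon"
    if method == "t":
        res = stats.ttest_rel(a, b)
        return PairedTestResult("t", float(res.statistic), float(res.pvalue))
    if method == "wilcoxon":
        res = stats.wilcoxon(a, b, method="auto")
        return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue))
    raise ValueError(f"unknown method '{method}'")


@dataclass
class GradeTableResult:
    per_grade: dict[str, tuple[str, float]]  # grade -> (test used, p)
    overall_p: float


def grade_table_test(
    counts_a: dict[str, int], counts_b: dict[str, int], method: str = "auto"
) -> GradeTableResult:
    """Compare two grade distributions (e.g. A/B/C counts of two cohorts).

    Per grade: a 2x2 (grade vs rest, cohort a vs b) tested with chi-square
    when all expected counts are >= 5, else Fisher's exact; ``method`` can
    force 'chi2' or 'fisher'.  Overall: chi-square on the full 2xG table.
    """
    grades = sorted(set(counts_a) | set(counts_b))
    if not grades:
        raise ValueError("empty grade table")
    ca = np.array([counts_a.get(g, 0) for g in grades])
    cb = np.array([counts_b.get(g, 0) for g in grades])
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("counts must be non-negative")
    per_grade: dict[str, tuple[str, float]] = {}
    for g, na, nb in zip(grades, ca, cb):
        table = np.array([[na, ca.sum() - na], [nb, cb.sum() - nb]])
        expected = stats.contingency.expected_freq(table)
        use = method
        if use == "auto":
            use = "chi2" if (expected >= 5).all() else "fisher"
        if use == "chi2":
            p = float(stats.chi2_contingency(table)[1])
        else:
            p = float(stats.fisher_exact(table)[1])
        per_grade[g] = (use, p)
    keep = (ca + cb) > 0
    overall = float(stats.chi2_contingency(np.vstack([ca[keep], cb[keep]]))[1])
    return GradeTableResult(per_grade=per_grade, overall_p=overall)


def agreement_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-metric agreement summary from a long-format paired CSV.

    Input columns: ``case_id, metric, value_auto, value_manual``.  Output
    mirrors the usual reporting layout: Bias ± SD, LOA, ICC [95% CI], and the
    proportional-bias P per metric.
    """
    required = {"case_id", "metric", "value_auto", "value_manual"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    rows = []
    for metric, g in df.groupby("metric", sort=False):
        data = PairedMeasurements(
            subjects=g["case_id"].to_numpy(),
            method_a=g["value_auto"].to_numpy(float),
            method_b=g["value_manual"].to_numpy(float),
        )
        r = bland_altman(data)
        rows.append(
            {
                "metric": metric,
                "n": r.n,
                "bias": r.bias,
                "sd": r.sd_diff,
                "loa_lower": r.loa[0],
                "loa_upper": r.loa[1],
                "icc": r.icc,
                "icc_ci_lower": r.icc_ci[0],
                "icc_ci_upper": r.icc_ci[1],
                "proportional_bias_p": r.proportional_bias_p,
            }
        )
    return pd.DataFrame(rows)
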
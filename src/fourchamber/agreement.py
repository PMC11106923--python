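"""Rater-vs-model agreement statistics for paired clinical measurements.

Workflow for a column of rater values and a column of automated values of the
same quantity (cardiac axis in degrees, or cardiothoracic ratio):

1. Shapiro–Wilk normality test on the paired differences; P > alpha routes to
   the paired t-test, P <= alpha to the Wilcoxon signed-rank test.
2. Bland–Altman analysis: bias = mean(rater − model), 95% CI of the bias from
   the t distribution, and 95% limits of agreement bias ± 1.96·SD(diff).
3. ICC(2,1): two-way random-effects, absolute-agreement, single-measurement
   intraclass correlation, with a 95% CI from the F distribution (McGraw &
   Wong).  Absolute agreement is the right form here because the question is
   whether the model can replace a rater, so systematic offsets must count
   against it.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "paired_compare",
    "bland_altman",
    "icc",
    "agreement_report",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Equal-length rater and model vectors of one quantity, no missing values."""

    rater: np.ndarray
    model: np.ndarray
    quantity: str = "cax_deg"

    def __post_init__(self) -> None:
        r = np.asarray(self.rater, dtype=float)
        m = np.asarray(self.model, dtype=float)
        if r.ndim != 1 or m.ndim != 1 or len(r) != len(m):
            raise ValueError("rater and model must be 1-D vectors of equal length")
        keep = np.isfinite(r) & np.isfinite(m)  # explicit pairwise deletion
        r, m = r[keep], m[keep]
        if len(r) < 3:
            raise ValueError("need at least 3 complete pairs")
        object.__setattr__(self, "rater", r)
        object.__setattr__(self, "model", m)

    @property
    def n(self) -> int:
        return len(self.rater)

    @property
    def differences(self) -> np.ndarray:
        """rater − model (positive bias: rater reads higher than the model)."""
        return self.rater - self.model


@dataclass(frozen=True)
class AgreementReport:
    quantity: str
    n: int
    normality_p: float
    test_used: str  # "paired_t" | "wilcoxon"
    test_p: float
    bias: float
    sd_diff: float
    bias_ci: tuple[float, float]
    loa: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    warnings: tuple[str, ...] = ()
    normality_p_rater: float | None = None
    normality_p_model: float | None = None

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "n": self.n,
            "normality_p": self.normality_p,
            "normality_p_rater": self.normality_p_rater,
            "normality_p_model": self.normality_p_model,
            "test_used": self.test_used,
            "test_p": self.test_p,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "bias_ci": list(self.bias_ci),
            "loa": list(self.loa),
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "warnings": list(self.warnings),
        }


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 1.0  # constant sample: no evidence against normality to act on
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def paired_compare(
    pm: PairedMeasurements, alpha: float = 0.05
) -> tuple[float, str, float]:
    """Normality-gated paired comparison of rater vs model.

    Shapiro–Wilk on the differences; P > alpha -> paired t-test, P <= alpha ->
    Wilcoxon signed-rank.  All-zero differences make both tests degenerate and
    are reported as (1.0, "paired_t", 1.0).
    """
    d = pm.differences
    normality_p = _shapiro_p(d)
    if np.all(d == 0):
        return normality_p, "paired_t", 1.0
    if normality_p > alpha:
        test_used = "paired_t"
        p = float(stats.ttest_rel(pm.rater, pm.model).pvalue)
    else:
        test_used = "wilcoxon"
        p = float(stats.wilcoxon(pm.rater, pm.model).pvalue)
    return normality_p, test_used, p


def bland_altman(
    pm: PairedMeasurements,
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Bland–Altman bias, SD of differences, 95% bias CI and 95% LoA.

    bias = mean(rater − model); LoA = bias ± 1.96·SD; the bias CI uses the
    exact t quantile, bias ± t_{0.975, n−1}·SD/√n.
    """
    d = pm.differences
    n = pm.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tq = float(stats.t.ppf(0.975, n - 1))
    half = tq * sd / np.sqrt(n)
    return (
        bias,
        sd,
        (bias - half, bias + half),
        (bias - 1.96 * sd, bias + 1.96 * sd),
    )


def icc(pm: PairedMeasurements) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with its 95% confidence interval.

    Two-way random-effects ANOVA on the n×2 table (subjects × raters),
    absolute agreement, single measurement:

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

    with MS_R/MS_C/MS_E the subject, rater and residual mean squares and
    k = 2 raters.  The CI follows McGraw & Wong's F-based construction.
    """
    if pm.n < 5:
        raise ValueError("ICC needs at least 5 subjects")
    data = np.column_stack([pm.rater, pm.model])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("constant subjects: between-subject variance is zero")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc_val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong (1996) F-based CI for ICC(A,1), Satterthwaite df
    if mse <= 0:
        return float(icc_val), (1.0, 1.0)
    fc = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * icc_val * fc + n * (1 + (k - 1) * icc_val) - k * icc_val
    ) ** 2
    vd = (n - 1) * k**2 * icc_val**2 * fc**2 + (
        n * (1 + (k - 1) * icc_val) - k * icc_val
    ) ** 2
    v = vn / vd
    f1 = stats.f.ppf(0.975, n - 1, v)
    f2 = stats.f.ppf(0.975, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return float(icc_val), (float(lower), float(upper))


def agreement_report(pm: PairedMeasurements, alpha: float = 0.05) -> AgreementReport:
    """Assemble the full agreement analysis for one measured quantity."""
    warns: list[str] = []
    d = pm.differences
    normality_p, test_used, test_p = paired_compare(pm, alpha)
    if np.all(d == 0):
        warns.append("rater and model agree exactly; paired tests are degenerate")
    bias, sd, bias_ci, loa = bland_altman(pm)
    try:
        icc_val, icc_ci = icc(pm)
    except ValueError as exc:
        warns.append(f"ICC unavailable: {exc}")
        icc_val, icc_ci = float("nan"), (float("nan"), float("nan"))
    return AgreementReport(
        quantity=pm.quantity,
        n=pm.n,
        normality_p=normality_p,
        test_used=test_used,
        test_p=test_p,
        bias=bias,
        sd_diff=sd,
        bias_ci=bias_ci,
        loa=loa,
        icc=icc_val,
        icc_ci=icc_ci,
        warnings=tuple(warns),
        normality_p_rater=_shapiro_p(pm.rater),
        normality_p_model=_shapiro_p(pm.model),
    )


def plot_bland_altman(pm: PairedMeasurements, report: AgreementReport, path) -> None:
    """Render the Bland–Altman plot: mean on x, difference on y, bias and LoA."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mean = (pm.rater + pm.model) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, pm.differences, s=14, alpha=0.7, edgecolors="none")
    ax.axhline(report.bias, color="tab:blue", ls="--", label=f"bias {report.bias:.3g}")
    for v in report.loa:
        ax.axhline(v, color="tab:red", ls=":")
    ax.set_xlabel(f"mean of rater and model ({pm.quantity})")
    ax.set_ylabel("rater − model")
    ax.set_title(f"Bland–Altman, n={pm.n}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
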
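"""Method-agreement statistics: regression, Bland-Altman, ICC, RPC, ROC, contingency.

These are the routines used to validate an imaging method against a gold
standard: ordinary regression and Bland-Altman limits of agreement for paired
continuous measurements, two-way random-effects absolute-agreement ICC(2,1)
with F-based confidence limits for observer/test-retest reproducibility, the
repeatability coefficient 1.96 x SD of paired differences, Mann-Whitney AUC
with a Youden-J operating point, and contingency sensitivity / specificity /
accuracy with Clopper-Pearson 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PairedMeasurements:
    a: np.ndarray
    b: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be matching 1-D arrays")
        if self.a.size < 3:
            raise ValueError("need at least 3 pairs")
        if np.any(np.isnan(self.a)) or np.any(np.isnan(self.b)):
            raise ValueError("NaN in paired measurements")


@dataclass
class AgreementResult:
    r: float
    slope: float
    intercept: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    prop_bias_r: float
    prop_bias_p: float


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    best_cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]


@dataclass
class ReproResult:
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    bias_sd: float
    rpc: float
    rpc_percent: float


@dataclass
class ContingencyResult:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    tp: int
    fp: int
    fn: int
    tn: int

    def rounded(self, ndigits: int = 2) -> dict:
        """Report-display rounding of the three headline metrics."""
        return {
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "accuracy": round(self.accuracy, ndigits),
        }


# ---------------------------------------------------------------------------
# Regression and Bland-Altman
# ---------------------------------------------------------------------------

def linear_regression(pm: PairedMeasurements) -> tuple[float, float, float, float]:
    """OLS of b on a: returns (slope, intercept, Pearson r, two-sided p)."""
    if np.var(pm.a) == 0:
        raise ValueError("zero variance in predictor")
    res = sps.linregress(pm.a, pm.b)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def bland_altman(pm: PairedMeasurements) -> AgreementResult:
    """Bias and 95% limits of agreement of a-b, plus proportional-bias trend."""
    slope, intercept, r, p = linear_regression(pm)
    diff = pm.a - pm.b
    mean = 0.5 * (pm.a + pm.b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.var(mean) > 0 and sd > 0:
        trend = sps.linregress(mean, diff)
        prop_r, prop_p = float(trend.rvalue), float(trend.pvalue)
    else:
        prop_r, prop_p = 0.0, 1.0
    return AgreementResult(
        r=r, slope=slope, intercept=intercept, p_value=p,
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        prop_bias_r=prop_r, prop_bias_p=prop_p,
    )


# ---------------------------------------------------------------------------
# ICC(2,1) and repeatability
# ---------------------------------------------------------------------------

def _icc_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, error) for an n x k table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(pm: PairedMeasurements, confidence: float = 0.95) -> ReproResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    The F-based confidence interval follows McGraw & Wong (1996) with the
    Satterthwaite approximation for the denominator degrees of freedom.
    """
    data = np.stack([pm.a, pm.b], axis=1)
    n, k = data.shape
    diff = pm.a - pm.b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rpc = 1.96 * sd
    grand_mean = float(data.mean())
    rpc_pct = 100.0 * rpc / grand_mean if grand_mean != 0 else np.nan

    if np.allclose(pm.a, pm.b) and np.var(pm.a) == 0:
        warnings.warn("degenerate ICC input (all values identical); ICC = 1 by convention")
        return ReproResult(icc=1.0, icc_ci=(1.0, 1.0), bias=bias, bias_sd=sd,
                           rpc=rpc, rpc_percent=rpc_pct)

    msr, msc, mse = _icc_mean_squares(data)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if np.allclose(pm.a, pm.b):
        return ReproResult(icc=1.0, icc_ci=(1.0, 1.0), bias=bias, bias_sd=sd,
                           rpc=rpc, rpc_percent=rpc_pct)

    # McGraw & Wong (1996) interval for ICC(A,1), Satterthwaite df for the
    # mixed denominator term.
    alpha = 1 - confidence
    a_coef = k * icc / (n * (1 - icc))
    b_coef = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a_coef * msc + b_coef * mse) ** 2 / (
        (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_upper = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = sps.f.ppf(1 - alpha / 2, v, n - 1)
    denom_extra = k * msc + (k * n - k - n) * mse
    lower = n * (msr - f_upper * mse) / (f_upper * denom_extra + n * msr)
    upper = n * (f_lower * msr - mse) / (denom_extra + n * f_lower * msr)
    icc_ci = (float(max(-1.0, lower)), float(min(1.0, upper)))
    return ReproResult(icc=float(icc), icc_ci=icc_ci, bias=bias, bias_sd=sd,
                       rpc=rpc, rpc_percent=rpc_pct)


def repeatability_coefficient(diffs: np.ndarray, grand_mean: float | None = None) -> tuple[float, float | None]:
    """RPC = 1.96 x sample SD of differences; percent of the grand mean if given."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 differences")
    rpc = 1.96 * float(diffs.std(ddof=1))
    pct = 100.0 * rpc / grand_mean if grand_mean else None
    return rpc, pct


# ---------------------------------------------------------------------------
# ROC and contingency
# ---------------------------------------------------------------------------

def _clopper_pearson(successes: int, total: int, confidence: float = 0.95) -> tuple[float, float]:
    alpha = 1 - confidence
    lo = sps.beta.ppf(alpha / 2, successes, total - successes + 1) if successes > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, successes + 1, total - successes) if successes < total else 1.0
    return float(lo), float(hi)


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC via the rank formulation; ties between classes count one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_ci(scores: np.ndarray, truth: np.ndarray, auc: float,
               confidence: float = 0.95) -> tuple[float, float]:
    pos = scores[truth]
    neg = scores[~truth]
    m, n = pos.size, neg.size
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(0.5 + confidence / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_analysis(scores: np.ndarray, truth_labels: np.ndarray) -> RocResult:
    """ROC with Youden-J optimal cutoff (ties -> lowest cutoff; positive = score > cutoff)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    auc = mann_whitney_auc(scores, truth)  # raises on single-class input
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos

    best = None
    for cut in np.unique(scores):
        pred = scores > cut
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        sens = tp / n_pos
        spec = 1 - fp / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, tp, fp)
    _, cut, tp, fp = best
    fn = n_pos - tp
    tn = n_neg - fp
    cm = contingency_metrics(tp, fp, fn, tn)
    return RocResult(
        auc=auc,
        auc_ci=_delong_ci(scores, truth, auc),
        best_cutoff=float(cut),
        sensitivity=cm.sensitivity, specificity=cm.specificity, accuracy=cm.accuracy,
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity_ci=cm.sensitivity_ci, specificity_ci=cm.specificity_ci,
        accuracy_ci=cm.accuracy_ci,
    )


def contingency_metrics(tp: int, fp: int, fn: int, tn: int) -> ContingencyResult:
    """Sensitivity, specificity and accuracy with Clopper-Pearson 95% intervals."""
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both margins of the contingency table must be populated")
    total = tp + fp + fn + tn
    return ContingencyResult(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / total,
        sensitivity_ci=_clopper_pearson(tp, tp + fn),
        specificity_ci=_clopper_pearson(tn, tn + fp),
        accuracy_ci=_clopper_pearson(tp + tn, total),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )
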
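"""Discrimination and inference layer.

ROC analysis (midrank/Mann-Whitney AUC with DeLong or bootstrap confidence
intervals), sensitivity/specificity and positive likelihood ratios with
log-scale confidence intervals, single-predictor binary logistic regression by
iteratively reweighted least squares, inversion of the fitted model to the
critical index value where P(ruptured) = 0.5, odds ratios per increment, and
the descriptive two-group tests (Welch t, Pearson chi-squared).

Orientation convention: rupture is associated with LOWER values of the
WTR-family indices, while AR/BF/SR point the other way.  ROC analyses state an
orientation explicitly and internally flip scores so that higher = ruptured,
making AUC > 0.5 comparable across indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Orientation",
    "RocAnalysis",
    "LogisticModel",
    "GroupComparison",
    "SeparationError",
    "ConvergenceError",
    "auc_midrank",
    "auc_ci",
    "sens_spec_at_cutoff",
    "youden_cutoff",
    "positive_lr",
    "lr_ci",
    "roc_points",
    "roc_analysis",
    "fit_logistic",
    "logistic_from_coefficients",
    "critical_value",
    "odds_ratio_per_delta",
    "percent_difference",
    "welch_t_test",
    "chi_squared_test",
]

Orientation = Literal["higher_is_ruptured", "lower_is_ruptured"]


class SeparationError(RuntimeError):
    """The two outcome classes are perfectly separated by the predictor."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# ROC / AUC


def _as_oriented(scores, labels, orientation: Orientation = "higher_is_ruptured"):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if orientation == "lower_is_ruptured":
        s = -s
    elif orientation != "higher_is_ruptured":
        raise ValueError(f"unknown orientation {orientation!r}")
    return s, y


def auc_midrank(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score) with ties counted 1/2.

    Scores must already be oriented so that higher = ruptured (case).  Equals
    the trapezoidal area under the empirical ROC curve.
    """
    s, y = _as_oriented(scores, labels)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(s)  # midranks handle ties
    return (ranks[y].sum() - m * (m + 1) / 2.0) / (m * n)


def _delong_variance(s: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-component variance of the midrank AUC."""
    cases, controls = s[y], s[~y]
    m, n = len(cases), len(controls)
    # placement of each case among controls and vice versa
    v10 = np.empty(m)
    for i, x in enumerate(cases):
        v10[i] = (np.sum(x > controls) + 0.5 * np.sum(x == controls)) / n
    v01 = np.empty(n)
    for j, x in enumerate(controls):
        v01[j] = (np.sum(cases > x) + 0.5 * np.sum(cases == x)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(
    scores,
    labels,
    method: Literal["delong", "bootstrap"] = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """95% confidence interval for the midrank AUC, clipped to [0, 1].

    ``delong`` uses the nonparametric structural-component variance;
    ``bootstrap`` stratified-resamples cases and controls separately.
    """
    s, y = _as_oriented(scores, labels)
    m, n = int(y.sum()), int((~y).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls for an AUC interval")
    a = auc_midrank(s, y)
    if method == "delong":
        se = math.sqrt(_delong_variance(s, y))
        lo, hi = a - 1.959963984540054 * se, a + 1.959963984540054 * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        cases, controls = s[y], s[~y]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            cs = rng.choice(cases, size=m, replace=True)
            ct = rng.choice(controls, size=n, replace=True)
            bs = np.concatenate([cs, ct])
            by = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
            aucs[b] = auc_midrank(bs, by)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
    else:
        raise ValueError(f"unknown AUC CI method {method!r}")
    return max(0.0, float(lo)), min(1.0, float(hi))


def sens_spec_at_cutoff(
    scores, labels, cutoff: float, orientation: Orientation
) -> tuple[float, float]:
    """Sensitivity and specificity at a cutoff.

    For ``lower_is_ruptured`` a score <= cutoff is called positive (ruptured);
    for ``higher_is_ruptured`` a score >= cutoff is.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if orientation == "lower_is_ruptured":
        positive = s <= cutoff
    elif orientation == "higher_is_ruptured":
        positive = s >= cutoff
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    sens = float(np.sum(positive & y)) / n_case if n_case else float("nan")
    spec = float(np.sum(~positive & ~y)) / n_ctrl if n_ctrl else float("nan")
    return sens, spec


def _candidate_cutoffs(s: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus flanking cutoffs."""
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    span = (u[-1] - u[0]) or 1.0
    return np.concatenate([[u[0] - span], u, mids, [u[-1] + span]])


def roc_points(scores, labels, orientation: Orientation):
    """Empirical ROC curve as (cutoff, sensitivity, specificity) triples."""
    s = np.asarray(scores, dtype=float)
    cuts = np.sort(_candidate_cutoffs(s))
    pts = [
        (float(c), *sens_spec_at_cutoff(s, labels, c, orientation)) for c in cuts
    ]
    return pts


def youden_cutoff(scores, labels, orientation: Orientation) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent distinct scores plus one
    cutoff beyond each extreme, so a perfectly separating gap yields its
    midpoint.  Ties are broken toward higher sensitivity, then the smaller
    cutoff.  With a single distinct score every cutoff is equivalent (J = 0)
    and that score is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to choose a cutoff")
    u = np.unique(s)
    if len(u) == 1:
        return float(u[0])
    span = u[-1] - u[0]
    cands = np.concatenate([[u[0] - span], (u[:-1] + u[1:]) / 2.0, [u[-1] + span]])
    best = None
    for c in cands:
        sens, spec = sens_spec_at_cutoff(s, y, c, orientation)
        key = (sens + spec - 1.0, sens, -c)
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1]


def positive_lr(sens: float, spec: float) -> float:
    """Positive likelihood ratio sens / (1 - spec).

    Perfect specificity gives an infinite LR, returned as ``inf`` (flagged by
    the caller, not raised: it is a legitimate boundary of a diagnostic test).
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if spec == 1.0:
        return math.inf
    return sens / (1.0 - spec)


def lr_ci(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, bool]:
    """95% CI for the positive likelihood ratio by the log-method.

    Variance of ln LR+ is (1-sens)/tp + spec/fp.  A zero cell triggers the 0.5
    continuity correction on all four counts; the returned flag is True when
    the correction was applied.  Returns ``(low, high, corrected)``.
    """
    counts = [tp, fn, tn, fp]
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented in the confusion counts")
    corrected = tp == 0 or fp == 0
    if corrected:
        tp, fn, tn, fp = (c + 0.5 for c in counts)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr = positive_lr(sens, spec)
    var = (1.0 - sens) / tp + spec / fp
    half = 1.959963984540054 * math.sqrt(var)
    return lr * math.exp(-half), lr * math.exp(half), corrected


@dataclass(frozen=True)
class RocAnalysis:
    """Full ROC summary for one index on one cohort."""

    index_name: str
    orientation: Orientation
    points: list[tuple[float, float, float]]  # (cutoff, sens, spec)
    auc: float
    auc_ci: tuple[float, float]
    chosen_cutoff: float
    sens: float
    spec: float
    positive_lr: float
    lr_ci: tuple[float, float]
    lr_ci_corrected: bool = False
    n_cases: int = 0
    n_controls: int = 0


def roc_analysis(
    index_name: str,
    scores,
    labels,
    orientation: Orientation,
    cutoff: Optional[float] = None,
    ci_method: Literal["delong", "bootstrap"] = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> RocAnalysis:
    """ROC curve, AUC with 95% CI, and operating point with LR+ and its CI.

    The operating point is the supplied ``cutoff`` if given (so printed
    cutoffs from other studies can be evaluated directly), else the
    Youden-optimal one.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    oriented = -s if orientation == "lower_is_ruptured" else s
    a = auc_midrank(oriented, y)
    ci = auc_ci(oriented, y, method=ci_method, n_boot=n_boot, seed=seed)
    if cutoff is None:
        cutoff = youden_cutoff(s, y, orientation)
    sens, spec = sens_spec_at_cutoff(s, y, cutoff, orientation)
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    tp = round(sens * n_case)
    fp = round((1 - spec) * n_ctrl)
    lo, hi, corrected = lr_ci(tp, n_case - tp, n_ctrl - fp, fp)
    return RocAnalysis(
        index_name=index_name,
        orientation=orientation,
        points=roc_points(s, y, orientation),
        auc=float(a),
        auc_ci=ci,
        chosen_cutoff=float(cutoff),
        sens=float(sens),
        spec=float(spec),
        positive_lr=positive_lr(sens, spec),
        lr_ci=(lo, hi),
        lr_ci_corrected=corrected,
        n_cases=n_case,
        n_controls=n_ctrl,
    )


# ---------------------------------------------------------------------------
# Logistic regression


@dataclass(frozen=True)
class LogisticModel:
    """Single-predictor logistic model P(y=1|x) = 1 / (1 + exp(-(b0 + b1 x)))."""

    index_name: str
    beta0: float
    beta1: float
    se_beta0: float = math.nan
    se_beta1: float = math.nan
    p_value: float = math.nan  # Wald test on the slope
    converged: bool = True
    n_iter: int = 0
    n: int = 0

    def predict(self, x):
        eta = self.beta0 + self.beta1 * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def logistic_from_coefficients(index_name: str, beta0: float, beta1: float) -> LogisticModel:
    """Wrap externally reported coefficients (e.g. a published fit) as a model."""
    return LogisticModel(index_name=index_name, beta0=beta0, beta1=beta1)


def fit_logistic(
    x, y, index_name: str = "x", tol: float = 1e-8, max_iter: int = 100
) -> LogisticModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Converges when the largest absolute coefficient change drops below ``tol``.
    Perfect separation is detected by coefficient divergence (|beta| beyond
    1e3 on standardized data) and raised as :class:`SeparationError` rather
    than returned as a huge unstable estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("y must be binary (0/1)")
    if y.sum() == 0 or y.sum() == len(y):
        raise SeparationError("both outcomes must be present to fit a logistic model")
    # with one predictor, perfect separation is exactly a disjoint support split
    x1, x0 = x[y == 1], x[y == 0]
    if x0.max() < x1.min() or x1.max() < x0.min():
        raise SeparationError(
            "perfect separation: the predictor splits the outcome classes exactly"
        )

    # standardize x for numerical conditioning; transform back at the end
    mu, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0:
        raise ValueError("predictor is constant; slope is unidentifiable")
    z = (x - mu) / sd
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        # Fisher scoring step
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (perfect separation or degenerate data)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "coefficients diverged; the classes are (quasi-)separated by the predictor"
            )
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    # covariance on the standardized scale, then back-transform
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov_z = np.linalg.inv(X.T @ (X * w[:, None]))
    b1 = beta[1] / sd
    b0 = beta[0] - beta[1] * mu / sd
    # var(b1) = var(bz1)/sd^2 ; var(b0) = var(bz0) + (mu/sd)^2 var(bz1) - 2(mu/sd)cov
    var_b1 = cov_z[1, 1] / sd**2
    var_b0 = cov_z[0, 0] + (mu / sd) ** 2 * cov_z[1, 1] - 2 * (mu / sd) * cov_z[0, 1]
    se1 = math.sqrt(var_b1)
    wald = b1 / se1
    p_val = 2.0 * sps.norm.sf(abs(wald))
    return LogisticModel(
        index_name=index_name,
        beta0=float(b0),
        beta1=float(b1),
        se_beta0=math.sqrt(var_b0),
        se_beta1=se1,
        p_value=float(p_val),
        converged=True,
        n_iter=n_iter,
        n=len(y),
    )


def critical_value(model: LogisticModel, p: float = 0.5) -> float:
    """Index value at which the fitted probability equals ``p``.

    Inverts the linear predictor: x* = (logit(p) - beta0) / beta1; for
    p = 0.5 this is -beta0/beta1, the 50% rupture-probability point.
    """
    if model.beta1 == 0:
        raise ValueError("slope is zero: the model never crosses the target probability")
    if not 0 < p < 1:
        raise ValueError("target probability must lie strictly in (0, 1)")
    return (math.log(p / (1.0 - p)) - model.beta0) / model.beta1


def odds_ratio_per_delta(model: LogisticModel, delta: float) -> float:
    """Odds-ratio magnitude per ``delta`` increase of the index: exp(|b1|*delta).

    Reported as a magnitude (> 1 for any nonzero slope) regardless of the
    slope's sign, matching the convention of reporting 'OR per 0.001 increase'
    alongside a model whose probability decreases with the index.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    return math.exp(abs(model.beta1) * delta)


def percent_difference(reference: float, computed: float) -> float:
    """|computed - reference| / |computed| * 100.

    The denominator is the cohort-calculated value, so this answers 'by how
    many percent does the theoretical reference differ from what the data
    gave'.
    """
    if computed == 0:
        raise ValueError("computed value is zero; percent difference undefined")
    return abs(computed - reference) / abs(computed) * 100.0


# ---------------------------------------------------------------------------
# Descriptive group comparisons


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    statistic: float
    p_value: float
    test: Literal["welch_t", "chi_squared"]
    df: float = math.nan
    n: int = 0


def welch_t_test(a, b, variable: str = "") -> GroupComparison:
    """Two-tailed heteroscedastic (Welch) t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return GroupComparison(variable, 0.0, 1.0, "welch_t", df=len(a) + len(b) - 2,
                                   n=len(a) + len(b))
        raise ValueError("both samples have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return GroupComparison(
        variable, float(res.statistic), float(res.pvalue), "welch_t",
        df=float(df), n=len(a) + len(b),
    )


def chi_squared_test(table, variable: str = "") -> GroupComparison:
    """Pearson chi-squared on a 2 x k contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell count; chi-squared is undefined")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return GroupComparison(variable, float(chi2), float(p), "chi_squared",
                           df=float(df), n=int(t.sum()))
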
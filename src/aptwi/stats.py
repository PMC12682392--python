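"""Cohort statistics: group comparison, logistic modelling, ROC and DeLong.

The chain mirrors standard practice for a two-arm response-prediction study:

1. normality gate (Shapiro-Wilk) choosing between the independent-samples
   t-test (pooled or Welch by a variance-ratio F test) and the Mann-Whitney
   U test for continuous features;
2. Pearson chi-square (Yates continuity correction when the smallest expected
   cell count is below 5) or Fisher's exact test for 2x2 categoricals, and a
   fixed-margins Monte-Carlo exact test for sparse r x c tables;
3. univariate maximum-likelihood logistic regression per candidate, then
   forward-stepwise multivariate selection by likelihood-ratio tests;
4. ROC analysis with DeLong standard errors and Youden-index cutoffs, and
   DeLong's paired test for comparing correlated AUCs.

All p-values are two-sided; no multiple-testing adjustment is applied (the
number of tests performed is carried on the report instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln
from sklearn.metrics import roc_curve

__all__ = [
    "SeparationError",
    "ContingencyTable2x2",
    "GroupComparisonResult",
    "ChiSquareResult",
    "LogisticTerm",
    "LogisticModel",
    "ROCResult",
    "shapiro_wilk",
    "compare_groups",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "fisher_rxc_montecarlo",
    "univariate_logistic",
    "fit_logistic",
    "stepwise_logistic",
    "roc_analysis",
    "delong_variance",
    "delong_test",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit is perfectly (quasi-)separated."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a,b,c,d: rows = factor level, columns = response class."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be nonnegative integers")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self) -> int:
        return int(self.a + self.b + self.c + self.d)

    def expected(self) -> np.ndarray:
        t = self.array
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass(frozen=True)
class GroupComparisonResult:
    test_used: str               # "t" | "welch_t" | "mann_whitney"
    statistic: float
    p_value: float
    summaries: tuple             # per-group dicts (mean/sd/median/iqr/n)
    normal: bool                 # both groups passed the normality gate


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    correction_applied: bool
    min_expected: float
    fisher_recommended: bool     # min expected < 1: use the exact test


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    beta: float
    se: float
    z: float                     # Wald z = beta / se
    wald_chi2: float             # z**2 (the chi-square form of the same test)
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LogisticModel:
    terms: tuple                 # LogisticTerm per predictor
    intercept: float
    intercept_se: float
    log_likelihood: float
    n: int
    converged: bool = True
    warnings_: tuple = ()

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> tuple:
        return tuple(t.name for t in self.terms)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        betas = np.array([t.beta for t in self.terms])
        return self.intercept + X @ betas


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se_delong: float
    ci95: tuple
    cutoff: float
    sensitivity: float           # percent
    specificity: float           # percent
    accuracy: float              # percent
    counts: tuple                # (tp, fn, tn, fp) at the cutoff
    orientation: str = ">="      # ">=" predicts positive above cutoff


# ---------------------------------------------------------------------------
# Distribution tests and group comparison
# ---------------------------------------------------------------------------

def shapiro_wilk(values: Sequence[float]) -> tuple:
    """Shapiro-Wilk W and p (Royston's AS R94 approximation), 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk approximation valid only up to n=5000")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: W undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _variance_ratio_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F test of equal variances."""
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    dfx, dfy = x.size - 1, y.size - 1
    p = 2.0 * min(sps.f.cdf(f, dfx, dfy), sps.f.sf(f, dfx, dfy))
    return float(min(p, 1.0))


def _summary(x: np.ndarray) -> dict:
    q25, q50, q75 = np.percentile(x, [25, 50, 75], method="linear")
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
    }


def compare_groups(
    values: Sequence[float],
    group_labels: Sequence,
    alpha_normality: float = 0.05,
) -> GroupComparisonResult:
    """Two-group comparison gated on normality.

    Both groups normal by Shapiro-Wilk at *alpha_normality*: t-test (Welch
    form if the variance-ratio F test rejects equal variances at 0.05, else
    pooled).  Otherwise: Mann-Whitney U with normal approximation and tie
    correction.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    x, y = v[g == levels[0]], v[g == levels[1]]
    if min(x.size, y.size) < 3:
        raise ValueError("each group needs n >= 3")

    def _normal(a: np.ndarray) -> bool:
        if np.ptp(a) == 0.0:
            return False
        return shapiro_wilk(a)[1] > alpha_normality

    summaries = (_summary(x), _summary(y))
    if _normal(x) and _normal(y):
        welch = _variance_ratio_p(x, y) < 0.05
        res = sps.ttest_ind(x, y, equal_var=not welch)
        return GroupComparisonResult(
            "welch_t" if welch else "t",
            float(res.statistic), float(res.pvalue), summaries, True,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparisonResult(
        "mann_whitney", float(res.statistic), float(res.pvalue), summaries, False
    )


# ---------------------------------------------------------------------------
# Categorical tests
# ---------------------------------------------------------------------------

def chi_square_2x2(t: ContingencyTable2x2) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 table, df = 1.

    No correction when every expected count is >= 5; Yates continuity
    correction when the minimum expected count is in [1, 5); below 1 the
    statistic is still returned but the caller is directed to Fisher's exact
    test via ``fisher_recommended``.
    """
    table = t.array
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin: chi-square undefined")
    min_exp = float(t.expected().min())
    correction = min_exp < 5.0
    res = sps.chi2_contingency(table, correction=correction)
    return ChiSquareResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        correction_applied=correction,
        min_expected=min_exp,
        fisher_recommended=min_exp < 1.0,
    )


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    fixed-margin tables no more probable than the observed one."""
    return float(sps.fisher_exact(t.array, alternative="two-sided")[1])


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r x c table under fixed margins (hypergeometric)."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_rxc_montecarlo(
    table: np.ndarray, reps: int = 20000, seed: int = 0
) -> tuple:
    """Monte-Carlo exact test for an r x c table with fixed margins.

    Samples *reps* tables with the observed margins (Patefield algorithm) and
    returns (p, mc_se) where p is the add-one-estimated share of tables whose
    fixed-margin probability does not exceed the observed table's.
    """
    if reps < 10_000:
        raise ValueError("reps must be >= 10000 for a stable Monte-Carlo p")
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D nonnegative count array")
    obs_lp = _log_table_prob(t)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    samples = dist.rvs(reps, method="patefield", random_state=rng)
    lps = np.array([_log_table_prob(s) for s in samples])
    hits = int(np.sum(lps <= obs_lp + 1e-9))
    p = (hits + 1) / (reps + 1)
    se = float(np.sqrt(p * (1 - p) / reps))
    return float(p), se


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

_SEPARATION_BETA = 15.0  # |beta| beyond this on standardized-ish data = separation


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic fit (Newton-Raphson) with Wald inference.

    SEs come from the observed information; odds ratios are exp(beta) with
    95% Wald intervals exp(beta +/- 1.96 SE).  Perfect or quasi-perfect
    separation raises SeparationError rather than returning runaway betas.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(y).size:
        X = X.T
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size != 2 or not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("y must contain both classes, coded 0/1")
    if len(names) != X.shape[1]:
        raise ValueError("names must match the number of predictors")
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(
                disp=0, method="newton", tol=tol, maxiter=maxiter
            )
        except Exception as exc:  # singular Hessian etc. on separated data
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    msgs = tuple(str(w.message) for w in wlist)
    if any("separation" in m.lower() for m in msgs):
        raise SeparationError("perfect separation detected in logistic fit")
    if np.any(np.abs(res.params[1:]) > _SEPARATION_BETA):
        raise SeparationError("runaway coefficient: data are (quasi-)separated")
    terms = []
    for i, name in enumerate(names, start=1):
        b, se = float(res.params[i]), float(res.bse[i])
        z = b / se
        terms.append(LogisticTerm(
            name=name, beta=b, se=se, z=z, wald_chi2=z * z,
            p=float(2.0 * sps.norm.sf(abs(z))),
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - 1.96 * se)),
            ci_high=float(np.exp(b + 1.96 * se)),
        ))
    return LogisticModel(
        terms=tuple(terms),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        log_likelihood=float(res.llf),
        n=int(y.size),
        converged=bool(res.mle_retvals.get("converged", True)),
        warnings_=msgs,
    )


def univariate_logistic(
    x: Sequence[float], y: Sequence[int], name: str = "x"
) -> LogisticModel:
    """Single-predictor ML logistic regression of a binary outcome on x.

    For a binary predictor the fitted odds ratio equals the contingency
    cross-product ratio (a*d)/(b*c) — the saturated-model identity.  A zero
    cell makes the data quasi-separated and raises SeparationError.
    """
    x = np.asarray(x, dtype=float)
    return fit_logistic(x.reshape(-1, 1), np.asarray(y, dtype=float), [name])


def _intercept_ll(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = y.size - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def stepwise_logistic(
    candidates: dict,
    y: Sequence[int],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> LogisticModel:
    """Forward-stepwise multivariate logistic regression.

    At each step the excluded candidate with the smallest likelihood-ratio
    p-value (vs the current model) enters if p < p_enter; after each entry,
    included terms whose LR p against the reduced model exceeds p_remove are
    dropped.  Ties and candidate ordering resolve lexicographically by name,
    so the procedure is deterministic.  Candidates that fail to fit
    (separation) are skipped.  If nothing enters, the intercept-only model is
    returned (with a warning recorded on the model).
    """
    y = np.asarray(y, dtype=float)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    cand = {k: np.asarray(v, dtype=float) for k, v in sorted(candidates.items())}
    n = y.size
    if n <= 10 * len(cand):
        warnings.warn(
            f"n={n} is small for {len(cand)} candidates (events-per-variable)",
            stacklevel=2,
        )

    def _fit(names: list) -> LogisticModel | None:
        if not names:
            return None
        X = np.column_stack([cand[k] for k in names])
        return fit_logistic(X, y, names)

    def _ll(model: LogisticModel | None) -> float:
        return _intercept_ll(y) if model is None else model.log_likelihood

    included: list = []
    current: LogisticModel | None = None
    while True:
        best_name, best_p = None, None
        for name in cand:
            if name in included:
                continue
            try:
                trial = _fit(sorted(included + [name]))
            except SeparationError:
                continue
            lr = 2.0 * (trial.log_likelihood - _ll(current))
            p = float(sps.chi2.sf(max(lr, 0.0), df=1))
            if best_p is None or p < best_p:  # strict: lexicographic tie-break
                best_name, best_p = name, p
        if best_name is None or best_p >= p_enter:
            break
        included = sorted(included + [best_name])
        current = _fit(included)
        # backward pass: re-test each included term against its reduced model
        changed = True
        while changed and len(included) > 1:
            changed = False
            for name in list(included):
                reduced = _fit(sorted(set(included) - {name}))
                lr = 2.0 * (current.log_likelihood - _ll(reduced))
                p = float(sps.chi2.sf(max(lr, 0.0), df=1))
                if p > p_remove:
                    included = sorted(set(included) - {name})
                    current = reduced
                    changed = True
                    break
    if current is None:
        warnings.warn("no candidate met p_enter; returning intercept-only model",
                      stacklevel=2)
        p1 = y.mean()
        return LogisticModel(
            terms=(), intercept=float(np.log(p1 / (1 - p1))),
            intercept_se=float("nan"), log_likelihood=_intercept_ll(y),
            n=int(n), warnings_=("intercept-only",),
        )
    return current


# ---------------------------------------------------------------------------
# ROC and DeLong
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """DeLong structural components (placement values) and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # psi(X_i, Y_j) = 1 if X>Y, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """(AUC, DeLong variance of the AUC estimator)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01, auc = _placements(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis with DeLong SE and a Youden-index operating point.

    AUC is the area under the empirical ROC curve by the trapezoidal rule
    (ties contribute half), identical to the normalized Mann-Whitney U
    statistic.  If the raw AUC is below 0.5 the orientation flips (lower
    scores predict the positive class) and all operating statistics are
    reported for the flipped classifier.  The cutoff is the smallest observed
    score attaining the maximum Youden index J = sens + spec - 1, with the
    "score >= cutoff -> positive" convention.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("both outcome classes must be present")
    auc_raw, _ = delong_variance(s, y)
    orientation = ">="
    if auc_raw < 0.5:
        s = -s
        orientation = "<="
    auc, var = delong_variance(s, y)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    jmax = j.max()
    # candidates at max J; pick the smallest reported cutoff value
    cand = np.flatnonzero(j >= jmax - 1e-12)
    cut_internal = min(thr[i] for i in cand if np.isfinite(thr[i]))
    pred = s >= cut_internal
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    cutoff = -cut_internal if orientation == "<=" else cut_internal
    return ROCResult(
        auc=float(auc), se_delong=se, ci95=ci, cutoff=float(cutoff),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / y.size,
        counts=(tp, fn, tn, fp),
        orientation=orientation,
    )


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> tuple:
    """DeLong's paired test for two correlated AUCs on the same subjects.

    Returns (z, p) with z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov),
    covariance estimated from the placement values, p two-sided normal.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired design: both score vectors must match labels")
    if np.unique(y).size != 2:
        raise ValueError("both outcome classes must be present")
    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(v10a, v10b, ddof=1)
    s01 = np.cov(v01a, v01b, ddof=1)
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0:
        if auc_a == auc_b:
            raise ValueError("zero variance of the AUC difference")
        var_diff = max(var_diff, 1e-300)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p
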
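"""Behavioural and brain-behaviour statistics.

Paired comparisons use a Shapiro-Wilk gate: normal-looking paired
differences get a paired t-test (effect size Cohen's d), otherwise a
Wilcoxon signed-rank test (Pratt's zero handling, exact null for small
samples, normal approximation with continuity correction beyond that;
effect size r = Z/sqrt(N)).  Repeated-measures ANOVA applies the
Greenhouse-Geisser correction when Mauchly's test rejects sphericity.
Brain-behaviour regressions are robust (IRLS, Tukey bisquare, Huber
start).  The within-participant mediation follows the two-condition
difference-score formulation: the a path is the mean mediator difference,
the b path the slope of the outcome difference on the centred mediator
difference (controlling the centred mediator mean), and the indirect
effect a*b gets a Monte-Carlo confidence interval from independent normal
draws of the two paths.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

EXACT_WILCOXON_MAX_N = 12


# --------------------------------------------------------------------------
@dataclass
class PairedTestResult:
    statistic: float
    p: float
    p_corrected: float
    effect_size: float
    effect_size_type: str      # "cohen_d", "r", or "eta_p2"
    method: str                # "t", "wilcoxon", "rm_anova"
    n: int
    df: tuple[float, float] | float | None = None


@dataclass
class RegressionResult:
    beta: float
    p: float
    n: int
    se: float
    estimator: str = "IRLS bisquare (Huber start)"


@dataclass
class MediationResult:
    a_path: float
    b_path: float
    indirect: float
    ci: tuple[float, float]
    n_mc: int
    alpha: float
    total_beta_before: float
    direct_beta_after: float
    a_p: float
    b_p: float
    total_p: float
    direct_p: float
    n: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        lo, hi = self.ci
        return not (lo <= 0.0 <= hi)

    @property
    def full_mediation(self) -> bool:
        return (self.significant and self.total_p < self.alpha
                and self.direct_p >= self.alpha)


# --------------------------------------------------------------------------
def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> str:
    """Choose 't' or 'wilcoxon' from a Shapiro-Wilk test on the differences."""
    d = np.asarray(differences, float)
    if len(d) < 3:
        raise ValueError("need at least 3 paired differences")
    if np.ptp(d) == 0:
        warnings.warn("constant differences: falling back to wilcoxon",
                      stacklevel=2)
        return "wilcoxon"
    _, p = sps.shapiro(d)
    return "t" if p >= alpha else "wilcoxon"


def _signed_rank_parts(d: np.ndarray):
    """Pratt ranking: rank |d| with zeros included, then drop zeros."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))      # mid-ranks for ties
    nz = d != 0
    return ranks[nz], np.sign(d[nz]), int((~nz).sum())


def wilcoxon_signed_rank(d: np.ndarray) -> tuple[float, float, float]:
    """Signed-rank test on paired differences; returns (W+, Z, two-sided p).

    Pratt's method for zeros; exact enumeration of the sign-flip null when
    n <= 12 pairs, otherwise a normal approximation with tie and zero
    corrections and a 0.5 continuity correction.  Z is always reported
    (from the normal approximation) so r = Z/sqrt(N) is available.
    """
    d = np.asarray(d, float)
    n = len(d)
    ranks, signs, n_zero = _signed_rank_parts(d)
    w_plus = float(ranks[signs > 0].sum())

    # normal approximation moments under Pratt's treatment of zeros
    zr = n_zero
    mean = (n * (n + 1) - zr * (zr + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - zr * (zr + 1) * (2 * zr + 1)) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    if var <= 0:
        return w_plus, 0.0, 1.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var) if delta != 0 else 0.0

    if n <= EXACT_WILCOXON_MAX_N:
        m = len(ranks)
        total = 2**m
        count_le = count_ge = 0
        for signs_iter in itertools.product((0.0, 1.0), repeat=m):
            w = float(np.dot(signs_iter, ranks))
            if w <= w_plus + 1e-12:
                count_le += 1
            if w >= w_plus - 1e-12:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, float(z), float(p)


def paired_tests(a: np.ndarray, b: np.ndarray, n_comparisons: int = 1,
                 method: str | None = None) -> PairedTestResult:
    """Paired comparison of two conditions with Bonferroni correction.

    ``method`` None auto-selects via the Shapiro-Wilk gate; 't' and
    'wilcoxon' force a choice.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("conditions must be equal-length 1-D arrays")
    d = a - b
    n = len(d)
    if method is None:
        method = normality_gate(d)

    if method == "t":
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance differences: t-test undefined")
        t_stat, p = sps.ttest_rel(a, b)
        eff = float(d.mean() / sd)
        stat, es_type, dfree = float(t_stat), "cohen_d", float(n - 1)
    elif method == "wilcoxon":
        _, z, p = wilcoxon_signed_rank(d)
        eff = float(z / np.sqrt(n))
        stat, es_type, dfree = float(z), "r", None
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedTestResult(statistic=stat, p=float(p),
                            p_corrected=float(min(1.0, p * n_comparisons)),
                            effect_size=eff, effect_size_type=es_type,
                            method=method, n=n, df=dfree)


def rm_anova(values: np.ndarray | pd.DataFrame) -> PairedTestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``values`` is subjects x levels (complete cells required).  The
    corrected p is used whenever Mauchly's test rejects sphericity; with
    two levels sphericity holds trivially and epsilon is 1.  Effect size
    is partial eta squared.
    """
    import pingouin as pg

    arr = np.asarray(values, float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a subjects x levels matrix with >= 2 levels")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing cells: repeated-measures ANOVA needs complete data")
    n_subj, k = arr.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), k),
        "level": np.tile(np.arange(k), n_subj),
        "value": arr.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=long, dv="value", within="level",
                          subject="subject", correction="auto", detailed=True)
    row = aov.iloc[0]
    ss_eff = float(row["SS"])
    ss_err = float(aov.iloc[1]["SS"])
    eta_p2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    f_stat = float(row["F"])
    p = float(row["p_unc"])
    if not np.isfinite(f_stat):
        # degenerate 0/0 case (e.g. identical columns): no effect, no error
        scale = max(np.abs(arr).max() ** 2, 1.0)
        if ss_eff <= 1e-12 * scale:
            f_stat, p = 0.0, 1.0
    sphericity_violated = ("sphericity" in aov.columns
                           and row["sphericity"] == False)  # noqa: E712
    if sphericity_violated and "p_GG_corr" in aov.columns and np.isfinite(
            float(row["p_GG_corr"])):
        p = float(row["p_GG_corr"])
    return PairedTestResult(statistic=f_stat, p=p, p_corrected=p,
                            effect_size=float(eta_p2),
                            effect_size_type="eta_p2", method="rm_anova",
                            n=n_subj, df=(float(row["DF"]),
                                          float(aov.iloc[1]["DF"])))


def robust_regression(x: np.ndarray, y: np.ndarray,
                      standardize: bool = True) -> RegressionResult:
    """Robust simple regression (standardised slope by default).

    IRLS with a Tukey bisquare M-estimator, initialised from a Huber fit
    (convex, hence a reproducible starting point).  The slope p-value uses
    a t reference with n-2 degrees of freedom.  With ``standardize=False``
    the slope is reported in raw units.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance in x")
    if standardize:
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
    else:
        xs, ys = x, y
    X = sm.add_constant(xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.RLM(ys, X, M=sm.robust.norms.HuberT()).fit().params
        fit = sm.RLM(ys, X, M=sm.robust.norms.TukeyBiweight()).fit(
            start_params=start)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(2.0 * sps.t.sf(abs(beta / se), n - 2)) if se > 0 else 0.0
    return RegressionResult(beta=beta, p=p, n=n, se=se)


def within_mediation(
    m: np.ndarray,
    y: np.ndarray,
    n_mc: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    control_mediator_mean: bool = True,
) -> MediationResult:
    """Within-participant mediation for two repeated conditions.

    ``m`` and ``y`` are subjects x 2 arrays (columns: reference condition,
    treatment condition); the binary predictor is the condition contrast
    itself.  The indirect effect is a*b exactly; only its Monte-Carlo
    confidence interval is stochastic.
    """
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if m.shape != y.shape or m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("mediator and outcome must be subjects x 2 arrays")
    n = m.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")

    md = m[:, 1] - m[:, 0]
    yd = y[:, 1] - y[:, 0]
    msum_c = m.mean(axis=1) - m.mean()

    a = float(md.mean())
    se_a = float(md.std(ddof=1) / np.sqrt(n))
    a_t = a / se_a if se_a > 0 else 0.0
    a_p = float(2.0 * sps.t.sf(abs(a_t), n - 1))

    if control_mediator_mean and msum_c.std() > 0:
        r = np.corrcoef(md, msum_c)[0, 1] if md.std() > 0 else 0.0
        if abs(r) > 0.999:      # collinear covariate carries no information
            control_mediator_mean = False
    # mediator difference enters uncentred: the intercept is then the
    # direct effect (expected outcome difference at zero mediator change)
    cols = [np.ones(n), md] + ([msum_c] if control_mediator_mean else [])
    X = np.column_stack(cols)
    ols = sm.OLS(yd, X).fit()
    b = float(ols.params[1])
    se_b = float(ols.bse[1])
    b_p = float(ols.pvalues[1])
    direct = float(ols.params[0])
    direct_p = float(ols.pvalues[0])

    total = float(yd.mean())
    se_tot = float(yd.std(ddof=1) / np.sqrt(n))
    total_p = float(2.0 * sps.t.sf(abs(total / se_tot), n - 1)) if se_tot > 0 else 1.0

    rng = np.random.default_rng(seed)
    draws = (a + se_a * rng.standard_normal(n_mc)) * \
            (b + se_b * rng.standard_normal(n_mc))
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MediationResult(a_path=a, b_path=b, indirect=float(a * b),
                           ci=(float(lo), float(hi)), n_mc=n_mc, alpha=alpha,
                           total_beta_before=total, direct_beta_after=direct,
                           a_p=a_p, b_p=b_p, total_p=total_p,
                           direct_p=direct_p, n=n, seed=seed)


def mediation_continuous(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_mc: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MediationResult:
    """Product-of-coefficients mediation for a continuous predictor.

    Used for across-subject difference scores (e.g. Delta entrainment ->
    Delta Mu suppression -> Delta SCR frequency): a is the slope of m on x,
    b the slope of y on m controlling x; the indirect effect a*b gets the
    same Monte-Carlo interval as the within-participant case.  Variables
    are standardised so paths are comparable across measures.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be equal-length 1-D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 subjects")

    def z(v: np.ndarray) -> np.ndarray:
        s = v.std(ddof=1)
        if s == 0:
            raise ValueError("zero-variance variable in mediation")
        return (v - v.mean()) / s

    xs, ms, ys = z(x), z(m), z(y)
    fit_a = sm.OLS(ms, sm.add_constant(xs)).fit()
    a, se_a, a_p = (float(fit_a.params[1]), float(fit_a.bse[1]),
                    float(fit_a.pvalues[1]))
    X2 = np.column_stack([np.ones(n), ms, xs])
    fit_b = sm.OLS(ys, X2).fit()
    b, se_b, b_p = (float(fit_b.params[1]), float(fit_b.bse[1]),
                    float(fit_b.pvalues[1]))
    direct, direct_p = float(fit_b.params[2]), float(fit_b.pvalues[2])
    fit_c = sm.OLS(ys, sm.add_constant(xs)).fit()
    total, total_p = float(fit_c.params[1]), float(fit_c.pvalues[1])

    rng = np.random.default_rng(seed)
    draws = (a + se_a * rng.standard_normal(n_mc)) * \
            (b + se_b * rng.standard_normal(n_mc))
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MediationResult(a_path=a, b_path=b, indirect=float(a * b),
                           ci=(float(lo), float(hi)), n_mc=n_mc, alpha=alpha,
                           total_beta_before=total, direct_beta_after=direct,
                           a_p=a_p, b_p=b_p, total_p=total_p,
                           direct_p=direct_p, n=n, seed=seed)
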
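"""Normality-gated tests, outlier rules, multiplicity corrections, and
random-intercept mixed-model likelihood-ratio tests.

Two related samples are compared with a paired t-test when the Shapiro-Wilk
test of the paired differences does not reject normality (p >= 0.05) and a
Wilcoxon signed-rank test otherwise; correlations analogously switch between
Pearson and Spearman.  Correlation inputs first pass the 1.5-IQR outlier
rule.  Families of correlations are corrected with Benjamini-Hochberg FDR,
post-hoc model contrasts with Holm's method.

The mixed-model layer fits random-intercept linear models by maximum
likelihood and compares nested fixed-effect structures by likelihood-ratio
chi-square, the standard R ``lmer`` + ``anova`` workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

SHAPIRO_ALPHA = 0.05


@dataclass
class TestResult:
    method: str            # paired_t | wilcoxon | pearson | spearman
    statistic: float
    p_value: float
    n: int
    df: float | None = None
    gate_p: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"method": self.method, "statistic": self.statistic,
                "p_value": self.p_value, "n": self.n, "df": self.df,
                "gate_p": self.gate_p, "degenerate": self.degenerate}


@dataclass
class ModelComparison:
    full_terms: list[str]
    reduced_terms: list[str]
    lr_statistic: float
    df: int
    p_value: float
    singular: bool = False
    posthoc: list[tuple[str, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"full_terms": self.full_terms,
                "reduced_terms": self.reduced_terms,
                "lr_statistic": self.lr_statistic, "df": self.df,
                "p_value": self.p_value, "singular": self.singular,
                "posthoc": [list(c) for c in self.posthoc]}


def _safe_shapiro(x: np.ndarray) -> float:
    """Shapiro-Wilk p, treating zero-variance input as trivially normal."""
    if np.ptp(x) == 0:
        return 1.0
    return float(sps.shapiro(x).pvalue)


def gated_paired_test(x, y, alpha_gate: float = SHAPIRO_ALPHA) -> TestResult:
    """Paired t-test or Wilcoxon signed-rank, gated on difference normality."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.all(d == 0):
        return TestResult("paired_t", 0.0, 1.0, n, df=n - 1, gate_p=1.0,
                          degenerate=True)
    gate_p = _safe_shapiro(d)
    if gate_p >= alpha_gate:
        res = sps.ttest_rel(x, y)
        return TestResult("paired_t", float(res.statistic),
                          float(res.pvalue), n, df=float(n - 1), gate_p=gate_p)
    res = sps.wilcoxon(x, y, alternative="two-sided")
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue), n,
                      gate_p=gate_p)


def iqr_outliers(x) -> np.ndarray:
    """Flags for values beyond 1.5 interquartile ranges outside [Q1, Q3].

    Quartiles use linear interpolation of order statistics.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def gated_correlation(x, y, alpha_gate: float = SHAPIRO_ALPHA) -> TestResult:
    """Pearson or Spearman correlation, gated on marginal normality.

    Pairs with either coordinate flagged by the 1.5-IQR rule are removed
    first; Pearson requires both remaining variables to pass Shapiro-Wilk.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    keep = ~(iqr_outliers(x) | iqr_outliers(y))
    x, y = x[keep], y[keep]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance after outlier removal")
    gate = min(_safe_shapiro(x), _safe_shapiro(y))
    if gate >= alpha_gate:
        r, p = sps.pearsonr(x, y)
        return TestResult("pearson", float(r), float(p), x.size,
                          df=float(x.size - 2), gate_p=gate)
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), x.size, gate_p=gate)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _fit_mixed(formula: str, data: pd.DataFrame, group: str, reml: bool,
               methods: tuple[str, ...] = ("lbfgs",)):
    """Fit a random-intercept model, keeping the best finite likelihood.

    Boundary fits (random-effect variance near 0) can stall one optimiser or
    leave a singular Hessian; later optimisers in ``methods`` serve as
    fallbacks and the highest-likelihood finite fit wins.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM.from_formula(formula, groups=data[group], data=data)
        best = None
        last_err = None
        exhaustive = len(methods) > 1
        fallbacks = [m for m in ("bfgs", "powell", "nm") if m not in methods]
        for method in list(methods) + fallbacks:
            try:
                res = model.fit(reml=reml, method=method, maxiter=500,
                                disp=False)
            except np.linalg.LinAlgError as err:
                last_err = err
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
            # single-method callers stop at the first usable fit
            if best is not None and not exhaustive:
                return best
        if best is None:
            raise last_err or np.linalg.LinAlgError("all mixed fits failed")
        return best


def _pairwise_contrasts(result, term: str, data: pd.DataFrame,
                        ) -> list[tuple[str, float, float]]:
    """Holm-adjusted pairwise level contrasts of a categorical fixed effect.

    For an additive treatment-coded model, differences of estimated marginal
    means between factor levels equal differences of the corresponding
    coefficients; SEs come from the fixed-effect covariance and a normal
    reference is used.
    """
    levels = sorted(data[term].astype(str).unique())
    if len(levels) < 2:
        return []
    names = list(result.fe_params.index)
    cov = np.asarray(result.cov_params())[:len(names), :][:, :len(names)]

    def vec(level: str) -> np.ndarray:
        v = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == f"{term}[T.{level}]" or nm == f"C({term})[T.{level}]":
                v[i] = 1.0
        return v

    contrasts, raw_p = [], []
    for a, b in combinations(levels, 2):
        L = vec(b) - vec(a)
        est = float(L @ result.fe_params.values)
        se = float(np.sqrt(L @ cov @ L))
        if se == 0:
            continue
        z = est / se
        raw_p.append(2 * sps.norm.sf(abs(z)))
        contrasts.append((f"{b} - {a}", est))
    adj = holm(raw_p)
    return [(name, est, float(p)) for (name, est), p in zip(contrasts, adj)]


def lme_lrt(data: pd.DataFrame, response: str, fixed_terms: list[str],
            dropped_term: str, group: str = "subject_id",
            reml: bool = False) -> ModelComparison:
    """Likelihood-ratio test for one fixed effect in a random-intercept model.

    Fits ``response ~ fixed_terms + (1 | group)`` and the same model without
    ``dropped_term``, both by maximum likelihood (REML fits are not nested
    across fixed-effect structures); the statistic is
    ``2 (ll_full - ll_reduced)`` on as many degrees of freedom as parameters
    dropped.  When the dropped term is a categorical factor, Holm-adjusted
    pairwise contrasts of its levels are attached.
    """
    if dropped_term not in fixed_terms:
        raise ValueError(f"{dropped_term!r} not among fixed terms")
    # drop incomplete rows ourselves so the groups vector stays aligned with
    # the design matrix the formula machinery builds
    used = [c for c in {response, group, *fixed_terms} if c in data.columns]
    data = data.dropna(subset=used).reset_index(drop=True)
    counts = data.groupby(group).size()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 observations")
    reduced_terms = [t for t in fixed_terms if t != dropped_term]
    full_f = f"{response} ~ {' + '.join(fixed_terms)}"
    red_f = (f"{response} ~ {' + '.join(reduced_terms)}"
             if reduced_terms else f"{response} ~ 1")
    full = _fit_mixed(full_f, data, group, reml=False)
    red = _fit_mixed(red_f, data, group, reml=False)
    if full.llf < red.llf - 1e-8:
        # nested models: the full fit cannot be worse at the true optimum
        fallback = ("lbfgs", "bfgs", "powell", "nm")
        full = _fit_mixed(full_f, data, group, reml=False, methods=fallback)
        red = _fit_mixed(red_f, data, group, reml=False, methods=fallback)
    lr = max(0.0, 2.0 * (full.llf - red.llf))
    df = len(full.fe_params) - len(red.fe_params)
    if df < 1:
        raise ValueError("dropped term contributes no parameters")
    p = float(sps.chi2.sf(lr, df))
    singular = bool(np.asarray(full.cov_re).min() < 1e-8
                    or not full.converged)
    posthoc = []
    if not np.issubdtype(data[dropped_term].dtype, np.number):
        posthoc = _pairwise_contrasts(full, dropped_term, data)
    return ModelComparison(list(fixed_terms), reduced_terms, float(lr), df, p,
                           singular=singular, posthoc=posthoc)
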
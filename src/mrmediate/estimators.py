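"""Two-sample MR estimators: Wald ratio, IVW, MR-Egger, weighted median.

All estimators consume per-SNP summary associations: exposure effects
``gamma_j`` with standard errors ``se_gamma_j`` and outcome effects
``Gamma_j`` with ``se_Gamma_j`` for J independent instruments.  Under the
instrumental-variable assumptions each per-SNP Wald ratio
``b_j = Gamma_j / gamma_j`` estimates the same causal effect; the methods
differ in how they pool the ratios and which assumption violations they
tolerate.

The estimators are written as scikit-learn style classes — ``fit`` takes
the exposure effects as ``X`` and outcome effects as ``y`` with standard
errors as fit parameters, and exposes fitted attributes ``beta_``, ``se_``,
``ci_low_``, ``ci_high_``, ``pval_`` — with thin module-level functions
(:func:`ivw`, :func:`egger`, :func:`weighted_median`, :func:`wald_ratio`)
operating directly on a :class:`~mrmediate.gwas_io.HarmonizedSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .gwas_io import HarmonizedSet

__all__ = [
    "MrResult",
    "EggerResult",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
]

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


@dataclass
class MrResult:
    """One method's causal estimate on the log-OR (or SD-unit) scale.

    ``or_point``/``or_ci`` are the exp-transformed estimate and 95% CI,
    meaningful when the outcome is binary.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_row(self) -> dict:
        lo, hi = self.or_ci
        return {"method": self.method, "n_snps": self.n_snps,
                "beta": self.beta, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "pval": self.pval, "or": self.or_point,
                "or_ci_low": lo, "or_ci_high": hi}


@dataclass
class EggerResult(MrResult):
    """MR-Egger slope plus the intercept (directional-pleiotropy) test."""

    intercept: float = 0.0
    intercept_se: float = float("nan")
    intercept_pval: float = 1.0

    def to_row(self) -> dict:
        row = super().to_row()
        row.update(intercept=self.intercept, intercept_se=self.intercept_se,
                   intercept_pval=self.intercept_pval)
        return row


def _two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2 * stats.norm.sf(np.abs(z))


def _validate_xy(X, y, se_exposure, se_outcome):
    gamma = np.asarray(X, dtype=float).reshape(-1)
    Gamma = np.asarray(y, dtype=float).reshape(-1)
    se_g = np.asarray(se_exposure, dtype=float).reshape(-1) \
        if se_exposure is not None else np.full_like(gamma, np.nan)
    se_G = np.asarray(se_outcome, dtype=float).reshape(-1)
    if not (len(gamma) == len(Gamma) == len(se_G)):
        raise ValueError("gamma, Gamma and se_outcome lengths differ")
    if np.any(se_G <= 0):
        raise ValueError("outcome standard errors must be positive")
    if np.any(gamma == 0):
        raise ValueError("zero exposure effects must be filtered upstream")
    return gamma, Gamma, se_g, se_G


# --------------------------------------------------------------------------
# Wald ratio

def wald_ratio(gamma: float, se_gamma: float, Gamma: float,
               se_Gamma: float) -> MrResult:
    """Single-instrument causal estimate Gamma/gamma.

    The standard error is first-order: se = se_Gamma / |gamma| (uncertainty
    in the exposure effect ignored, standard for strong instruments).
    """
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    return MrResult("wald", float(beta), float(se),
                    float(_two_sided_p(beta / se)), 1)


# --------------------------------------------------------------------------
# IVW

class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    Equivalent to weighted least squares of the outcome effects on the
    exposure effects through the origin with weights 1/se_outcome²; in
    ratio space the weights are w_j = gamma_j²/se_Gamma_j².

    Parameters
    ----------
    mode : {"fixed", "multiplicative_random", "auto"}
        Fixed-effect SE, multiplicative-random-effects SE (inflated by
        sqrt(max(1, Q/(J-1)))), or automatic escalation to MRE when
        Cochran's Q has p < ``q_escalation_p``.
    q_escalation_p : float
        Heterogeneity p-value below which "auto" switches to MRE.

    Attributes
    ----------
    beta_, se_, ci_low_, ci_high_, pval_ : float
        Causal estimate on the input scale with normal-based 95% CI.
    q_, q_df_, q_pval_ : float
        Cochran's heterogeneity statistic about the IVW fit.
    mode_used_ : str
        "fixed" or "multiplicative_random" after auto-resolution.
    n_snps_ : int
    """

    def __init__(self, mode: str = "fixed", q_escalation_p: float = 0.05):
        self.mode = mode
        self.q_escalation_p = q_escalation_p

    def fit(self, X, y, se_outcome=None, se_exposure=None):
        if self.mode not in ("fixed", "multiplicative_random", "auto"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if se_outcome is None:
            raise ValueError("se_outcome is required")
        gamma, Gamma, _, se_G = _validate_xy(X, y, se_exposure, se_outcome)
        J = len(gamma)
        if J < 1:
            raise InsufficientInstrumentsError("IVW needs at least 1 SNP")

        w = gamma**2 / se_G**2
        b = Gamma / gamma
        sw = w.sum()
        beta = float((w * b).sum() / sw)
        se_fe = float(sw ** -0.5)

        if J >= 2:
            q = float((w * (b - beta) ** 2).sum())
            q_df = J - 1
            q_pval = float(stats.chi2.sf(q, q_df))
        else:
            q, q_df, q_pval = 0.0, 0, 1.0

        mode = self.mode
        if mode == "auto":
            mode = ("multiplicative_random"
                    if J >= 2 and q_pval < self.q_escalation_p else "fixed")
        se = se_fe
        if mode == "multiplicative_random" and J >= 2:
            se = se_fe * float(np.sqrt(max(1.0, q / (J - 1))))

        self.beta_, self.se_ = beta, se
        self.ci_low_, self.ci_high_ = beta - Z95 * se, beta + Z95 * se
        self.pval_ = float(_two_sided_p(beta / se))
        self.q_, self.q_df_, self.q_pval_ = q, q_df, q_pval
        self.mode_used_ = mode
        self.n_snps_ = J
        return self

    def predict(self, X):
        """Fitted outcome effects beta_ * gamma for given exposure effects."""
        return self.beta_ * np.asarray(X, dtype=float).reshape(-1)

    def to_result(self) -> MrResult:
        method = ("ivw_mre" if self.mode_used_ == "multiplicative_random"
                  else "ivw_fe")
        return MrResult(method, self.beta_, self.se_, self.pval_,
                        self.n_snps_)


def ivw(hset: HarmonizedSet, mode: str = "fixed",
        q_escalation_p: float = 0.05) -> MrResult:
    """IVW causal estimate from a harmonized set (J=1 → Wald ratio)."""
    if hset.n_snps == 1:
        return wald_ratio(hset.beta_exposure[0], hset.se_exposure[0],
                          hset.beta_outcome[0], hset.se_outcome[0])
    est = IVWEstimator(mode=mode, q_escalation_p=q_escalation_p)
    est.fit(hset.beta_exposure, hset.beta_outcome,
            se_outcome=hset.se_outcome, se_exposure=hset.se_exposure)
    return est.to_result()


# --------------------------------------------------------------------------
# MR-Egger

class EggerEstimator(BaseEstimator):
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept.

    Each SNP is first oriented so its exposure effect is positive (both
    effects negated when gamma_j < 0); the regression
    ``Gamma_j = b0 + b1 * gamma_j`` with weights 1/se_Gamma_j² then gives
    the causal slope ``b1`` and the average directional pleiotropy ``b0``.
    A nonzero intercept signals violation of the exclusion restriction.

    ``mode="multiplicative_random"`` scales both standard errors by
    sqrt(max(1, Q_E/(J-2))), Q_E the weighted residual sum of squares.
    """

    def __init__(self, mode: str = "fixed"):
        self.mode = mode

    def fit(self, X, y, se_outcome=None, se_exposure=None):
        if self.mode not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if se_outcome is None:
            raise ValueError("se_outcome is required")
        gamma, Gamma, _, se_G = _validate_xy(X, y, se_exposure, se_outcome)
        J = len(gamma)
        if J < 3:
            raise InsufficientInstrumentsError("MR-Egger needs >= 3 SNPs")

        flip = np.sign(gamma)
        g, G = gamma * flip, Gamma * flip
        w = 1.0 / se_G**2
        if np.isclose(np.average((g - np.average(g, weights=w)) ** 2,
                                 weights=w), 0.0):
            raise ValueError("no variance in exposure effects (collinear)")

        # weighted normal equations for [intercept, slope]
        Xd = np.column_stack([np.ones(J), g])
        xtwx = Xd.T @ (w[:, None] * Xd)
        xtwy = Xd.T @ (w * G)
        coef = np.linalg.solve(xtwx, xtwy)
        cov = np.linalg.inv(xtwx)

        resid = G - Xd @ coef
        q_e = float((w * resid**2).sum())
        scale = 1.0
        if self.mode == "multiplicative_random":
            scale = float(np.sqrt(max(1.0, q_e / (J - 2))))

        b0, b1 = float(coef[0]), float(coef[1])
        se0 = float(np.sqrt(cov[0, 0])) * scale
        se1 = float(np.sqrt(cov[1, 1])) * scale

        self.beta_, self.se_ = b1, se1
        self.ci_low_, self.ci_high_ = b1 - Z95 * se1, b1 + Z95 * se1
        self.pval_ = float(_two_sided_p(b1 / se1))
        self.intercept_, self.intercept_se_ = b0, se0
        self.intercept_pval_ = float(_two_sided_p(b0 / se0))
        self.q_, self.q_df_ = q_e, J - 2
        self.q_pval_ = float(stats.chi2.sf(q_e, J - 2))
        self.n_snps_ = J
        return self

    def predict(self, X):
        g = np.abs(np.asarray(X, dtype=float).reshape(-1))
        return self.intercept_ + self.beta_ * g

    def to_result(self) -> EggerResult:
        res = EggerResult("egger", self.beta_, self.se_, self.pval_,
                          self.n_snps_)
        res.intercept = self.intercept_
        res.intercept_se = self.intercept_se_
        res.intercept_pval = self.intercept_pval_
        return res


def egger(hset: HarmonizedSet, mode: str = "fixed") -> EggerResult:
    """MR-Egger slope/intercept from a harmonized set."""
    est = EggerEstimator(mode=mode)
    est.fit(hset.beta_exposure, hset.beta_outcome,
            se_outcome=hset.se_outcome, se_exposure=hset.se_exposure)
    return est.to_result()


# --------------------------------------------------------------------------
# Weighted median

def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Weight-0.5 quantile of the ratio distribution.

    Ratios are ordered; each carries a cumulative probability midpoint
    p_j = S_{j-1} + w'_j/2 with normalized weights.  The estimate linearly
    interpolates b at p = 0.5; outside [p_1, p_J] the nearest ratio is
    returned without extrapolation.
    """
    order = np.argsort(b, kind="mergesort")
    b, w = b[order], w[order]
    wn = w / w.sum()
    cum = np.cumsum(wn)
    mid = cum - wn / 2
    if 0.5 <= mid[0]:
        return float(b[0])
    if 0.5 >= mid[-1]:
        return float(b[-1])
    return float(np.interp(0.5, mid, b))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Consistent when instruments contributing at least half the total weight
    are valid.  Ratios b_j = Gamma_j/gamma_j are weighted by
    w_j = gamma_j²/se_Gamma_j²; the standard error is the SD of the
    estimate over ``n_boot`` replicates re-drawing each study's effects
    from Normal(estimate, se).
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, se_outcome=None, se_exposure=None):
        if se_outcome is None or se_exposure is None:
            raise ValueError("both se_exposure and se_outcome are required")
        gamma, Gamma, se_g, se_G = _validate_xy(X, y, se_exposure, se_outcome)
        J = len(gamma)
        if J < 3:
            raise InsufficientInstrumentsError(
                "weighted median needs >= 3 SNPs")
        if np.any(~np.isfinite(se_g)) or np.any(se_g <= 0):
            raise ValueError("exposure standard errors must be positive")

        beta = _weighted_median_point(Gamma / gamma, gamma**2 / se_G**2)

        rng = np.random.default_rng(self.random_state)
        g_star = rng.normal(gamma, se_g, size=(self.n_boot, J))
        G_star = rng.normal(Gamma, se_G, size=(self.n_boot, J))
        g_star = np.where(g_star == 0, np.finfo(float).tiny, g_star)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            boots[i] = _weighted_median_point(
                G_star[i] / g_star[i], g_star[i]**2 / se_G**2)
        se = float(boots.std(ddof=1))

        self.beta_, self.se_ = float(beta), se
        self.ci_low_, self.ci_high_ = beta - Z95 * se, beta + Z95 * se
        self.pval_ = float(_two_sided_p(beta / se)) if se > 0 else 1.0
        self.n_snps_ = J
        return self

    def to_result(self) -> MrResult:
        return MrResult("weighted_median", self.beta_, self.se_,
                        self.pval_, self.n_snps_)


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrResult:
    """Weighted-median estimate from a harmonized set (seeded bootstrap)."""
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed)
    est.fit(hset.beta_exposure, hset.beta_outcome,
            se_outcome=hset.se_outcome, se_exposure=hset.se_exposure)
    return est.to_result()
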
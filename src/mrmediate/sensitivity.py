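"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

Complements the point estimators with the standard two-sample MR
sensitivity battery: Cochran's Q for heterogeneity (IVW or Egger basis),
leave-one-out influence analysis, and MR-PRESSO — a parametric-simulation
test that detects pleiotropic outlier instruments (global test), localizes
them (outlier test), and measures whether removing them changes the
estimate (distortion test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerEstimator, MrResult, ivw
from .gwas_io import HarmonizedSet

__all__ = [
    "QStats",
    "LooResult",
    "PressoResult",
    "cochran_q",
    "leave_one_out",
    "mr_presso",
    "presso_rerun",
]


@dataclass(frozen=True)
class QStats:
    """Cochran heterogeneity statistic with its chi-square reference."""

    Q: float
    df: int
    pval: float
    basis: str


@dataclass
class LooResult:
    """Leave-one-out re-estimates: one IVW fit per omitted instrument."""

    full: MrResult
    rows: pd.DataFrame  # snp_id, beta, se, ci_low, ci_high, pval, flagged

    @property
    def influential(self) -> list[str]:
        return list(self.rows.loc[self.rows["flagged"], "snp_id"])


@dataclass
class PressoResult:
    """MR-PRESSO global / outlier / distortion test results."""

    global_rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]  # Bonferroni-adjusted, capped at 1
    outlier_ids: list[str]
    estimate_before: MrResult
    estimate_after: MrResult | None
    distortion_pval: float | None
    degenerate: bool = False
    n_sim: int = 0


def cochran_q(hset: HarmonizedSet, basis: str = "ivw") -> QStats:
    """Heterogeneity of per-SNP effects about the IVW or Egger fit.

    IVW basis: Q = sum w_j (b_j - beta_IVW)² over Wald ratios with ratio
    weights, df = J-1.  Egger basis: the weighted residual sum of squares
    about the Egger regression, df = J-2.  p is the upper chi-square tail.
    """
    J = hset.n_snps
    if basis == "ivw":
        if J < 2:
            raise ValueError("Q on IVW basis needs >= 2 SNPs")
        w = hset.beta_exposure**2 / hset.se_outcome**2
        b = hset.beta_outcome / hset.beta_exposure
        beta = float((w * b).sum() / w.sum())
        q = float((w * (b - beta) ** 2).sum())
        df = J - 1
    elif basis == "egger":
        if J < 3:
            raise ValueError("Q on Egger basis needs >= 3 SNPs")
        est = EggerEstimator().fit(
            hset.beta_exposure, hset.beta_outcome,
            se_outcome=hset.se_outcome, se_exposure=hset.se_exposure)
        q, df = est.q_, est.q_df_
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return QStats(q, df, float(stats.chi2.sf(q, df)), basis)


def leave_one_out(hset: HarmonizedSet, mode: str = "fixed",
                  shift_fraction: float = 0.5) -> LooResult:
    """Re-estimate IVW J times, omitting each instrument once.

    An omission is flagged as influential when it flips the 95% CI across
    zero relative to the full fit, or moves the estimate by more than
    ``shift_fraction`` of the full-set CI half-width.
    """
    J = hset.n_snps
    if J < 3:
        raise ValueError("leave-one-out needs >= 3 SNPs")
    full = ivw(hset, mode=mode)
    half_width = full.ci_high - full.beta

    rows = []
    for j in range(J):
        mask = np.ones(J, dtype=bool)
        mask[j] = False
        res = ivw(hset.subset(mask), mode=mode)
        crosses_full = full.ci_low <= 0 <= full.ci_high
        crosses_loo = res.ci_low <= 0 <= res.ci_high
        flagged = (crosses_full != crosses_loo) or \
            (abs(res.beta - full.beta) > shift_fraction * half_width)
        rows.append({"snp_id": hset.snp_id[j], "beta": res.beta,
                     "se": res.se, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "pval": res.pval,
                     "flagged": flagged})
    return LooResult(full, pd.DataFrame(rows))


def _loo_ivw_betas(gamma: np.ndarray, Gamma: np.ndarray,
                   se_G: np.ndarray) -> np.ndarray:
    """Vector of IVW estimates each excluding one SNP (rows broadcast).

    Accepts 1-D arrays (J,) or 2-D (n_sim, J); returns matching shape.
    """
    num = gamma * Gamma / se_G**2
    den = gamma**2 / se_G**2
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def _weighted_rss_terms(gamma, Gamma, se_G) -> np.ndarray:
    """Per-SNP leave-one-out expected-value residual terms
    (Gamma_j - gamma_j * beta_{-j})² / se_Gamma_j²."""
    beta_loo = _loo_ivw_betas(gamma, Gamma, se_G)
    return (Gamma - gamma * beta_loo) ** 2 / se_G**2


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000,
              seed: int | None = None,
              sig_level: float = 0.05) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    Global test: the observed RSS — each instrument's squared residual from
    the IVW fit that excludes it, inversely weighted by its outcome
    variance — is referenced against ``n_sim`` parametric simulations that
    redraw both studies' effects from their sampling distributions under
    the no-pleiotropy expectation.  The empirical p uses add-one smoothing
    so it is never exactly 0.

    Outlier test: each SNP's observed residual term against its own
    simulated distribution, two-sided empirical p, Bonferroni-multiplied by
    J; SNPs with adjusted p below ``sig_level`` are outliers.

    Distortion test: the relative change in the IVW estimate after removing
    the detected outliers, compared with the distribution of the same
    quantity when removing equally many random SNPs.
    """
    J = hset.n_snps
    if J < 4:
        raise ValueError("MR-PRESSO needs >= 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)

    gamma, Gamma = hset.beta_exposure, hset.beta_outcome
    se_g, se_G = hset.se_exposure, hset.se_outcome

    obs_terms = _weighted_rss_terms(gamma, Gamma, se_G)
    rss_obs = float(obs_terms.sum())

    # simulate under the per-SNP no-pleiotropy expectation gamma_j*beta_{-j}
    beta_loo_obs = _loo_ivw_betas(gamma, Gamma, se_G)
    g_star = rng.normal(gamma, se_g, size=(n_sim, J))
    G_star = rng.normal(gamma * beta_loo_obs, se_G, size=(n_sim, J))
    sim_terms = _weighted_rss_terms(g_star, G_star, se_G)
    rss_sim = sim_terms.sum(axis=1)

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    # per-SNP two-sided empirical p, Bonferroni-corrected
    upper = (np.sum(sim_terms >= obs_terms, axis=0) + 1) / (n_sim + 1)
    lower = (np.sum(sim_terms <= obs_terms, axis=0) + 1) / (n_sim + 1)
    p_raw = 2 * np.minimum(upper, lower)
    p_adj = np.minimum(p_raw * J, 1.0)
    outlier_mask = p_adj < sig_level
    outlier_ids = [str(s) for s in hset.snp_id[outlier_mask]]

    before = ivw(hset)
    after: MrResult | None = None
    distortion_pval: float | None = None
    degenerate = False

    if outlier_ids:
        keep = ~outlier_mask
        if keep.sum() <= 2:
            degenerate = True
        else:
            after = ivw(hset.subset(keep))
            if before.beta != 0:
                d_obs = (after.beta - before.beta) / abs(before.beta)
                k = int(outlier_mask.sum())
                # random k-subsets drawn without replacement, vectorized
                drop_idx = np.argsort(rng.random((n_sim, J)),
                                      axis=1)[:, :k]
                num = gamma * Gamma / se_G**2
                den = gamma**2 / se_G**2
                num_drop = num[drop_idx].sum(axis=1)
                den_drop = den[drop_idx].sum(axis=1)
                b_sim = (num.sum() - num_drop) / (den.sum() - den_drop)
                d_sim = (b_sim - before.beta) / abs(before.beta)
                upper_d = (np.sum(d_sim >= d_obs) + 1) / (n_sim + 1)
                lower_d = (np.sum(d_sim <= d_obs) + 1) / (n_sim + 1)
                distortion_pval = float(min(1.0, 2 * min(upper_d, lower_d)))
    else:
        after = before

    return PressoResult(
        global_rss_obs=rss_obs, global_pval=global_pval,
        outlier_pvals={str(s): float(p)
                       for s, p in zip(hset.snp_id, p_adj)},
        outlier_ids=outlier_ids,
        estimate_before=before, estimate_after=after,
        distortion_pval=distortion_pval, degenerate=degenerate,
        n_sim=n_sim,
    )


@dataclass
class PressoRerun:
    """Outcome of the detect → remove → re-estimate loop (single pass)."""

    first_pass: PressoResult
    removed: list[str] = field(default_factory=list)
    second_pass: PressoResult | None = None

    @property
    def final_estimate(self) -> MrResult:
        if self.second_pass is not None:
            return self.second_pass.estimate_before
        if self.removed and self.first_pass.estimate_after is not None:
            return self.first_pass.estimate_after
        return self.first_pass.estimate_before


def presso_rerun(hset: HarmonizedSet, n_sim: int = 1000,
                 seed: int | None = None,
                 sig_level: float = 0.05) -> PressoRerun:
    """Detect outliers, remove them, and rerun the analysis once.

    Mirrors the standard workflow: if the first MR-PRESSO pass flags
    outliers, they are excluded and both the MR estimate and MR-PRESSO are
    recomputed on the reduced set; both passes are reported.
    """
    first = mr_presso(hset, n_sim=n_sim, seed=seed, sig_level=sig_level)
    if not first.outlier_ids or first.degenerate:
        return PressoRerun(first_pass=first)
    keep = ~np.isin(hset.snp_id.astype(str), first.outlier_ids)
    reduced = hset.subset(keep)
    second: PressoResult | None = None
    if reduced.n_snps >= 4:
        second = mr_presso(reduced, n_sim=n_sim, seed=seed,
                           sig_level=sig_level)
    return PressoRerun(first_pass=first, removed=first.outlier_ids,
                       second_pass=second)
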
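"""Two-step mediation MR: product-of-coefficients decomposition.

The total causal effect of an exposure on an outcome (``alpha``, from MR
with the exposure's instruments) is decomposed into an indirect path
through a mediator — the product of the exposure→mediator effect ``beta1``
and the mediator→outcome effect ``beta2`` — and the remaining direct
effect.  The proportion mediated is (beta1·beta2)/alpha.  Standard errors
for the product use the Sobel (first-order delta) approximation treating
the three estimates as independent, justified by non-overlapping two-sample
designs.

Multiple-testing control across result families uses Bonferroni thresholds
0.05/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrResult, ivw
from .gwas_io import HarmonizedSet

__all__ = [
    "MediationResult",
    "TestFamily",
    "total_effect",
    "mediator_effects",
    "mediate",
    "bonferroni_family",
    "pval_from_or_ci",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationResult:
    """Effect decomposition along one exposure → mediator → outcome chain.

    All effects are on the log-OR (or SD) scale.  ``proportion`` is NaN
    when the total effect is zero (decomposition undefined).
    """

    alpha: float
    se_alpha: float
    beta1: float
    se_beta1: float
    beta2: float
    se_beta2: float
    indirect: float = field(init=False)
    se_indirect: float = field(init=False)
    proportion: float = field(init=False)
    se_proportion: float = field(init=False)
    direct: float = field(init=False)

    def __post_init__(self) -> None:
        b1, b2, a = self.beta1, self.beta2, self.alpha
        s1, s2, sa = self.se_beta1, self.se_beta2, self.se_alpha
        self.indirect = b1 * b2
        self.se_indirect = math.sqrt(b1**2 * s2**2 + b2**2 * s1**2)
        self.direct = a - self.indirect
        if a == 0:
            self.proportion = float("nan")
            self.se_proportion = float("nan")
        else:
            self.proportion = self.indirect / a
            # delta method over (beta1, beta2, alpha) assumed independent
            self.se_proportion = math.sqrt(
                (b2 / a) ** 2 * s1**2
                + (b1 / a) ** 2 * s2**2
                + (b1 * b2 / a**2) ** 2 * sa**2)

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_row(self) -> dict:
        return {
            "alpha": self.alpha, "se_alpha": self.se_alpha,
            "beta1": self.beta1, "se_beta1": self.se_beta1,
            "beta2": self.beta2, "se_beta2": self.se_beta2,
            "indirect": self.indirect, "se_indirect": self.se_indirect,
            "direct": self.direct,
            "proportion": self.proportion,
            "proportion_pct": self.proportion_pct,
            "se_proportion": self.se_proportion,
        }


@dataclass
class TestFamily:
    """A Bonferroni-controlled family of hypothesis tests."""

    name: str
    m: int
    threshold: float
    table: pd.DataFrame  # columns: label, pval, significant

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "label"])


def total_effect(hset: HarmonizedSet, mode: str = "auto") -> MrResult:
    """Total exposure→outcome effect: IVW on the exposure's instruments.

    Default mode "auto" escalates to multiplicative random effects when
    Cochran's Q is significant.
    """
    return ivw(hset, mode=mode)


def mediator_effects(exposure_to_mediator: HarmonizedSet,
                     mediator_to_outcome: HarmonizedSet,
                     exposure_instruments: list[str] | None = None,
                     overlap_policy: str = "drop-shared",
                     mode: str = "auto") -> tuple[MrResult, MrResult | None]:
    """Estimate the two mediator-path effects beta1 and beta2.

    beta1 uses the exposure's (drug-target) instruments against the
    mediator GWAS; beta2 uses the mediator's own (pQTL) instruments against
    the outcome GWAS.  With ``overlap_policy="drop-shared"`` (default) any
    mediator instrument that is also an exposure instrument is excluded
    from the beta2 estimation, so the exposure pathway cannot contaminate
    the mediator effect; ``"none"`` keeps all.  Returns ``(beta1, beta2)``;
    beta2 is None when no mediator instruments survive the exclusion.
    """
    if overlap_policy not in ("drop-shared", "none"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    beta1 = ivw(exposure_to_mediator, mode=mode)

    hset2 = mediator_to_outcome
    if overlap_policy == "drop-shared" and exposure_instruments:
        shared = set(map(str, exposure_instruments))
        keep = ~np.isin(hset2.snp_id.astype(str), list(shared))
        if not keep.any():
            return beta1, None
        hset2 = hset2.subset(keep)
    beta2 = ivw(hset2, mode=mode)
    return beta1, beta2


def mediate(alpha: float, se_alpha: float, beta1: float, se_beta1: float,
            beta2: float, se_beta2: float) -> MediationResult:
    """Product-of-coefficients mediation from three effect estimates.

    indirect = beta1*beta2 (Sobel SE); proportion = indirect/alpha
    (first-order delta SE); direct = alpha - indirect.  The identities
    direct + indirect == alpha and proportion*alpha == indirect hold
    exactly on the stored floats.
    """
    return MediationResult(alpha, se_alpha, beta1, se_beta1, beta2, se_beta2)


def bonferroni_family(pvals, m: int | None = None,
                      labels=None, name: str = "family") -> TestFamily:
    """Mark each test significant iff raw p < 0.05/m.

    ``m`` defaults to the number of supplied p-values but may be overridden
    (e.g. when the family is defined by the number of hypotheses screened,
    not the number carried forward).  An m smaller than the number of
    p-values warns rather than fails.
    """
    pvals = list(map(float, pvals))
    if m is None:
        m = len(pvals)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(pvals):
        import warnings
        warnings.warn(f"Bonferroni m={m} is smaller than the number of "
                      f"tests ({len(pvals)})", stacklevel=2)
    threshold = 0.05 / m
    if labels is None:
        labels = [f"test_{i}" for i in range(len(pvals))]
    table = pd.DataFrame({
        "label": list(labels),
        "pval": pvals,
        "significant": [p < threshold for p in pvals],
    })
    return TestFamily(name=name, m=m, threshold=threshold, table=table)


def pval_from_or_ci(or_point: float, ci_low: float,
                    ci_high: float) -> float:
    """Two-sided normal p back-calculated from an OR and its 95% CI.

    Useful for reconciling published forest-plot rows: the SE is recovered
    from the CI width on the log scale, se = (ln hi - ln lo)/(2·1.959964),
    and the p-value from z = ln(OR)/se.
    """
    if not (0 < ci_low < or_point < ci_high):
        raise ValueError("need 0 < ci_low < or_point < ci_high")
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
    z = math.log(or_point) / se
    return float(2 * stats.norm.sf(abs(z)))
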
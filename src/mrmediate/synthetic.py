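"""Seeded generator of two-sample GWAS summary statistics with known truth.

Emulates the three-table mediation design — an exposure biomarker GWAS (a
lipid trait in a large biobank), a circulating-protein (mediator) GWAS, and
a binary-outcome case/control GWAS — under the linear structural model

    exposure_j  = gamma_j
    mediator_j  = beta1 * gamma_j + delta_j
    outcome_j   = (alpha_direct + beta1*beta2) * gamma_j
                  + beta2 * delta_j + theta_j

per SNP j, where ``gamma_j`` is nonzero only for cis variants of the
exposure's target gene, ``delta_j`` only for mediator-specific pQTLs (which
is what makes the mediator→outcome effect identifiable from its own
instruments), and ``theta_j`` is optional pleiotropy on the exposure's
instruments.  Observed effects add independent sampling noise with standard
errors derived from sample size and allele frequency,
sigma = 1/sqrt(2 n p (1-p)) for standardized quantitative traits and
sigma = 1/sqrt(2 n phi (1-phi) p (1-p)) for a binary outcome with case
fraction phi (log-OR scale).

Everything is reproducible from the config seed.  Default sample sizes
mirror the study design the generator emulates: a ~441k-participant lipid
GWAS, a ~15k pQTL study, and a ~1.03M-participant outcome GWAS with ~5.9%
cases.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import GwasTable, TraitMeta
from .instruments import GeneRegion, LdMatrix

__all__ = ["SimConfig", "SimTruth", "SimStudy", "simulate_study",
           "inject_outlier", "harmonized_sets", "make_fixture_suite"]

# non-palindromic allele pairs only, so harmonization never drops by strand
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic three-table MR study.

    ``n_snps`` cis instruments for the exposure's target gene (of which
    ``round(cis_fraction * n_snps)`` fall inside the gene window),
    ``n_pqtl`` mediator-specific instruments, ``n_null`` unassociated
    background SNPs.  ``alpha_direct`` is the direct exposure→outcome
    effect; the total effect is ``alpha_direct + beta1*beta2``.
    ``pleiotropy`` is ``"none"``, ``"balanced"`` (theta ~ N(0, tau)) or
    ``"directional"`` (theta = |N(0, tau)|) on the cis SNPs.  LD is
    block-diagonal over consecutive cis SNPs with within-block r² = rho².
    """

    n_snps: int = 30
    n_pqtl: int = 20
    n_null: int = 0
    n_exposure: int = 441_016
    n_mediator: int = 14_824
    n_outcome: int = 1_030_836
    case_fraction: float = 0.0588
    alpha_direct: float = -0.1456
    beta1: float = -0.20
    beta2: float = 0.072
    pleiotropy: str = "none"
    pleiotropy_scale: float = 0.0
    gamma_range: tuple[float, float] = (0.03, 0.12)
    pqtl_effect_range: tuple[float, float] = (0.15, 0.60)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    cis_fraction: float = 1.0
    outcome_type: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_snps, self.n_pqtl) < 1 or self.n_null < 0:
            raise ValueError("SNP counts must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.pleiotropy_scale < 0:
            raise ValueError("pleiotropy_scale must be >= 0")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0 < self.eaf_range[0] <= self.eaf_range[1] < 1):
            raise ValueError("eaf_range must lie within (0, 1)")
        if self.outcome_type not in ("binary", "quantitative"):
            raise ValueError("outcome_type must be binary or quantitative")

    @property
    def alpha_total(self) -> float:
        return self.alpha_direct + self.beta1 * self.beta2

    @property
    def proportion_mediated(self) -> float:
        return self.beta1 * self.beta2 / self.alpha_total


@dataclass
class SimTruth:
    """Ground truth of one simulated study, for recovery tests."""

    config: SimConfig
    gamma: np.ndarray        # true exposure effects, all SNPs
    delta: np.ndarray        # true mediator-specific effects
    theta: np.ndarray        # per-SNP pleiotropy on the outcome
    snp_class: np.ndarray    # "cis" | "pqtl" | "null"
    snp_ids: list[str]
    outlier_ids: list[str] = field(default_factory=list)

    @property
    def alpha_total(self) -> float:
        return self.config.alpha_total

    @property
    def proportion_mediated(self) -> float:
        return self.config.proportion_mediated


@dataclass
class SimStudy:
    """The three generated tables plus LD, region, and truth."""

    exposure: GwasTable
    mediator: GwasTable
    outcome: GwasTable
    ld: LdMatrix
    region: GeneRegion
    truth: SimTruth


def _se_quantitative(n: float, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1 - eaf))


def _se_binary(n: float, case_fraction: float,
               eaf: np.ndarray) -> np.ndarray:
    phi = case_fraction
    return 1.0 / np.sqrt(2.0 * n * phi * (1 - phi) * eaf * (1 - eaf))


def _table(snp_ids, chrom, pos, ea, oa, eaf, beta_true, se, n,
           trait: TraitMeta, rng) -> GwasTable:
    beta = beta_true + rng.normal(0.0, se)
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    pval = np.maximum(pval, np.nextafter(0.0, 1.0))
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval, "n": float(n),
    })
    return GwasTable(df, trait)


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate one exposure/mediator/outcome study from the config.

    Returns a :class:`SimStudy`; identical configs (including seed) produce
    identical tables.  Cis SNPs are laid out inside (or, for the
    ``1 - cis_fraction`` remainder, just outside) a synthetic gene window;
    pQTL and null SNPs are placed on other chromosomes.
    """
    rng = np.random.default_rng(config.seed)
    n_cis, n_pqtl, n_null = config.n_snps, config.n_pqtl, config.n_null
    total = n_cis + n_pqtl + n_null

    region = GeneRegion("GENE1", "1", 1_000_000, 1_050_000, flank_kb=100.0)
    lo, hi = region.window

    n_inside = int(round(config.cis_fraction * n_cis))
    pos_cis = np.empty(n_cis, dtype=int)
    pos_cis[:n_inside] = np.linspace(lo, hi, max(n_inside, 1), dtype=int) \
        if n_inside else []
    if n_cis - n_inside:
        # remainder just beyond the flank, same chromosome
        pos_cis[n_inside:] = hi + 50_000 + 10_000 * np.arange(
            n_cis - n_inside)
    chrom = np.array(["1"] * n_cis + ["2"] * n_pqtl + ["3"] * n_null)
    pos = np.concatenate([
        pos_cis,
        5_000_000 + 200_000 * np.arange(n_pqtl),
        9_000_000 + 200_000 * np.arange(n_null),
    ]).astype(int)

    snp_ids = [f"rs{1000 + i}" for i in range(total)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    eaf = rng.uniform(*config.eaf_range, size=total)

    sign = rng.choice([-1.0, 1.0], size=total)
    gamma = np.zeros(total)
    gamma[:n_cis] = sign[:n_cis] * rng.uniform(*config.gamma_range,
                                               size=n_cis)
    delta = np.zeros(total)
    delta[n_cis:n_cis + n_pqtl] = sign[n_cis:n_cis + n_pqtl] * rng.uniform(
        *config.pqtl_effect_range, size=n_pqtl)

    theta = np.zeros(total)
    if config.pleiotropy != "none" and config.pleiotropy_scale > 0:
        draws = rng.normal(0.0, config.pleiotropy_scale, size=n_cis)
        if config.pleiotropy == "directional":
            # positive on the oriented (gamma > 0) scale: allele coding is
            # arbitrary, so direction is defined relative to the instrument
            theta[:n_cis] = np.abs(draws) * np.sign(gamma[:n_cis])
        else:
            theta[:n_cis] = draws

    beta_exp = gamma
    beta_med = config.beta1 * gamma + delta
    beta_out = config.alpha_total * gamma + config.beta2 * delta + theta

    se_exp = _se_quantitative(config.n_exposure, eaf)
    se_med = _se_quantitative(config.n_mediator, eaf)
    if config.outcome_type == "binary":
        se_out = _se_binary(config.n_outcome, config.case_fraction, eaf)
        out_meta = TraitMeta("outcome", "binary", "log_or")
    else:
        se_out = _se_quantitative(config.n_outcome, eaf)
        out_meta = TraitMeta("outcome", "quantitative", "sd")

    exposure = _table(snp_ids, chrom, pos, ea, oa, eaf, beta_exp, se_exp,
                      config.n_exposure,
                      TraitMeta("exposure", "quantitative", "sd"), rng)
    mediator = _table(snp_ids, chrom, pos, ea, oa, eaf, beta_med, se_med,
                      config.n_mediator,
                      TraitMeta("mediator", "quantitative", "sd"), rng)
    outcome = _table(snp_ids, chrom, pos, ea, oa, eaf, beta_out, se_out,
                     config.n_outcome, out_meta, rng)

    r2 = np.eye(total)
    if config.ld_block_size > 1 and config.ld_rho > 0:
        r2_val = config.ld_rho**2
        for start in range(0, n_cis, config.ld_block_size):
            stop = min(start + config.ld_block_size, n_cis)
            r2[start:stop, start:stop] = r2_val
        np.fill_diagonal(r2, 1.0)
    ld = LdMatrix(snp_ids, r2)

    truth = SimTruth(config=config, gamma=gamma, delta=delta, theta=theta,
                     snp_class=np.array(["cis"] * n_cis + ["pqtl"] * n_pqtl
                                        + ["null"] * n_null),
                     snp_ids=snp_ids)
    return SimStudy(exposure, mediator, outcome, ld, region, truth)


def inject_outlier(study: SimStudy, snp_index: int = 0,
                   n_sigma: float = 10.0) -> SimStudy:
    """Displace one cis SNP's outcome effect by ``n_sigma`` standard errors.

    Returns the same study with the outcome table modified in place and the
    SNP recorded in ``truth.outlier_ids`` — a controlled pleiotropic
    outlier for testing detection methods.
    """
    df = study.outcome.df
    df.loc[snp_index, "beta"] += n_sigma * df.loc[snp_index, "se"]
    z = df.loc[snp_index, "beta"] / df.loc[snp_index, "se"]
    df.loc[snp_index, "pval"] = max(2 * stats.norm.sf(abs(z)),
                                    np.nextafter(0.0, 1.0))
    study.truth.outlier_ids.append(str(df.loc[snp_index, "snp_id"]))
    return study


def harmonized_sets(study: SimStudy) -> dict[str, "HarmonizedSet"]:
    """Aligned effect sets for the three MR legs of a simulated study.

    The generator writes all three tables on the same strand with the same
    effect alleles, so alignment is a direct column pairing: the exposure's
    cis SNPs instrument the exposure→outcome and exposure→mediator legs,
    the mediator-specific pQTLs the mediator→outcome leg.
    """
    from .gwas_io import HarmonizedSet

    cls = study.truth.snp_class
    out = {}
    for name, inst_mask, left, right in (
            ("exposure_outcome", cls == "cis", study.exposure,
             study.outcome),
            ("exposure_mediator", cls == "cis", study.exposure,
             study.mediator),
            ("mediator_outcome", cls == "pqtl", study.mediator,
             study.outcome)):
        ldf, rdf = left.df.loc[inst_mask], right.df.loc[inst_mask]
        out[name] = HarmonizedSet(
            snp_id=ldf["snp_id"].to_numpy(dtype=object),
            effect_allele=ldf["effect_allele"].to_numpy(dtype=object),
            beta_exposure=ldf["beta"].to_numpy(),
            se_exposure=ldf["se"].to_numpy(),
            beta_outcome=rdf["beta"].to_numpy(),
            se_outcome=rdf["se"].to_numpy(),
        )
    return out


_FIXTURES: dict[str, SimConfig] = {
    # a clean study at the default (study-like) conditions
    "clean": SimConfig(seed=101),
    # directional pleiotropy on the instruments
    "directional_pleiotropy": SimConfig(pleiotropy="directional",
                                        pleiotropy_scale=0.01, seed=102),
    # mediation study with true proportion mediated = 0.09
    "mediation_p09": SimConfig(alpha_direct=-0.1456, beta1=-0.20,
                               beta2=0.072, seed=103),
    # LD blocks, for clumping paths
    "ld_blocks": SimConfig(ld_block_size=5, ld_rho=0.8, seed=104),
    # boundary cases for cis selection: 40% of cis SNPs outside the window
    "cis_boundary": SimConfig(cis_fraction=0.6, seed=105),
}


def make_fixture_suite(out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write the named fixture studies used in tests and docs.

    Each study becomes exposure/mediator/outcome TSVs in the dialect
    :func:`mrmediate.gwas_io.read_gwas` reads by default, a long-format LD
    file, a BED-like region file, and a JSON truth sidecar.  The
    ``single_outlier`` study additionally records the displaced SNP.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}

    studies = {name: simulate_study(cfg) for name, cfg in _FIXTURES.items()}
    studies["single_outlier"] = inject_outlier(
        simulate_study(SimConfig(seed=106)), snp_index=0)

    for name, study in studies.items():
        d = out_dir / name
        d.mkdir(exist_ok=True)
        paths: dict[str, Path] = {}
        for role in ("exposure", "mediator", "outcome"):
            table: GwasTable = getattr(study, role)
            df = table.df.rename(columns={
                "chrom": "chromosome", "pos": "base_pair_location",
                "eaf": "effect_allele_frequency", "se": "standard_error",
                "pval": "p_value"})
            paths[role] = d / f"{role}.tsv"
            df.to_csv(paths[role], sep="\t", index=False)
        # self-pairs declare the SNP universe even when all off-diagonal
        # r2 are zero
        ids = study.ld.snp_ids
        long_rows = [(s, s, 1.0) for s in ids]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if study.ld.r2[i, j] != 0:
                    long_rows.append((ids[i], ids[j], study.ld.r2[i, j]))
        paths["ld"] = d / "ld.tsv"
        pd.DataFrame(long_rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            paths["ld"], sep="\t", index=False)
        paths["regions"] = d / "regions.tsv"
        r = study.region
        pd.DataFrame([[r.chrom, r.start, r.end, r.gene_symbol]]).to_csv(
            paths["regions"], sep="\t", index=False, header=False)
        truth = {
            "config": asdict(study.truth.config),
            "alpha_total": study.truth.alpha_total,
            "proportion_mediated": study.truth.proportion_mediated,
            "outlier_ids": study.truth.outlier_ids,
            "snp_class": study.truth.snp_class.tolist(),
            "gamma": study.truth.gamma.tolist(),
            "delta": study.truth.delta.tolist(),
            "theta": study.truth.theta.tolist(),
        }
        paths["truth"] = d / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1) + "\n")
        written[name] = paths
    return written
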
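"""Genetic-instrument selection for drug-target and pQTL MR.

Instruments proxying pharmacological modulation of a drug target are chosen
cis: genome-wide-significant SNPs within a flanking window of the target
gene, pruned for linkage disequilibrium by greedy clumping, filtered on
effect-allele frequency, and screened against a user-supplied blocklist of
confounder-associated variants.  Instrument strength is summarized by the
per-SNP F-statistic (beta/se)^2; a mean F at or below 10 flags potential
weak-instrument bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import GwasTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "ClumpParams",
    "LdMatrix",
    "InstrumentSet",
    "DRUG_TARGET_PRESET",
    "PQTL_PRESET",
    "DRUG_TARGET_REGIONS",
    "select_cis_snps",
    "clump",
    "exclude_confounder_snps",
    "f_statistics",
    "read_regions",
    "read_ld_matrix",
    "read_blocklist",
]


@dataclass(frozen=True)
class GeneRegion:
    """A gene's span plus the cis flank within which instruments are taken.

    Coordinates are 1-based inclusive; the selection window is
    ``[start - flank_kb*1000, end + flank_kb*1000]``, inclusive on both
    ends.
    """

    gene_symbol: str
    chrom: str
    start: int
    end: int
    flank_kb: float = 100.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start > end")
        if self.flank_kb < 0:
            raise ValueError("flank_kb must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        flank = int(round(self.flank_kb * 1000))
        return max(1, self.start - flank), self.end + flank


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping configuration.

    ``r2_primary`` is tried first; if fewer than ``min_snps`` instruments
    survive, clumping reruns from scratch at ``r2_fallback``.  Pairs farther
    apart than ``window_kb`` are treated as independent regardless of r².
    """

    r2_primary: float = 0.3
    r2_fallback: float = 0.4
    min_snps: int = 3
    window_kb: float = 10_000.0
    p_threshold: float = 5e-8

    def __post_init__(self) -> None:
        if not (0 < self.r2_primary <= self.r2_fallback < 1):
            raise ValueError("need 0 < r2_primary <= r2_fallback < 1")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


#: Lipid-biomarker instruments for drug-target proxies.
DRUG_TARGET_PRESET = ClumpParams(r2_primary=0.3, r2_fallback=0.4,
                                 min_snps=3, window_kb=10_000.0,
                                 p_threshold=5e-8)
#: Circulating-protein (pQTL) instruments.
PQTL_PRESET = ClumpParams(r2_primary=0.001, r2_fallback=0.001,
                          min_snps=1, window_kb=10_000.0,
                          p_threshold=5e-6)

#: The ten lipid-lowering drug-target genes (GRCh37 spans).  LDL-C lowering:
#: LDLR, HMGCR, NPC1L1, PCSK9, APOB, ABCG5, ABCG8; TG lowering: LPL, APOC3,
#: PPARA.
DRUG_TARGET_REGIONS: tuple[GeneRegion, ...] = (
    GeneRegion("LDLR", "19", 11_200_038, 11_244_505),
    GeneRegion("HMGCR", "5", 74_632_154, 74_657_929),
    GeneRegion("NPC1L1", "7", 44_552_134, 44_580_914),
    GeneRegion("PCSK9", "1", 55_505_221, 55_530_525),
    GeneRegion("APOB", "2", 21_224_301, 21_266_945),
    GeneRegion("ABCG5", "2", 44_039_611, 44_066_000),
    GeneRegion("ABCG8", "2", 44_066_103, 44_105_605),
    GeneRegion("LPL", "8", 19_796_764, 19_824_770),
    GeneRegion("APOC3", "11", 116_700_623, 116_703_788),
    GeneRegion("PPARA", "22", 46_546_429, 46_639_653),
)


@dataclass
class LdMatrix:
    """Squared-correlation matrix over an ordered SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        return float(self.r2[self._index[snp_a], self._index[snp_b]])

    def __contains__(self, snp: str) -> bool:
        return snp in self._index


@dataclass
class InstrumentSet:
    """Selected instruments with strength diagnostics and provenance.

    ``provenance`` records filter-by-filter drop counts so that
    input = retained + sum(drops) can be audited; ``r2_applied`` is the LD
    threshold that actually produced the set (primary or fallback).
    """

    snp_ids: list[str]
    f_stats: dict[str, float] = field(default_factory=dict)
    mean_f: float = float("nan")
    r2_applied: float = float("nan")
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def weak_instrument_flag(self) -> bool:
        return not self.mean_f > 10


def select_cis_snps(table: GwasTable, region: GeneRegion,
                    p_threshold: float = 5e-8, eaf_min: float = 0.01,
                    strict_maf: bool = False) -> GwasTable:
    """Restrict a GWAS table to significant cis SNPs around a gene.

    Retains records on the region's chromosome with position inside the
    flanked window (boundaries inclusive), ``pval < p_threshold`` (strict),
    and effect-allele frequency above ``eaf_min``.  With ``strict_maf`` the
    frequency filter applies to min(eaf, 1-eaf) instead of eaf as stored.
    Records with missing EAF pass the frequency filter.
    """
    df = table.df
    lo, hi = region.window
    on_chrom = df["chrom"].astype(str) == str(region.chrom)
    in_window = on_chrom & (df["pos"] >= lo) & (df["pos"] <= hi)
    significant = df["pval"] < p_threshold
    freq = df["eaf"]
    if strict_maf:
        freq = np.minimum(freq, 1 - freq)
    frequent = freq.isna() | (freq > eaf_min)

    keep = in_window & significant & frequent
    kept = df.loc[keep].reset_index(drop=True)
    logger.info("select_cis_snps[%s]: %d/%d retained "
                "(window %d, significance %d, eaf %d dropped)",
                region.gene_symbol, len(kept), int(on_chrom.sum()),
                int((on_chrom & ~in_window).sum()),
                int((in_window & ~significant).sum()),
                int((in_window & significant & ~frequent).sum()))
    if len(kept) == 0:
        logger.warning("select_cis_snps[%s]: empty instrument candidate set",
                       region.gene_symbol)
    return GwasTable(kept, table.trait)


def _greedy_clump(df: pd.DataFrame, ld: LdMatrix, r2_threshold: float,
                  window_kb: float) -> list[str]:
    # deterministic priority: smallest p, then position, then snp_id
    order = df.sort_values(["pval", "pos", "snp_id"],
                           kind="mergesort").reset_index(drop=True)
    remaining = list(order.itertuples(index=False))
    kept: list[str] = []
    window_bp = window_kb * 1000
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp.snp_id)
        remaining = [
            s for s in remaining
            if not (abs(s.pos - index_snp.pos) <= window_bp
                    and ld.lookup(s.snp_id, index_snp.snp_id) > r2_threshold)
        ]
    return kept


def clump(table: GwasTable, ld: LdMatrix,
          params: ClumpParams = DRUG_TARGET_PRESET) -> InstrumentSet:
    """Greedy LD clumping with an adaptive fallback threshold.

    SNPs are taken most-significant-first; each chosen index SNP removes
    remaining candidates within ``window_kb`` whose r² with it exceeds the
    threshold.  If the primary threshold yields fewer than ``min_snps``
    instruments, clumping reruns from scratch at the fallback threshold and
    the larger result is kept.  The applied threshold is recorded.
    """
    df = table.df
    missing = [s for s in df["snp_id"] if s not in ld]
    if missing:
        raise ValueError(f"SNPs absent from LD matrix: {missing}")

    kept = _greedy_clump(df, ld, params.r2_primary, params.window_kb)
    applied = params.r2_primary
    if len(kept) < params.min_snps and params.r2_fallback > params.r2_primary:
        fallback = _greedy_clump(df, ld, params.r2_fallback, params.window_kb)
        logger.info("clump: %d < min_snps=%d at r2<%g; fallback r2<%g "
                    "yields %d", len(kept), params.min_snps,
                    params.r2_primary, params.r2_fallback, len(fallback))
        kept, applied = fallback, params.r2_fallback

    inst = InstrumentSet(
        snp_ids=kept, r2_applied=applied,
        provenance={"candidates": len(df),
                    "clump_removed": len(df) - len(kept)},
    )
    return f_statistics(table.restrict(kept), inst)


def exclude_confounder_snps(inst: InstrumentSet,
                            blocklist: pd.DataFrame) -> InstrumentSet:
    """Remove instruments listed in a confounder-SNP blocklist.

    ``blocklist`` has columns ``snp_id`` and ``trait`` (the confounder the
    SNP is associated with, e.g. BMI or smoking).  Removals are logged with
    their annotated trait and counted in provenance.
    """
    if len(blocklist) == 0:
        return inst
    annotated = dict(zip(blocklist["snp_id"].astype(str),
                         blocklist["trait"].astype(str)))
    removed = [s for s in inst.snp_ids if s in annotated]
    kept = [s for s in inst.snp_ids if s not in annotated]
    for snp in removed:
        logger.info("exclude_confounder_snps: removed %s (%s)",
                    snp, annotated[snp])
    if not kept:
        logger.warning("exclude_confounder_snps: all instruments removed")
    prov = dict(inst.provenance)
    prov["confounder_removed"] = len(removed)
    return replace(inst,
                   snp_ids=kept,
                   f_stats={s: f for s, f in inst.f_stats.items()
                            if s in kept},
                   mean_f=(float(np.mean([inst.f_stats[s] for s in kept]))
                           if kept and inst.f_stats else float("nan")),
                   provenance=prov)


def f_statistics(table: GwasTable,
                 inst: InstrumentSet | None = None) -> InstrumentSet:
    """Per-SNP F-statistics F_j = (beta_j / se_j)² and their mean.

    The mean F summarizes instrument strength; values at or below 10 raise
    the weak-instrument flag on the returned set.
    """
    df = table.df
    f = (df["beta"] / df["se"]) ** 2
    f_map = dict(zip(df["snp_id"], f.astype(float)))
    mean_f = float(f.mean()) if len(f) else float("nan")
    if inst is None:
        inst = InstrumentSet(snp_ids=list(df["snp_id"]))
    inst.f_stats = f_map
    inst.mean_f = mean_f
    if inst.weak_instrument_flag:
        logger.warning("f_statistics: mean F = %.2f <= 10 "
                       "(possible weak-instrument bias)", mean_f)
    return inst


def read_regions(path: str | Path, flank_kb: float = 100.0) -> list[GeneRegion]:
    """Read gene regions from a BED-like 4-column file.

    Columns: chrom, start, end, gene_symbol (tab-separated, no header,
    1-based inclusive coordinates as used in GWAS files).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_symbol"])
    return [GeneRegion(r.gene_symbol, str(r.chrom), int(r.start),
                       int(r.end), flank_kb)
            for r in df.itertuples(index=False)]


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read an LD r² matrix: square (SNP ids as header row and first
    column) or long-format triplets (snp_a, snp_b, r2; missing pairs 0)."""
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=1)
    if set(head.columns) >= {"snp_a", "snp_b", "r2"}:
        long = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        snps = sorted(set(long["snp_a"]) | set(long["snp_b"]))
        idx = {s: i for i, s in enumerate(snps)}
        mat = np.eye(len(snps))
        for row in long.itertuples(index=False):
            i, j = idx[row.snp_a], idx[row.snp_b]
            mat[i, j] = mat[j, i] = row.r2
        return LdMatrix(snps, mat)
    square = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix([str(s) for s in square.columns], square.to_numpy())


def read_blocklist(path: str | Path) -> pd.DataFrame:
    """Read a confounder-SNP blocklist: two-column TSV (snp_id, trait)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "trait"} <= set(df.columns):
        raise ValueError("blocklist needs columns snp_id and trait")
    return df
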
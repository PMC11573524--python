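"""Reading, validation, and allele harmonization of GWAS summary statistics.

Two-sample MR consumes per-SNP association summaries for an exposure and an
outcome measured in non-overlapping samples.  Before any estimation the two
tables must be *harmonized*: the outcome effect of every shared SNP is
re-expressed per copy of the exposure's effect allele, resolving allele
swaps, strand flips, and (where frequency allows) palindromic ambiguity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitMeta",
    "GwasTable",
    "HarmonizedSet",
    "DEFAULT_COLUMN_MAP",
    "read_gwas",
    "harmonize",
    "write_results",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: Default column names, following GWAS-SSF-style headers.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pval")


class GwasIOError(ValueError):
    """Configuration or data error while reading summary statistics."""


@dataclass(frozen=True)
class TraitMeta:
    """Metadata shared by all records of one GWAS table.

    ``trait_type`` is ``"quantitative"`` (beta in SD units) or ``"binary"``
    (beta on the log-odds scale).  ``genome_build`` is declarative only —
    no liftover is performed.
    """

    name: str
    trait_type: str = "quantitative"
    effect_scale: str = "sd"
    genome_build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise GwasIOError(f"unknown trait_type {self.trait_type!r}")


@dataclass
class GwasTable:
    """One trait's summary statistics: a validated DataFrame plus metadata.

    Columns: ``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta,
    se, pval, n`` (``eaf``/``n`` may be NaN).  Positions are 1-based
    inclusive, the GWAS file convention.
    """

    df: pd.DataFrame
    trait: TraitMeta

    def __post_init__(self) -> None:
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"]
            raise GwasIOError(f"duplicate snp_id in table: {list(dups[:5])}")

    def __len__(self) -> int:
        return len(self.df)

    def restrict(self, snp_ids: Sequence[str]) -> "GwasTable":
        """Subset to the given SNPs, preserving table order."""
        keep = self.df["snp_id"].isin(set(snp_ids))
        return GwasTable(self.df.loc[keep].reset_index(drop=True), self.trait)


@dataclass
class HarmonizedSet:
    """Per-SNP aligned exposure/outcome effects ready for estimation.

    For SNP j the exposure association is ``beta_exposure[j]`` with standard
    error ``se_exposure[j]`` and the outcome association (expressed per copy
    of the *same* effect allele) is ``beta_outcome[j]`` with
    ``se_outcome[j]``.
    """

    snp_id: np.ndarray
    effect_allele: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        for name in ("beta_exposure", "se_exposure",
                     "beta_outcome", "se_outcome"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise GwasIOError(f"non-finite values in {name}")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise GwasIOError("standard errors must be positive")
        if len(self) < 1:
            raise GwasIOError("harmonized set needs at least one SNP")

    def __len__(self) -> int:
        return len(self.beta_exposure)

    @property
    def n_snps(self) -> int:
        return len(self)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask)
        return HarmonizedSet(
            self.snp_id[mask], self.effect_allele[mask],
            self.beta_exposure[mask], self.se_exposure[mask],
            self.beta_outcome[mask], self.se_outcome[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id,
            "effect_allele": self.effect_allele,
            "beta_exposure": self.beta_exposure,
            "se_exposure": self.se_exposure,
            "beta_outcome": self.beta_outcome,
            "se_outcome": self.se_outcome,
        })


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating record invariants; return kept rows + drop counts."""
    drops: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            drops[reason] = n
            logger.info("read_gwas: dropped %d rows (%s)", n, reason)
        return ~mask

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    keep = pd.Series(True, index=df.index)
    bad_allele = (~df["effect_allele"].isin(_VALID_ALLELES)
                  | ~df["other_allele"].isin(_VALID_ALLELES))
    keep &= _drop(keep & bad_allele, "invalid_allele")
    keep &= _drop(keep & (df["effect_allele"] == df["other_allele"]),
                  "identical_alleles")
    for col in ("pos", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        keep &= _drop(keep & df[col].isna(), f"missing_{col}")
    keep &= _drop(keep & (df["se"] <= 0), "nonpositive_se")

    # p = 0 would break downstream log-space arithmetic
    zero_p = keep & (df["pval"] == 0)
    if zero_p.any():
        df.loc[zero_p, "pval"] = np.nextafter(0.0, 1.0)
        logger.info("read_gwas: replaced %d zero p-values with smallest "
                    "positive float", int(zero_p.sum()))
    keep &= _drop(keep & ((df["pval"] <= 0) | (df["pval"] > 1)),
                  "pval_out_of_range")

    if "eaf" in df.columns:
        df["eaf"] = pd.to_numeric(df["eaf"], errors="coerce")
        bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
        keep &= _drop(keep & bad_eaf, "eaf_out_of_range")
    else:
        df["eaf"] = np.nan
    if "n" in df.columns:
        df["n"] = pd.to_numeric(df["n"], errors="coerce")
    else:
        df["n"] = np.nan

    return df.loc[keep].reset_index(drop=True), drops


def read_gwas(path: str | Path,
              column_map: Mapping[str, str] | None = None,
              trait_meta: TraitMeta | None = None,
              sep: str | None = None) -> GwasTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Maps canonical field names (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``) to the file's column names.  Defaults to
        GWAS-SSF-style names; entries you supply override the defaults.
    trait_meta
        Trait name/type/scale; defaults to a quantitative trait named after
        the file stem.
    sep
        Field separator; inferred from the extension when omitted
        (``.csv`` → comma, otherwise tab).

    Rows violating record invariants (bad alleles, non-positive SE,
    out-of-range p or EAF) are dropped and counted, not fatal.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"

    raw = pd.read_csv(path, sep=sep, dtype={cmap["snp_id"]: str})
    missing = [cmap[k] for k in _MANDATORY if cmap[k] not in raw.columns]
    if missing:
        raise GwasIOError(
            f"{path}: missing mandatory columns {missing}; "
            f"available: {list(raw.columns)}")

    rename = {v: k for k, v in cmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    df = df[[c for c in ("snp_id", "chrom", "pos", "effect_allele",
                         "other_allele", "eaf", "beta", "se", "pval", "n")
             if c in df.columns]].copy()

    df, drops = _validate_rows(df)
    if len(df) == 0:
        raise GwasIOError(f"{path}: no valid rows after validation "
                          f"(drops: {drops})")
    meta = trait_meta or TraitMeta(name=path.stem)
    table = GwasTable(df, meta)
    return table


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(exposure: GwasTable, outcome: GwasTable,
              palindrome_policy: str = "infer-by-frequency",
              maf_threshold: float = 0.42) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    For every SNP shared between the tables the outcome record is matched to
    the exposure's allele pair in one of eight orientations: direct match,
    allele swap (negate beta, mirror EAF), strand flip (complement bases),
    or flip + swap.  Palindromic SNPs (A/T or G/C) are strand-ambiguous and
    handled per ``palindrome_policy``:

    ``"infer-by-frequency"`` (default)
        Use allele frequency to infer strand: keep only if both sides have
        minor-allele frequency below ``maf_threshold``; align so the effect
        allele is on the same side of 0.5 in both studies.
    ``"drop"``
        Discard all palindromic SNPs.

    Unresolvable SNPs are dropped with a per-reason count stored on the
    returned set (``drop_counts``).
    """
    if palindrome_policy not in ("infer-by-frequency", "drop"):
        raise GwasIOError(f"unknown palindrome_policy {palindrome_policy!r}")

    exp = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise GwasIOError("no SNPs shared between exposure and outcome")

    drops: dict[str, int] = {}
    rows: list[tuple] = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        b_out, eaf_out = float(o["beta"]), o["eaf"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]

        if _is_palindromic(ea, oa):
            if {o_ea, o_oa} != {ea, oa}:
                drops["allele_mismatch"] = drops.get("allele_mismatch", 0) + 1
                continue
            if palindrome_policy == "drop":
                drops["palindromic"] = drops.get("palindromic", 0) + 1
                continue
            eaf_exp = e["eaf"]
            if pd.isna(eaf_exp) or pd.isna(eaf_out):
                drops["palindromic_no_eaf"] = \
                    drops.get("palindromic_no_eaf", 0) + 1
                continue
            # for a palindrome the swap and strand-flip orientations are
            # indistinguishable from alleles; frequency decides instead
            if min(eaf_exp, 1 - eaf_exp) >= maf_threshold or \
                    min(eaf_out, 1 - eaf_out) >= maf_threshold:
                drops["palindromic_ambiguous_maf"] = \
                    drops.get("palindromic_ambiguous_maf", 0) + 1
                continue
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                b_out = -b_out
        else:
            if (o_ea, o_oa) == (ea, oa):
                pass
            elif (o_ea, o_oa) == (oa, ea):
                b_out = -b_out
            else:
                f_ea, f_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
                if (f_ea, f_oa) == (ea, oa):
                    pass
                elif (f_ea, f_oa) == (oa, ea):
                    b_out = -b_out
                else:
                    drops["allele_mismatch"] = \
                        drops.get("allele_mismatch", 0) + 1
                    continue

        rows.append((snp, ea, float(e["beta"]), float(e["se"]),
                     b_out, float(o["se"])))

    if not rows:
        raise GwasIOError(f"no SNPs survived harmonization (drops: {drops})")
    arr = list(zip(*rows))
    hset = HarmonizedSet(
        snp_id=np.array(arr[0], dtype=object),
        effect_allele=np.array(arr[1], dtype=object),
        beta_exposure=np.array(arr[2]), se_exposure=np.array(arr[3]),
        beta_outcome=np.array(arr[4]), se_outcome=np.array(arr[5]),
        drop_counts=drops,
    )
    if drops:
        logger.info("harmonize: dropped %s", drops)
    return hset


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  manifest_extra: Mapping | None = None) -> list[Path]:
    """Write one TSV per result family plus a JSON run manifest.

    ``tables`` maps a family name (e.g. ``"mr_results"``) to a DataFrame;
    an empty DataFrame yields a header-only file.  The manifest records row
    counts, software version, and any caller-supplied configuration echo so
    a run can be traced and reproduced.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "software": {"name": "mrmediate", "version": __version__,
                     "python": sys.version.split()[0]},
        "tables": {},
    }
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["tables"][name] = {"rows": int(len(df)),
                                    "file": path.name}
        written.append(path)
    if manifest_extra:
        manifest.update({k: _jsonable(v) for k, v in manifest_extra.items()})
    mpath = out_dir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                default=str) + "\n")
    written.append(mpath)
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return obj
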
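"""Reading, validation and harmonization of GWAS / cis-eQTL summary statistics.

Summary-statistic tables are carried as :class:`pandas.DataFrame` objects with a
fixed canonical column set (:data:`CANONICAL_COLUMNS`).  A *dialect* maps the
columns of an arbitrary tab-separated file onto that canonical set, so that
differently shaped GWAS and eQTL exports can be ingested without rewriting
them.  Missing derivable columns are filled in: ``z`` from ``beta/se`` and
``pvalue`` from the two-sided standard-normal tail of ``z``.

Harmonization aligns the eQTL effect allele to the GWAS effect allele,
negating effects where the two datasets label the alleles in opposite
orientation, and drops SNPs whose allele pairs are incompatible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical per-variant association columns
CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "allele_effect", "allele_other",
    "beta", "se", "z", "pvalue", "maf", "n",
]

MANDATORY = ["rsid", "chrom", "pos", "allele_effect", "allele_other"]

#: minimum p-value carried through reports (underflow clamp)
P_FLOOR = 1e-300


class SumstatsError(ValueError):
    """Configuration or content error in a summary-statistics table."""


class NoOverlapError(SumstatsError):
    """The GWAS and eQTL tables share no SNPs."""


@dataclass
class VariantAssociation:
    """One SNP's summary statistics for one trait."""

    rsid: str
    chrom: str
    pos: int
    allele_effect: str
    allele_other: str
    beta: float
    se: float
    z: float
    pvalue: float
    maf: float
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise SumstatsError(f"{self.rsid}: se must be positive, got {self.se}")
        if abs(self.z - self.beta / self.se) > 1e-6:
            raise SumstatsError(f"{self.rsid}: z inconsistent with beta/se")
        if not 0.0 <= self.maf <= 0.5:
            raise SumstatsError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")
        if not 0.0 < self.pvalue <= 1.0:
            raise SumstatsError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")


@dataclass
class ProbeAssociation:
    """cis-eQTL summary statistics for one expression probe in one tissue."""

    probe_id: str
    gene: str
    tissue: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.records["rsid"].duplicated().any():
            dup = self.records.loc[self.records["rsid"].duplicated(), "rsid"].iloc[0]
            raise SumstatsError(f"probe {self.probe_id}: duplicate rsid {dup}")


def two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal-tail p-value for a Z statistic, clamped at ``P_FLOOR``."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, P_FLOOR)


def read_association_table(path, dialect: dict[str, str], sep: str = "\t") -> pd.DataFrame:
    """Read a summary-statistics table and return canonical, validated records.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header row.
    dialect : dict
        Maps canonical column names (see :data:`CANONICAL_COLUMNS`) to the
        column names used in the file.  ``rsid``, ``chrom``, ``pos`` and the
        two allele columns are mandatory; of the statistics, any subset from
        which ``beta``, ``se``, ``z`` and ``pvalue`` can be completed is
        accepted (``z`` is filled from ``beta/se``, ``pvalue`` from ``z``).

    Returns
    -------
    DataFrame
        Canonical columns; rows failing validation are dropped and counted in
        a log summary (attribute ``.attrs["n_dropped"]``).
    """
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        raise SumstatsError(f"{path}: empty summary-statistics table")
    for canon in MANDATORY:
        col = dialect.get(canon)
        if col is None or col not in raw.columns:
            raise SumstatsError(f"{path}: dialect does not map mandatory column '{canon}'")

    df = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        col = dialect.get(canon)
        df[canon] = raw[col] if col is not None and col in raw.columns else np.nan

    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for c in ("allele_effect", "allele_other"):
        df[c] = df[c].astype(str).str.upper()
    for c in ("pos", "beta", "se", "z", "pvalue", "maf", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    # derive z and p where absent
    fill_z = df["z"].isna() & df["beta"].notna() & (df["se"] > 0)
    df.loc[fill_z, "z"] = df.loc[fill_z, "beta"] / df.loc[fill_z, "se"]
    fill_b = df["beta"].isna() & df["z"].notna() & (df["se"] > 0)
    df.loc[fill_b, "beta"] = df.loc[fill_b, "z"] * df.loc[fill_b, "se"]
    fill_p = df["pvalue"].isna() & df["z"].notna()
    df.loc[fill_p, "pvalue"] = two_sided_p(df.loc[fill_p, "z"].to_numpy())

    ok = (
        df["pos"].notna()
        & (df["se"] > 0)
        & df["beta"].notna()
        & df["z"].notna()
        & df["pvalue"].between(P_FLOOR, 1.0, inclusive="both")
        & df["maf"].between(0.0, 0.5, inclusive="both").fillna(True)  # maf may be absent
        & df["allele_effect"].str.fullmatch(r"[ACGT]+")
        & df["allele_other"].str.fullmatch(r"[ACGT]+")
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    out = df.loc[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    out.attrs["n_dropped"] = n_dropped
    return out


def is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return a1.map(lambda s: "".join(comp.get(c, "N") for c in s)) == a2


def harmonize_pair(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame | ProbeAssociation,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Intersect a GWAS table with one probe's eQTL table and align alleles.

    The eQTL effect is flipped (beta and z negated, allele labels swapped)
    whenever its effect/other alleles are swapped relative to the GWAS.
    Records with incompatible allele pairs are dropped and logged.
    Palindromic (A/T, C/G) SNPs are retained by default and matched by allele
    letters; set ``drop_palindromic=True`` to discard them.

    Returns a harmonized DataFrame with columns
    ``rsid, chrom, pos, allele_effect, allele_other, b_gwas, se_gwas, z_gwas,
    p_gwas, maf_gwas, b_eqtl, se_eqtl, z_eqtl, p_eqtl, maf_eqtl``.
    """
    if isinstance(eqtl, ProbeAssociation):
        eqtl = eqtl.records
    merged = gwas.merge(eqtl, on="rsid", suffixes=("_g", "_e"), how="inner")
    if merged.empty:
        raise NoOverlapError("no overlapping SNPs between GWAS and eQTL tables")

    same = (merged["allele_effect_g"] == merged["allele_effect_e"]) & (
        merged["allele_other_g"] == merged["allele_other_e"]
    )
    flipped = (merged["allele_effect_g"] == merged["allele_other_e"]) & (
        merged["allele_other_g"] == merged["allele_effect_e"]
    )
    compatible = same | flipped
    n_bad = int((~compatible).sum())
    if n_bad:
        logger.info("harmonize_pair: dropped %d allele-incompatible SNP(s)", n_bad)
    merged = merged.loc[compatible].copy()
    if merged.empty:
        raise NoOverlapError("no allele-compatible overlapping SNPs")
    flipped = flipped.loc[merged.index]

    if drop_palindromic:
        pal = is_palindromic(merged["allele_effect_g"], merged["allele_other_g"])
        merged = merged.loc[~pal]
        flipped = flipped.loc[merged.index]
        if merged.empty:
            raise NoOverlapError("all overlapping SNPs palindromic and dropped")

    sign = np.where(flipped, -1.0, 1.0)
    out = pd.DataFrame(
        {
            "rsid": merged["rsid"],
            "chrom": merged["chrom_g"],
            "pos": merged["pos_g"],
            "allele_effect": merged["allele_effect_g"],
            "allele_other": merged["allele_other_g"],
            "b_gwas": merged["beta_g"],
            "se_gwas": merged["se_g"],
            "z_gwas": merged["z_g"],
            "p_gwas": merged["pvalue_g"],
            "maf_gwas": merged["maf_g"],
            "b_eqtl": merged["beta_e"] * sign,
            "se_eqtl": merged["se_e"],
            "z_eqtl": merged["z_e"] * sign,
            "p_eqtl": merged["pvalue_e"],
            "maf_eqtl": merged["maf_e"],
        }
    ).reset_index(drop=True)
    out.attrs["n_incompatible"] = n_bad
    return out


def apply_snp_filters(
    records: pd.DataFrame,
    maf_min: float = 0.03,
    z2_min: float = 10.0,
    panel_maf: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply SNP eligibility filters to harmonized records.

    ``analysis_set``: SNPs present in both datasets with MAF >= ``maf_min``
    in both (inclusive).  ``instrument_candidates``: the subset additionally
    satisfying ``z_gwas**2 >= z2_min`` (inclusive) — candidates for the
    instrumental "top" SNP.

    A missing MAF is imputed from ``panel_maf`` (rsid -> MAF) when supplied;
    otherwise the record fails the MAF filter.
    """
    rec = records.copy()
    for col in ("maf_gwas", "maf_eqtl"):
        if panel_maf is not None:
            miss = rec[col].isna()
            rec.loc[miss, col] = rec.loc[miss, "rsid"].map(panel_maf)
    maf_ok = (rec["maf_gwas"] >= maf_min) & (rec["maf_eqtl"] >= maf_min)
    analysis_set = rec.loc[maf_ok.fillna(False)].reset_index(drop=True)
    inst = analysis_set.loc[analysis_set["z_gwas"] ** 2 >= z2_min].reset_index(drop=True)
    return analysis_set, inst


def select_top_snp(instrument_candidates: pd.DataFrame) -> str | None:
    """Instrumental SNP: lowest GWAS p-value; ties by position, then rsid.

    Returns ``None`` when there are no candidates (probe is skipped upstream).
    """
    if instrument_candidates.empty:
        return None
    ordered = instrument_candidates.sort_values(
        ["p_gwas", "pos", "rsid"], kind="mergesort"
    )
    return str(ordered["rsid"].iloc[0])


def write_harmonized_tsv(records: pd.DataFrame, path) -> None:
    """Write harmonized records in the fixed external column order."""
    cols = [
        "rsid", "chrom", "pos", "allele_effect",
        "b_gwas", "se_gwas", "b_eqtl", "se_eqtl", "maf_gwas", "maf_eqtl",
    ]
    records[cols].rename(columns={"allele_effect": "allele"}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
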
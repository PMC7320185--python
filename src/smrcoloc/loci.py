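"""Locus discovery, European-ancestry confirmation and cross-dataset matching.

A locus is a ±``flank`` window (default 250 kb, inclusive ends) around a lead
SNP reaching genome-wide significance (P < 5e-8).  Loci discovered in a
mixed-ancestry meta-analysis are kept only if at least one SNP in the window
reaches P < 5e-7 in a European-ancestry dataset, and are then re-anchored on
that European lead.  Loci from two source datasets are considered the same
signal when their lead SNPs lie on the same chromosome less than 250 kb apart
(strict); matching is one-to-one, globally closest pair first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_FLANK = 250_000


@dataclass(frozen=True)
class LocusDefinition:
    """A lead SNP and its ±flank window."""

    lead_rsid: str
    chrom: str
    lead_pos: int
    flank: int = DEFAULT_FLANK
    source_dataset: str = ""
    lead_pvalue: float = float("nan")

    @property
    def window(self) -> tuple[int, int]:
        return (self.lead_pos - self.flank, self.lead_pos + self.flank)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return chrom == self.chrom and lo <= pos <= hi


def find_genomewide_loci(
    gwas: pd.DataFrame,
    p_threshold: float = 5.0e-8,
    flank: int = DEFAULT_FLANK,
    source: str = "",
) -> list[LocusDefinition]:
    """Greedy P-ranked clumping into loci.

    Repeatedly take the most significant remaining SNP below ``p_threshold``
    as a lead and absorb all SNPs within ``flank`` of it on the same
    chromosome.  Loci are returned sorted by (chromosome, position).
    """
    sig = gwas.loc[gwas["pvalue"] < p_threshold, ["rsid", "chrom", "pos", "pvalue"]]
    sig = sig.sort_values(["pvalue", "pos", "rsid"], kind="mergesort")
    loci: list[LocusDefinition] = []
    taken = pd.Series(False, index=sig.index)
    for idx, row in sig.iterrows():
        if taken[idx]:
            continue
        lead = LocusDefinition(
            str(row["rsid"]), str(row["chrom"]), int(row["pos"]),
            flank=flank, source_dataset=source, lead_pvalue=float(row["pvalue"]),
        )
        loci.append(lead)
        absorbed = (sig["chrom"] == row["chrom"]) & (
            (sig["pos"] - row["pos"]).abs() <= flank
        )
        taken |= absorbed
    return sorted(loci, key=lambda L: (L.chrom, L.lead_pos))


def confirm_european_support(
    locus: LocusDefinition,
    euro_gwas: pd.DataFrame,
    p_threshold: float = 5.0e-7,
) -> tuple[bool, LocusDefinition | None]:
    """Keep a locus iff the European dataset supports it within the window.

    Kept iff the minimum European P inside the window is below
    ``p_threshold`` (strict).  A kept locus is re-anchored on the most
    significant European SNP (new lead, new ±flank window).
    """
    lo, hi = locus.window
    inside = euro_gwas.loc[
        (euro_gwas["chrom"] == locus.chrom) & euro_gwas["pos"].between(lo, hi)
    ]
    if inside.empty:
        return False, None
    best = inside.sort_values(["pvalue", "pos", "rsid"], kind="mergesort").iloc[0]
    if not best["pvalue"] < p_threshold:
        return False, None
    return True, LocusDefinition(
        str(best["rsid"]), locus.chrom, int(best["pos"]),
        flank=locus.flank, source_dataset=locus.source_dataset,
        lead_pvalue=float(best["pvalue"]),
    )


def lead_distance(a: LocusDefinition, b: LocusDefinition) -> float:
    """Distance in bp between two lead SNPs; infinity across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return abs(a.lead_pos - b.lead_pos)


def round_kb(bp: float, decimals: int = 1) -> float:
    """Report distance in kb, half-up rounding (269397 bp -> 269.4 kb)."""
    kb = bp / 1000.0
    scale = 10 ** decimals
    return math.floor(kb * scale + 0.5) / scale


def match_loci(
    set_a: list[LocusDefinition],
    set_b: list[LocusDefinition],
    max_dist: int = DEFAULT_FLANK,
) -> tuple[list[tuple[LocusDefinition, LocusDefinition]],
           list[LocusDefinition], list[LocusDefinition]]:
    """One-to-one greedy matching of loci by lead-SNP distance.

    Repeatedly pair the globally closest unpaired (a, b) with distance
    strictly below ``max_dist``; each locus is used at most once.  Returns
    (matched pairs, unmatched from A, unmatched from B) — unmatched loci are
    retained for the final union rather than discarded.
    """
    pairs = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            d = lead_distance(a, b)
            if d < max_dist:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((set_a[i], set_b[j]))
    unmatched_a = [a for i, a in enumerate(set_a) if i not in used_a]
    unmatched_b = [b for j, b in enumerate(set_b) if j not in used_b]
    return matched, unmatched_a, unmatched_b


def loci_to_bed(loci: list[LocusDefinition]) -> pd.DataFrame:
    """BED-like frame: 0-based half-open windows, lead rsid and P as name/score."""
    return pd.DataFrame(
        {
            "chrom": [L.chrom for L in loci],
            "start": [max(L.window[0] - 1, 0) for L in loci],
            "end": [L.window[1] for L in loci],
            "name": [L.lead_rsid for L in loci],
            "score": [L.lead_pvalue for L in loci],
        }
    )
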
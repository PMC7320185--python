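"""Multi-source gene-evidence aggregation for trait-associated loci.

The packaged fixture transcribes, for each of 51 coronary-artery-disease
loci, the candidate genes proposed by each line of evidence — expression
colocalization (SMR/HEIDI), experimental literature, three SNP-based
bioinformatics prioritization studies (two of them with integer gene
scores), and one gene-based association study — together with the manually
curated per-locus conclusion.  Conclusions are stored as data, not
recomputed: the original synthesis was a manual judgment.  A separate
heuristic scorer for synthetic runs lives in :func:`heuristic_conclusion`
and is never asserted against the fixture.

Evidence-source keys: ``smr_heidi``, ``literature``, ``braenne``,
``lempiainen``, ``vanderharst``, ``svishcheva``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from scipy import stats as _sstats

from .ld import ld_group_links

CONCLUSIONS = ("causal", "most_likely_causal", "inconsistent", "insufficient", "none")
SOURCES = ("smr_heidi", "literature", "braenne", "lempiainen", "vanderharst", "svishcheva")


class FixtureError(ValueError):
    """Schema violation in the evidence fixture."""


@dataclass
class GeneEvidence:
    """One gene's evidence at one locus, merged across sources."""

    locus_id: int
    gene: str
    sources: set = field(default_factory=set)
    score_braenne: int | None = None
    score_lempiainen: int | None = None
    svishcheva_datasets: int = 0
    literature_strength: str | None = None  # strong | suggestive
    linked_snps: list = field(default_factory=list)
    ld_group: int | None = None


@dataclass
class LocusEvidence:
    locus_id: int
    lead_rsid: str
    chrom: str
    lead_pos: int
    nearest_genes: list
    gene_evidence: list  # of GeneEvidence
    conclusion: str
    verdict_genes: list
    might_also: list
    conclusion_text: str
    raw: dict = field(repr=False, default_factory=dict)


def _fixture_dict() -> dict:
    with resources.files("smrcoloc").joinpath("data/table1_loci.json").open() as fh:
        return json.load(fh)


def _canonicalizer(aliases: dict[str, list[str]]):
    lut = {}
    for canon, alts in aliases.items():
        lut[canon.upper()] = canon
        for a in alts:
            lut[a.upper()] = canon
    return lambda g: lut.get(g.upper(), g)


def _linked_snp(locus_id: int, group: int) -> str:
    # synthetic placeholder id encoding the printed arrow group (see fixture note)
    return f"rsL{locus_id}g{group}"


def load_table1_fixture(path=None) -> list[LocusEvidence]:
    """Load and validate the packaged 51-locus evidence fixture.

    Raises :class:`FixtureError` naming the offending locus and field on any
    schema violation.
    """
    if path is None:
        data = _fixture_dict()
    else:
        with open(path) as fh:
            data = json.load(fh)
    ranges = data["score_ranges"]
    canon = _canonicalizer(data.get("aliases", {}))
    out: list[LocusEvidence] = []
    singleton = 0
    for row in data["loci"]:
        lid = row["locus_id"]
        if row["conclusion"] not in CONCLUSIONS:
            raise FixtureError(f"locus {lid}: unknown conclusion {row['conclusion']!r}")
        if bool(row["verdict_genes"]) != (
            row["conclusion"] in ("causal", "most_likely_causal")
        ):
            raise FixtureError(f"locus {lid}: verdict_genes inconsistent with conclusion")
        genes: dict[str, GeneEvidence] = {}

        def entry(sym: str) -> GeneEvidence:
            g = canon(sym)
            if g not in genes:
                genes[g] = GeneEvidence(lid, g)
            return genes[g]

        for source in SOURCES:
            for e in row.get(source, []):
                ge = entry(e["gene"])
                ge.sources.add(source)
                if source == "braenne":
                    lo, hi = ranges["braenne"]
                    if not lo <= e["score"] <= hi:
                        raise FixtureError(
                            f"locus {lid}: braenne score {e['score']} for "
                            f"{e['gene']} outside [{lo}, {hi}]")
                    ge.score_braenne = e["score"]
                if source == "lempiainen":
                    lo, hi = ranges["lempiainen"]
                    if not lo <= e["score"] <= hi:
                        raise FixtureError(
                            f"locus {lid}: lempiainen score {e['score']} for "
                            f"{e['gene']} outside [{lo}, {hi}]")
                    ge.score_lempiainen = e["score"]
                if source == "svishcheva":
                    if not 0 <= e["datasets"] <= 2:
                        raise FixtureError(
                            f"locus {lid}: svishcheva datasets {e['datasets']}")
                    ge.svishcheva_datasets = max(ge.svishcheva_datasets, e["datasets"])
                if source == "literature":
                    strength = "strong" if e.get("strong") else "suggestive"
                    if ge.literature_strength != "strong":
                        ge.literature_strength = strength
                for grp in e.get("arrows", []):
                    snp = _linked_snp(lid, grp)
                    if snp not in ge.linked_snps:
                        ge.linked_snps.append(snp)
                if not e.get("arrows") and source != "literature":
                    singleton += 1
                    snp = f"rsL{lid}u{singleton}"
                    if source != "svishcheva":  # gene-based study: no SNP link
                        ge.linked_snps.append(snp)
        for ge in genes.values():
            if not ge.sources:
                raise FixtureError(f"locus {lid}: {ge.gene} has no evidence source")
        out.append(
            LocusEvidence(
                lid, row["lead_rsid"], row["chrom"], row["lead_pos"],
                list(row["nearest_genes"]), list(genes.values()),
                row["conclusion"], [canon(g) for g in row["verdict_genes"]],
                [canon(g) for g in row.get("might_also", [])],
                row.get("conclusion_text", ""), raw=row,
            )
        )
    if len(out) != 51:
        raise FixtureError(f"expected 51 loci, found {len(out)}")
    return out


def overlapping_pairs(path=None) -> list[tuple[int, int]]:
    data = _fixture_dict() if path is None else json.load(open(path))
    return [tuple(p) for p in data["overlapping_pairs"]]


def summarize_conclusions(evidence: list[LocusEvidence]) -> dict:
    """Category counts over loci and deduplicated verdict genes.

    Verdict genes appearing in two loci (the overlapping-locus case) are
    counted once, in the stronger category if the categories differ.
    """
    by_cat = {c: 0 for c in CONCLUSIONS}
    genes_by_cat: dict[str, set] = {"causal": set(), "most_likely_causal": set()}
    for L in evidence:
        by_cat[L.conclusion] += 1
        if L.conclusion in genes_by_cat:
            genes_by_cat[L.conclusion].update(L.verdict_genes)
    genes_by_cat["most_likely_causal"] -= genes_by_cat["causal"]
    n_inferred = by_cat["causal"] + by_cat["most_likely_causal"]
    return {
        "n_loci": len(evidence),
        "loci_per_category": by_cat,
        "n_loci_with_inference": n_inferred,
        "n_loci_without_inference": len(evidence) - n_inferred,
        "verdict_genes_causal": sorted(genes_by_cat["causal"]),
        "verdict_genes_most_likely": sorted(genes_by_cat["most_likely_causal"]),
        "n_verdict_genes": len(genes_by_cat["causal"])
        + len(genes_by_cat["most_likely_causal"]),
    }


def well_known_summary(evidence: list[LocusEvidence]) -> dict:
    """Loci/genes whose literature support is 'strong' (well-known genes),
    and how many of those genes also carry expression-colocalization
    evidence at some locus."""
    loci = [L for L in evidence
            if any(g.literature_strength == "strong" for g in L.gene_evidence)]
    genes = sorted({g.gene for L in loci for g in L.gene_evidence
                    if g.literature_strength == "strong"})
    smr_genes = {g.gene for L in evidence for g in L.gene_evidence
                 if "smr_heidi" in g.sources}
    in_smr = sorted(set(genes) & smr_genes)
    return {
        "n_well_known_loci": len(loci),
        "well_known_genes": genes,
        "n_well_known_genes": len(genes),
        "well_known_in_smr": in_smr,
        "n_well_known_in_smr": len(in_smr),
    }


def candidate_multiplicity(evidence: list[LocusEvidence]) -> pd.DataFrame:
    """Per-locus count of distinct candidate genes across all evidence
    sources (alias-normalized; the nearest gene is not itself evidence)."""
    rows = [
        {
            "locus_id": L.locus_id,
            "n_candidates": len({g.gene for g in L.gene_evidence}),
            "conclusion": L.conclusion,
        }
        for L in evidence
    ]
    return pd.DataFrame(rows)


def multiplicity_summary(evidence: list[LocusEvidence]) -> dict:
    df = candidate_multiplicity(evidence)
    multi = df.loc[df["n_candidates"] >= 2]
    return {
        "n_loci_multiple_candidates": int(len(multi)),
        "n_loci": int(len(df)),
        "max_candidates": int(df["n_candidates"].max()),
        "locus_with_max": int(df.loc[df["n_candidates"].idxmax(), "locus_id"]),
    }


def score_correlation(
    scores_a: dict[str, float],
    scores_b: dict[str, float],
    restrict: set[str] | None = None,
) -> float:
    """Spearman rank correlation over the gene intersection (average ranks).

    Raises ``ValueError`` when fewer than 3 genes overlap.
    """
    shared = set(scores_a) & set(scores_b)
    if restrict is not None:
        shared &= set(restrict)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError(f"insufficient overlap: {len(shared)} gene(s) shared")
    a = [scores_a[g] for g in shared]
    b = [scores_b[g] for g in shared]
    return float(_sstats.spearmanr(a, b).statistic)


def annotate_ld_groups(locus: LocusEvidence, r2_min: float = 0.8) -> list[dict]:
    """Reproduce the locus's evidence LD grouping from its linked SNPs.

    Links are (snp, gene, source) triples from the fixture; grouping follows
    the r² >= 0.8 transitive-closure convention.  Within-group placeholder
    SNPs are identical, so the printed arrow groups come back exactly.
    """
    links = []
    for ge in locus.gene_evidence:
        for snp in ge.linked_snps:
            for src in sorted(ge.sources):
                links.append((snp, ge.gene, src))
    return ld_group_links(links, None, r2_min=r2_min, r2_lookup={})


def heuristic_conclusion(locus: LocusEvidence) -> str:
    """Weighted source-count rule for synthetic runs only.

    Counts independent evidence sources per gene (strong literature counts
    double).  Clearly labelled heuristic: it is never asserted against the
    curated conclusions.
    """
    if not locus.gene_evidence:
        return "none"
    weight = {}
    for ge in locus.gene_evidence:
        w = len(ge.sources) + (1 if ge.literature_strength == "strong" else 0)
        weight[ge.gene] = w
    best = max(weight.values())
    leaders = [g for g, w in weight.items() if w == best]
    if best >= 4 and len(leaders) == 1:
        return "causal"
    if best >= 3 and len(leaders) == 1:
        return "most_likely_causal"
    if best >= 2:
        return "inconsistent"
    return "insufficient"


_SOURCE_TITLES = {
    "smr_heidi": "Prioritized by SMR/HEIDI",
    "literature": "Candidate genes from literature",
    "braenne": "Braenne et al. (score 1-11)",
    "lempiainen": "Lempiainen et al. (score 2-54)",
    "vanderharst": "van der Harst et al.",
    "svishcheva": "Svishcheva et al. (gene-based)",
}


def locus_markdown(locus: LocusEvidence) -> str:
    """Render one locus as a markdown block in the evidence-table layout."""
    lines = [
        f"### Locus {locus.locus_id}: {locus.lead_rsid} "
        f"({locus.chrom}:{locus.lead_pos:,})",
        f"Nearest gene: {', '.join(locus.nearest_genes)}",
        "",
    ]
    for source, title in _SOURCE_TITLES.items():
        entries = [g for g in locus.gene_evidence if source in g.sources]
        if not entries:
            continue
        parts = []
        for g in sorted(entries, key=lambda e: e.gene):
            extra = ""
            if source == "braenne" and g.score_braenne is not None:
                extra = f" (score {g.score_braenne})"
            elif source == "lempiainen" and g.score_lempiainen is not None:
                extra = f" (score {g.score_lempiainen})"
            elif source == "svishcheva":
                extra = f" ({g.svishcheva_datasets} dataset(s))"
            elif source == "literature" and g.literature_strength == "strong":
                extra = " (strong)"
            parts.append(f"{g.gene}{extra}")
        lines.append(f"- **{title}**: " + "; ".join(parts))
    lines += ["", f"**Conclusion**: {locus.conclusion_text or locus.conclusion}"]
    return "\n".join(lines) + "\n"


def to_tsv(evidence: list[LocusEvidence]) -> pd.DataFrame:
    """Flat gene-level table mirroring the fixture's column order."""
    rows = []
    for L in evidence:
        for ge in sorted(L.gene_evidence, key=lambda g: g.gene):
            rows.append(
                {
                    "locus_id": L.locus_id,
                    "lead_rsid": L.lead_rsid,
                    "chrom": L.chrom,
                    "lead_pos": L.lead_pos,
                    "gene": ge.gene,
                    "sources": ",".join(sorted(ge.sources)),
                    "score_braenne": ge.score_braenne,
                    "score_lempiainen": ge.score_lempiainen,
                    "svishcheva_datasets": ge.svishcheva_datasets,
                    "literature_strength": ge.literature_strength,
                    "conclusion": L.conclusion,
                    "verdict_genes": ";".join(L.verdict_genes),
                }
            )
    return pd.DataFrame(rows)
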
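"""Linkage-disequilibrium correlations from a reference genotype panel.

LD is the Pearson correlation *r* of genotype dosages (the standard composite
estimate on unphased hard calls); *r²* is its square.  The panel is held as a
complete individuals × variants dosage matrix.  Monomorphic and multiallelic
variants never enter LD computation.

``ld_group_links`` implements the evidence-grouping convention used when
annotating per-locus gene evidence: two SNP-linked pieces of evidence belong
to the same group when their SNPs are identical or in high LD (r² >= 0.8 by
default), closed transitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PanelError(ValueError):
    """Malformed panel input or unknown variant lookup."""


@dataclass
class GenotypePanel:
    """Reference panel of hard-call dosages (values in [0, 2])."""

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: rsid, chrom, pos, ref, alt
    dosages: np.ndarray = field(repr=False)  # individuals x variants

    def __post_init__(self) -> None:
        self._index = {r: i for i, r in enumerate(self.variants["rsid"])}
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise PanelError("dosage matrix shape does not match samples/variants")

    def column(self, rsid: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[rsid]]
        except KeyError:
            raise PanelError(f"unknown rsid: {rsid}") from None

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def maf(self, rsid: str) -> float:
        """Minor-allele frequency of one variant from its dosages."""
        f = float(np.mean(self.column(rsid))) / 2.0
        return min(f, 1.0 - f)

    def maf_map(self) -> dict[str, float]:
        f = self.dosages.mean(axis=0) / 2.0
        f = np.minimum(f, 1.0 - f)
        return dict(zip(self.variants["rsid"], f.astype(float)))

    def filter_maf(self, maf_min: float = 0.03) -> "GenotypePanel":
        """Drop variants below a MAF threshold (default mirrors the 0.03 panel filter)."""
        f = self.dosages.mean(axis=0) / 2.0
        keep = np.minimum(f, 1.0 - f) >= maf_min
        return GenotypePanel(
            self.sample_ids,
            self.variants.loc[keep].reset_index(drop=True),
            self.dosages[:, keep],
        )


@dataclass
class LDView:
    """Symmetric matrix of LD correlations *r* over an ordered variant list."""

    rsids: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.rsids)}

    def r_of(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2_of(self, a: str, b: str) -> float:
        return self.r_of(a, b) ** 2

    def submatrix(self, rsids: list[str]) -> np.ndarray:
        idx = [self._index[s] for s in rsids]
        return self.r[np.ix_(idx, idx)]


def _drop_constant(panel: GenotypePanel) -> GenotypePanel:
    var = panel.dosages.var(axis=0)
    keep = var > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.info("panel: excluded %d monomorphic variant(s)", n_const)
    return GenotypePanel(
        panel.sample_ids,
        panel.variants.loc[keep].reset_index(drop=True),
        panel.dosages[:, keep],
    )


def read_panel(path, format: str = "vcf") -> GenotypePanel:
    """Read a reference genotype panel.

    ``format="vcf"``: VCF v4.x with GT hard calls; biallelic SNVs only
    (multiallelic sites dropped and logged).  ``format="dosage"``:
    whitespace-delimited matrix with a header row of rsids and one row of
    dosages per individual.  Monomorphic variants are excluded either way.
    """
    if format == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, cols = [], []
        n_multi = 0
        for v in vcf:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            rows.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), v.POS, v.REF, v.ALT[0]))
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            dos = np.array([0.0, 1.0, np.nan, 2.0])[v.gt_types]
            if np.isnan(dos).any():  # mean-impute sporadic missing calls
                dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
            cols.append(dos)
        if n_multi:
            logger.info("%s: dropped %d multiallelic site(s)", path, n_multi)
        if not rows:
            raise PanelError(f"{path}: no biallelic variants")
        variants = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt"])
        dosages = np.column_stack(cols)
    elif format == "dosage":
        df = pd.read_csv(path, sep=r"\s+")
        if df.empty:
            raise PanelError(f"{path}: empty dosage matrix")
        variants = pd.DataFrame(
            {"rsid": df.columns, "chrom": "NA", "pos": 0, "ref": "A", "alt": "B"}
        )
        dosages = df.to_numpy(dtype=float)
        if np.any((dosages < 0) | (dosages > 2)):
            bad = int(np.argmax(np.any((dosages < 0) | (dosages > 2), axis=1)))
            raise PanelError(f"{path}: dosage outside [0, 2] at data line {bad + 1}")
        samples = [f"I{i}" for i in range(dosages.shape[0])]
    else:
        raise PanelError(f"unknown panel format: {format}")
    return _drop_constant(GenotypePanel(samples, variants, dosages))


def pairwise_r(panel: GenotypePanel, a: str, b: str) -> float:
    """Pearson correlation of the dosage vectors of two variants."""
    if a == b:
        panel.column(a)  # raises for unknown rsid
        return 1.0
    xa, xb = panel.column(a), panel.column(b)
    if xa.std() == 0 or xb.std() == 0:
        raise PanelError(f"constant dosage column in pair ({a}, {b})")
    return float(np.corrcoef(xa, xb)[0, 1])


def ld_matrix(panel: GenotypePanel, rsids: list[str], ridge: float = 0.0) -> LDView:
    """Symmetric LD correlation matrix over ``rsids``.

    An optional ridge ``ridge`` is added to the diagonal (and the matrix
    renormalized to unit diagonal) to guarantee positive definiteness before
    eigen-decomposition downstream.
    """
    missing = [s for s in rsids if s not in panel]
    if missing:
        raise PanelError(f"rsids not in panel: {missing}")
    x = np.column_stack([panel.column(s) for s in rsids])
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r = (r + r.T) / 2.0
    if ridge > 0:
        r = (r + ridge * np.eye(len(rsids))) / (1.0 + ridge)
    np.fill_diagonal(r, 1.0)
    return LDView(list(rsids), r)


def ld_group_links(
    links: list[tuple[str, str, str]],
    panel_or_ld: GenotypePanel | LDView | None,
    r2_min: float = 0.8,
    r2_lookup: dict[frozenset, float] | None = None,
) -> list[dict]:
    """Group SNP-linked evidence by LD.

    ``links`` are ``(snp, gene, source)`` triples.  Two SNPs are adjacent iff
    identical or r² >= ``r2_min``; groups are connected components of that
    graph (transitive closure).  r² comes from ``panel_or_ld`` or, for SNPs
    absent from it, from ``r2_lookup`` keyed by ``frozenset({a, b})``.  Links
    whose SNP has no LD information form singleton groups (logged).

    Returns the links annotated with ``group`` (0-based component id, ordered
    by first appearance); the output is a partition of the input links.
    """
    snps = list(dict.fromkeys(s for s, _, _ in links))
    g = nx.Graph()
    g.add_nodes_from(snps)

    def _r2(a: str, b: str) -> float | None:
        if r2_lookup is not None:
            v = r2_lookup.get(frozenset((a, b)))
            if v is not None:
                return v
        if isinstance(panel_or_ld, LDView):
            if a in panel_or_ld._index and b in panel_or_ld._index:
                return panel_or_ld.r2_of(a, b)
        elif isinstance(panel_or_ld, GenotypePanel):
            if a in panel_or_ld and b in panel_or_ld:
                return pairwise_r(panel_or_ld, a, b) ** 2
        return None

    for i, a in enumerate(snps):
        for b in snps[i + 1:]:
            r2 = _r2(a, b)
            if r2 is None:
                logger.info("ld_group_links: no LD info for pair (%s, %s); kept apart", a, b)
            elif r2 >= r2_min:
                g.add_edge(a, b)

    comp_of: dict[str, int] = {}
    for comp in nx.connected_components(g):
        # stable ids by first appearance of any member in the link order
        first = min(snps.index(s) for s in comp)
        for s in comp:
            comp_of[s] = first
    order = {f: i for i, f in enumerate(sorted(set(comp_of.values())))}
    return [
        {"snp": s, "gene": gene, "source": src, "group": order[comp_of[s]]}
        for s, gene, src in links
    ]
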
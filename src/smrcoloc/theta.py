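"""Theta-metric colocalization check.

The theta metric scores the similarity of two association patterns at a
locus.  It is computed here as the Pearson correlation between the
allele-aligned GWAS and eQTL Z-score vectors over the locus's shared,
filtered SNPs; it is a documented surrogate behind a named strategy point
(:func:`theta_metric` can be swapped for an alternative formula) and is not
claimed to reproduce any external implementation numerically.  A probe is
called colocalized when |theta| > 0.7 with strictly more than 3 SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

THETA_MIN = 0.7
N_MIN_EXCLUSIVE = 3


class UndefinedTheta(ValueError):
    """Theta is undefined (constant vector or too few SNPs)."""


@dataclass
class ThetaResult:
    probe_id: str
    tissue: str
    theta: float  # nan when undefined
    n_snps: int
    call: str  # colocalized | not_colocalized | untested


def theta_metric(z_gwas, z_eqtl) -> float:
    """Pearson correlation between two aligned Z-score vectors (in [-1, 1])."""
    zg = np.asarray(z_gwas, dtype=float)
    ze = np.asarray(z_eqtl, dtype=float)
    if zg.shape != ze.shape or zg.ndim != 1:
        raise ValueError("z_gwas and z_eqtl must be equal-length 1-d vectors")
    if zg.size < 2:
        raise UndefinedTheta("need at least 2 SNPs")
    if np.std(zg) == 0.0 or np.std(ze) == 0.0:
        raise UndefinedTheta("constant Z-score vector")
    r = float(np.corrcoef(zg, ze)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def theta_call(
    theta: float | None,
    n_snps: int,
    theta_min: float = THETA_MIN,
    n_min_exclusive: int = N_MIN_EXCLUSIVE,
) -> str:
    """Decision rule: colocalized iff |theta| > theta_min and n > n_min (both strict)."""
    if n_snps <= n_min_exclusive:
        return "untested"
    if theta is None or not np.isfinite(theta):
        return "untested"
    return "colocalized" if abs(theta) > theta_min else "not_colocalized"


def analyze_theta(
    analysis_set, probe_id: str = "", tissue: str = "",
    theta_min: float = THETA_MIN, n_min_exclusive: int = N_MIN_EXCLUSIVE,
) -> ThetaResult:
    """Theta over a probe's harmonized analysis set (same SNPs as SMR/HEIDI,
    without the top-SNP exclusion)."""
    n = len(analysis_set)
    try:
        th = theta_metric(
            analysis_set["z_gwas"].to_numpy(), analysis_set["z_eqtl"].to_numpy()
        )
    except UndefinedTheta:
        return ThetaResult(probe_id, tissue, float("nan"), n, "untested")
    return ThetaResult(
        probe_id, tissue, th, n, theta_call(th, n, theta_min, n_min_exclusive)
    )
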
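"""SMR test, Wald-ratio estimate, HEIDI heterogeneity test and the
colocalization decision rule.

The SMR statistic combines the GWAS and eQTL Z-scores at the instrumental
("top") SNP,

    T_SMR = z_gwas^2 * z_eqtl^2 / (z_gwas^2 + z_eqtl^2),

referred to a 1-df chi-square.  The Wald ratio b_xy = b_gwas / b_eqtl
estimates the effect of gene expression on the trait, with delta-method
standard error se_xy = |b_xy| * sqrt(1/z_gwas^2 + 1/z_eqtl^2).

HEIDI asks whether b_xy is homogeneous across SNPs in LD with the top SNP:
under pleiotropy (one shared causal variant) all SNPs estimate the same
ratio; under linkage (distinct causal variants) the ratios disagree.  The
differences d_i = b_xy(i) - b_xy(top) are standardized using a first-order
delta-method covariance that carries the LD correlations, and the statistic
S = sum_i (d_i / sd_i)^2 is referred to a weighted sum of 1-df chi-squares
whose weights are the eigenvalues of the correlation matrix of the
standardized d vector.  The tail probability is evaluated by numerical
inversion of the characteristic function (Imhof's method), falling back to
two-moment (Satterthwaite) matching if the quadrature fails.

A probe colocalizes ("pass") iff its BH-adjusted SMR p-value is below 0.05
and HEIDI was tested with 3-20 SNPs and did not reject at 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from .ld import LDView
from .sumstats import P_FLOOR, select_top_snp

logger = logging.getLogger(__name__)

HEIDI_R2_WINDOW = (0.05, 0.9)


class UndefinedStatistic(ValueError):
    """Degenerate inputs for which the statistic is undefined."""


@dataclass
class SMRResult:
    probe_id: str
    gene: str
    tissue: str
    top_snp: str
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float
    q_fdr: float = float("nan")


@dataclass
class HEIDIResult:
    probe_id: str
    tissue: str
    snps_used: int
    p_heidi: float | None
    status: str  # tested | skipped_too_few_snps | skipped_no_instrument
    tail_method: str = ""  # imhof | satterthwaite | degenerate
    stat: float | None = None  # S = sum of squared standardized differences
    eigenvalues: np.ndarray | None = None  # weights of the chi-square mixture


def smr_statistic(z_gwas: float, z_eqtl: float) -> tuple[float, float]:
    """SMR chi-square statistic and its 1-df upper-tail p-value."""
    zg2, ze2 = z_gwas**2, z_eqtl**2
    if zg2 + ze2 == 0.0:
        raise UndefinedStatistic("smr_statistic undefined for z_gwas = z_eqtl = 0")
    t = zg2 * ze2 / (zg2 + ze2)
    p = max(float(stats.chi2.sf(t, df=1)), P_FLOOR)
    return float(t), p


def wald_ratio(
    b_gwas: float, se_gwas: float, b_eqtl: float, se_eqtl: float
) -> tuple[float, float]:
    """Wald-ratio effect of expression on trait with delta-method SE."""
    if b_eqtl == 0.0:
        raise UndefinedStatistic("wald_ratio undefined for b_eqtl = 0")
    b_xy = b_gwas / b_eqtl
    zg, ze = b_gwas / se_gwas, b_eqtl / se_eqtl
    if zg == 0.0:
        # delta method with b_gwas = 0: var = (se_gwas/b_eqtl)^2
        se_xy = abs(se_gwas / b_eqtl) * np.sqrt(1.0)
    else:
        se_xy = abs(b_xy) * np.sqrt(1.0 / zg**2 + 1.0 / ze**2)
    return float(b_xy), float(se_xy)


def _imhof_tail(x: float, lam: np.ndarray) -> tuple[float, bool]:
    """P(sum_k lam_k * chi2_1 > x) by Imhof's characteristic-function inversion.

    P(Q > x) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du with
    theta(u) = (1/2) sum_k arctan(lam_k u) - x u / 2 and
    rho(u) = prod_k (1 + lam_k^2 u^2)^(1/4).  The integrand's envelope
    1/(u * rho(u)) decays polynomially, so integration is truncated where the
    envelope falls below 1e-13 (tail contribution negligible).

    Returns (p, converged).
    """

    def theta(u):
        u = np.asarray(u, dtype=float)
        return 0.5 * np.sum(np.arctan(np.outer(lam, u)), axis=0) - 0.5 * x * u

    def rho(u):
        u = np.asarray(u, dtype=float)
        return np.prod((1.0 + np.outer(lam, u) ** 2) ** 0.25, axis=0)

    def integrand(u):
        u = np.asarray(u, dtype=float)
        return np.sin(theta(u)) / (u * rho(u))

    # truncate where the oscillation envelope is negligible
    upper = 1.0
    while upper < 1e8 and 1.0 / (upper * rho([upper])[0]) > 1e-13:
        upper *= 2.0
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(
                lambda u: integrand([u])[0], 0.0, upper, limit=500
            )
    except Exception:  # quadrature blow-up
        return np.nan, False
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-6:
        return np.nan, False
    return float(min(max(p, 0.0), 1.0)), True


def _satterthwaite_tail(x: float, lam: np.ndarray) -> float:
    """Two-moment chi-square approximation to the weighted-sum tail."""
    s1, s2 = lam.sum(), (lam**2).sum()
    if s1 <= 0 or s2 <= 0:
        return 1.0
    a = s2 / s1
    g = s1**2 / s2
    return float(stats.chi2.sf(x / a, df=g))


def mixture_chi2_sf(x: float, lam: np.ndarray) -> tuple[float, str]:
    """Upper tail of sum_k lam_k chi2_1 at x; returns (p, method used)."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0 or x <= 0:
        return 1.0, "degenerate"
    p, ok = _imhof_tail(x, lam)
    if ok:
        return max(p, P_FLOOR), "imhof"
    logger.info("mixture_chi2_sf: Imhof inversion failed; Satterthwaite fallback")
    return max(_satterthwaite_tail(x, lam), P_FLOOR), "satterthwaite"


def _bxy_cov(
    bxy: np.ndarray, zg: np.ndarray, ze: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """First-order delta-method covariance of the Wald ratios.

    Cov(bxy_i, bxy_j) ~ bxy_i bxy_j [ r_ij/(zg_i zg_j) + r_ij/(ze_i ze_j) ].
    """
    outer = np.outer(bxy, bxy)
    return outer * r * (1.0 / np.outer(zg, zg) + 1.0 / np.outer(ze, ze))


def heidi_test(
    records: pd.DataFrame,
    ld: LDView,
    top: str,
    min_snps: int = 3,
    max_snps: int = 20,
    r2_window: tuple[float, float] = HEIDI_R2_WINDOW,
    probe_id: str = "",
    tissue: str = "",
    ridge: float = 1e-8,
) -> HEIDIResult:
    """HEIDI heterogeneity test around the top SNP.

    ``records`` is the harmonized analysis set (must contain ``top``).
    Candidate SNPs are those whose r² with the top SNP lies inside
    ``r2_window``; they are ranked by eQTL significance and truncated to
    ``max_snps``.  The test is skipped (no p-value) with fewer than
    ``min_snps`` candidates.
    """
    rec = records.set_index("rsid", drop=False)
    if top not in rec.index:
        raise UndefinedStatistic(f"top SNP {top} not in records")
    others = [s for s in rec.index if s != top and s in ld._index]
    r2_top = np.array([ld.r2_of(s, top) for s in others])
    lo, hi = r2_window
    eligible = [s for s, r2 in zip(others, r2_top) if lo <= r2 <= hi]
    # rank by eQTL significance (largest |z_eqtl| first), cap at max_snps
    eligible.sort(key=lambda s: (-abs(rec.at[s, "z_eqtl"]), rec.at[s, "pos"], s))
    eligible = eligible[:max_snps]
    if len(eligible) < min_snps:
        return HEIDIResult(probe_id, tissue, len(eligible), None,
                           "skipped_too_few_snps")

    snps = [top] + eligible
    sub = rec.loc[snps]
    bg, se_g = sub["b_gwas"].to_numpy(), sub["se_gwas"].to_numpy()
    be, se_e = sub["b_eqtl"].to_numpy(), sub["se_eqtl"].to_numpy()
    zg, ze = bg / se_g, be / se_e
    if np.any(be == 0.0):
        raise UndefinedStatistic("b_eqtl = 0 among HEIDI SNPs")
    bxy = bg / be
    r = ld.submatrix(snps)

    cov_b = _bxy_cov(bxy, zg, ze, r)
    # d_i = bxy_i - bxy_top, i over candidates (index 0 is the top SNP)
    k = len(eligible)
    d = bxy[1:] - bxy[0]
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, [0]]
        - cov_b[[0], 1:]
        + cov_b[0, 0]
    )
    sd = np.sqrt(np.clip(np.diag(cov_d), 0.0, None))
    if np.all(np.abs(d) < 1e-12):
        return HEIDIResult(probe_id, tissue, k, 1.0, "tested", "degenerate", 0.0)
    if np.any(sd <= 0):
        raise UndefinedStatistic("zero variance for a HEIDI difference")
    u = d / sd
    s_stat = float(u @ u)
    corr = cov_d / np.outer(sd, sd)
    corr = (corr + corr.T) / 2.0 + ridge * np.eye(k)
    lam = np.linalg.eigvalsh(corr)
    p, method = mixture_chi2_sf(s_stat, lam)
    return HEIDIResult(probe_id, tissue, k, p, "tested", method, s_stat, lam)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def classify_probe(
    smr: SMRResult,
    heidi: HEIDIResult,
    fdr_max: float = 0.05,
    heidi_min: float = 0.001,
) -> str:
    """Colocalization call: pass | fail_smr | fail_heidi | untested_heidi.

    pass       — SMR FDR < fdr_max and HEIDI tested with p >= heidi_min
    fail_heidi — SMR passes but HEIDI rejects (linkage, not pleiotropy)
    untested_heidi — SMR passes but HEIDI was skipped (too few SNPs)
    fail_smr   — SMR FDR >= fdr_max
    """
    if smr.probe_id != heidi.probe_id or smr.tissue != heidi.tissue:
        raise ValueError(
            f"mismatched probe/tissue: {smr.probe_id}/{smr.tissue}"
            f" vs {heidi.probe_id}/{heidi.tissue}"
        )
    if not smr.q_fdr < fdr_max:
        return "fail_smr"
    if heidi.status != "tested":
        return "untested_heidi"
    return "pass" if heidi.p_heidi >= heidi_min else "fail_heidi"


def analyze_probe(
    analysis_set: pd.DataFrame,
    instrument_candidates: pd.DataFrame,
    ld: LDView,
    probe_id: str = "",
    gene: str = "",
    tissue: str = "",
    min_snps: int = 3,
    max_snps: int = 20,
    r2_window: tuple[float, float] = HEIDI_R2_WINDOW,
) -> tuple[SMRResult | None, HEIDIResult]:
    """SMR at the top SNP plus HEIDI for one probe×tissue.

    Returns ``(None, HEIDIResult(status="skipped_no_instrument"))`` when no
    instrument candidate survives the filters.
    """
    top = select_top_snp(instrument_candidates)
    if top is None:
        logger.info("probe %s/%s skipped: no instrument", probe_id, tissue)
        return None, HEIDIResult(probe_id, tissue, 0, None, "skipped_no_instrument")
    row = analysis_set.set_index("rsid").loc[top]
    t, p = smr_statistic(float(row["z_gwas"]), float(row["z_eqtl"]))
    b_xy, se_xy = wald_ratio(
        float(row["b_gwas"]), float(row["se_gwas"]),
        float(row["b_eqtl"]), float(row["se_eqtl"]),
    )
    smr = SMRResult(probe_id, gene, tissue, top, b_xy, se_xy, t, p)
    heidi = heidi_test(
        analysis_set, ld, top, min_snps=min_snps, max_snps=max_snps,
        r2_window=r2_window, probe_id=probe_id, tissue=tissue,
    )
    return smr, heidi


def results_table(results: list[tuple[SMRResult, HEIDIResult, str]]) -> pd.DataFrame:
    """One row per probe×tissue in the fixed external column order."""
    rows = []
    for smr, heidi, call in results:
        rows.append(
            {
                "probe": smr.probe_id,
                "gene": smr.gene,
                "tissue": smr.tissue,
                "top_snp": smr.top_snp,
                "b_xy": smr.b_xy,
                "se_xy": smr.se_xy,
                "T_SMR": smr.t_smr,
                "p_smr": smr.p_smr,
                "q_fdr": smr.q_fdr,
                "n_heidi_snps": heidi.snps_used,
                "p_heidi": heidi.p_heidi if heidi.p_heidi is not None else np.nan,
                "call": call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["probe", "gene", "tissue", "top_snp", "b_xy", "se_xy",
                 "T_SMR", "p_smr", "q_fdr", "n_heidi_snps", "p_heidi", "call"],
    )
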
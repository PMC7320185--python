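"""Synthetic LD-structured panels and paired GWAS/eQTL summary statistics.

The generator produces the statistical structure that the colocalization
tests assume, under three architectures:

``pleiotropy``
    one SNP is causal for both trait and expression (the colocalization
    null that HEIDI should *not* reject);
``linkage``
    two distinct, LD-correlated SNPs are causal — one for the trait, one
    for expression (HEIDI should reject);
``null``
    no trait association (lambda_gwas = 0); the SMR test should not fire.

Genotypes: each individual draws a latent AR(1)-correlated standard-normal
vector (parameter ``ld_rho``) that is thresholded at Hardy–Weinberg
quantiles for each SNP's MAF, giving hard-call dosages in {0, 1, 2}.

Summary statistics are simulated directly at the Z-score level:
z ~ MVN(R @ lambda, R) where R is the panel's LD matrix and lambda places a
non-centrality (Z-score scale) at the causal index for each trait.  Betas
and SEs are back-filled for a standardized phenotype:
se = 1/sqrt(2*maf*(1-maf)*n), beta = z*se.  This gives exact marginal
distributional control and is orders of magnitude faster than
individual-level phenotype regression, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ld import GenotypePanel, LDView

SCENARIOS = ("pleiotropy", "linkage", "null")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated locus.

    Defaults describe a moderately LD-structured 30-SNP locus with common
    variants, a large GWAS and a moderate eQTL study, and strong shared
    signal (non-centrality 8 on the Z scale) — the regime in which the
    colocalization tests are meant to operate.
    """

    n_individuals: int = 2_000
    n_snps: int = 30
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    scenario: str = "pleiotropy"
    causal_index_gwas: int = 14
    causal_index_eqtl: int = 14
    lambda_gwas: float = 8.0
    lambda_eqtl: float = 8.0
    n_gwas: int = 200_000
    n_eqtl: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"degenerate maf_range {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0, 1)")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "pleiotropy" and self.causal_index_gwas != self.causal_index_eqtl:
            raise ConfigError("pleiotropy requires equal causal indices")
        if self.scenario == "linkage" and self.causal_index_gwas == self.causal_index_eqtl:
            raise ConfigError("linkage requires distinct causal indices")
        if self.scenario == "null" and self.lambda_gwas != 0.0:
            raise ConfigError("null scenario requires lambda_gwas = 0")
        for idx in (self.causal_index_gwas, self.causal_index_eqtl):
            if not 0 <= idx < self.n_snps:
                raise ConfigError(
                    f"causal index {idx} outside the {self.n_snps}-SNP locus")


@dataclass
class SimulatedStudy:
    panel: GenotypePanel
    gwas_table: pd.DataFrame
    eqtl_table: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """AR(1)-latent genotype panel, deterministic given the config seed."""
    rng = rng or np.random.default_rng(config.seed)
    n, m, rho = config.n_individuals, config.n_snps, config.ld_rho
    lat = np.empty((n, m))
    lat[:, 0] = rng.standard_normal(n)
    for j in range(1, m):
        lat[:, j] = rho * lat[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    # HWE genotype thresholds: P(0) = (1-p)^2, P(2) = p^2 for alt frequency p
    from scipy.stats import norm

    q0 = norm.ppf((1 - mafs) ** 2)
    q2 = norm.ppf(1 - mafs**2)
    dos = (lat > q0).astype(float) + (lat > q2)
    variants = pd.DataFrame(
        {
            "rsid": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": 1_000_000 + 5_000 * np.arange(m),
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i + 1}" for i in range(n)]
    return GenotypePanel(samples, variants, dos)


def panel_ld(panel: GenotypePanel) -> LDView:
    from .ld import ld_matrix

    return ld_matrix(panel, list(panel.variants["rsid"]))


def _sumstats_frame(panel: GenotypePanel, z: np.ndarray, n_trait: int) -> pd.DataFrame:
    mafs = panel.dosages.mean(axis=0) / 2.0
    mafs = np.minimum(mafs, 1.0 - mafs)
    se = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * n_trait)
    beta = z * se
    from .sumstats import two_sided_p

    return pd.DataFrame(
        {
            "rsid": panel.variants["rsid"],
            "chrom": panel.variants["chrom"],
            "pos": panel.variants["pos"],
            "allele_effect": panel.variants["alt"],
            "allele_other": panel.variants["ref"],
            "beta": beta,
            "se": se,
            "z": z,
            "pvalue": two_sided_p(z),
            "maf": mafs,
            "n": float(n_trait),
        }
    )


def simulate_summary_stats(
    config: SimulationConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
    ld: LDView | None = None,
    ridge: float = 1e-6,
) -> SimulatedStudy:
    """Paired GWAS/eQTL marginal Z-scores drawn as MVN(R @ lambda, R)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    ld = ld or panel_ld(panel)
    m = len(ld.rsids)
    r = ld.r + ridge * np.eye(m)
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "LD matrix not positive definite after ridge; increase `ridge`"
        ) from e

    lam_g = np.zeros(m)
    lam_e = np.zeros(m)
    if config.scenario != "null" and config.lambda_gwas != 0.0:
        lam_g[config.causal_index_gwas] = config.lambda_gwas
    if config.lambda_eqtl != 0.0:
        lam_e[config.causal_index_eqtl] = config.lambda_eqtl

    z_gwas = ld.r @ lam_g + chol @ rng.standard_normal(m)
    z_eqtl = ld.r @ lam_e + chol @ rng.standard_normal(m)

    gwas = _sumstats_frame(panel, z_gwas, config.n_gwas)
    eqtl = _sumstats_frame(panel, z_eqtl, config.n_eqtl)
    truth = {
        "scenario": config.scenario,
        "causal_index_gwas": config.causal_index_gwas,
        "causal_index_eqtl": config.causal_index_eqtl,
        "causal_rsid_gwas": ld.rsids[config.causal_index_gwas],
        "causal_rsid_eqtl": ld.rsids[config.causal_index_eqtl],
        "b_xy_true": true_bxy(config, panel),
    }
    return SimulatedStudy(panel, gwas, eqtl, truth)


def true_bxy(config: SimulationConfig, panel: GenotypePanel) -> float | None:
    """Expression-to-trait effect ratio implied by the config (pleiotropy only).

    At the shared causal SNP, E[b_gwas]/E[b_eqtl] =
    (lambda_gwas/lambda_eqtl) * sqrt(n_eqtl/n_gwas) for a common MAF.
    """
    if config.scenario != "pleiotropy" or config.lambda_eqtl == 0.0:
        return None
    return (config.lambda_gwas / config.lambda_eqtl) * np.sqrt(
        config.n_eqtl / config.n_gwas
    )


def scenario_truth(config: SimulationConfig, causal_r2: float | None = None) -> dict:
    """Expected downstream colocalization call for a scenario.

    pleiotropy -> pass; linkage -> fail_heidi; null -> fail_smr.  A linkage
    scenario whose causal pair is in near-perfect LD is flagged
    ``indistinguishable`` (no call expected: pleiotropy and linkage cannot
    be separated by any statistical test in that regime).
    """
    expected = {"pleiotropy": "pass", "linkage": "fail_heidi", "null": "fail_smr"}[
        config.scenario
    ]
    out = {"scenario": config.scenario, "expected_call": expected,
           "indistinguishable": False}
    if config.scenario == "linkage" and causal_r2 is not None and causal_r2 > 0.95:
        out["indistinguishable"] = True
        out["expected_call"] = None
    return out


def write_study(study: SimulatedStudy, outdir, config: SimulationConfig | None = None) -> dict:
    """Emit the study as sumstats TSVs + a VCF panel + a JSON manifest.

    Floats are written with fixed 6-significant-digit formatting so that
    identical seeds yield byte-identical files.
    """
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": outdir / "gwas.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "panel": outdir / "panel.vcf",
        "manifest": outdir / "manifest.json",
    }
    for key in ("gwas", "eqtl"):
        getattr(study, f"{key}_table").to_csv(
            paths[key], sep="\t", index=False, float_format="%.6g"
        )
    write_vcf(study.panel, paths["panel"])
    manifest = {"truth": {k: v for k, v in study.truth.items()}}
    if config is not None:
        manifest["config"] = asdict(config)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    return {k: str(v) for k, v in paths.items()}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a minimal VCFv4.2 with hard-call GT fields."""
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(panel.variants["chrom"]), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, row in panel.variants.iterrows():
            calls = "\t".join(gt[d] for d in panel.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['rsid']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )
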
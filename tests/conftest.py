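import numpy as np
import pandas as pd
import pytest

from smrcoloc.ld import ld_matrix
from smrcoloc.simulate import SimulationConfig, simulate_panel

IDENTITY_DIALECT = {
    c: c
    for c in ("rsid", "chrom", "pos", "allele_effect", "allele_other",
              "beta", "se", "z", "pvalue", "maf", "n")
}


@pytest.fixture(scope="session")
def panel30():
    """Shared 2000x30 AR(1) reference panel (latent rho 0.8)."""
    return simulate_panel(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def ld30(panel30):
    return ld_matrix(panel30, list(panel30.variants["rsid"]))


def make_sumstats(rows, **defaults) -> pd.DataFrame:
    """Build a canonical sumstats frame from compact row dicts."""
    base = dict(chrom="1", allele_effect="A", allele_other="G", maf=0.25, n=1000.0)
    base.update(defaults)
    recs = []
    for i, row in enumerate(rows):
        r = dict(base)
        r.setdefault("rsid", f"rs{i + 1}")
        r.setdefault("pos", 100 + i)
        r.update(row)
        if "z" not in r and "beta" in r and "se" in r:
            r["z"] = r["beta"] / r["se"]
        if "pvalue" not in r and "z" in r:
            from smrcoloc.sumstats import two_sided_p

            r["pvalue"] = float(two_sided_p(r["z"]))
        recs.append(r)
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
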
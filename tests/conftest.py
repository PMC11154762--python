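import numpy as np
import pandas as pd
import pytest

from cytomr.sumstats import GwasDataset


def make_instruments(beta_exp, se_exp, beta_out, se_out, **extra):
    """Harmonized-instrument frame from parallel arrays."""
    beta_exp = np.asarray(beta_exp, float)
    j = len(beta_exp)
    base = dict(
        snp_id=[f"rs{i}" for i in range(j)],
        beta_exp=beta_exp,
        se_exp=np.broadcast_to(np.asarray(se_exp, float), (j,)).copy(),
        beta_out=np.asarray(beta_out, float),
        se_out=np.broadcast_to(np.asarray(se_out, float), (j,)).copy(),
        eaf_exp=np.full(j, 0.3),
        pval_exp=np.full(j, 1e-10),
        pval_out=np.full(j, 0.5),
        n_exp=np.full(j, 8293),
        n_out=np.full(j, 254894),
    )
    base.update(extra)
    return pd.DataFrame(base)


def make_dataset(trait_name="trait", **columns):
    """Small GwasDataset; scalar column values are broadcast."""
    defaults = dict(
        snp_id=["rs1", "rs2", "rs3"],
        chrom=["1", "2", "3"],
        pos=[1_000_000, 2_000_000, 3_000_000],
        effect_allele=["A", "A", "A"],
        other_allele=["G", "G", "G"],
        eaf=[0.3, 0.3, 0.3],
        beta=[0.1, 0.1, 0.1],
        se=[0.01, 0.01, 0.01],
        pval=[1e-10, 1e-10, 1e-10],
        n=[8293, 8293, 8293],
    )
    defaults.update(columns)
    j = len(defaults["snp_id"])
    for key, val in defaults.items():
        if np.isscalar(val):
            defaults[key] = [val] * j
        elif len(val) != j:  # resize unprovided default columns by cycling
            defaults[key] = [val[i % len(val)] for i in range(j)]
    return GwasDataset(trait_name=trait_name, records=pd.DataFrame(defaults))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_instruments(rng):
    """Five instruments with heterogeneous effects and SEs."""
    bx = rng.uniform(0.1, 0.3, 5) * rng.choice([-1, 1], 5)
    return make_instruments(
        beta_exp=bx,
        se_exp=rng.uniform(0.005, 0.02, 5),
        beta_out=0.1 * bx + rng.normal(0, 0.01, 5),
        se_out=rng.uniform(0.005, 0.02, 5),
    )
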
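import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.gwas_io import GwasTable, HarmonizedSet, TraitMeta

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_table(rows, trait=None) -> GwasTable:
    """Build a GwasTable from a list of row dicts, filling defaults."""
    defaults = {"chrom": "1", "pos": 1_000_000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01,
                "pval": 1e-10, "n": 10_000.0}
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("snp_id", f"rs{i}")
        r.update(row)
        full.append(r)
    return GwasTable(pd.DataFrame(full), trait or TraitMeta("test"))


def make_hset(gamma, Gamma, se_gamma=None, se_Gamma=None) -> HarmonizedSet:
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    J = len(gamma)
    return HarmonizedSet(
        snp_id=np.array([f"rs{i}" for i in range(J)], dtype=object),
        effect_allele=np.array(["A"] * J, dtype=object),
        beta_exposure=gamma,
        se_exposure=np.full(J, 0.01) if se_gamma is None
        else np.asarray(se_gamma, dtype=float),
        beta_outcome=Gamma,
        se_outcome=np.full(J, 0.01) if se_Gamma is None
        else np.asarray(se_Gamma, dtype=float),
    )


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def table_factory():
    return make_table
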
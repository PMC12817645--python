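import dataclasses

import numpy as np
import pandas as pd
import pytest

import mrmediate as mm


def make_sumstats(rows, columns=None):
    """Build a summary-stat frame from (rsid, chrom, pos, ea, oa, eaf, beta,
    se, pval, n) tuples."""
    cols = columns or ["rsid", "chrom", "pos", "effect_allele",
                       "other_allele", "eaf", "beta", "se", "pval", "n"]
    df = pd.DataFrame(rows, columns=cols)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def make_harmonized(bx, sx, by, sy):
    """Minimal harmonized-effects frame for estimator-level tests."""
    return pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(len(bx))],
        "beta_exposure": np.asarray(bx, float),
        "se_exposure": np.asarray(sx, float),
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.asarray(sy, float),
    })


@pytest.fixture(scope="session")
def presets():
    return mm.scenario_presets()


@pytest.fixture(scope="session")
def clean_study(presets):
    return mm.simulate_study(dataclasses.replace(presets["clean"], seed=42))


@pytest.fixture(scope="session")
def clean_harmonized(clean_study):
    s = clean_study
    inst = mm.select_instruments(s.exposure, ld=s.ld)
    return mm.harmonize(inst.table, s.outcome)
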
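import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import phylometab as pm

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_table(mz, rt=None, intensities=None, ion_mode=None, ids=None):
    """Small FeatureTable builder for hand-written cases."""
    n = len(mz)
    ids = ids or [f"F{i+1:03d}" for i in range(n)]
    rt = rt if rt is not None else [1.0] * n
    meta = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(ids, name="feature_id"))
    if intensities is None:
        intensities = {"S1": [10.0] * n, "S2": [20.0] * n}
    inten = pd.DataFrame(intensities, index=meta.index)
    return pm.FeatureTable(meta=meta, intensities=inten, ion_mode=ion_mode)


def make_manifest(outgroup=(), pre=(), post=()):
    rows = [{"specimen_id": s, "patient_id": "", "role": "outgroup"} for s in outgroup]
    rows += [{"specimen_id": s, "patient_id": s, "role": "pre_RT"} for s in pre]
    rows += [{"specimen_id": s, "patient_id": s.replace("_post", ""), "role": "post_RT"} for s in post]
    return pm.SampleManifest(pd.DataFrame(rows))


def random_states(rng, n_taxa, n_chars, prefix="t"):
    return pd.DataFrame(
        rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8),
        index=pd.Index([f"{prefix}{i}" for i in range(n_taxa)], name="specimen"),
        columns=[f"c{j}" for j in range(n_chars)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    cfg = pm.CohortConfig(n_outgroup=6, n_patients=6, n_noise_features=20, seed=42)
    return pm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def table1():
    return pm.load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return pm.load_table2_fixture()
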
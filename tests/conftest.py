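import dataclasses

import pandas as pd
import pytest

from alcodoc import classify, cohort, simulate


def as_csv_frames(extract):
    """Render datetime columns as ISO strings, mimicking a CSV round trip."""
    out = {}
    for name, df in extract.tables().items():
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        out[name] = df
    return out


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(n_patients=4000, n_providers=25, seed=123)


@pytest.fixture(scope="session")
def small_extract(small_config):
    return simulate.simulate_extract(small_config)


@pytest.fixture(scope="session")
def csv_frames(small_extract):
    return as_csv_frames(small_extract)


@pytest.fixture(scope="session")
def small_classified(small_extract):
    return classify.classify_table(small_extract.riskfactor)


@pytest.fixture(scope="session")
def small_cohort(small_extract, small_classified):
    frames = as_csv_frames(small_extract)
    return cohort.assemble_cohort(
        frames["patients.csv"], frames["encounters.csv"],
        frames["conditions.csv"], frames["providers.csv"],
        small_classified)


@pytest.fixture()
def null_effects_config():
    """Generator config with every covariate effect switched off."""
    return simulate.SimConfig(
        n_patients=4000, n_providers=25, seed=9,
        doc_logit_effects={}, risk_logit_effects={})


@pytest.fixture()
def rules():
    return classify.default_rules()
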
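import warnings

import numpy as np
import pytest

from aomphen import cohort, featurize, synth


@pytest.fixture(scope="session")
def small_tables():
    """A small but complete synthetic dataset shared across tests."""
    cfg = synth.SynthConfig(n_patients=40, seed=7)
    return cfg, synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    """Periods + events derived from the small dataset."""
    cfg, tables = small_tables
    records = cohort.records_from_frame(tables["drug_exposure"])
    sessions = cohort.build_sessions(cohort.filter_oaom_records(records))
    periods = cohort.derive_pre_aom_periods(cohort.select_medium_long(sessions))
    return cfg, tables, periods


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Featurized temporal dataset for the small cohort."""
    cfg, tables, periods = small_cohort
    meas_ids = sorted(tables["measurement"]["feature_id"].unique())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalizer = featurize.fit_normalizer(periods, tables["measurement"], meas_ids)
    ds = featurize.build_dataset(
        periods, tables["measurement"], tables["condition"],
        list(range(cfg.n_ccs_features)), normalizer,
    )
    return cfg, tables, periods, normalizer, ds


def make_record(pid=0, start=0, end=10, ingredients=("X",), off_label=False):
    return cohort.ExposureRecord(
        person_id=pid, start_day=start, end_day=end,
        ingredients=frozenset(ingredients), is_off_label=off_label,
    )
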
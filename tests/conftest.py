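import numpy as np
import pandas as pd
import pytest

from suicohort import default_config, filter_complete, generate_cohort
from suicohort.anchors import SI_COEFFICIENTS
from suicohort.coding import SCHOOL_YEARS, code_records


def make_raw(n=60, seed=0, missing=False):
    """Small hand-rolled raw cohort with optional missingness."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "school_year": rng.choice(SCHOOL_YEARS, n),
            "age": rng.integers(13, 28, n),
            "gender": rng.choice(["male", "female"], n),
            "k10_score": rng.integers(10, 51, n),
            "si": rng.choice(["never", "occasionally", "sometimes", "often"], n),
            "sa": rng.choice(["yes", "no"], n, p=[0.05, 0.95]),
        }
    )
    if missing:
        df.loc[df.index[:3], "gender"] = [np.nan, "other", np.nan]
        df.loc[df.index[3:5], "k10_score"] = np.nan
        df.loc[df.index[5], "si"] = np.nan
        df.loc[df.index[6:9], "sa"] = "no_answer"
    return df


@pytest.fixture
def raw_cohort():
    return make_raw(n=200, seed=1)


@pytest.fixture
def coded_cohort(raw_cohort):
    kept, _ = filter_complete(code_records(raw_cohort))
    return kept


def structure_cohort(n, seed, planted=True, n_years=len(SCHOOL_YEARS)):
    """Cohort drawn from exactly the default SI generating structure
    (zero year offsets so the fitted term set matches generation)."""
    years = SCHOOL_YEARS[:n_years]
    coeffs = dict(SI_COEFFICIENTS)
    if not planted:
        coeffs.pop("<18 + high")
    cfg = default_config(
        n_per_year=n // len(years),
        years=years,
        sa_no_answer_rate=0.0,
        si_coefficients=coeffs,
    )
    raw = generate_cohort(cfg, seed=seed)
    kept, _ = filter_complete(code_records(raw))
    return kept
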
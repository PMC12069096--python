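import numpy as np
import pandas as pd
import pytest

from hgpintake.synthdata import TruthConfig, generate_all
from hgpintake.twopart import TwoPartParams

CHILD_COLS = ["const", "male", "age", "age_sp11", "male_age",
              "male_age_sp11", "end_of_week", "second_recall"]


def recovery_truth() -> TwoPartParams:
    """Child-cohort truth for parameter-recovery studies.

    Placed where the random-effect parameters are well identified:
    consumption probability around 0.55-0.6 so a large share of persons
    consume on both days (the rows separating the person-level amount
    variance from day-to-day noise), equal between/within variances, and a
    moderate frequency-amount correlation.
    """
    return TwoPartParams(
        beta_prob=pd.Series([0.2, 0.3, 0.02, -0.02, 0.0, 0.0, 0.2, -0.1],
                            index=CHILD_COLS),
        beta_amount=pd.Series([9.0, 0.6, 0.12, -0.04, 0.0, 0.0, 0.4, -0.2],
                              index=CHILD_COLS),
        var_u1=1.0, var_u2=3.0, rho=0.5, var_eps=3.0, lam=0.4,
        cohort="child",
    )


@pytest.fixture(scope="session")
def synth_data():
    """Shared mid-size synthetic data set (full age range)."""
    return generate_all(TruthConfig(n_persons=800, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
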
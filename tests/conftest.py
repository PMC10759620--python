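import numpy as np
import pytest

from opsinkit.behavior import lightdark_test
from opsinkit.synthgen.activity import ActivitySimParams, simulate_activity


@pytest.fixture(scope="session")
def null_activity_raw_pvalues():
    """Raw Wilcoxon p-values from 100 null activity simulations
    (equal light/dark activity probability, 27 days, no persistence).

    Shared between the type-I-error unit test and the acceptance
    criterion to avoid simulating twice.
    """
    pvals = []
    for seed in range(100):
        table = simulate_activity(
            ActivitySimParams(
                days=27,
                p_active_light=0.5,
                p_active_dark=0.5,
                persistence=0.0,
                seed=seed,
            )
        )
        report = lightdark_test(table)
        pvals.append(float(report["p_raw"].iloc[0]))
    return np.array(pvals)
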
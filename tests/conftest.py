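import numpy as np
import pytest

from abpsim import TreatedFlow, load_preset


@pytest.fixture(scope="session")
def lca_config():
    return load_preset("lca")


@pytest.fixture(scope="session")
def dlbcl_config():
    return load_preset("dlbcl")


def make_flow(initiated):
    """A TreatedFlow with everything in the backlog component."""
    initiated = np.asarray(initiated, dtype=float)
    return TreatedFlow(
        backlog_component=initiated, incident_component=np.zeros_like(initiated)
    )


def brute_force_abp(initiated, annuity_amount, n, horizon=None):
    """Independent per-(cohort, payment-year) ledger enumeration.

    Walks every patient cohort and every one of its n payment years
    explicitly; used as the oracle for the vectorized stream builder.
    With ``horizon`` set, payments falling at or beyond it are dropped
    (window-only accounting); otherwise the ledger runs to completion.
    """
    length = len(initiated) + n - 1 if horizon is None else horizon
    out = np.zeros(length)
    for year_treated, count in enumerate(initiated):
        for k in range(n):
            due = year_treated + k
            if due < length:
                out[due] += annuity_amount * count
    return out
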
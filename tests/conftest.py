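import numpy as np
import pytest

import procswitch as ps

#: published best-fit rate constants of the switch scheme, s^-1,
#: with k1 per RPA2 concentration (nM).
K1_BY_CONC = {0.0: 0.02, 2.0: 0.059, 5.0: 0.065, 10.0: 0.200, 50.0: 1.15}
K1_SIGMA = {0.0: 0.006, 2.0: 0.017, 5.0: 0.019, 10.0: 0.059, 50.0: 0.39}
K_MINUS1 = 0.18
K2 = 0.17
K_OFF = 0.037


@pytest.fixture(scope="session")
def table_rates():
    return {c: ps.KineticRates(k1=k1, k_minus1=K_MINUS1, k2=K2, k_off=K_OFF)
            for c, k1 in K1_BY_CONC.items()}


@pytest.fixture(scope="session")
def table_params(table_rates):
    return ps.FitParams.from_rates(table_rates)


def make_trace(y, rate=89.0, force=12.0, **meta):
    y = np.asarray(y, dtype=float)
    return ps.Trace(time=np.arange(y.size) / rate, position=y,
                    force=force, sampling_rate=rate, metadata=meta)
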
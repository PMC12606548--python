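import numpy as np
import pytest

from greatwall import DesignConfig, DoseCombo, scenario_library


class StubSource:
    """Deterministic outcome source: fixed per-dose DLT count per cohort.

    ``dlt`` maps (j, k) -> number of DLTs to produce in each cohort drawn
    there (default 0); every patient responds unless ``eff`` overrides the
    per-dose responder count; survival times are constant.
    """

    def __init__(self, J, K, dlt=None, eff=None, time=12.0):
        self.J = J
        self.K = K
        self._dlt = {DoseCombo(*d): v for d, v in (dlt or {}).items()}
        self._eff = {DoseCombo(*d): v for d, v in (eff or {}).items()}
        self._time = time

    def draw(self, dose, n, rng=None):
        n_tox = min(self._dlt.get(dose, 0), n)
        n_eff = min(self._eff.get(dose, n), n)
        y_tox = np.zeros(n, dtype=bool)
        y_tox[:n_tox] = True
        y_eff = np.zeros(n, dtype=bool)
        y_eff[:n_eff] = True
        return y_eff, y_tox, np.full(n, self._time)


@pytest.fixture
def config():
    return DesignConfig()


@pytest.fixture
def library():
    return scenario_library()


@pytest.fixture
def stub_source():
    return StubSource
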
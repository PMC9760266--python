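import warnings

import numpy as np
import pandas as pd
import pytest

from epcmir import generate_cohort, preprocess_pipeline, table2_defaults
from epcmir.cohort import CategoricalParam, ContinuousParam, ProbeSignalMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """178-patient cohort with 200 target probes and 6 planted effects."""
    spec = table2_defaults().with_(seed=11, n_target_probes=200)
    cohort, raw = generate_cohort(spec)
    return spec, cohort, raw


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    spec, cohort, raw = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report, expr = preprocess_pipeline(raw)
    return cohort, report, expr


@pytest.fixture(scope="session")
def null_spec():
    """Spec whose outcome is independent of every covariate and probe."""
    base = table2_defaults()
    params = {}
    for name, par in base.covariate_params.items():
        if isinstance(par, ContinuousParam):
            params[name] = ContinuousParam(par.mean0, par.sd0, par.mean0, par.sd0, par.floor)
        else:
            params[name] = CategoricalParam(par.categories, par.probs0, par.probs0)
    return base.with_(covariate_params=params, informative_probes=(), n_target_probes=50)


def make_signal_matrix(signals: dict, roles: dict, flags: dict | None = None) -> ProbeSignalMatrix:
    """Hand-built probe matrix for boundary-case tests.

    ``signals``: probe -> per-sample values; ``roles``: probe -> role;
    ``flags``: probe -> per-sample booleans (default all False).
    """
    sig = pd.DataFrame(signals).T
    sig.columns = [f"S{i + 1}" for i in range(sig.shape[1])]
    role = pd.Series(roles).reindex(sig.index)
    if flags is None:
        flg = pd.DataFrame(False, index=sig.index, columns=sig.columns)
    else:
        flg = pd.DataFrame(flags).T
        flg.columns = sig.columns
        flg = flg.reindex(sig.index, fill_value=False).astype(bool)
    chips = pd.Series({s: s for s in sig.columns})
    return ProbeSignalMatrix(signals=sig.astype(float), roles=role, flags=flg, chip_ids=chips)
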
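import numpy as np
import pandas as pd
import pytest

from panelgvar.panel import AGE_COL, SUBJECT_COL, WAVE_COL, PanelDataset
from panelgvar.params import GGM, PanelGVARParams
from panelgvar.synthetic import GroundTruth, simulate_panel


def make_toy_panel(n_subjects=5, waves=("2013", "2015", "2018"), items=("item1", "item2"), seed=0, ages=None):
    """Small complete integer-coded panel for io tests."""
    rng = np.random.default_rng(seed)
    subjects = [f"s{i:03d}" for i in range(n_subjects)]
    rows = []
    for s in subjects:
        for w in waves:
            rows.append({SUBJECT_COL: s, WAVE_COL: w, **{it: int(rng.integers(0, 4)) for it in items}})
    age = pd.Series(ages if ages is not None else rng.uniform(60, 80, n_subjects), index=pd.Index(subjects, name=SUBJECT_COL), name=AGE_COL)
    return PanelDataset(data=pd.DataFrame(rows), waves=list(waves), items=list(items), baseline_age=age)


def single_edge_truth(p=4, omega_edge=(0, 1), omega_value=0.4, autoreg=0.3, n_subjects=1000, seed=42, n_waves=4):
    """Continuous-mode truth with one contemporaneous edge and pure autoregressions."""
    omega_z = np.zeros((p, p))
    i, j = omega_edge
    omega_z[i, j] = omega_z[j, i] = omega_value
    params = PanelGVARParams(
        mu=np.zeros(p),
        beta=np.diag(np.full(p, autoreg)),
        contemporaneous=GGM(omega_z, np.ones(p)),
        between=GGM(np.zeros((p, p)), np.full(p, 1.2)),
    )
    return GroundTruth(params=params, thresholds=None, reverse_items=frozenset(), n_subjects=n_subjects, n_waves=n_waves, seed=seed)


@pytest.fixture(scope="session")
def single_edge_sim():
    truth = single_edge_truth()
    return truth, simulate_panel(truth)


@pytest.fixture(scope="session")
def single_edge_fit(single_edge_sim):
    from panelgvar.model import PanelGVAR

    truth, sim = single_edge_sim
    model = PanelGVAR(sim.latent, truth.params.p, truth.n_waves)
    fit = model.fit()
    fit.label = "saturated"
    return truth, model, fit
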
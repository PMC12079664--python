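import numpy as np
import pandas as pd
import pytest

from medsift import dynamics, synthetic_data as sd


@pytest.fixture(scope="session")
def reference_course() -> pd.DataFrame:
    """Sigmoidal naive-marker reference time course, 0-36 h."""
    markers = {m: lvl for m, lvl in zip(dynamics.NAIVE_MARKERS, [8, 7.5, 9, 6.5, 8.5, 7, 8.2])}
    rates = {m: r for m, r in zip(dynamics.NAIVE_MARKERS, [0.05, 0.07, 0.09, 0.11, 0.13, 0.15, 0.17])}
    return sd.simulate_reference_timecourse(markers, t_max_h=36.0, step_h=2.0, rates=rates)


@pytest.fixture(scope="session")
def small_screen() -> sd.ScreenDataset:
    """50 genes, 3 planted negative regulators, one 1% low gate."""
    truth = sd.ScreenTruth(
        n_genes=50,
        n_controls=100,
        depth=200_000,
        effect={"gene0000": -2.5, "gene0001": -2.5, "gene0002": -2.5},
        gates=((0.01, 6, "low"),),
        seed=11,
    )
    return sd.simulate_screen(truth)


@pytest.fixture(scope="session")
def bulk_attenuated(reference_course) -> sd.BulkDataset:
    """Noise-free bulk dataset: attenuation 0.5, delay +6 h, planted mTOR activity."""
    truth = sd.ExpressionTruth(
        attenuation=0.5, delay_h=6.0, noise_sd=0.0, n_replicates=3, seed=7,
        pathway_activities={"mTOR": 0.8},
    )
    sets = {
        "mTOR": [f"mtor{i:02d}" for i in range(50)],
        "Wnt": [f"wnt{i:02d}" for i in range(50)],
        "FGF": [f"fgf{i:02d}" for i in range(50)],
    }
    return sd.simulate_bulk_expression(truth, reference_course, pathway_sets=sets)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
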
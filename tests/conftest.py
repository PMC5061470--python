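import numpy as np
import pytest

from bromobind import simulate as sim


@pytest.fixture
def flat_baseline_spec():
    return {
        "well": "A1", "protein": "BRD4(1)", "compound": None, "conc_uM": 0.0,
        "tm": 50.0, "dh_unfold": 120.0,
        "native_baseline": [1000.0, 0.0], "denatured_baseline": [5000.0, 0.0],
    }


@pytest.fixture
def noiseless_melt_curve(flat_baseline_spec):
    curves, _ = sim.gen_melt_plate([flat_baseline_spec], noise_sd=0.0, seed=0)
    return curves[0]


@pytest.fixture
def brd4_titration():
    """Noiseless reverse titration at the strongest-binder preset."""
    titration, truth = sim.gen_titration(
        n_sites=0.94, kd_nM=41.8, dh_kcal=-11.09,
        syringe_conc=258.0, cell_conc=20.0, noise_sd=0.0, seed=0,
    )
    return titration, truth


def random_melt_spec(rng: np.random.Generator, well: str = "A1") -> dict:
    return {
        "well": well, "protein": "P", "compound": None, "conc_uM": 0.0,
        "tm": float(rng.uniform(42.0, 75.0)),
        "dh_unfold": float(rng.uniform(60.0, 200.0)),
        "native_baseline": [float(rng.uniform(500, 1500)), float(rng.uniform(-2, 4))],
        "denatured_baseline": [float(rng.uniform(4000, 6000)), float(rng.uniform(-8, 0))],
    }
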
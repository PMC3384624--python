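import numpy as np
import pandas as pd
import pytest

from ffmnet import panel_io
from ffmnet import synthetic_data as sd


def small_panel(n_per_class: dict[str, int] | None = None) -> panel_io.PanelDefinition:
    """Compact panel for fast tests: a p180 subset with several classes."""
    full = panel_io.load_panel_preset("p180")
    n_per_class = n_per_class or {
        "amino_acid": 21, "acylcarnitine": 12, "lysoPC": 8,
        "PC_aa": 10, "PC_ae": 10, "sphingomyelin": 7, "hexose": 1,
    }
    taken: dict[str, int] = {}
    keep = []
    for met in full.metabolites:
        quota = n_per_class.get(met.chem_class, 0)
        if taken.get(met.chem_class, 0) < quota:
            keep.append(met.name)
            taken[met.chem_class] = taken.get(met.chem_class, 0) + 1
    return full.subset(keep)


@pytest.fixture(scope="session")
def p180():
    return panel_io.load_panel_preset("p180")


@pytest.fixture(scope="session")
def small_cohort():
    """Fast default cohort: 300 subjects on a 60-metabolite panel."""
    panel = small_panel()
    cfg = sd.SimulationConfig(
        n_subjects=300, panel=panel, seed=11,
        high_cv_metabolites=(), outlier_rate=0.0, missing_rate=0.0,
    )
    return sd.generate_cohort(cfg)


@pytest.fixture()
def toy_pheno():
    rng = np.random.default_rng(5)
    n = 120
    h = rng.normal(1.7, 0.07, n)
    ffm = rng.normal(52, 6, n)
    fm = rng.normal(22, 5, n)
    return pd.DataFrame({
        "age": rng.uniform(51, 80, n),
        "sex": rng.integers(0, 2, n),
        "height_m": h,
        "ffm_kg": ffm,
        "fm_kg": fm,
        "weight_kg": ffm + fm,
        "activity": np.where(rng.random(n) < 0.4, "active", "inactive"),
        "batch": rng.integers(0, 3, n),
    }, index=pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id"))
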
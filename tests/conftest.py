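import numpy as np
import pandas as pd
import pytest

from geoseason.data_model import add_calendar_columns, label_event
from geoseason.gam import ModelConfig
from geoseason.simulate import SimConfig, simulate_gpp


@pytest.fixture(scope="session")
def small_scene():
    """Default-condition scene at reduced grid size; (table, truth)."""
    return simulate_gpp(SimConfig(nx=10, ny=10, seed=101))


@pytest.fixture(scope="session")
def fast_config():
    """Model configuration used for replicate studies: no tensor term,
    reduced spatial rank (the generated truth has no space-time
    interaction, so the dropped term is null)."""
    return ModelConfig(space_k=25, include_tensors=False)


@pytest.fixture(scope="session")
def fitted_eq2(small_scene, fast_config):
    from geoseason.gam import fit_eq2

    table, _ = small_scene
    return fit_eq2(table, fast_config)


@pytest.fixture(scope="session")
def fitted_eq1():
    from geoseason.gam import fit_eq1

    cfg = SimConfig(nx=8, ny=8, years=(2018, 2022), epochs_per_month=1,
                    trend_slope=0.1, delta=0.0, seed=55)
    table, truth = simulate_gpp(cfg)
    fit = fit_eq1(table, ModelConfig(space_k=20, include_tensors=False))
    return fit, table, truth


def random_long_table(n, seed=0, years=("2010-01-01", "2022-12-31")):
    """Unstructured noise table over random pixels/dates."""
    rs = np.random.default_rng(seed)
    dates = pd.to_datetime(rs.choice(pd.date_range(*years, freq="8D"), n))
    tab = pd.DataFrame(
        {
            "longitude": rs.uniform(30, 33, n).round(3),
            "latitude": rs.uniform(46, 49, n).round(3),
            "date": dates,
            "gpp": rs.normal(size=n),
        }
    )
    return label_event(add_calendar_columns(tab))
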
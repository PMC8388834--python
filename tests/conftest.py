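import numpy as np
import pytest

import fluogrowth as fg
from fluogrowth.platedata import ChannelDef, PlateLayout, WellSpec


@pytest.fixture
def small_layout():
    """Two sample wells (one strain, red reporter) plus two blanks."""
    return PlateLayout(
        plate_id="unit",
        wells={
            "A1": WellSpec(role="sample", strains=[("Pe_red", "red")],
                           medium="NB", condition="NB 100%", replicate_group="r1"),
            "A2": WellSpec(role="sample", strains=[("Pe_red", "red")],
                           medium="NB", condition="NB 100%", replicate_group="r2"),
            "H11": WellSpec(role="blank", medium="NB"),
            "H12": WellSpec(role="blank", medium="NB"),
        },
        channels=[
            ChannelDef(name="OD600", kind="absorbance"),
            ChannelDef(name="red", kind="fluorescence",
                       excitation_nm=(567, 587), emission_nm=(613, 626)),
        ],
    )


def make_ts(times, wells, **channels):
    return fg.PlateTimeSeries(
        times_h=np.asarray(times, float),
        wells=list(wells),
        data={k: np.asarray(v, float) for k, v in channels.items()},
    )


@pytest.fixture(scope="session")
def dilution_plate():
    """Blank-corrected metrics of the default simulated NB dilution series."""
    layout, models, noise = fg.dilution_series_design(seed=101)
    t_grid = np.arange(0.0, 20.001, 0.25)
    ts, truth, _ = fg.simulate_plate(layout, models, noise, t_grid)
    for channel in ts.channels:
        ts, _ = fg.blank_correct(ts, layout, channel)
    return fg.metrics_table(ts, layout), truth


@pytest.fixture(scope="session")
def isogenic_plate():
    """Blank-corrected metrics of the default isogenic 48-h competition."""
    layout, models, noise = fg.isogenic_competition_design(seed=202)
    t_grid = np.arange(0.0, 48.001, 0.25)
    ts, truth, _ = fg.simulate_plate(layout, models, noise, t_grid)
    for channel in ts.channels:
        ts, _ = fg.blank_correct(ts, layout, channel)
    return fg.metrics_table(ts, layout), truth
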
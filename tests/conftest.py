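import numpy as np
import pytest

import whamtherm as wt


@pytest.fixture(scope="session")
def truth() -> wt.GroundTruth:
    return wt.GroundTruth()


@pytest.fixture(scope="session")
def well_plan() -> wt.SimulationPlan:
    """Reduced layout covering the wall, well and barrier rise (0-15 Å)."""
    return wt.SimulationPlan(
        centers=tuple(np.round(np.arange(0.0, 15.01, 0.5), 6)),
        n_per_window=2000,
        seed=11,
    )


@pytest.fixture(scope="session")
def well_windows_310(well_plan, truth) -> list[wt.WindowTimeSeries]:
    return wt.simulate_windows(well_plan, truth, 313.0)


@pytest.fixture(scope="session")
def well_profile_310(well_windows_310) -> wt.PMFProfile:
    grid = wt.default_grid([w.meta for w in well_windows_310], n_bins=100)
    hists = wt.build_histograms(well_windows_310, grid)
    return wt.solve_wham(hists)


@pytest.fixture(scope="session")
def short_range_truth() -> wt.GroundTruth:
    """Ground truth with the barrier pulled in to 10 Å so a 0-12 Å window
    layout resolves the full well-to-barrier profile quickly; the post-crest
    decline is steepened so it stays resolvable over the short tail."""
    return wt.GroundTruth(shape={"barrier_position": 10.0, "plateau_slope": -0.15})


@pytest.fixture(scope="session")
def short_range_plan() -> wt.SimulationPlan:
    return wt.SimulationPlan(
        centers=tuple(np.round(np.arange(0.0, 12.01, 0.5), 6)),
        temperatures=(293.0, 313.0, 333.0),
        n_per_window=1500,
        seed=5,
    )


@pytest.fixture(scope="session")
def short_range_windows_313(short_range_plan, short_range_truth):
    """Windows whose layout resolves the full well-to-barrier profile."""
    return wt.simulate_windows(short_range_plan, short_range_truth, 313.0)
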
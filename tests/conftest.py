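import numpy as np
import pytest

from grainprices import SyntheticConfig, build_panel, calendars_from_series, simulate


def season_oracle(p, threshold, min_run_length=1, arid_cutoff=200.0, max_seasons=2):
    """Brute-force circular wet-run scanner, independent of the implementation.

    Walks every month, grows a run forward from each run start (a wet month
    whose predecessor is dry), and applies the same post rules: arid if the
    annual total is under the cutoff or no run exists; keep the wettest runs
    when more than ``max_seasons`` are found; harvest is the month after a
    run; an all-wet year has no harvest month.
    Returns (is_arid, seasons, harvest_months, year_round).
    """
    p = [float(v) for v in p]
    wet = [v >= threshold for v in p]
    if sum(p) < arid_cutoff:
        return True, (), (), False
    if all(wet):
        return False, ((1, 12),), (), True
    runs = []
    for s in range(12):
        if wet[s] and not wet[(s - 1) % 12]:
            months = [s + 1]
            k = (s + 1) % 12
            while wet[k]:
                months.append(k + 1)
                k = (k + 1) % 12
            runs.append(months)
    runs = [r for r in runs if len(r) >= min_run_length]
    if not runs:
        return True, (), (), False
    if len(runs) > max_seasons:
        totals = [sum(p[m - 1] for m in r) for r in runs]
        order = sorted(range(len(runs)), key=lambda i: (-totals[i], runs[i][0]))[:max_seasons]
        runs = [runs[i] for i in sorted(order)]
    seasons = tuple((r[0], r[-1]) for r in runs)
    harvests = tuple(r[-1] % 12 + 1 for r in runs)
    return False, seasons, harvests, False


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_markets=40, n_arid_markets=2,
                           year_start=2006, year_end=2017)


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_panel(small_data):
    return build_panel(small_data.records, small_data.deflators, impute_maize=True)


@pytest.fixture(scope="session")
def small_calendars(small_data):
    return calendars_from_series(small_data.market_rain)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
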
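import datetime as dt

import numpy as np
import pytest

import fissionfusion as ff
from fissionfusion.association import DailyAssociationSet


def make_daily(patterns, start=dt.date(2020, 1, 1)):
    """Build daily association sets from an iterable of iterables of parts."""
    return [
        DailyAssociationSet(start + dt.timedelta(days=k), [frozenset(p) for p in parts])
        for k, parts in enumerate(patterns)
    ]


@pytest.fixture(scope="session")
def toy_daily():
    """Six days over A, B, C with one discordant day (for jackknife oracles)."""
    return make_daily(
        [
            [{"A", "B"}],
            [{"A"}, {"B"}],
            [{"A", "B"}],
            [{"C"}],
            [{"A", "B", "C"}],
            [{"A"}],
        ]
    )


@pytest.fixture(scope="session")
def planted_sim():
    """Strong-contrast planted-unit simulation: 10 units x 8 members, 300 days."""
    cfg = ff.planted_units_config(seed=1, n_days=300)
    ids, truth = ff.generate_population(cfg)
    table, truth = ff.simulate_sightings(ids, truth)
    daily = ff.aggregate_daily(table)
    matrix = ff.compute_sri(daily)
    return cfg, ids, truth, table, daily, matrix


@pytest.fixture(scope="session")
def paper_like_pipeline():
    """Five-season synthetic study with the bundled defaults, fully aggregated."""
    cfg = ff.paper_like_config(seed=5)
    ids, truth = ff.generate_population(cfg)
    table, truth = ff.simulate_sightings(ids, truth)
    partition = ff.synthetic.season_partition_of(cfg)
    tables = partition.split(table)
    daily = {lab: ff.aggregate_daily(tables[lab]) for lab in cfg.season_labels}
    mats = {lab: ff.compute_sri(daily[lab]) for lab in cfg.season_labels}
    residents, core = ff.select_cohort(
        [tables[lab] for lab in cfg.season_labels],
        [daily[lab] for lab in cfg.season_labels],
        ff.CohortSpec(min_total_sightings=30, top_n=5),
        season_labels=list(cfg.season_labels),
    )
    return {
        "cfg": cfg,
        "truth": truth,
        "table": table,
        "tables": tables,
        "daily": daily,
        "mats": mats,
        "residents": residents,
        "core": core,
    }
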
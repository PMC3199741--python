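#!/usr/bin/env python
"""Companion fidelity: slot allocation, turnover, and the degree-strength
trade-off.

Ranks each core individual's top-5 associates per season, tallies how many
seasons each associate stays in the top-5 (the companion-slot distribution
F(m), compared against the random-reshuffling null), counts companions
retained across all five seasons, and fits the trade-off between the number
of associates and mean tie strength.
"""

import json
import pathlib

import pandas as pd

import fissionfusion as ff
from _study import load_study

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
TOP_N = 5


def main() -> None:
    study = load_study()
    cfg = study["cfg"]
    OUT.mkdir(exist_ok=True)
    seasons = list(cfg.season_labels)
    core = sorted(study["core"])
    mats = [study["mats"][lab] for lab in seasons]
    counts = study["table"].sighting_counts()

    topn = ff.per_season_top_n(mats, core, n=TOP_N, sighting_counts=counts)
    alloc = ff.slot_allocation(topn)
    F_obs = alloc.population_mean_f()
    F_null = ff.null_slot_allocation(len(core), TOP_N, len(seasons), mode="analytic")
    df = pd.DataFrame(
        {
            "m": list(range(1, len(seasons) + 1)),
            "observed_F_pct": [round(100 * F_obs[m], 1) for m in range(1, 6)],
            "null_F_pct": [round(100 * F_null[m], 4) for m in range(1, 6)],
        }
    )
    df.to_csv(OUT / "companion_slots.csv", index=False)
    print("companion-slot allocation F(m), observed vs random-reshuffle null (%):")
    print(df.to_string(index=False))

    turn = ff.companion_turnover(topn)
    hist = turn.histogram()
    tdf = pd.DataFrame(
        {"retained": list(hist), "pct_individuals": [round(100 * v, 1) for v in hist.values()]}
    )
    tdf.to_csv(OUT / "companion_turnover.csv", index=False)
    print("\ncompanions retained in the top-5 across all seasons (% of individuals):")
    print(tdf.to_string(index=False))

    trade = ff.gregariousness_tradeoff(mats, core)
    out = {
        "slope": round(trade["slope"], 4),
        "r_squared": round(trade["r_squared"], 3),
        "p_value": trade["p_value"],
        "n_individuals": len(trade["points"]),
    }
    (OUT / "gregariousness_tradeoff.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"\ndegree vs mean tie strength: slope {out['slope']}, "
          f"R^2 {out['r_squared']}, p {out['p_value']:.2g} "
          f"({'negative trade-off' if out['slope'] < 0 else 'no trade-off'})")
    print(f"wrote {OUT / 'companion_slots.csv'}, companion_turnover.csv, "
          "gregariousness_tradeoff.json")


if __name__ == "__main__":
    main()
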
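#!/usr/bin/env python
"""Generate the synthetic dataset the downstream analyses consume.

Writes a conditioning session (trial table, events, task-responsive
units), a firing-pattern panel (bursting / Poisson-like / regular
units), a two-channel photometry session, a lag-coupled region pair and
a pupil trace — all with their ground truth — under results/simulated/.
"""

import json
from pathlib import Path

import numpy as np

from cholinepipe import io
from cholinepipe import synthetic as syn

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    trials, events, trains, task_truth = syn.gen_task_session(
        n_trials=100,
        response_spec={
            "unit_reward_act": {"event": "reward", "latency": 0.02, "duration": 0.2, "gain": 4.0},
            "unit_punish_act": {"event": "punishment", "latency": 0.02, "duration": 0.2, "gain": 4.0},
            "unit_punish_inh": {"event": "punishment", "latency": 0.02, "duration": 0.3, "gain": 0.1},
        },
        seed=SEED,
    )
    io.write_trials(trials, OUT / "trials.tsv")
    io.write_spike_trains(list(trains.values()), OUT / "task_units.csv")

    panel = []
    for k in range(8):
        tr, _ = syn.gen_bursting_train(duration=600.0, seed=100 + k, unit_id=f"burst{k}")
        panel.append(tr)
    for k in range(8):
        tr, _ = syn.gen_poisson_train(8.0, 600.0, seed=200 + k, unit_id=f"poisson{k}")
        panel.append(tr)
    for k in range(4):
        tr, _ = syn.gen_regular_theta_train(duration=900.0, seed=300 + k, unit_id=f"regular{k}")
        panel.append(tr)
    io.write_spike_trains(panel, OUT / "pattern_panel.csv")

    session, phot_truth = syn.gen_photometry(duration=300.0, seed=SEED)
    io.write_photometry(session, OUT / "photometry.csv")

    x, y, pair_truth = syn.gen_coupled_pair(duration=120.0, lag=0.8, noise_sd=0.2, seed=SEED)
    np.savetxt(OUT / "region_pair.csv", np.column_stack([x.t, x.dff, y.dff]),
               delimiter=",", header="time,region_a,region_b", comments="")
    pupil, pupil_truth = syn.gen_pupil_coupled(x, pupil_lag=0.7, seed=SEED)
    np.savetxt(OUT / "pupil.csv", np.column_stack([x.t, pupil]),
               delimiter=",", header="time,diameter", comments="")

    truth = {
        "seed": SEED,
        "task": {k: v for k, v in task_truth.params.items() if k != "response_spec"},
        "photometry_transients": len(phot_truth.params["transient_times"]),
        "pair_lag_s": pair_truth.params["lag"],
        "pupil_lag_s": pupil_truth.params["pupil_lag"],
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))
    print(f"Simulated dataset written to {OUT}")
    print(f"  {trials.n_trials} trials, {len(trains)} task units, {len(panel)} panel units")
    print(f"  photometry: {len(session.t)} samples at {session.fs:.0f} Hz, "
          f"{len(phot_truth.params['transient_times'])} transients")
    print(f"  coupled pair lag {pair_truth.params['lag']:.2f} s, pupil lag "
          f"{pupil_truth.params['pupil_lag']:.2f} s")


if __name__ == "__main__":
    main()
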
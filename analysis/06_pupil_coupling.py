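#!/usr/bin/env python
"""Pupil-calcium coupling: diameter geometry, calcium-peak-triggered
pupil averaging, and directed transfer entropy."""

from pathlib import Path

import numpy as np
import pandas as pd

from cholinepipe import coupling as cp
from cholinepipe import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    x, _, _ = syn.gen_coupled_pair(duration=600.0, lag=0.0, noise_sd=0.0, seed=1)
    pupil_trace, truth = syn.gen_pupil_coupled(
        x, pupil_lag=0.7, smoothing_tau=0.2, noise_sd=0.05, seed=1
    )

    # run the trace through the landmark geometry and back
    lm, _ = syn.gen_pupil_landmarks(x.t, 20.0 + pupil_trace, seed=1)
    _, diameter = cp.pupil_diameter(lm, target_t=x.t)

    pta = cp.peak_triggered_average(x, diameter, threshold_sd=1.5)
    lag_at_max = pta["lags"][np.argmax(pta["average"])]

    # 200-bin discretization reproduces the procedure but its plug-in
    # estimate is bias-dominated at this sample size (descriptive only).
    # The directional comparison needs the discretized series to resolve
    # the ~0.7 s coupling lag: downsample to 2 Hz so two history samples
    # span the lag, and use a coarse 4-bin discretization for sample
    # efficiency.
    te200 = cp.transfer_entropy(x.dff, diameter, n_bins=200, fs=x.fs, downsample_to=20.0)
    te = cp.transfer_entropy(
        x.dff, diameter, n_bins=4, history_len=2, fs=x.fs, downsample_to=2.0
    )

    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    pd.DataFrame({"lag_s": pta["lags"], "pupil_mean": pta["average"]}).to_csv(
        out_dir / "pupil_triggered_average.csv", index=False
    )
    summary = pd.DataFrame([{
        "n_calcium_peaks": pta["n_peaks"],
        "pupil_lag_at_max_s": round(lag_at_max, 3),
        "true_pupil_lag_s": truth.params["pupil_lag"],
        "te_calcium_to_pupil_bits": round(te.te_xy, 4),
        "te_pupil_to_calcium_bits": round(te.te_yx, 4),
        "te200_calcium_to_pupil_bits": round(te200.te_xy, 4),
        "te200_pupil_to_calcium_bits": round(te200.te_yx, 4),
    }])
    summary.to_csv(out_dir / "pupil_coupling.csv", index=False)
    print(summary.to_string(index=False))
    direction = "calcium -> pupil" if te.te_xy > te.te_yx else "pupil -> calcium"
    consistent = "consistent with" if te.te_xy > te.te_yx else "contradicting"
    print(f"\nTriggered pupil dilation peaks {lag_at_max:.2f} s after calcium transients "
          f"(imposed lag {truth.params['pupil_lag']:.2f} s).")
    print(f"Transfer entropy (4 bins, 2-sample history at 2 Hz) favors {direction}, "
          f"{consistent} the construction; the 200-bin values are bias-dominated at "
          f"this n and reported for completeness.")
    print(f"Wrote {out_dir / 'pupil_coupling.csv'}")


if __name__ == "__main__":
    main()
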
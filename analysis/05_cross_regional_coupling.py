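#!/usr/bin/env python
"""Cross-regional coupling: normalized cross-correlation of the
simulated region pair and its lag recovery across sessions."""

from pathlib import Path

import numpy as np
import pandas as pd

from cholinepipe import coupling as cp
from cholinepipe import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ccrs = []
    true_lags = []
    for seed in range(10):
        x, y, truth = syn.gen_coupled_pair(duration=120.0, lag=0.8, noise_sd=0.3, seed=seed)
        ccrs.append(cp.normalized_xcorr(x, y, max_lag=10.0))
        true_lags.append(truth.params["lag"])
    avg, table = cp.average_ccr(ccrs)

    per_session = pd.DataFrame(table)
    per_session["true_lag_s"] = true_lags
    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    per_session.to_csv(out_dir / "ccr_sessions.csv", index=False)
    pd.DataFrame({"lag_s": avg.lags, "ccr": avg.values, "excluded": avg.excluded_mask}).to_csv(
        out_dir / "ccr_average.csv", index=False
    )

    print(per_session.to_string(index=False))
    print(f"\nSession-average CCR peaks at {avg.peak_lag:+.3f} s "
          f"(value {avg.peak_value:.3f}); imposed lag was +0.800 s.")
    print(f"Mean per-session peak lag: {per_session['peak_lag'].mean():+.3f} s")
    print(f"Wrote {out_dir / 'ccr_sessions.csv'} and {out_dir / 'ccr_average.csv'}")


if __name__ == "__main__":
    main()
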
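"""Autocorrelation timescales and power spectra of shape and speed dynamics.

Detrends each cell's PC1-3 and speed series (0.0025 Hz high-pass), fits an
exponential decay to the peaks of the (oscillating) autocorrelation to get
tau_ACF, and locates the dominant spectral band.  Channels failing the SNR
gate (signal sd / propagated PC uncertainty < 2.5, or a near-stationary
uropod for speed) are excluded.  Also demonstrates the estimator on
dedicated long oscillatory fixtures (tau 225 s / period 100 s).

Outputs: results/timeseries_stats.csv, results/tau_recovery.csv
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from morphocell.config import RunConfig
from morphocell.pipeline import run_pipeline
from morphocell.synthetic import default_cohort, make_oscillatory_signal
from morphocell.tsstats import acf_tau, detrend

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results")
OUT.mkdir(exist_ok=True)


def main():
    cfg = RunConfig(seed=SEED)
    cohort = default_cohort(seed=SEED)
    res = run_pipeline(cohort, cfg)
    stats = res["stats_table"]
    stats.to_csv(OUT / "timeseries_stats.csv", index=False)
    print(stats[["dataset_id", "channel", "tau_acf_s", "peak_freq_hz", "fallback"]]
          .round(4).to_string(index=False))
    for ch in ("PC1", "speed"):
        sub = stats[stats.channel == ch]
        if len(sub):
            print(f"{ch}: median tau_ACF {sub.tau_acf_s.median():.0f} s, "
                  f"median spectral peak {sub.peak_freq_hz.median():.4f} Hz")

    # controlled recovery check on long damped-cosine fixtures
    rows = []
    for s in range(20):
        x = make_oscillatory_signal(225.0, 100.0, 6000, 5.0, noise_sd=0.05, seed=SEED * 7919 + s)
        fit = acf_tau(detrend(x, 5.0), 5.0)
        rows.append({"seed": s, "tau_hat_s": fit.tau, "rel_error": abs(fit.tau - 225) / 225})
    rec = pd.DataFrame(rows)
    rec.to_csv(OUT / "tau_recovery.csv", index=False)
    print(f"tau_ACF recovery on 20 fixtures (truth 225 s): median estimate "
          f"{rec.tau_hat_s.median():.0f} s, median relative error {rec.rel_error.median():.1%}")


if __name__ == "__main__":
    main()
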
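"""Fit and interrogate the SR response-surface model.

Fits SR ~ N_E + pitch + width + exp(1/v) + SNR to the simulated sweep,
reports standardized half effects with 95% CIs and type-II significance,
and maps the SR >= 0.8 "safe" region over SNR x velocity x channel
length, including the coherent averaging needed below it.

Writes results/sr_model.json, results/sr_half_effects.csv and
results/sr_safe_region.csv.  Requires 02_sr_sweep.py to have run.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nervechip.sr_model import (
    fit_sr_model,
    predict_sr,
    safe_region,
    standardized_half_effects,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    dataset = pd.read_csv(OUT / "sr_dataset.csv")
    model = fit_sr_model(dataset)
    (OUT / "sr_model.json").write_text(model.to_json() + "\n")
    print(f"fit on {model.n_obs} conditions, R^2 = {model.r_squared:.3f}")

    effects = standardized_half_effects(model)
    pd.DataFrame(
        [
            {
                "term": h.term,
                "half_effect": h.half_effect,
                "ci_low": h.ci_low,
                "ci_high": h.ci_high,
                "p_value": h.p_value,
                "significant": h.significant,
            }
            for h in effects
        ]
    ).to_csv(OUT / "sr_half_effects.csv", index=False)
    print("standardized half effects (SR units):")
    for h in sorted(effects, key=lambda h: -abs(h.half_effect)):
        star = "*" if h.significant else " "
        print(f"  {h.term:>18s} {h.half_effect:+.3f} "
              f"[{h.ci_low:+.3f}, {h.ci_high:+.3f}] {star}")

    region = safe_region(
        model,
        snr_values=list(np.arange(0.0, 41.0, 2.0)),
        velocities=list(np.arange(5.0, 61.0, 5.0)),
        channel_lengths=[4.0, 5.0, 6.0, 10.0],
        width=0.1,
        n_electrodes=8,
        pitch=1.0,
    )
    region.to_csv(OUT / "sr_safe_region.csv", index=False)
    frac_safe = region.groupby("channel_length")["safe"].mean()
    print("fraction of the grid in the safe region by channel length:")
    print(frac_safe.to_string())
    at35 = region[(region.velocity == 35.0) & (region.channel_length == 4.0)]
    unsafe = at35[~at35["safe"]]
    if len(unsafe):
        worst = unsafe.sort_values("snr_db").iloc[0]
        print(
            f"at 35 m/s in a 4 mm channel, the lowest-SNR grid point "
            f"({worst.snr_db:.0f} dB) needs {worst.n_averages:.0f} averages "
            f"to reach SR >= 0.8"
        )


if __name__ == "__main__":
    main()
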
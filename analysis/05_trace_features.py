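#!/usr/bin/env python
"""Extract features from the synthetic sensor traces and audio envelopes.

Closes the loop on stage 01: reads each generated trace, recovers baseline,
response magnitude and per-cycle amplitude, compares with the generator's
ground truth, and estimates sniff rates from the noisy audio envelopes.
Writes results/traces/features.csv.
"""

import json
from pathlib import Path

import pandas as pd

from sniffmodel.trace import (extract_features, read_trace_csv,
                              sniff_frequency_from_envelope)

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "traces"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in sorted(SYN.glob("trace_*Hz.csv")):
        truth = json.loads((SYN / f"{path.name}.truth.json").read_text())
        trace = read_trace_csv(path)
        feats = extract_features(trace, truth["sniff_frequency"])
        err = abs(feats.mean_amplitude - truth["cycle_amplitude"]) / \
            truth["cycle_amplitude"]
        rows.append({
            "trace": path.name,
            "freq_hz": truth["sniff_frequency"],
            "baseline_mA": feats.baseline,
            "response_mA": feats.response_magnitude,
            "amplitude_mA": feats.mean_amplitude,
            "true_amplitude_mA": truth["cycle_amplitude"],
            "amplitude_rel_err": err,
            "onset_s": feats.onset_time,
            "above_noise": feats.above_noise,
        })
        print(f"{path.name}: A = {feats.mean_amplitude:.3f} mA "
              f"(truth {truth['cycle_amplitude']}, err {100 * err:.1f}%), "
              f"response {feats.response_magnitude:.1f} mA")
    pd.DataFrame(rows).to_csv(OUT / "features.csv", index=False)

    for path in sorted(SYN.glob("envelope_*Hz.csv")):
        df = pd.read_csv(path)
        rate = 1.0 / (df["time_s"].iloc[1] - df["time_s"].iloc[0])
        est = sniff_frequency_from_envelope(df["envelope"].to_numpy(), rate)
        print(f"{path.name}: estimated sniff rate {est:.1f} Hz")


if __name__ == "__main__":
    main()
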
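#!/usr/bin/env python
"""Generate the synthetic inputs every later stage consumes.

Writes, under results/synthetic/:
  * animals.csv          -- 16 mammals drawn from f = 8 M^-0.18 Hz with
                            log-normal scatter (emulating the observed
                            mass--frequency table's structure);
  * trace_<f>Hz.csv      -- sensor-current traces at the device's four
                            sniffing frequencies, with ground truth;
  * envelope_<r>Hz.csv   -- audio-envelope pulse trains at rat (8 Hz) and
                            elephant/giraffe (2 Hz) sniff rates.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sniffmodel.allometry import write_animal_table
from sniffmodel.synthetic import (AllometryGenSpec, EnvelopeGenSpec,
                                  TraceGenSpec, gen_allometry, gen_envelope,
                                  gen_sensor_trace)
from sniffmodel.trace import write_trace_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260922

# generated cycle amplitudes decline with sniff frequency, as the deposition
# model predicts for the device's frequency ladder
TRACE_LADDER = [(0.14, 0.5), (0.2, 0.4), (0.25, 0.3), (0.3, 0.25)]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    records, truth = gen_allometry(AllometryGenSpec(seed=SEED))
    write_animal_table(records, OUT / "animals.csv")
    (OUT / "animals.truth.json").write_text(json.dumps(truth, indent=2,
                                                       default=list))
    masses = [r.mass for r in records]
    print(f"animals.csv: {len(records)} animals, "
          f"{min(masses):.3g}-{max(masses):.4g} kg, "
          f"truth f = {truth['true_prefactor']} M^{truth['true_exponent']}")

    for i, (freq, amp) in enumerate(TRACE_LADDER):
        spec = TraceGenSpec(sniff_frequency=freq, cycle_amplitude=amp,
                            noise_sd=0.03, seed=SEED + i)
        trace, truth = gen_sensor_trace(spec)
        name = f"trace_{freq}Hz.csv"
        write_trace_csv(trace, OUT / name)
        (OUT / f"{name}.truth.json").write_text(
            json.dumps(truth, indent=2, default=list))
        print(f"{name}: {len(trace.times)} samples, baseline "
              f"{spec.baseline} mA, ripple {amp} mA")

    for rate in (2.0, 8.0):
        env, truth = gen_envelope(EnvelopeGenSpec(pulse_rate=rate, snr=3.0,
                                                  seed=SEED))
        t = np.arange(len(env)) / truth["sample_rate"]
        name = f"envelope_{rate:g}Hz.csv"
        pd.DataFrame({"time_s": t, "envelope": env}).to_csv(OUT / name,
                                                            index=False)
        print(f"{name}: {len(env)} samples at SNR 3")


if __name__ == "__main__":
    main()
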
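#!/usr/bin/env python
"""Run the odor-deposition trade-off sweep for the bench device.

Sweeps sniffing frequency for the three ethanol concentrations (8.9, 44.5
and 89 parts per thousand), with the sensor gain beta calibrated so the
lowest concentration meets the 0.03 mA noise floor at 0.3 Hz.  Writes
amplitude-vs-Wo*C curves, per-sniff and per-second molecule counts, regime
classifications and the optimal frequency per concentration to
results/tradeoff/.
"""

from pathlib import Path

from sniffmodel.pipeline import RunConfig, reproduce_tradeoff

OUT = Path(__file__).resolve().parents[1] / "results" / "tradeoff"


def main() -> None:
    report = reproduce_tradeoff(RunConfig(), OUT)
    print(f"calibrated beta = {report['beta_mA_per_molecule']:.3e} "
          f"mA/molecule; noise floor {report['noise_floor_mA']} mA, "
          f"slow-sniff limit Wo*C = {report['slow_sniff_woc']}")
    for conc, opt in report["optima"].items():
        if opt["feasible"]:
            print(f"  {conc}: fastest feasible sniff "
                  f"{opt['optimal_frequency_hz']:.2f} Hz "
                  f"(Wo = {opt['optimal_womersley']:.2f})")
        else:
            print(f"  {conc}: no feasible frequency on the grid")
    print(f"curves written to {OUT / 'tradeoff_curves.csv'}")


if __name__ == "__main__":
    main()
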
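#!/usr/bin/env python
"""Fit the sniff-frequency scaling law and tabulate the mechanistic models.

Reads results/synthetic/animals.csv (run 01_simulate_data.py first; a real
animal table with the same columns works identically), fits
f = a M^b by OLS in log-log space, and writes the empirical curve together
with the four mechanistic predictions (inertial f1, resonant f2, laminar
ceiling f3, infinite-tube f4) and the relaxed-breathing line to
results/scaling/.
"""

from pathlib import Path

from sniffmodel.pipeline import RunConfig, reproduce_scaling

ROOT = Path(__file__).resolve().parents[1]
ANIMALS = ROOT / "results" / "synthetic" / "animals.csv"
OUT = ROOT / "results" / "scaling"


def main() -> None:
    report = reproduce_scaling(RunConfig(), ANIMALS, OUT)
    emp = report["empirical"]
    print(f"empirical fit over {report['n_animals']} animals: "
          f"f = {emp['prefactor_hz']:.2f} M^{emp['exponent']:.3f} Hz "
          f"(R^2 = {emp['r_squared']:.2f}, "
          f"exponent SE {emp['exponent_se']:.3f})")
    for name, m in report["models"].items():
        print(f"  {name:18s} {m['value_at_1kg_hz']:8.2f} Hz at 1 kg, "
              f"slope {m['exponent']}")
    print(f"curves written to {OUT / 'scaling_curves.csv'}")


if __name__ == "__main__":
    main()
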
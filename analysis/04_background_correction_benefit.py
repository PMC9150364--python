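"""Quantify how much the background correction de-biases the score at f = 0.

With zero planted co-positioning, any apparent correlation is an artifact.
This script compares the naive whole-stack Pearson against the pipeline
score across 10 replicate stacks with the membrane layer on, and repeats
the comparison with the layer dark as a control.  Writes
results/background_benefit.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

import stedcoloc as sc

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 7


def main() -> None:
    rows = []
    for label, mean in [("membrane_on", 150.0), ("membrane_off", 0.0)]:
        params = dataclasses.replace(sc.SimulationParams(), membrane_mean=mean)
        table = sc.run_recovery_experiment([0.0], 10, params, seed=SEED)
        rows.append(
            {
                "condition": label,
                "abs_mean_naive_pc": abs(table["naive_pc"].mean()),
                "abs_mean_pipeline_pc": abs(table["pipeline_pc"].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out.round(4).to_csv(OUT / "background_benefit.csv", index=False)
    print(out.round(4).to_string(index=False))

    on = out[out["condition"] == "membrane_on"].iloc[0]
    print(
        f"\nWith the membrane layer on and no true colocalization, the naive "
        f"score reports |PC| = {on['abs_mean_naive_pc']:.3f} while the pipeline "
        f"reports |PC| = {on['abs_mean_pipeline_pc']:.3f}: the median filter + "
        "xz-slice top-hat removes essentially all of the autofluorescence-"
        "induced correlation bias."
    )


if __name__ == "__main__":
    main()
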
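"""Run the full per-cell scoring pipeline on the example stack.

Reads results/example_stack.ome.tiff (written by 01_simulate_example_stack.py;
regenerated here if missing), scores it with the standard pipeline —
3×3×3 median filter, per-xz-slice top-hat with a radius-5 disk, 400 nm
y-sections, per-section MIP Pearson, per-cell mean — and writes the
per-cell and per-slab reports to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import stedcoloc as sc

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    stack_path = OUT / "example_stack.ome.tiff"
    if stack_path.exists():
        stack = sc.read_stack(stack_path)
    else:
        stack, _ = sc.simulate_stack(sc.SimulationParams(coloc_fraction=0.5, seed=1))

    roi = sc.CellROI(np.ones(stack.shape, dtype=bool), cell_id="cell1")
    result = sc.cell_coloc_score(stack, roi, sc.PreprocessParams(), slab_nm=400.0)
    sc.write_report([result], OUT / "example_scores.csv")

    naive = sc.global_pearson(stack)
    print(pd.read_csv(OUT / "example_scores.csv").to_string(index=False))
    print(
        f"\nPipeline mean PC = {result.mean_pc:.3f} over {len(result.slab_pcs)} "
        f"400-nm sections ({result.excluded_slabs} excluded); naive whole-stack "
        f"PC = {naive:.3f}. The pipeline score tracks the planted pairing "
        "fraction, while the naive score is biased upward by the shared "
        "membrane autofluorescence."
    )


if __name__ == "__main__":
    main()
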
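"""Labyrinth indices and their PCA, with the damaged-specimen variant.

Computes the two angles, TLI and the six canal/cochlea ratio indices per
specimen, runs the standardized index PCA, and repeats it the way an
incomplete labyrinth (missing anterior canal) forces: masking the
ANL-dependent columns so that specimen can re-enter the analysis.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cochleashape.labyrinth import (
    INDEX_COLUMNS, LabyrinthMeasurements, compute_indices, index_pca,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)

    meas = LabyrinthMeasurements(
        table=pd.read_csv(out / "measurements.csv").set_index("specimen_id"))
    idx = compute_indices(meas)
    idx.to_csv(out / "indices.csv")

    scores, loadings, fractions = index_pca(idx)
    scores.to_csv(out / "index_pca_scores.csv")
    loadings.to_csv(out / "index_pca_loadings.csv")
    ranked = loadings["PC1"].abs().sort_values(ascending=False)
    print(f"index PCA: PC1 {100 * fractions[0]:.1f}%, "
          f"PC2 {100 * fractions[1]:.1f}% of variance")
    print("strongest PC1 contributors:", ", ".join(ranked.index[:5]))

    # variant: one specimen loses its anterior canal -> drop ANL columns
    damaged = idx.index[-1]
    idx_damaged = idx.copy()
    for col in ("HZL/ANL", "POL/ANL", "ECL/ANL"):
        idx_damaged.loc[damaged, col] = np.nan
    keep = [c for c in INDEX_COLUMNS if "ANL" not in c]
    scores_v, loadings_v, fractions_v = index_pca(idx_damaged, columns=keep)
    scores_v.to_csv(out / "index_pca_scores_no_anl.csv")
    assert damaged in scores_v.index
    print(f"ANL-free variant keeps all {len(scores_v)} specimens "
          f"(PC1 {100 * fractions_v[0]:.1f}%)")


if __name__ == "__main__":
    main()
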
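"""Selection vs drift from the between/within covariance structure.

Pools within-taxon covariance (W), forms the covariance of taxon means (B),
decomposes B relative to W, tests proportionality by the ML log-eigenvalue
dispersion statistic, ordinates all taxon covariance matrices together with
W and B, and compares the relative eigenvalues with F_ST drift expectations.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cochleashape import covariance as cov


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--n-pcs", type=int, default=3)
    args = ap.parse_args()
    out = Path(args.out_dir)

    scores = pd.read_csv(out / "tpca_scores.csv")
    meta = pd.read_csv(out / "metadata.csv").set_index("specimen_id")
    labels = np.asarray(
        [meta.loc[s, "taxon"] for s in scores["specimen_id"]], dtype=object)
    known = labels != "unknown"
    X = scores.filter(like="PC").to_numpy()[:, : args.n_pcs]

    comp = cov.compare_taxon_covariances(X[known], labels[known])
    lam = comp.relative_eigenvalues
    print("relative eigenvalues of B with respect to W:",
          np.round(lam, 2).tolist())
    print(f"leading ratio lambda1/lambda2 = {lam[0] / lam[1]:.2f}")

    n_within = sum(comp.n_g.values()) - len(comp.n_g)
    T, df, p = cov.proportionality_test_ml(comp.B, comp.W,
                                           n1=len(comp.n_g) - 1, n2=n_within)
    verdict = "deviates from proportionality (selection)" if p < 0.05 \
        else "compatible with proportional divergence (drift)"
    print(f"ML proportionality test: T = {T:.2f}, df = {df}, p = {p:.4g} "
          f"-> {verdict}")

    ordn = cov.covariance_ordination({**comp.S_g, "W": comp.W, "B": comp.B})
    ordn.to_csv(out / "covariance_ordination.csv")
    b_rank = np.argsort(-np.abs(ordn["PCo1"]))
    print(f"ordination: B at PCo1 = {ordn.loc['B', 'PCo1']:.2f} "
          f"(taxa and W span {ordn.drop('B')['PCo1'].min():.2f}"
          f"..{ordn.drop('B')['PCo1'].max():.2f})")

    drift = cov.drift_comparison(lam)
    drift.to_csv(out / "drift_comparison.csv", index=False)
    n_exceed = int(drift["exceeds_drift"].sum())
    print(f"{n_exceed} of {len(lam)} relative eigenvalues exceed the "
          f"between-species F_ST drift band")

    with open(out / "covariance_selection.json", "w") as fh:
        json.dump({
            "relative_eigenvalues": [float(v) for v in lam],
            "lambda1_over_lambda2": float(lam[0] / lam[1]),
            "proportionality_statistic": float(T),
            "proportionality_df": int(df),
            "proportionality_p": float(p),
            "n_exceeding_drift": n_exceed,
        }, fh, indent=2)


if __name__ == "__main__":
    main()
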
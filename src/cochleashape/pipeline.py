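"""End-to-end orchestration of the synthetic-study analysis.

``run_pipeline`` chains the stages — generate (or load) curves, Fréchet mean
and tangent PCA, Frenet profiles per taxon, classification/clustering,
covariance comparison, measurement-error statistics and the OU scenario fit
— persisting every stage's outputs under one directory and returning the
headline numbers as a dict.  Deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariance as cov
from . import elastic, frenet, labyrinth, ou, taxa
from .curves import read_curves_csv, write_curves_csv
from .simulate import StudyConfig, default_study_config, generate_study

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level knobs: root seed, PC count, output directory, stage params."""

    seed: int = 0
    n_pcs: int = 3
    n_points: int = 200
    out_dir: str = "results/pipeline"
    n_perm: int = 1000
    cluster_candidates: tuple = (2, 3, 4, 5, 6, 7)
    ou_n_iter: int = 50_000
    run_ou: bool = True
    run_frenet: bool = True

    _KNOWN = None  # populated after class creation

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: PipelineConfig | None = None,
                 study: StudyConfig | None = None) -> dict:
    """Run the full analysis on a (synthetic) study; returns headline numbers.

    Every stage writes its tables under ``config.out_dir``; a resolved copy
    of the configuration is stored alongside them.
    """
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({k: v for k, v in asdict(cfg).items()
                        if not k.startswith("_")}, fh)

    logger.info("stage simulate: seed=%d", cfg.seed)
    bundle = generate_study(study, seed=cfg.seed)
    write_curves_csv(bundle.curves, out / "curves.csv")
    bundle.metadata.to_csv(out / "metadata.csv", index=False)
    bundle.measurements.to_csv(out / "measurements.csv")

    logger.info("stage elastic: Fréchet mean + tangent PCA over %d curves",
                len(bundle.curves))
    mean, info = elastic.frechet_mean(bundle.curves, n_points=cfg.n_points,
                                      return_info=True)
    tp = elastic.tangent_pca(bundle.curves, mean=mean, n_points=cfg.n_points)
    scores = pd.DataFrame(
        tp.scores[:, : max(cfg.n_pcs, 3)],
        columns=[f"PC{i+1}" for i in range(max(cfg.n_pcs, 3))],
    )
    scores.insert(0, "specimen_id", tp.specimen_ids)
    scores.to_csv(out / "tpca_scores.csv", index=False)
    write_curves_csv([mean.with_points(mean.points)], out / "mean_curve.csv")

    results = {
        "n_specimens": len(bundle.curves),
        "frechet_iterations": info["n_iter"],
        "tpca_variance_fractions": [float(v) for v in
                                    tp.variance_fractions[:5]],
        "tpca_first3_variance": float(tp.variance_fractions[:3].sum()),
    }

    if cfg.run_frenet:
        logger.info("stage frenet: per-taxon mean profiles")
        taxon_order = list(dict.fromkeys(bundle.labels))
        for taxon in taxon_order:
            group = [c for c, lab in zip(bundle.curves, bundle.labels)
                     if lab == taxon]
            if len(group) < 2:
                continue
            prof = frenet.profile_of_mean(group, n_points=cfg.n_points)
            frenet.export_profile(prof, out / f"frenet_{taxon}.csv")

    logger.info("stage classify/cluster")
    ls = taxa.LabeledScores(tp.specimen_ids, tp.scores, bundle.labels)
    preds, bacc = taxa.knn_balanced_accuracy(ls, n_pcs=cfg.n_pcs)
    preds.to_csv(out / "knn_predictions.csv", index=False)
    best_k, cluster_report = taxa.select_cluster_count(
        ls, cfg.cluster_candidates, seed=cfg.seed, n_pcs=cfg.n_pcs)
    cluster_report.to_csv(out / "cluster_selection.csv", index=False)
    labels3 = taxa.cluster_scores(ls, 3, seed=cfg.seed, n_pcs=cfg.n_pcs)
    _, _, v3 = taxa.v_measure(
        np.asarray(bundle.labels, object)[ls.known_mask],
        labels3[ls.known_mask])
    pr_mask = np.asarray(
        [lab == "Paranthropus_robustus" for lab in bundle.labels])
    pr_isolated = bool(pr_mask.any()) and len(set(labels3[pr_mask])) == 1 \
        and not np.any(np.isin(labels3[~pr_mask], labels3[pr_mask]))
    results.update({
        "knn_balanced_accuracy": float(bacc),
        "best_cluster_count": int(best_k),
        "v_measure_3_clusters": float(v3),
        "paranthropus_isolated_at_3": pr_isolated,
    })

    logger.info("stage covariance comparison")
    known = ls.known_mask
    comp = cov.compare_taxon_covariances(
        tp.scores[known, : cfg.n_pcs],
        np.asarray(bundle.labels, object)[known])
    n_within = sum(comp.n_g.values()) - len(comp.n_g)
    T, dfree, pval = cov.proportionality_test_ml(
        comp.B, comp.W, n1=len(comp.n_g) - 1, n2=n_within)
    ordn = cov.covariance_ordination(
        {**comp.S_g, "W": comp.W, "B": comp.B}
        if _all_spd(comp) else {"W": comp.W, "B": comp.B})
    ordn.to_csv(out / "covariance_ordination.csv")
    drift = cov.drift_comparison(comp.relative_eigenvalues)
    drift.to_csv(out / "drift_comparison.csv", index=False)
    results.update({
        "relative_eigenvalues": [float(v) for v in comp.relative_eigenvalues],
        "proportionality_statistic": float(T),
        "proportionality_p": float(pval),
        "n_eigenvalues_exceeding_drift": int(drift["exceeds_drift"].sum()),
    })

    logger.info("stage measurement error")
    icc_vals = _measurement_icc(bundle, cfg)
    flat = [c for pair in bundle.repeats for c in pair]
    D = elastic.pairwise_distance_matrix(flat, n_points=cfg.n_points)
    ids = np.repeat(bundle.repeat_ids, 2)
    stat, p_perm = labyrinth.procrustes_permutation_test(
        D, ids, n_perm=cfg.n_perm, seed=cfg.seed)
    results.update({
        "icc_min": float(icc_vals.min()),
        "icc_median": float(icc_vals.median()),
        "permutation_statistic": float(stat),
        "permutation_p": float(p_perm),
    })

    if cfg.run_ou and bundle.tip_values:
        logger.info("stage OU fit on scenario %s", bundle.scenario_id)
        tree = ou.scenario_tree(bundle.scenario_id)
        fit = ou.ou_fit_mcmc(bundle.tip_values, tree, n_iter=cfg.ou_n_iter,
                             seed=cfg.seed)
        fit["summary"].to_csv(out / "ou_posterior_summary.csv")
        results.update({
            "ou_alpha_posterior_median": float(
                fit["summary"].loc["alpha", "median"]),
            "ou_acceptance_rate": float(fit["acceptance_rate"]),
        })

    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results


def _all_spd(comp) -> bool:
    return all(np.all(np.linalg.eigvalsh(S) > 0) for S in comp.S_g.values())


def _measurement_icc(bundle, cfg) -> pd.Series:
    """ICC over two simulated measurement sessions of the index table."""
    rng = np.random.default_rng(cfg.seed + 101)
    meas = labyrinth.LabyrinthMeasurements(table=bundle.measurements)
    idx = labyrinth.compute_indices(meas)
    noise_sd = idx.std(ddof=1) * 0.15     # session error well below specimen
    s1 = idx + rng.normal(scale=noise_sd.to_numpy(), size=idx.shape)
    s2 = idx + rng.normal(scale=noise_sd.to_numpy(), size=idx.shape)
    return labyrinth.icc(s1, s2)


def validate_inputs(curve_csv=None, measurement_csv=None, tree_path=None,
                    tip_values=None) -> list:
    """Check a bundle of input files for structural problems.

    Returns a list of human-readable issue strings (empty when clean).
    """
    issues = []
    curves = None
    if curve_csv is not None:
        try:
            raw = pd.read_csv(curve_csv)
            for sid, grp in raw.groupby("specimen_id", sort=False):
                if not grp["point_index"].is_monotonic_increasing:
                    issues.append(
                        f"{curve_csv}: specimen {sid!r} has shuffled "
                        f"point_index order")
            curves = read_curves_csv(curve_csv)
            counts = {c.n_points for c in curves}
            if len(counts) > 1:
                issues.append(
                    f"{curve_csv}: inconsistent landmark counts {sorted(counts)}")
        except (ValueError, OSError, KeyError) as exc:
            issues.append(f"{curve_csv}: {exc}")
    if measurement_csv is not None:
        try:
            m = labyrinth.read_measurements_csv(measurement_csv)
            if curves is not None:
                curve_ids = {c.specimen_id for c in curves}
                missing = curve_ids - set(m.table.index)
                if missing:
                    issues.append(
                        f"{measurement_csv}: no measurements for "
                        f"{sorted(missing)[:5]}")
        except (ValueError, OSError, KeyError) as exc:
            issues.append(f"{measurement_csv}: {exc}")
    if tree_path is not None:
        try:
            tree = ou.read_newick(tree_path)
            if tip_values is not None:
                tips = set(tree.tip_labels)
                vals = set(tip_values)
                if tips != vals:
                    issues.append(
                        f"{tree_path}: tip/value mismatch "
                        f"(missing {sorted(tips - vals)[:5]}, "
                        f"extra {sorted(vals - tips)[:5]})")
        except (ValueError, OSError) as exc:
            issues.append(f"{tree_path}: {exc}")
    return issues
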
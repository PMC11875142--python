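"""End-to-end analysis orchestration with reproducible outputs.

``run_full_analysis`` chains the stages — summary-table loading and
validation, PCA + k-means of the five performance parameters, linear
regression of stability duration with confidence limits, and the RBF
network with reliability detection — writing one CSV per artefact plus a
machine-readable manifest of every setting and seed, so a bundle can be
recreated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import load_paper_dataset, read_steady_state_table, validate_records
from .multivariate import (PERFORMANCE_PARAMETERS, cluster_condition_crosstab,
                           kmeans, pca, performance_matrix)
from .regression import (contribution_weights, coverage, fit_mlr,
                         mlr_confidence, train_test_split)
from .rbf import (fit_rbf, fit_reliability_model, input_density,
                  rbf_confidence, stability_surface)

__all__ = ["AnalysisConfig", "run_full_analysis", "reproduce_paper"]


@dataclass
class AnalysisConfig:
    """Settings for a full analysis run; defaults are the study settings."""

    input_table: str | None = None   # None -> packaged reference dataset
    seed: int = 0
    pca_components: int = 3
    clusters: int = 3
    kmeans_restarts: int = 50
    train_fraction: float = 0.7
    alpha: float = 0.05
    rbf_hidden: int = 3
    stability_cap: float = 500.0     # h
    surface_grid: tuple = (3000.0, 6200.0, 50.0)  # bp: start, stop, step
    steady_state_cv: float = 0.10
    structural_decline_fraction: float = 0.2
    structural_plasmid_floor: float = 0.9


def _load(config: AnalysisConfig):
    if config.input_table is None:
        return load_paper_dataset()
    records = read_steady_state_table(config.input_table)
    if not records:
        raise ValueError("input table contains no fermentation records")
    return records


def run_full_analysis(config: AnalysisConfig, outdir) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Returns the manifest dict.  Any stage failure removes partial outputs
    and re-raises with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(name)

    stage = "load"
    try:
        records = _load(config)
        flagged = validate_records(records)

        stage = "pca"
        X = performance_matrix(records)
        pres = pca(X, config.pca_components, PERFORMANCE_PARAMETERS)
        emit(pd.DataFrame(pres.loadings,
                          columns=PERFORMANCE_PARAMETERS,
                          index=[f"PC{i+1}" for i in range(config.pca_components)]
                          ).rename_axis("component").reset_index(),
             "pca_loadings.csv")
        emit(pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(config.pca_components)],
            "variance_fraction": pres.variance_fractions,
        }), "pca_variance.csv")
        scores = pd.DataFrame(pres.scores,
                              columns=[f"PC{i+1}" for i in range(config.pca_components)])
        scores.insert(0, "ferm_id", [r.ferm_id for r in records])

        stage = "kmeans"
        model = kmeans(pres.scores, k=config.clusters, seed=config.seed,
                       n_init=config.kmeans_restarts)
        scores["cluster"] = model.assignments
        emit(scores, "pca_scores.csv")
        emit(cluster_condition_crosstab(model, records).reset_index(),
             "cluster_condition_crosstab.csv")

        stage = "mlr"
        train, test = train_test_split(records, config.train_fraction, config.seed)
        lm = fit_mlr(train, alpha=config.alpha)
        emit(pd.DataFrame({
            "predictor": lm.predictor_names,
            "coefficient_std": lm.coefficients,
            "contribution": [contribution_weights(lm)[p] for p in lm.predictor_names],
        }), "mlr_coefficients.csv")
        pred, lo, hi = mlr_confidence(lm, records=test)
        emit(pd.DataFrame({
            "ferm_id": [r.ferm_id for r in test],
            "observed": [r.stability_duration for r in test],
            "prediction": pred, "lower": lo, "upper": hi,
        }), "mlr_test_predictions.csv")
        mlr_cov = coverage(lm, test)

        stage = "rbf"
        from .regression import design_matrix
        Xd = design_matrix(records)
        y = np.array([r.stability_duration for r in records], float)
        Xtr = design_matrix(train)
        ytr = np.array([r.stability_duration for r in train], float)
        net = fit_rbf(Xtr, ytr, n_hidden=config.rbf_hidden, seed=config.seed,
                      alpha=config.alpha)
        rel = fit_reliability_model(net)
        p_all, lo_all, hi_all = rbf_confidence(net, Xd)
        emit(pd.DataFrame({
            "ferm_id": [r.ferm_id for r in records],
            "observed": y, "prediction": p_all, "lower": lo_all, "upper": hi_all,
            "density": input_density(net, Xd),
            "split": ["train" if r in train else "test" for r in records],
        }), "rbf_predictions.csv")
        start, stop, step = config.surface_grid
        grid = np.arange(start, stop + step / 2, step)
        conditions = sorted({(r.dilution_rate, r.temperature) for r in records})
        emit(pd.DataFrame(stability_surface(net, rel, grid, conditions,
                                            cap=config.stability_cap)),
             "rbf_surface.csv")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "n_records": len(records),
            "flagged_records": sorted(flagged),
            "pca_variance_fractions": [float(v) for v in pres.variance_fractions],
            "mlr_test_coverage": mlr_cov,
            "outputs": written,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        for name in written:
            (outdir / name).unlink(missing_ok=True)
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc


def reproduce_paper(outdir, seed: int = 0) -> dict:
    """Run the full analysis on the packaged reference dataset.

    Prints a short pass/fail table for the headline quantities of the
    reference analysis (PCA variance split, condition group means) and
    returns the manifest augmented with those checks.
    """
    config = AnalysisConfig(seed=seed)
    manifest = run_full_analysis(config, outdir)

    records = load_paper_dataset()
    vf = manifest["pca_variance_fractions"]
    lo_t = [r for r in records if r.dilution_rate == 0.033 and r.temperature == 37]
    lo_c = [r for r in records if r.dilution_rate == 0.033 and r.temperature == 30]
    checks = {
        "pc1_variance_pct": (round(100 * vf[0]), 51),
        "pc2_variance_pct": (round(100 * vf[1]), 22),
        "pc3_variance_pct": (round(100 * vf[2]), 20),
        "cumulative_variance_gt_93pct": (sum(vf[:3]) > 0.93, True),
        "mean_yield_ps_D0.033_T37": (round(float(np.mean([r.yield_ps for r in lo_t])), 2), 0.55),
        "mean_yield_ps_D0.033_T30": (round(float(np.mean([r.yield_ps for r in lo_c])), 2), 0.66),
        "mean_qp_D0.033_T37": (round(float(np.mean([r.specific_productivity for r in lo_t])), 2), 0.20),
        "mean_qp_D0.033_T30": (round(float(np.mean([r.specific_productivity for r in lo_c])), 2), 0.22),
    }
    width = max(len(k) for k in checks)
    for name, (got, want) in checks.items():
        ok = "PASS" if got == want else "FAIL"
        print(f"{name:<{width}}  computed={got!r:<8} expected={want!r:<8} {ok}")
    manifest["checks"] = {k: {"computed": got, "expected": want, "pass": got == want}
                          for k, (got, want) in checks.items()}
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
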
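"""End-to-end orchestration of the QSAR workflow.

The full pipeline mirrors the classical chemometrics sequence: autoscale the
descriptor matrix, screen descriptors by activity correlation, explore with
PCA (variance table, loadings, scores) and HCA (dendrogram, two-class cut),
fit PLS and PCR with leave-one-out validation, assemble the statistics suite,
and optionally predict an external test set.  Every stage writes plain-text
tables (CSV/JSON/Newick) into the output directory and logs its parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hca, pca
from .dataset import QSARDataError, QSARDataset, builtin_fixture, load_dataset
from .preprocess import (
    DEFAULT_CORRELATION_CUTOFF,
    fit_autoscale,
    filter_by_activity_correlation,
)
from .regression import (
    compare_models,
    compute_fit_statistics,
    fit_latent_model,
    loo_cross_validate,
    predict,
    select_n_components,
)

__all__ = ["PipelineConfig", "run_full_pipeline"]

logger = logging.getLogger("qsarpipe")

#: Decimal places used in all floating-point table output by default,
#: matching the precision conventional in QSAR reports.
DEFAULT_FLOAT_PRECISION = 4


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run; defaults are the classical settings
    (correlation cutoff 0.20, three latent variables, incremental linkage)."""

    training_path: str | None = None  # None -> built-in artemisinin training set
    test_path: str | None = None  # optional external set; "builtin" -> fixture
    activity_name: str = "logRA"
    reference_ic50: float | None = 97.0
    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF
    n_components: int = 3
    linkage: str = "incremental"
    output_dir: str = "qsarpipe_output"
    seed: int | None = None
    float_precision: int | None = DEFAULT_FLOAT_PRECISION

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation_cutoff <= 1.0:
            raise QSARDataError(
                f"correlation_cutoff must lie in [0, 1], got {self.correlation_cutoff}"
            )
        if self.n_components < 1:
            raise QSARDataError("n_components must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise QSARDataError(f"{path}: config must be a flat key-value mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise QSARDataError(f"{path}: unknown config key(s) {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        fields = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(fields, sort_keys=False))


def _fmt(df: pd.DataFrame, precision: int | None) -> pd.DataFrame:
    if precision is None:
        return df
    return df.round(precision)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute screen -> PCA -> HCA -> PLS & PCR (+LOO) -> statistics -> predict.

    Returns a summary dict of the key numbers and writes all tables under
    ``config.output_dir``.  Stage failures propagate as exceptions carrying
    the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prec = config.float_precision

    def write(df: pd.DataFrame, name: str) -> None:
        _fmt(df, prec).to_csv(out / name, index=False)

    stage = "load"
    try:
        if config.training_path is None:
            training = builtin_fixture("training", config.reference_ic50 or 97.0)
        else:
            training = load_dataset(config.training_path, config.activity_name)
        logger.info(
            "stage=load training n=%d m=%d", training.n_compounds, training.n_descriptors
        )

        stage = "filter"
        retained, discard_report = filter_by_activity_correlation(
            training, config.correlation_cutoff
        )
        write(discard_report, "descriptor_screen.csv")
        logger.info(
            "stage=filter cutoff=%.4g retained=%d/%d",
            config.correlation_cutoff, retained.n_descriptors, training.n_descriptors,
        )

        stage = "pca"
        scaler = fit_autoscale(retained)
        xs = scaler.transform(retained)
        pca_model = pca.fit_pca(xs)
        write(pca.variance_table(pca_model), "pca_variance.csv")
        write(
            pd.DataFrame(
                pca_model.loadings,
                index=pd.Index(retained.descriptor_names, name="descriptor"),
                columns=[f"PC{i+1}" for i in range(pca_model.n_features)],
            ).reset_index(),
            "pca_loadings.csv",
        )
        scores_df = pd.DataFrame(
            pca_model.scores,
            columns=[f"PC{i+1}" for i in range(pca_model.n_features)],
        )
        scores_df.insert(0, "compound_id", retained.compound_ids)
        write(scores_df, "pca_scores.csv")
        (out / "pca_equations.txt").write_text(
            "\n".join(
                pca.render_pc_equation(pca_model, i, retained.descriptor_names)
                for i in range(min(2, pca_model.n_features))
            )
            + "\n"
        )
        logger.info("stage=pca cumulative_pct=%s", np.round(pca_model.cumulative_pct, 4))

        stage = "hca"
        dist = hca.euclidean_distances(xs, retained.compound_ids)
        dendrogram = hca.agglomerate(dist, config.linkage)
        write(hca.merge_table(dendrogram), "hca_merges.csv")
        (out / "hca_dendrogram.nwk").write_text(hca.to_newick(dendrogram) + "\n")
        clusters = hca.cut_clusters(dendrogram, 2)
        write(
            pd.DataFrame(
                {"compound_id": list(clusters), "cluster": list(clusters.values())}
            ),
            "hca_clusters.csv",
        )
        logger.info("stage=hca linkage=%s k=2", config.linkage)

        stage = "regression"
        summary: dict = {"stages": {}}
        loo_results = {}
        for method in ("PLS", "PCR"):
            model = fit_latent_model(method, retained, config.n_components)
            cal = predict(model, retained)
            best_a, press_by_a = select_n_components(
                method, retained, config.n_components
            )
            loo, _ = loo_cross_validate(method, retained, best_a)
            loo_results[method] = loo
            stats = compute_fit_statistics(
                retained.activity(), cal.predicted, loo.predicted,
                k=retained.n_descriptors,
            )
            write(cal.to_dataframe(), f"{method.lower()}_calibration.csv")
            write(loo.to_dataframe(), f"{method.lower()}_loo_predictions.csv")
            coef_df = pd.DataFrame(
                {"descriptor": model.descriptor_names, "coefficient": model.coefficients}
            )
            write(coef_df, f"{method.lower()}_coefficients.csv")
            stats_payload = stats.to_dict() | {
                "n_components_calibration": config.n_components,
                "n_components_validation": best_a,
                "loo_press_by_components": press_by_a,
            }
            (out / f"{method.lower()}_statistics.json").write_text(
                json.dumps(stats_payload, indent=2, default=float) + "\n"
            )
            summary["stages"][method] = stats.to_dict()
            logger.info(
                "stage=regression method=%s R2=%.4f Q2=%.4f (val components=%d)",
                method, stats.r2, stats.q2, best_a,
            )

        stage = "predict"
        if config.test_path is not None:
            test = (
                builtin_fixture("test")
                if config.test_path == "builtin"
                else load_dataset(config.test_path, config.activity_name)
            )
            preds = {}
            for method in ("PLS", "PCR"):
                best_a, _ = select_n_components(method, retained, config.n_components)
                model = fit_latent_model(method, retained, best_a)
                preds[method] = predict(model, test)
            comparison = compare_models(preds["PLS"], preds["PCR"]).rename(
                columns={"pred_a": "pred_pls", "pred_b": "pred_pcr"}
            )
            write(comparison, "test_predictions.csv")
            summary["test_predictions"] = {
                cid: float(p)
                for cid, p in zip(test.compound_ids, preds["PLS"].predicted)
            }
            logger.info("stage=predict n=%d", test.n_compounds)

        summary["output_dir"] = str(out)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
        return summary
    except Exception as exc:
        raise QSARDataError(f"pipeline stage {stage!r} failed: {exc}") from exc
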
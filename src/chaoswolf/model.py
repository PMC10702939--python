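"""End-to-end detection model: optimizer-driven feature selection + KNN.

Glue between the pipeline stages: split a document-term matrix 80/20, run a
chosen optimizer variant against the wrapper objective on the training
portion, decode the best wolf into a feature mask, and score the resulting
masked KNN classifier on the held-out test rows.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix, metrics
from .feature_selection import FitnessSpec, WrapperObjective, knn_predict
from .optimizer import OptimizerConfig, RunResult, run
from .text_pipeline import DocumentTermMatrix, split

__all__ = ["optimize_features", "detect"]


def optimize_features(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    config: OptimizerConfig,
    fit_spec: FitnessSpec = FitnessSpec(),
    val_fraction: float = 0.25,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Run one wrapper feature-selection search; returns result + best mask."""
    objective = WrapperObjective(
        train_matrix,
        train_labels,
        spec=fit_spec,
        val_fraction=val_fraction,
        seed=config.seed,
        validation=validation,
    )
    result: RunResult = run(config, train_matrix.shape[1], objective)
    mask = objective.mask_of(result.best_position)
    detail = objective.evaluate_mask(mask)
    return {
        "result": result,
        "mask": mask,
        "validation_accuracy": detail["accuracy"],
        "n_selected": detail["n_selected"],
        "fitness": detail["fitness"],
    }


def detect(
    dtm: DocumentTermMatrix,
    config: OptimizerConfig,
    fit_spec: FitnessSpec = FitnessSpec(),
    train_fraction: float = 0.8,
    split_seed: int | None = None,
    paper_protocol: bool = False,
) -> dict:
    """Full protocol on one labeled DTM.

    80/20 stratified split, wrapper search on the training side (fitness
    scored on an inner validation hold-out, or directly on the test split
    when ``paper_protocol`` is set), then confusion-matrix metrics of the
    selected-feature KNN classifier on the test rows.
    """
    train, test = split(
        dtm,
        train_fraction=train_fraction,
        seed=config.seed if split_seed is None else split_seed,
    )
    validation = (test.matrix, test.labels) if paper_protocol else None
    sel = optimize_features(
        train.matrix, train.labels, config, fit_spec=fit_spec, validation=validation
    )
    mask = sel["mask"]
    pred = knn_predict(
        train.matrix[:, mask], train.labels, test.matrix[:, mask], fit_spec.k_neighbors
    )
    cm = ConfusionMatrix.from_labels(test.labels, pred)
    test_metrics = metrics(cm)
    selected_terms = [dtm.vocabulary[j] for j in np.flatnonzero(mask)]
    return {
        **sel,
        "test_metrics": test_metrics,
        "confusion_matrix": cm,
        "selected_terms": selected_terms,
        "n_train": train.n_docs,
        "n_test": test.n_docs,
    }
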
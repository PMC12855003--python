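"""Prediction of perturbation responses from a trained model.

A prediction for perturbation p samples K random control cells (with
replacement; K = 300 by default), runs the eval-mode forward pass with the
composed perturbation embedding, and keeps all K predicted profiles; the
point estimate is their mean.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .data import PerturbDataset, PerturbationLabel, parse_label
from .embeddings import EmbeddingTable, embed_perturbation
from .model import ScouterModel

__all__ = ["PredictionResult", "predict", "predict_all", "no_change_baseline"]


@dataclass
class PredictionResult:
    """K per-control predicted profiles and their mean for one perturbation."""

    perturbation: str
    per_control: np.ndarray  # (K, n_genes)
    mean_profile: np.ndarray  # (n_genes,)
    K: int
    control_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.per_control.shape[0] != self.K:
            raise ValueError("per_control must have K rows")
        if not np.allclose(self.mean_profile, self.per_control.mean(axis=0)):
            raise ValueError("mean_profile must be the rowwise mean of per_control")


def _pert_seed(seed: int, canonical: str) -> int:
    """Stable per-perturbation seed so batch prediction is order-independent."""
    digest = hashlib.sha256(f"{seed}:{canonical}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def predict(
    model: ScouterModel,
    dataset: PerturbDataset,
    p: PerturbationLabel | str,
    embeddings: EmbeddingTable,
    K: int | None = None,
    seed: int = 0,
    chunk: int = 1024,
) -> PredictionResult:
    """Predict the response to perturbation ``p`` (seen or unseen).

    Samples K control cells uniformly with replacement (seeded), feeds each
    through the model with the perturbation embedding, and returns all K
    profiles plus their mean.
    """
    if isinstance(p, str):
        p = parse_label(p)
    k = K if K is not None else model.config.K_predict
    if k < 1:
        raise ValueError("K must be >= 1")
    controls = dataset.control_indices
    if controls.size == 0:
        raise ValueError("dataset has no control cells")
    emb = embed_perturbation(embeddings, p)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(41,)))
    chosen = controls[rng.integers(0, controls.size, size=k)]
    out = np.empty((k, dataset.n_genes))
    for start in range(0, k, chunk):
        idx = chosen[start : start + chunk]
        out[start : start + len(idx)] = np.atleast_2d(
            model.forward(dataset.expression[idx], np.tile(emb, (len(idx), 1)), mode="eval")
        )
    return PredictionResult(
        perturbation=p.canonical(),
        per_control=out,
        mean_profile=out.mean(axis=0),
        K=k,
        control_indices=chosen,
    )


def predict_all(
    model: ScouterModel,
    dataset: PerturbDataset,
    perturbations,
    embeddings: EmbeddingTable,
    K: int | None = None,
    seed: int = 0,
) -> list[PredictionResult]:
    """Batch convenience over :func:`predict`.

    Each perturbation gets its own seed derived from the master seed and its
    canonical string, so permuting the input list permutes the outputs
    without changing any individual result. Per-perturbation failures are
    aggregated into one error.
    """
    results: list[PredictionResult] = []
    failures: list[str] = []
    for p in perturbations:
        label = parse_label(p) if isinstance(p, str) else p
        try:
            results.append(
                predict(model, dataset, label, embeddings, K=K,
                        seed=_pert_seed(seed, label.canonical()))
            )
        except (KeyError, ValueError) as exc:
            failures.append(f"{label.canonical()}: {exc}")
    if failures:
        raise RuntimeError(
            f"prediction failed for {len(failures)} of {len(list(perturbations))} "
            "perturbations: " + "; ".join(failures)
        )
    return results


def no_change_baseline(dataset: PerturbDataset, perturbations) -> list[PredictionResult]:
    """Baseline that predicts the mean control profile for every perturbation.

    Scores normalized MSE exactly 1 by construction; the absolute reference
    every model comparison is anchored to.
    """
    c = dataset.mean_control_profile()
    results = []
    for p in perturbations:
        label = parse_label(p) if isinstance(p, str) else p
        results.append(
            PredictionResult(
                perturbation=label.canonical(),
                per_control=c[None, :].copy(),
                mean_profile=c.copy(),
                K=1,
                control_indices=np.array([-1]),
            )
        )
    return results
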
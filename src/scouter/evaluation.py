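"""Top-DEG prediction metrics with bootstrap confidence intervals.

Performance is scored per perturbation over the top-K differentially
expressed genes (K = 20 by default): the mean observed perturbed profile x,
the predicted profile x_hat and the mean control profile c are restricted
to the DEG coordinates, and

    normalized MSE = MSE(x, x_hat) / MSE(x, c)
    1 - PCC        = 1 - PearsonCorr(x - c, x_hat - c).

Normalized MSE is anchored at 1 for the no-change predictor (x_hat = c) and
0 for a perfect one; both metrics are invariant to jointly rescaling x,
x_hat and c. Aggregates are medians per subgroup (single / seen0 / seen1 /
seen2) and overall, with 50% bootstrap confidence intervals (25th-75th
percentiles of the bootstrap distribution of the median over
perturbations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import PerturbationLabel, PerturbDataset, assign_subgroup, parse_label

__all__ = [
    "DEGSet",
    "EvalReport",
    "top_degs",
    "top_k_indices",
    "normalized_mse",
    "one_minus_pcc",
    "evaluate",
]


@dataclass
class DEGSet:
    """Ordered top-K DEG gene indices for one perturbation."""

    perturbation: str
    genes: list[int]
    source: str = "computed"  # "computed" | "provided"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene indices in DEG set")
        if any(g < 0 for g in self.genes):
            raise ValueError("negative gene index in DEG set")


def top_k_indices(score: np.ndarray, k: int) -> list[int]:
    """Indices of the k largest scores, descending; ties by index ascending."""
    order = np.lexsort((np.arange(score.size), -np.asarray(score, dtype=np.float64)))
    return [int(i) for i in order[:k]]


def top_degs(
    dataset: PerturbDataset,
    p: PerturbationLabel | str,
    top_k: int = 20,
    provided: list[int] | None = None,
) -> DEGSet:
    """Top-K DEGs of a perturbation: |mean perturbed - mean control|, descending.

    A precomputed gene-index list (e.g. shipped with a preprocessed dataset)
    takes precedence over the default mean-difference ranking.
    """
    canon = p.canonical() if isinstance(p, PerturbationLabel) else parse_label(p).canonical()
    if provided is not None:
        return DEGSet(canon, list(provided[:top_k]), source="provided")
    cells = dataset.cells_of(canon)
    if cells.size == 0:
        raise ValueError(f"perturbation {canon} has no cells in the dataset")
    diff = np.abs(
        dataset.expression[cells].mean(axis=0) - dataset.mean_control_profile()
    )
    return DEGSet(canon, top_k_indices(diff, top_k), source="computed")


def normalized_mse(x: np.ndarray, xhat: np.ndarray, c: np.ndarray) -> float:
    """MSE(x, xhat) / MSE(x, c) over the supplied (DEG-restricted) coordinates."""
    x, xhat, c = (np.asarray(v, dtype=np.float64) for v in (x, xhat, c))
    denom = float(np.mean((x - c) ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("normalized MSE undefined: no true change over the DEGs")
    return float(np.mean((x - xhat) ** 2)) / denom


def one_minus_pcc(x: np.ndarray, xhat: np.ndarray, c: np.ndarray) -> float:
    """1 - Pearson correlation of the true and predicted changes vs control."""
    x, xhat, c = (np.asarray(v, dtype=np.float64) for v in (x, xhat, c))
    d_true = x - c
    d_pred = xhat - c
    if np.std(d_true) == 0.0 or np.std(d_pred) == 0.0:
        raise ZeroDivisionError("1-PCC undefined: a change vector has zero variance")
    r = float(np.corrcoef(d_true, d_pred)[0, 1])
    return 1.0 - r


@dataclass
class EvalReport:
    """Per-perturbation metrics plus per-subgroup / overall medians with CIs."""

    per_perturbation: list[dict]
    aggregates: dict[str, dict]
    excluded: list[dict] = field(default_factory=list)
    top_k: int = 20
    n_bootstrap: int = 1000
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_perturbation)

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        import json

        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(
                {"top_k": self.top_k, "n_bootstrap": self.n_bootstrap, "seed": self.seed,
                 "aggregates": self.aggregates,
                 "excluded": self.excluded},
                indent=2,
            ))

    def median(self, metric: str = "normalized_mse", subgroup: str = "overall") -> float:
        return self.aggregates[subgroup][metric]["median"]


def _bootstrap_ci(values: np.ndarray, n_bootstrap: int, rng: np.random.Generator) -> tuple[float, float]:
    """25th/75th percentiles of the bootstrap distribution of the median."""
    medians = np.median(
        values[rng.integers(0, values.size, size=(n_bootstrap, values.size))], axis=1
    )
    return float(np.percentile(medians, 25)), float(np.percentile(medians, 75))


def _build_report(rows, train_perts: set[str], top_k: int, n_bootstrap: int,
                  seed: int) -> EvalReport:
    """rows: (perturbation, x_full, xhat_full, c_full, DEGSet)."""
    per_pert: list[dict] = []
    excluded: list[dict] = []
    metrics = {"normalized_mse": normalized_mse, "one_minus_pcc": one_minus_pcc}
    for pert, x, xhat, c, deg in rows:
        idx = np.asarray(deg.genes, dtype=np.intp)
        subgroup = assign_subgroup(pert, train_perts)
        row = {"perturbation": pert, "subgroup": subgroup}
        for name, fn in metrics.items():
            # a metric undefined for one perturbation (zero denominator or
            # variance) is flagged and excluded from that metric's aggregates
            try:
                row[name] = fn(x[idx], xhat[idx], c[idx])
            except ZeroDivisionError as exc:
                row[name] = float("nan")
                excluded.append(
                    {"perturbation": pert, "subgroup": subgroup,
                     "metric": name, "reason": str(exc)}
                )
        per_pert.append(row)

    aggregates: dict[str, dict] = {}
    groups = {"overall": per_pert}
    for sg in sorted({r["subgroup"] for r in per_pert}):
        groups[sg] = [r for r in per_pert if r["subgroup"] == sg]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    for name, rows_g in groups.items():
        entry = {"n": len(rows_g)}
        for metric in metrics:
            vals = np.array([r[metric] for r in rows_g])
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            lo, hi = _bootstrap_ci(vals, n_bootstrap, rng)
            entry[metric] = {"median": float(np.median(vals)), "ci50": [lo, hi]}
        aggregates[name] = entry
    return EvalReport(per_pert, aggregates, excluded, top_k, n_bootstrap, seed)


def evaluate(
    dataset: PerturbDataset,
    predictions,
    train_perts: set[str],
    top_k: int = 20,
    n_bootstrap: int = 1000,
    seed: int = 0,
    deg_lists: dict[str, list[int]] | None = None,
) -> EvalReport:
    """Score a list of :class:`PredictionResult` against held-out cells.

    For each predicted perturbation, the observed profile is the mean over
    that perturbation's cells in ``dataset``, the reference is the mean
    control profile, and DEGs are computed from the same cells (or taken
    from ``deg_lists`` when provided). Perturbations with undefined metrics
    (no true change / zero variance over their DEGs) are reported in
    ``excluded`` and left out of the medians.
    """
    if not predictions:
        raise ValueError("empty prediction list")
    c = dataset.mean_control_profile()
    rows = []
    for pred in predictions:
        pert = pred.perturbation
        cells = dataset.cells_of(pert)
        if cells.size == 0:
            raise ValueError(f"predicted perturbation {pert} has no held-out cells")
        x = dataset.expression[cells].mean(axis=0)
        provided = deg_lists.get(pert) if deg_lists else None
        deg = top_degs(dataset, pert, top_k, provided=provided)
        rows.append((pert, x, pred.mean_profile, c, deg))
    return _build_report(rows, train_perts, top_k, n_bootstrap, seed)
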
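"""Training loop: random control-perturbed pairing, Adam with exponential LR
decay, early stopping with best-state restore, and hyperparameter grid search.

Rather than averaging profiles per perturbation, each epoch pairs every
perturbed cell of the phase with one control cell drawn uniformly at random
(with replacement). With n0 controls and n_k cells perturbed for gene k the
sample space holds n0 * sum_k n_k distinct (control, perturbed) pairs, so
even datasets with few perturbations yield abundant training triplets.
Training pairings are redrawn each epoch; the validation pairing is drawn
once per run so early stopping compares like with like.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data import PerturbDataset, SplitPlan
from .embeddings import EmbeddingTable, embed_perturbation
from .losses import TripletBatch, total_loss, total_loss_and_grad
from .model import ScouterConfig, ScouterModel, build_model
from .nn import Adam, clip_grad_norm

__all__ = ["PairingPlan", "GridSpec", "make_pairing", "train", "grid_search"]


@dataclass
class PairingPlan:
    """One epoch's (perturbed cell, control cell) pairs for a phase."""

    epoch: int
    perturbed_indices: np.ndarray  # every perturbed cell of the phase, once
    control_indices: np.ndarray  # uniform draws from the control pool

    def __post_init__(self) -> None:
        if self.perturbed_indices.shape != self.control_indices.shape:
            raise ValueError("pairing arrays misaligned")

    @property
    def n_pairs(self) -> int:
        return int(self.perturbed_indices.size)


@dataclass
class GridSpec:
    """Hyperparameter grids searched over validation loss."""

    gamma_loss_grid: list[float] = field(default_factory=lambda: [0.0, 2.0])
    lambda_grid: list[float] = field(default_factory=lambda: [0.01, 0.05, 0.1, 0.5])
    lr_grid: list[float] = field(default_factory=lambda: [0.001, 0.005, 0.01])

    def __post_init__(self) -> None:
        if not (self.gamma_loss_grid and self.lambda_grid and self.lr_grid):
            raise ValueError("grids must be nonempty")

    def points(self):
        return itertools.product(self.gamma_loss_grid, self.lambda_grid, self.lr_grid)


def _derive_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0] % (2**31))


def make_pairing(
    dataset: PerturbDataset,
    phase_perturbations: set[str],
    epoch: int,
    seed: int,
) -> PairingPlan:
    """Pair every perturbed cell of the phase with a uniform random control.

    Deterministic in ``(seed, epoch)``; every cell whose perturbation is in
    ``phase_perturbations`` appears exactly once.
    """
    pert_idx = np.array(
        [i for i, lab in enumerate(dataset.labels)
         if not lab.is_control and lab.canonical() in phase_perturbations],
        dtype=np.intp,
    )
    if pert_idx.size == 0:
        raise ValueError("phase has no perturbed cells")
    controls = dataset.control_indices
    if controls.size == 0:
        raise ValueError("phase has no control cells")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(epoch,)))
    ctrl_idx = controls[rng.integers(0, controls.size, size=pert_idx.size)]
    return PairingPlan(epoch=epoch, perturbed_indices=pert_idx, control_indices=ctrl_idx)


def _phase_embeddings(dataset: PerturbDataset, perts: set[str],
                      table: EmbeddingTable) -> dict[str, np.ndarray]:
    missing: list[str] = []
    out: dict[str, np.ndarray] = {}
    for p in sorted(perts):
        try:
            out[p] = embed_perturbation(table, p)
        except KeyError as exc:
            missing.append(str(exc))
    if missing:
        raise KeyError("embedding coverage failure: " + "; ".join(missing))
    return out


def _batch_from_pairing(dataset: PerturbDataset, plan: PairingPlan, rows: np.ndarray,
                        emb: dict[str, np.ndarray]) -> TripletBatch:
    pi = plan.perturbed_indices[rows]
    ci = plan.control_indices[rows]
    perts = [dataset.labels[i].canonical() for i in pi]
    return TripletBatch(
        X=dataset.expression[pi],
        C=dataset.expression[ci],
        P=perts,
        E=np.stack([emb[p] for p in perts]),
    )


def _phase_loss(model: ScouterModel, dataset: PerturbDataset, plan: PairingPlan,
                emb: dict[str, np.ndarray], cfg: ScouterConfig, chunk: int = 1024) -> float:
    """Exact total loss of the whole phase in eval mode.

    Computed in one pass over all pairs (chunked forward for memory), then a
    single loss evaluation so the per-perturbation normalization is exact.
    """
    n = plan.n_pairs
    xhat = np.empty((n, dataset.n_genes))
    all_rows = np.arange(n)
    perts = [dataset.labels[i].canonical() for i in plan.perturbed_indices]
    e = np.stack([emb[p] for p in perts])
    for start in range(0, n, chunk):
        rows = all_rows[start : start + chunk]
        xhat[rows] = model.forward(
            dataset.expression[plan.control_indices[rows]], e[rows], mode="eval"
        )
    batch = TripletBatch(
        X=dataset.expression[plan.perturbed_indices],
        C=dataset.expression[plan.control_indices],
        P=perts,
        E=e,
    )
    return total_loss(batch, xhat, cfg.gamma_loss, cfg.lambda_dir)


def train(
    model: ScouterModel,
    dataset: PerturbDataset,
    split: SplitPlan,
    embeddings: EmbeddingTable,
    config: ScouterConfig | None = None,
    direction_surrogate_alpha: float | None = None,
) -> ScouterModel:
    """Fit the model on the split's training perturbations.

    Adam at ``config.lr`` with per-epoch exponential decay ``lr_decay``,
    batches of ``batch_size`` from the epoch's shuffled triplets (last
    partial batch kept), gradient norm clipped at ``grad_clip``; at most
    ``max_epochs`` epochs with early stopping once validation loss has
    failed to improve by ``min_delta`` for ``patience`` consecutive epochs.
    The weights from the best-validation epoch are restored before return,
    and ``model.history`` records per-epoch lr / train / validation losses.
    """
    cfg = config or model.config
    train_emb = _phase_embeddings(dataset, split.train, embeddings)
    val_emb = _phase_embeddings(dataset, split.val, embeddings)

    pair_seed = _derive_seed(cfg.seed, 11)
    val_seed = _derive_seed(cfg.seed, 12)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(13,)))
    val_plan = make_pairing(dataset, split.val, epoch=0, seed=val_seed)

    optimizer = Adam(model.layers, lr=cfg.lr)
    history: dict[str, list[float]] = {"lr": [], "train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state()
    best_epoch = -1
    wait = 0

    for epoch in range(cfg.max_epochs):
        lr_e = cfg.lr * cfg.lr_decay**epoch
        optimizer.lr = lr_e
        plan = make_pairing(dataset, split.train, epoch=epoch, seed=pair_seed)
        order = shuffle_rng.permutation(plan.n_pairs)
        epoch_losses: list[float] = []
        for start in range(0, plan.n_pairs, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            batch = _batch_from_pairing(dataset, plan, rows, train_emb)
            xhat = model.forward(batch.C, batch.E, mode="train")
            loss, dxhat = total_loss_and_grad(
                batch, xhat, cfg.gamma_loss, cfg.lambda_dir,
                direction_surrogate_alpha=direction_surrogate_alpha,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss ({loss}) at epoch {epoch}; "
                    f"lr={lr_e:.3g}, gamma_loss={cfg.gamma_loss}, lambda={cfg.lambda_dir}"
                )
            model.backward(dxhat)
            clip_grad_norm(model.layers, cfg.grad_clip)
            optimizer.step()
            epoch_losses.append(loss)

        val_loss = _phase_loss(model, dataset, val_plan, val_emb, cfg)
        history["lr"].append(lr_e)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)

        if best_val - val_loss > cfg.min_delta:
            best_val = val_loss
            best_state = model.state()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    model.load_state(best_state)
    model.history = history
    model.best_epoch = best_epoch if best_epoch >= 0 else 0
    return model


def validation_loss(model: ScouterModel, dataset: PerturbDataset, split: SplitPlan,
                    embeddings: EmbeddingTable) -> float:
    """Loss of the (restored) model on the split's fixed validation pairing."""
    cfg = model.config
    val_emb = _phase_embeddings(dataset, split.val, embeddings)
    val_plan = make_pairing(dataset, split.val, epoch=0, seed=_derive_seed(cfg.seed, 12))
    return _phase_loss(model, dataset, val_plan, val_emb, cfg)


def grid_search(
    dataset: PerturbDataset,
    splits: list[SplitPlan],
    embeddings: EmbeddingTable,
    base_config: ScouterConfig,
    grid: GridSpec | None = None,
) -> ScouterConfig:
    """Pick (gamma_loss, lambda, lr) minimizing mean best-validation loss
    across splits; returns ``base_config`` updated with the winner."""
    if not splits:
        raise ValueError("need at least one split")
    grid = grid or GridSpec()
    best_point = None
    best_score = np.inf
    for gamma_loss, lam, lr in grid.points():
        cfg = base_config.with_updates(gamma_loss=gamma_loss, lambda_dir=lam, lr=lr)
        scores = []
        for split in splits:
            try:
                fitted = train(build_model(cfg), dataset, split, embeddings, cfg)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"training failed at grid point gamma_loss={gamma_loss}, "
                    f"lambda={lam}, lr={lr}: {exc}"
                ) from exc
            scores.append(min(fitted.history["val_loss"]))
        mean_score = float(np.mean(scores))
        if mean_score < best_score:
            best_score = mean_score
            best_point = (gamma_loss, lam, lr)
    gamma_loss, lam, lr = best_point
    return base_config.with_updates(gamma_loss=gamma_loss, lambda_dir=lam, lr=lr)
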
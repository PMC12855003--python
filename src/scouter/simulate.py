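"""Synthetic Perturb-seq-like data with embedding-linked ground-truth effects.

The generator emulates the structure the model assumes: every gene carries a
dense embedding, and a perturbation's true effect on the transcriptome is a
linear function of that embedding,

    delta(g) = mask_g * (W @ E(g)),

with W a fixed genes x dim linear map, so that extrapolating to held-out
perturbations is information-theoretically possible from the embeddings
alone. Control cells are noisy draws around a baseline profile mu; a
perturbed cell is mu + delta + noise; a two-gene perturbation adds the two
single-gene effects plus an optional interaction term. All values live in
log-normalized expression space with i.i.d. Gaussian noise; an optional
count mode (NB sampling + log1p) exists for loader-robustness tests only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import PerturbDataset, PerturbationLabel, parse_label
from .embeddings import EmbeddingTable

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "oracle_metrics"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults give 200 genes, 40 single perturbations of 100 cells each,
    2,000 controls, 32-dimensional embeddings and per-gene effect sizes a
    few times the noise standard deviation; effects are dense
    (``sparsity=1``) so the embedding -> effect map stays linear and
    held-out perturbations are recoverable in principle.
    """

    n_genes: int = 200
    n_perts: int = 40
    n_cells_per_pert: int = 100
    n_controls: int = 2000
    embedding_dim: int = 32
    effect_scale: float = 1.0
    noise_sd: float = 0.2
    sparsity: float = 1.0
    n_double: int = 0
    n_cells_per_double: int | None = None  # defaults to n_cells_per_pert
    interaction_sd: float = 0.0
    count_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_perts, self.n_cells_per_pert, self.n_controls,
               self.embedding_dim) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.interaction_sd < 0 or self.effect_scale < 0:
            raise ValueError("scales must be nonnegative")
        if self.n_double < 0 or self.n_double > self.n_perts * (self.n_perts - 1) // 2:
            raise ValueError("n_double out of range")


@dataclass
class GroundTruth:
    """Noise-free description of the simulated system."""

    baseline: np.ndarray  # mu, (n_genes,)
    W: np.ndarray  # (n_genes, dim) linear effect map
    effect_map: dict[str, np.ndarray]  # canonical perturbation -> delta
    interactions: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def true_profile(self, perturbation: str) -> np.ndarray:
        """mu + delta for a known perturbation (mu itself for "ctrl")."""
        if perturbation == "ctrl":
            return self.baseline.copy()
        if perturbation not in self.effect_map:
            raise KeyError(f"unknown perturbation: {perturbation}")
        return self.baseline + self.effect_map[perturbation]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "baseline": self.baseline.tolist(),
            "W": self.W.tolist(),
            "effect_map": {k: v.tolist() for k, v in self.effect_map.items()},
            "interactions": {k: v.tolist() for k, v in self.interactions.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            baseline=np.array(d["baseline"]),
            W=np.array(d["W"]),
            effect_map={k: np.array(v) for k, v in d["effect_map"].items()},
            interactions={k: np.array(v) for k, v in d["interactions"].items()},
            seed=int(d["seed"]),
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_dataset(cfg: SimConfig) -> tuple[PerturbDataset, EmbeddingTable, GroundTruth]:
    """Draw a dataset, its embedding table and the generating ground truth.

    Embeddings are i.i.d. N(0, 1/dim) per coordinate (unit expected norm);
    W entries are i.i.d. N(0, effect_scale^2), so per-gene effects are
    N(0, ~effect_scale^2). Single-gene perturbations target the first
    ``n_perts`` panel genes; two-gene combos pair distinct single targets.
    """
    gene_names = [f"G{i:04d}" for i in range(cfg.n_genes)]

    emb = _rng(cfg.seed, 1).normal(0.0, 1.0 / np.sqrt(cfg.embedding_dim),
                                   size=(cfg.n_genes, cfg.embedding_dim))
    table = EmbeddingTable(gene_names, emb)

    w = _rng(cfg.seed, 2).normal(0.0, cfg.effect_scale, size=(cfg.n_genes, cfg.embedding_dim))
    baseline = _rng(cfg.seed, 3).exponential(1.0, size=cfg.n_genes)

    single_targets = gene_names[: cfg.n_perts]
    mask_rng = _rng(cfg.seed, 4)
    effect_map: dict[str, np.ndarray] = {}
    for g in single_targets:
        mask = (
            np.ones(cfg.n_genes)
            if cfg.sparsity >= 1.0
            else (mask_rng.random(cfg.n_genes) < cfg.sparsity).astype(float)
        )
        effect_map[g] = mask * (w @ table.vector(g))

    pair_rng = _rng(cfg.seed, 5)
    interactions: dict[str, np.ndarray] = {}
    doubles: list[str] = []
    if cfg.n_double > 0:
        all_pairs = [
            (single_targets[i], single_targets[j])
            for i in range(len(single_targets))
            for j in range(i + 1, len(single_targets))
        ]
        chosen = pair_rng.choice(len(all_pairs), size=cfg.n_double, replace=False)
        for idx in sorted(chosen.tolist()):
            g1, g2 = all_pairs[idx]
            canon = PerturbationLabel((g1, g2)).canonical()
            inter = (
                pair_rng.normal(0.0, cfg.interaction_sd, size=cfg.n_genes)
                if cfg.interaction_sd > 0
                else np.zeros(cfg.n_genes)
            )
            interactions[canon] = inter
            effect_map[canon] = effect_map[g1] + effect_map[g2] + inter
            doubles.append(canon)

    noise_rng = _rng(cfg.seed, 6)
    blocks: list[np.ndarray] = []
    raw_labels: list[str] = []
    blocks.append(baseline + noise_rng.normal(0.0, cfg.noise_sd, size=(cfg.n_controls, cfg.n_genes)))
    raw_labels += ["ctrl"] * cfg.n_controls
    n_cd = cfg.n_cells_per_double or cfg.n_cells_per_pert
    for pert in single_targets + doubles:
        n_cells = cfg.n_cells_per_pert if pert in single_targets else n_cd
        mean = baseline + effect_map[pert]
        blocks.append(mean + noise_rng.normal(0.0, cfg.noise_sd, size=(n_cells, cfg.n_genes)))
        raw_labels += [pert] * n_cells
    x = np.vstack(blocks)

    if cfg.count_mode:
        count_rng = _rng(cfg.seed, 7)
        lam = np.exp(np.clip(x, None, 12.0))
        x = np.log1p(count_rng.poisson(lam).astype(np.float64))

    labels = [parse_label(r) for r in raw_labels]
    dataset = PerturbDataset(x, gene_names, labels)
    truth = GroundTruth(baseline=baseline, W=w, effect_map=effect_map,
                        interactions=interactions, seed=cfg.seed)
    return dataset, table, truth


def oracle_metrics(truth: GroundTruth, predictions, top_k: int = 20,
                   train_perts: set[str] | None = None):
    """Score predictions against the noise-free truth profiles mu + delta.

    DEGs are ranked by |delta| (ties by gene index), the control reference is
    mu itself, so the returned report is an upper bound on what any
    predictor can achieve on finite noisy data.
    """
    from .evaluation import DEGSet, _build_report, top_k_indices

    rows = []
    for pred in predictions:
        pert = pred.perturbation
        x = truth.true_profile(pert)
        delta = truth.effect_map[pert]
        deg = DEGSet(pert, top_k_indices(np.abs(delta), top_k), source="computed")
        rows.append((pert, x, pred.mean_profile, truth.baseline, deg))
    return _build_report(rows, train_perts or set(), top_k=top_k, n_bootstrap=1000, seed=0)
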
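"""The compressor-generator network for perturbation-response prediction.

The compressor C is an MLP that condenses a control cell's expression
profile c into a compact cell state S through a narrow bottleneck. S is
concatenated with the frozen embedding E(p) of the perturbed gene(s) and a
generator MLP D produces the predicted perturbed profile

    x_hat = D(S (+) E(p)),

where (+) is concatenation. Hidden layers use batch-norm followed by SELU;
the bottleneck and the output layer are purely linear. The embedding enters
as an external input vector, never as a trainable lookup.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .nn import SELU, AlphaDropout, BatchNorm1d, Dense, Layer, LayerNorm, Sequential

__all__ = ["ScouterConfig", "ScouterModel", "build_model", "synthetic_config", "PRESETS"]


@dataclass
class ScouterConfig:
    """Architecture and training hyperparameters.

    The loss exponent ``gamma_loss`` (exponent 2+gamma in the autofocus
    term) and the learning-rate decay ``lr_decay`` are distinct knobs even
    though both are conventionally written gamma.
    """

    n_genes: int = 0
    embedding_dim: int = 0
    compressor_hidden: list[int] = field(default_factory=lambda: [2048, 512])
    bottleneck: int = 64
    generator_hidden: list[int] = field(default_factory=lambda: [2048])
    activation: str = "SELU"
    batch_norm: bool = True
    layer_norm: bool = False
    dropout: float = 0.0
    gamma_loss: float = 0.0
    lambda_dir: float = 0.05
    lr: float = 1e-3
    lr_decay: float = 0.9
    batch_size: int = 256
    max_epochs: int = 40
    patience: int = 5
    min_delta: float = 1e-3
    grad_clip: float = 1.0
    K_predict: int = 300
    seed: int = 0
    bottleneck_nonlinear: bool = False  # activation/BN on the bottleneck layer

    def __post_init__(self) -> None:
        if any(w <= 0 for w in [*self.compressor_hidden, self.bottleneck, *self.generator_hidden]):
            raise ValueError("all layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.gamma_loss < 0 or self.lambda_dir < 0:
            raise ValueError("gamma_loss and lambda_dir must be nonnegative")
        if self.lr <= 0 or not 0 < self.lr_decay <= 1:
            raise ValueError("lr must be positive and lr_decay in (0, 1]")
        if self.activation != "SELU":
            raise ValueError("only SELU activation is supported")

    def with_updates(self, **kw) -> "ScouterConfig":
        return replace(self, **kw)


def synthetic_config(n_genes: int = 200, embedding_dim: int = 32, seed: int = 0,
                     **overrides) -> ScouterConfig:
    """Architecture scaled to the synthetic generator's default problem size.

    The full-scale widths (2048/512/64 and 2048) target ~5,000-gene
    Perturb-seq panels; for the 200-gene simulated panel the same
    compressor-generator shape is kept at proportionally smaller widths
    (256/128 -> 32 bottleneck; generator 256). Training protocol defaults
    are unchanged.
    """
    cfg = ScouterConfig(
        n_genes=n_genes,
        embedding_dim=embedding_dim,
        compressor_hidden=[256, 128],
        bottleneck=32,
        generator_hidden=[256],
        lr=0.005,
        lambda_dir=0.05,
        gamma_loss=0.0,
        seed=seed,
    )
    return cfg.with_updates(**overrides) if overrides else cfg


# Hyperparameters selected per reference Perturb-seq dataset (gamma_loss=0 for all).
PRESETS: dict[str, dict[str, float]] = {
    "dixit": {"gamma_loss": 0.0, "lambda_dir": 0.05, "lr": 0.01},
    "adamson": {"gamma_loss": 0.0, "lambda_dir": 0.01, "lr": 0.001},
    "norman": {"gamma_loss": 0.0, "lambda_dir": 0.05, "lr": 0.001},
    "replogle_k562": {"gamma_loss": 0.0, "lambda_dir": 0.5, "lr": 0.001},
    "replogle_rpe1": {"gamma_loss": 0.0, "lambda_dir": 0.5, "lr": 0.001},
}


def _mlp_block(n_in: int, widths: list[int], cfg: ScouterConfig,
               rng: np.random.Generator) -> tuple[list[Layer], int]:
    """Hidden stack: affine -> [batch-norm] -> SELU -> [alpha-dropout] per width."""
    layers: list[Layer] = []
    for w in widths:
        layers.append(Dense(n_in, w, rng))
        if cfg.batch_norm:
            layers.append(BatchNorm1d(w))
        if cfg.layer_norm:
            layers.append(LayerNorm(w))
        layers.append(SELU())
        if cfg.dropout > 0:
            layers.append(AlphaDropout(cfg.dropout, rng))
        n_in = w
    return layers, n_in


class ScouterModel:
    """Compressor + generator with explicit forward/backward; numpy arrays only.

    After training, ``history`` holds per-epoch losses and learning rates and
    ``best_epoch`` the epoch whose weights are loaded (lowest validation loss).
    """

    def __init__(self, config: ScouterConfig):
        if config.n_genes <= 0 or config.embedding_dim <= 0:
            raise ValueError("n_genes and embedding_dim must be set")
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))

        c_layers, width = _mlp_block(config.n_genes, config.compressor_hidden, config, rng)
        c_layers.append(Dense(width, config.bottleneck, rng))
        if config.bottleneck_nonlinear:
            if config.batch_norm:
                c_layers.append(BatchNorm1d(config.bottleneck))
            c_layers.append(SELU())
        self.compressor = Sequential(c_layers)

        g_in = config.bottleneck + config.embedding_dim
        g_layers, width = _mlp_block(g_in, config.generator_hidden, config, rng)
        g_layers.append(Dense(width, config.n_genes, rng))  # linear output
        self.generator = Sequential(g_layers)

        self.history: dict[str, list[float]] = {}
        self.best_epoch: int | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, control_profile: np.ndarray, pert_embedding: np.ndarray,
                mode: str = "eval") -> np.ndarray:
        """Predict perturbed profiles for a batch of (control, embedding) pairs.

        Accepts single vectors or (B, .) batches; eval mode is deterministic
        (normalization layers use accumulated statistics, no sampling).
        """
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        c = np.atleast_2d(np.asarray(control_profile, dtype=np.float64))
        e = np.atleast_2d(np.asarray(pert_embedding, dtype=np.float64))
        if c.shape[1] != self.config.n_genes:
            raise ValueError(f"control profile has {c.shape[1]} genes, expected {self.config.n_genes}")
        if e.shape[1] != self.config.embedding_dim:
            raise ValueError(f"embedding has dim {e.shape[1]}, expected {self.config.embedding_dim}")
        if e.shape[0] == 1 and c.shape[0] > 1:
            e = np.broadcast_to(e, (c.shape[0], e.shape[1]))
        if c.shape[0] != e.shape[0]:
            raise ValueError("batch sizes of control profiles and embeddings differ")
        train = mode == "train"
        s = self.compressor.forward(c, train)
        h = np.concatenate([s, e], axis=1)
        out = self.generator.forward(h, train)
        if np.asarray(control_profile).ndim == 1:
            return out[0]
        return out

    def backward(self, d_xhat: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the prediction through both modules."""
        dh = self.generator.backward(d_xhat)
        ds = dh[:, : self.config.bottleneck]
        self.compressor.backward(ds)

    # -- bookkeeping ---------------------------------------------------------

    @property
    def layers(self) -> list[Layer]:
        return self.compressor.layers + self.generator.layers

    def n_params(self) -> int:
        return self.compressor.n_params() + self.generator.n_params()

    def state(self) -> list[dict[str, np.ndarray]]:
        return [layer.state() for layer in self.layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, s in zip(self.layers, state):
            layer.load_state(s)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file NPZ checkpoint: config JSON + every layer array."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                arrays[f"layer{i}.{k}"] = v
        meta = {
            "config": asdict(self.config),
            "best_epoch": self.best_epoch,
            "history": self.history,
        }
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ScouterModel":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["_meta"].tobytes()).decode())
            cfg = ScouterConfig(**meta["config"])
            model = cls(cfg)
            for i, layer in enumerate(model.layers):
                layer.load_state({k: z[f"layer{i}.{k}"] for k in layer.state()})
        model.best_epoch = meta["best_epoch"]
        model.history = {k: list(v) for k, v in meta["history"].items()}
        return model


def build_model(config: ScouterConfig) -> ScouterModel:
    """Construct an untrained model from a config (weights seeded by ``config.seed``)."""
    return ScouterModel(config)
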
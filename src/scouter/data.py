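"""Labeled perturbation expression datasets: loading, label parsing, splits.

A Perturb-seq-style dataset is a cells x genes matrix of log-normalized
expression together with a per-cell label naming the perturbation the cell
received: ``"ctrl"`` for unperturbed control cells, ``"GENE"`` for a
single-gene perturbation, or ``"GENE1+GENE2"`` for a two-gene perturbation.
Splits are made over *perturbations*, never over cells, so that held-out
perturbations are genuinely unseen during training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PerturbationLabel",
    "PerturbDataset",
    "SplitPlan",
    "parse_label",
    "load_dataset",
    "write_dataset",
    "make_splits",
    "assign_subgroup",
]

SUBGROUPS = ("single", "seen0", "seen1", "seen2")


@dataclass(frozen=True, order=True)
class PerturbationLabel:
    """Parsed perturbation identity: 0 (control), 1, or 2 target genes.

    Two-gene labels are stored with targets sorted lexicographically, so
    ``A+B`` and ``B+A`` compare equal.
    """

    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.targets) > 2:
            raise ValueError(f"at most 2 targets supported, got {self.targets}")
        if any(not t for t in self.targets):
            raise ValueError("empty gene symbol in perturbation label")
        if len(self.targets) == 2:
            if self.targets[0] == self.targets[1]:
                raise ValueError(f"duplicate target in 2-gene label: {self.targets[0]}")
            if list(self.targets) != sorted(self.targets):
                object.__setattr__(self, "targets", tuple(sorted(self.targets)))

    @property
    def is_control(self) -> bool:
        return len(self.targets) == 0

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def canonical(self) -> str:
        """Canonical string form: "ctrl", "G", or "G1+G2" (sorted)."""
        return "ctrl" if self.is_control else "+".join(self.targets)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


CONTROL = PerturbationLabel(())


def parse_label(raw: str) -> PerturbationLabel:
    """Parse a raw label string into a :class:`PerturbationLabel`.

    Accepts both the bare ``"G"`` and the padded ``"G+ctrl"`` / ``"ctrl+G"``
    dialects for single perturbations; ``"ctrl"`` (any capitalization of the
    literal token, and ``"ctrl+ctrl"``) is control.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError(f"unparseable perturbation label: {raw!r}")
    parts = [p.strip() for p in raw.strip().split("+")]
    if any(not p for p in parts):
        raise ValueError(f"unparseable perturbation label: {raw!r}")
    targets = [p for p in parts if p.lower() != "ctrl"]
    if len(targets) > 2:
        raise ValueError(f"more than two targets in label: {raw!r}")
    return PerturbationLabel(tuple(sorted(targets)))


@dataclass
class PerturbDataset:
    """Cells x genes log-normalized expression with parsed perturbation labels."""

    expression: np.ndarray  # (n, n_genes) float
    gene_names: list[str]
    labels: list[PerturbationLabel]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D cells x genes matrix")
        n, g = self.expression.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(set(self.gene_names)) != g:
            raise ValueError("gene names are not unique")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} cells")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        if self.n0 < 1:
            raise ValueError("no control cells in dataset")
        if self.n - self.n0 < 1:
            raise ValueError("no perturbed cells in dataset")

    @property
    def n(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([lab.is_control for lab in self.labels], dtype=bool)

    @property
    def n0(self) -> int:
        return int(self.control_mask.sum())

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.control_mask)

    def perturbations(self) -> list[str]:
        """Sorted canonical strings of all non-control perturbations present."""
        return sorted({lab.canonical() for lab in self.labels if not lab.is_control})

    def cells_of(self, perturbation: str | PerturbationLabel) -> np.ndarray:
        """Row indices of cells carrying the given perturbation."""
        canon = (
            perturbation.canonical()
            if isinstance(perturbation, PerturbationLabel)
            else parse_label(perturbation).canonical()
        )
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab.canonical() == canon],
            dtype=np.intp,
        )

    def mean_control_profile(self) -> np.ndarray:
        return self.expression[self.control_mask].mean(axis=0)


def _looks_like_counts(x: np.ndarray) -> bool:
    sample = x[: min(200, x.shape[0])]
    return bool(np.allclose(sample, np.round(sample)) and sample.max(initial=0.0) > 50)


def _finish_load(matrix, gene_names, raw_labels) -> PerturbDataset:
    labels = [parse_label(str(r)) for r in raw_labels]
    ds = PerturbDataset(np.asarray(matrix, dtype=np.float64), list(gene_names), labels)
    if _looks_like_counts(ds.expression):
        warnings.warn(
            "expression matrix looks like raw counts (integer-valued, max > 50); "
            "the model expects log-normalized values and will not renormalize",
            UserWarning,
            stacklevel=3,
        )
    return ds


def load_dataset(
    path: str | Path,
    label_key: str = "condition",
    labels_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> PerturbDataset:
    """Load a labeled expression dataset from H5AD, or matrix + sidecars.

    For H5AD, the per-cell labels are read from ``adata.obs[label_key]``.
    For MTX/NPZ/CSV matrices, labels come from a TSV sidecar (one raw label
    per line) and gene names from a second sidecar (one symbol per line);
    NPZ files may carry ``matrix``, ``labels`` and ``gene_names`` arrays
    internally, in which case sidecars are optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()

    if suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        if label_key not in adata.obs.columns:
            raise KeyError(f"label column {label_key!r} not found in obs")
        x = adata.X
        if not isinstance(x, np.ndarray):
            x = x.toarray()
        return _finish_load(x, list(adata.var_names), adata.obs[label_key].tolist())

    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            matrix = z["matrix"]
            genes = (
                [str(s) for s in z["gene_names"]]
                if "gene_names" in z
                else _read_lines(genes_path, "gene names")
            )
            raws = (
                [str(s) for s in z["labels"]]
                if "labels" in z
                else _read_lines(labels_path, "labels")
            )
        return _finish_load(matrix, genes, raws)

    if suffix == ".mtx":
        from scipy.io import mmread

        matrix = np.asarray(mmread(path).todense())
        return _finish_load(
            matrix,
            _read_lines(genes_path, "gene names"),
            _read_lines(labels_path, "labels"),
        )

    if suffix == ".csv":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return _finish_load(
            df.to_numpy(dtype=np.float64),
            [str(c) for c in df.columns],
            _read_lines(labels_path, "labels"),
        )

    raise ValueError(f"unsupported dataset format: {path.name}")


def _read_lines(path: str | Path | None, what: str) -> list[str]:
    if path is None:
        raise ValueError(f"no {what} sidecar file provided")
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_dataset(dataset: PerturbDataset, path: str | Path, label_key: str = "condition") -> None:
    """Write a dataset as H5AD (labels in ``obs[label_key]``) or NPZ."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raws = [lab.canonical() for lab in dataset.labels]
    if path.suffix.lower() == ".h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=dataset.expression.copy(),
            obs=pd.DataFrame({label_key: pd.Categorical(raws)},
                             index=[f"cell{i}" for i in range(dataset.n)]),
            var=pd.DataFrame(index=pd.Index(dataset.gene_names, name="gene")),
        )
        adata.write_h5ad(path)
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(
            path,
            matrix=dataset.expression,
            gene_names=np.array(dataset.gene_names),
            labels=np.array(raws),
        )
    else:
        raise ValueError(f"unsupported output format: {path.name}")


@dataclass
class SplitPlan:
    """Disjoint train/val/test sets of canonical perturbation strings.

    Controls are never split: control cells are available to every phase.
    """

    train: set[str]
    val: set[str]
    test: set[str]
    seed: int
    scheme: str
    split_index: int = 0

    def __post_init__(self) -> None:
        if self.train & self.val or self.train & self.test or self.val & self.test:
            raise ValueError("split sets overlap")
        if "ctrl" in self.train | self.val | self.test:
            raise ValueError('"ctrl" must not appear in a split')

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "scheme": self.scheme,
                "seed": self.seed,
                "split_index": self.split_index,
                "train": sorted(self.train),
                "val": sorted(self.val),
                "test": sorted(self.test),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "SplitPlan":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            train=set(d["train"]),
            val=set(d["val"]),
            test=set(d["test"]),
            seed=int(d["seed"]),
            scheme=str(d["scheme"]),
            split_index=int(d.get("split_index", 0)),
        )


SCHEMES = ("test20_val10", "dixit_801010")


def _split_sizes(n_perts: int, scheme: str) -> tuple[int, int, int]:
    # floor for test, ceil for validation, remainder to train, each >= 1
    if scheme == "test20_val10":
        n_test = max(1, int(np.floor(0.2 * n_perts)))
        n_val = max(1, int(np.ceil(0.1 * (n_perts - n_test))))
    elif scheme == "dixit_801010":
        n_test = max(1, int(np.floor(0.1 * n_perts)))
        n_val = max(1, int(np.ceil(0.1 * n_perts)))
    else:
        raise ValueError(f"unknown split scheme {scheme!r}; choose from {SCHEMES}")
    n_train = n_perts - n_test - n_val
    if n_train < 1:
        raise ValueError(f"too few perturbations ({n_perts}) to populate all three sets")
    return n_train, n_val, n_test


def make_splits(
    dataset: PerturbDataset,
    scheme: str = "test20_val10",
    n_splits: int = 1,
    seed: int = 0,
) -> list[SplitPlan]:
    """Generate perturbation-level train/val/test splits.

    ``test20_val10`` holds out 20% of perturbations for testing and splits
    the remaining 80% into 90% train / 10% validation; ``dixit_801010`` uses
    an 80:10:10 ratio (for datasets with very few perturbations). All cells
    of one perturbation travel together; plans are deterministic in
    ``(seed, split index)``.
    """
    perts = dataset.perturbations()
    if len(perts) < 3:
        raise ValueError("need at least 3 non-control perturbations to split")
    n_train, n_val, n_test = _split_sizes(len(perts), scheme)
    plans = []
    for k in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        order = list(rng.permutation(perts))
        plans.append(
            SplitPlan(
                train=set(order[:n_train]),
                val=set(order[n_train : n_train + n_val]),
                test=set(order[n_train + n_val :]),
                seed=seed,
                scheme=scheme,
                split_index=k,
            )
        )
    return plans


def assign_subgroup(p: PerturbationLabel | str, train_perts: set[str]) -> str:
    """Subgroup of a test perturbation relative to the training perturbations.

    Single-gene labels are ``"single"``. A two-gene label is ``seen{0,1,2}``
    by how many of its two targets appear anywhere in training — alone or as
    a member of any training combination (but the pair itself being in
    training still counts each gene once; seen2 means "both perturbed, never
    simultaneously with each other" only when the pair is held out, which is
    the situation this is called in).
    """
    if isinstance(p, str):
        p = parse_label(p)
    if p.is_control:
        raise ValueError("control has no subgroup")
    if p.n_targets == 1:
        return "single"
    trained_genes = set()
    for t in train_perts:
        trained_genes.update(parse_label(t).targets)
    n_seen = sum(1 for g in p.targets if g in trained_genes)
    return f"seen{n_seen}"
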
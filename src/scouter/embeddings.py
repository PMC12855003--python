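"""Frozen per-gene embedding vectors and perturbation-embedding composition.

Each gene symbol maps to a fixed-length dense vector (LLM text embeddings of
gene descriptions; 1,536-dimensional in the reference tables, any length
here). The table is frozen: it conditions the network but is never updated.
A two-gene perturbation is embedded as the elementwise *sum* of the two gene
vectors.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .data import PerturbationLabel, PerturbDataset, parse_label

__all__ = ["EmbeddingTable", "load_embeddings", "embed_perturbation", "coverage_report"]


class EmbeddingTable:
    """Immutable gene symbol -> vector table with a fixed dimension."""

    def __init__(self, symbols: list[str], matrix: np.ndarray, case_insensitive: bool = False):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(symbols):
            raise ValueError("matrix must be (n_symbols, dim)")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("embedding vectors must be finite")
        seen: set[str] = set()
        for s in symbols:
            if not s:
                raise ValueError("empty gene symbol in embedding table")
            if s in seen:
                raise ValueError(f"duplicate symbol in embedding table: {s}")
            seen.add(s)
        self._symbols = list(symbols)
        self._matrix = matrix
        self._matrix.setflags(write=False)
        self._index = {s: i for i, s in enumerate(symbols)}
        self._case_insensitive = case_insensitive
        if case_insensitive:
            self._lower_index: dict[str, int] = {}
            for i, s in enumerate(symbols):
                self._lower_index.setdefault(s.lower(), i)

    @property
    def dim(self) -> int:
        return self._matrix.shape[1]

    @property
    def symbols(self) -> list[str]:
        return list(self._symbols)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def __len__(self) -> int:
        return len(self._symbols)

    def __contains__(self, symbol: str) -> bool:
        if symbol in self._index:
            return True
        return self._case_insensitive and symbol.lower() in self._lower_index

    def vector(self, symbol: str) -> np.ndarray:
        i = self._index.get(symbol)
        if i is None and self._case_insensitive:
            i = self._lower_index.get(symbol.lower())
        if i is None:
            raise KeyError(f"missing embedding: {symbol}")
        return self._matrix[i]

    def checksum(self) -> str:
        """SHA-256 over symbols and vector bytes; stable frozen-table fingerprint."""
        h = hashlib.sha256()
        for s in self._symbols:
            h.update(s.encode())
            h.update(b"\0")
        h.update(np.ascontiguousarray(self._matrix).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix.lower() == ".npz":
            np.savez_compressed(path, symbols=np.array(self._symbols), matrix=self._matrix)
        elif path.suffix.lower() == ".csv":
            header = "gene," + ",".join(f"e{i + 1}" for i in range(self.dim))
            with open(path, "w") as fh:
                fh.write(header + "\n")
                for s, row in zip(self._symbols, self._matrix):
                    fh.write(s + "," + ",".join(repr(float(v)) for v in row) + "\n")
        else:
            raise ValueError(f"unsupported embedding format: {path.name}")


def load_embeddings(path: str | Path, case_insensitive: bool = False) -> EmbeddingTable:
    """Load an embedding table from CSV (``gene,e1,...,edim``) or NPZ.

    The dimension is inferred from the data; ragged rows, non-numeric
    entries and duplicate symbols are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npz":
        with np.load(path, allow_pickle=False) as z:
            symbols = [str(s) for s in z["symbols"]]
            matrix = np.asarray(z["matrix"], dtype=np.float64)
        return EmbeddingTable(symbols, matrix, case_insensitive)
    if path.suffix.lower() == ".csv":
        symbols: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            first = fh.readline()
            # header optional: skip if the numeric fields don't parse
            if first.strip():
                parts = first.strip().split(",")
                try:
                    rows.append([float(v) for v in parts[1:]])
                    symbols.append(parts[0])
                except ValueError:
                    pass
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.strip().split(",")
                try:
                    rows.append([float(v) for v in parts[1:]])
                except ValueError as exc:
                    raise ValueError(f"non-numeric entry at line {lineno} of {path.name}") from exc
                symbols.append(parts[0])
        if not rows:
            raise ValueError(f"no embedding rows in {path.name}")
        dim = len(rows[0])
        for s, r in zip(symbols, rows):
            if len(r) != dim:
                raise ValueError(f"ragged embedding row for symbol {s}: {len(r)} != {dim}")
        return EmbeddingTable(symbols, np.array(rows, dtype=np.float64), case_insensitive)
    raise ValueError(f"unsupported embedding format: {path.name}")


def embed_perturbation(table: EmbeddingTable, p: PerturbationLabel | str) -> np.ndarray:
    """Embedding of a perturbation: the gene's vector, or the sum for a pair.

    Summation makes the composition symmetric and linear:
    ``embed({A,B}) == embed({A}) + embed({B})``.
    """
    if isinstance(p, str):
        p = parse_label(p)
    if p.is_control:
        raise ValueError("control has no perturbation embedding")
    missing = [g for g in p.targets if g not in table]
    if missing:
        raise KeyError("missing embedding: " + ", ".join(missing))
    vec = table.vector(p.targets[0]).copy()
    for g in p.targets[1:]:
        vec += table.vector(g)
    return vec


def coverage_report(table: EmbeddingTable, dataset: PerturbDataset) -> list[tuple[str, bool]]:
    """For each dataset perturbation, whether all of its targets are in the table."""
    report = []
    for pert in dataset.perturbations():
        targets = parse_label(pert).targets
        report.append((pert, all(g in table for g in targets)))
    return report
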
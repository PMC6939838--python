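"""Symmetric pairwise sketch-distance matrix over a sequence collection."""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sketch import Sketch, sketch_distance

__all__ = ["DistanceMatrix", "build_distance_matrix", "save_matrix", "load_matrix"]


@dataclass
class DistanceMatrix:
    """n×n matrix of pairwise sketch distances; zero diagonal, exact symmetry."""

    d: np.ndarray
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != self.d.shape[0]:
            raise ValueError("label count does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def validate(self) -> None:
        if not np.array_equal(np.diag(self.d), np.zeros(self.n)):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if not np.array_equal(self.d, self.d.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if self.d.min() < 0 or self.d.max() > 1.0:
            raise ValueError("distances must lie in [0, 1]")


def build_distance_matrix(
    sketches: Sequence[Sketch], workers: int = 1
) -> DistanceMatrix:
    """Compute all pairwise sketch distances (upper triangle, mirrored).

    The result is identical for any ``workers`` count; parallelism only
    splits the row loop.
    """
    n = len(sketches)
    if n < 1:
        raise ValueError("need at least one sketch")
    ref = sketches[0]
    for i, s in enumerate(sketches):
        if (s.k, s.q, s.seed) != (ref.k, ref.q, ref.seed):
            raise ValueError(
                f"sketch parameter mismatch between index 0 and index {i}: "
                f"({ref.k},{ref.q},{ref.seed}) vs ({s.k},{s.q},{s.seed})"
            )
    d = np.zeros((n, n), dtype=float)

    def fill_row(i: int) -> None:
        for j in range(i + 1, n):
            if len(sketches[i]) == 0 and len(sketches[j]) == 0:
                # nothing known about either sequence: place at the cap
                d[i, j] = 1.0
            else:
                d[i, j] = sketch_distance(sketches[i], sketches[j])

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(fill_row, range(n)))
    else:
        for i in range(n):
            fill_row(i)
    d = d + d.T
    labels = tuple(s.name or str(i) for i, s in enumerate(sketches))
    return DistanceMatrix(
        d=d, labels=labels, meta={"k": ref.k, "q": ref.q, "seed": ref.seed}
    )


def save_matrix(m: DistanceMatrix, path: str | Path) -> None:
    """Plain-text TSV dump: one header comment line, labels, then rows."""
    meta = m.meta
    lines = [
        "# n=%d k=%s q=%s seed=%s"
        % (m.n, meta.get("k", "-"), meta.get("q", "-"), meta.get("seed", "-")),
        "\t".join(m.labels),
    ]
    for row in m.d:
        lines.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_matrix(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: not an eccomp distance-matrix file")
    meta: dict = {}
    for tok in lines[0][1:].split():
        key, _, val = tok.partition("=")
        if val not in ("", "-"):
            meta[key] = int(val)
    labels = tuple(lines[1].split("\t"))
    d = np.array([[float(v) for v in line.split("\t")] for line in lines[2:]])
    meta.pop("n", None)
    return DistanceMatrix(d=d, labels=labels, meta=meta)
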
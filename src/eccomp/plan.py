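"""Two-level reference assignment: cluster medoids as references, plus one
final root reference R (the medoid of the medoids).

The reference graph is a tree of depth at most 2 rooted at R: every
non-medoid sequence points at its cluster medoid, every medoid except R
points at R, and R is the only sequence stored without a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import Clustering
from .distmatrix import DistanceMatrix

__all__ = [
    "CompressionPlan",
    "select_final_reference",
    "build_compression_plan",
    "fixed_reference_plan",
    "save_plan",
    "load_plan",
]


@dataclass
class CompressionPlan:
    """Per-sequence reference assignment (a depth-≤2 tree rooted at ``root``).

    ``ref_of`` maps every non-root sequence index to its reference index;
    ``levels`` maps every index to its depth (root 0, cluster references 1,
    members 2).
    """

    n: int
    root: int
    ref_of: dict[int, int]
    levels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.levels:
            self.levels = {self.root: 0}
            for i, r in self.ref_of.items():
                self.levels[i] = 1 if r == self.root else 2
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.root < self.n:
            raise ValueError("root index out of range")
        if self.root in self.ref_of:
            raise ValueError("root must not have a reference")
        if len(self.ref_of) != self.n - 1:
            raise ValueError(
                f"plan must cover n-1 = {self.n - 1} sequences, got {len(self.ref_of)}"
            )
        for i, r in self.ref_of.items():
            if not 0 <= r < self.n or r == i:
                raise ValueError(f"invalid reference {r} for sequence {i}")
            depth, node = 0, i
            while node != self.root:
                node = self.ref_of[node]
                depth += 1
                if depth > 2:
                    raise ValueError(f"reference chain of {i} exceeds depth 2")
        if self.levels[self.root] != 0:
            raise ValueError("root level must be 0")

    def decompression_order(self) -> list[int]:
        """Root first, then level-1 references, then members."""
        return sorted(range(self.n), key=lambda i: (self.levels[i], i))


def select_final_reference(
    m: DistanceMatrix | np.ndarray, centroids: list[int] | np.ndarray
) -> int:
    """The medoid of the centroid set: argmin_i Σ_j d(O_i, O_j), ties → lowest.

    The zero self-term is included in each sum (it cannot change the argmin).
    """
    d = m.d if isinstance(m, DistanceMatrix) else np.asarray(m, dtype=float)
    cent = np.array(sorted(int(c) for c in centroids), dtype=int)
    if cent.size == 0:
        raise ValueError("empty centroid list")
    sums = d[np.ix_(cent, cent)].sum(axis=1)
    return int(cent[np.argmin(sums)])


def build_compression_plan(c: Clustering, root: int) -> CompressionPlan:
    """Members → their cluster medoid; medoids (except ``root``) → ``root``."""
    centroids = set(int(x) for x in c.centroids)
    if root not in centroids:
        raise ValueError(f"root {root} is not a cluster centroid")
    ref_of: dict[int, int] = {}
    levels: dict[int, int] = {root: 0}
    for j in range(c.K):
        medoid = int(c.centroids[j])
        if medoid != root:
            ref_of[medoid] = root
            levels[medoid] = 1
        for i in c.members(j):
            i = int(i)
            if i != medoid:
                ref_of[i] = medoid
                levels[i] = 2
    return CompressionPlan(n=c.n, root=root, ref_of=ref_of, levels=levels)


def fixed_reference_plan(n: int, ref: int) -> CompressionPlan:
    """Single-reference baseline: every other sequence points at ``ref``."""
    if not 0 <= ref < n:
        raise ValueError("reference index out of range")
    return CompressionPlan(
        n=n, root=ref, ref_of={i: ref for i in range(n) if i != ref}
    )


def save_plan(plan: CompressionPlan, path: str | Path, labels=None) -> None:
    """Edge-list TSV dump: index, label, reference index ('-' for root), level."""
    lines = ["index\tlabel\treference\tlevel"]
    for i in range(plan.n):
        label = labels[i] if labels is not None else str(i)
        ref = plan.ref_of.get(i)
        lines.append(
            f"{i}\t{label}\t{'-' if ref is None else ref}\t{plan.levels[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_plan(path: str | Path) -> CompressionPlan:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("index\t"):
        raise ValueError(f"{path}: not an eccomp plan file")
    ref_of: dict[int, int] = {}
    levels: dict[int, int] = {}
    root = None
    for line in lines[1:]:
        idx_s, _label, ref_s, level_s = line.split("\t")
        idx = int(idx_s)
        levels[idx] = int(level_s)
        if ref_s == "-":
            root = idx
        else:
            ref_of[idx] = int(ref_s)
    if root is None:
        raise ValueError(f"{path}: plan has no root entry")
    return CompressionPlan(n=len(levels), root=root, ref_of=ref_of, levels=levels)
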
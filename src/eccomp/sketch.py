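"""Bottom-q MinHash sketches of nucleotide sequences and sketch distances.

A sequence is reduced to the set of its canonical k-mers (lexicographic
minimum of each A/C/G/T window and its reverse complement; windows with any
other character are skipped), each k-mer is mapped to a 64-bit hash, and the
q smallest distinct hash values form the sketch.  Two sketches give a
Jaccard estimate

    J'(A, B) = |Sk(A ∪ B, q) ∩ Sk(A, q) ∩ Sk(B, q)| / |Sk(A ∪ B, q)|

which is turned into an evolutionary-distance proxy

    d(A, B) = −(1/k) · ln( 2 J' / (1 + J') ),

capped at ``D_MAX`` = 1.0 (the transform diverges as J' → 0; disjoint
sketches are assigned the cap directly).

Hashing is a splitmix64 finalizer over the 2-bit packing of the canonical
k-mer, salted with a user seed.  The finalizer is a bijection on 64-bit
words, so distinct k-mers of the same length can never collide for k ≤ 31;
longer k-mers fall back to a keyed blake2b hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .fasta_io import SequenceRecord

__all__ = [
    "Sketch",
    "extract_kmers",
    "hash_kmer",
    "build_sketch",
    "jaccard_estimate",
    "sketch_distance",
    "DEFAULT_K",
    "DEFAULT_Q",
    "DEFAULT_SEED",
    "D_MAX",
]

DEFAULT_K = 21
DEFAULT_Q = 1000
DEFAULT_SEED = 42
D_MAX = 1.0

_MASK64 = (1 << 64) - 1
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i


def _mix64(x: int) -> int:
    """splitmix64 finalizer (pure-Python ints)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _mix64_np(a: np.ndarray) -> np.ndarray:
    a = (a + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    a = (a ^ (a >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    a = (a ^ (a >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return a ^ (a >> np.uint64(31))


def _salt(k: int, seed: int) -> int:
    return _mix64(((seed & _MASK64) << 8 | (k & 0xFF)) & _MASK64)


def extract_kmers(residues: str, k: int) -> Iterator[str]:
    """Yield the canonical k-mer of every valid window (duplicates included).

    Windows containing characters outside {A, C, G, T} after uppercasing are
    skipped; a sequence shorter than k yields nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = residues.upper()
    acgt = frozenset("ACGT")
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if set(w) <= acgt:
            rc = w.translate(_COMPLEMENT)[::-1]
            yield min(w, rc)


def hash_kmer(kmer: str, seed: int) -> int:
    """Deterministic 64-bit hash of a k-mer string under ``seed``.

    The k-mer is hashed as given (callers canonicalize first).
    """
    if not kmer:
        raise ValueError("empty k-mer")
    k = len(kmer)
    salt = _salt(k, seed)
    up = kmer.upper()
    if k <= 31 and set(up) <= frozenset("ACGT"):
        packed = 0
        for ch in up:
            packed = (packed << 2) | int(_CODES[ord(ch)])
        return _mix64(packed ^ salt)
    digest = hashlib.blake2b(
        up.encode("ascii"), digest_size=8, key=salt.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "little")


@dataclass(eq=False)
class Sketch:
    """Bottom-q sketch: the q smallest distinct canonical-k-mer hash values."""

    k: int
    q: int
    seed: int
    hashes: np.ndarray  # uint64, strictly ascending
    n_kmers: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > self.q:
            raise ValueError("sketch larger than its capacity q")
        if self.hashes.size > 1 and not np.all(self.hashes[1:] > self.hashes[:-1]):
            raise ValueError("sketch hashes must be strictly ascending")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.k == other.k
            and self.q == other.q
            and self.seed == other.seed
            and np.array_equal(self.hashes, other.hashes)
        )

    def __len__(self) -> int:
        return int(self.hashes.size)

    # -- sidecar serialization -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "q": self.q,
            "seed": self.seed,
            "n_kmers": self.n_kmers,
            "name": self.name,
            "hashes": [format(int(h), "016x") for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(
            k=d["k"],
            q=d["q"],
            seed=d["seed"],
            n_kmers=d.get("n_kmers", 0),
            name=d.get("name", ""),
            hashes=np.array([int(h, 16) for h in d["hashes"]], dtype=np.uint64),
        )


def _canonical_packed(residues: str, k: int) -> np.ndarray:
    """2-bit packings of the canonical k-mers of all valid windows (k <= 31)."""
    data = np.frombuffer(residues.upper().encode("latin-1"), dtype=np.uint8)
    if data.size < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODES[data]
    invalid = codes == 255
    w = data.size - k + 1
    fwd = np.zeros(w, dtype=np.uint64)
    rc = np.zeros(w, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for t in range(k):
        chunk = c64[t : t + w]
        fwd = (fwd << np.uint64(2)) | chunk
        rc = rc | ((np.uint64(3) - chunk) << np.uint64(2 * t))
    cs = np.concatenate(([0], np.cumsum(invalid)))
    valid = (cs[k:] - cs[:-k]) == 0
    return np.minimum(fwd, rc)[valid]


def build_sketch(
    record: SequenceRecord | str,
    k: int = DEFAULT_K,
    q: int = DEFAULT_Q,
    seed: int = DEFAULT_SEED,
) -> Sketch:
    """Sketch a sequence: the q smallest distinct canonical-k-mer hashes.

    A sequence yielding zero valid k-mers produces an empty sketch and a
    warning (it cannot be placed by distance).
    """
    if k < 1 or q < 1:
        raise ValueError("k and q must be >= 1")
    residues = record.residues if isinstance(record, SequenceRecord) else record
    name = record.id if isinstance(record, SequenceRecord) else ""
    salt = np.uint64(_salt(k, seed))
    if k <= 31:
        packed = np.unique(_canonical_packed(residues, k))
        hashes = np.sort(_mix64_np(packed ^ salt))
    else:
        hs = {hash_kmer(km, seed) for km in extract_kmers(residues, k)}
        hashes = np.sort(np.array(sorted(hs), dtype=np.uint64))
    n_kmers = int(hashes.size)
    if n_kmers == 0:
        warnings.warn(
            f"sequence {name or '<unnamed>'!r} yields no valid k-mers at k={k}; "
            "its sketch is empty",
            stacklevel=2,
        )
    return Sketch(k=k, q=q, seed=seed, hashes=hashes[:q], n_kmers=n_kmers, name=name)


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if (a.k, a.q, a.seed) != (b.k, b.q, b.seed):
        raise ValueError(
            f"incompatible sketches: (k,q,seed)=({a.k},{a.q},{a.seed}) vs "
            f"({b.k},{b.q},{b.seed})"
        )


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Sketch-based Jaccard estimate J'(A, B) in [0, 1].

    The denominator is the merged bottom-q sketch (its actual length when
    the union holds fewer than q values).  Raises if both sketches are empty.
    """
    _check_compatible(a, b)
    if len(a) == 0 and len(b) == 0:
        raise ValueError("empty sketch comparison: both sketches have no k-mers")
    merged = np.union1d(a.hashes, b.hashes)[: a.q]
    inter = np.intersect1d(
        np.intersect1d(merged, a.hashes, assume_unique=True),
        b.hashes,
        assume_unique=True,
    )
    return float(inter.size) / float(merged.size)


def sketch_distance(a: Sketch, b: Sketch) -> float:
    """Mash-style distance −(1/k)·ln(2J'/(1+J')), capped at ``D_MAX``.

    Identical sketches give exactly 0; disjoint sketches give the cap.
    """
    j = jaccard_estimate(a, b)
    if j == 0.0:
        return D_MAX
    if j == 1.0:
        return 0.0
    d = -(1.0 / a.k) * float(np.log(2.0 * j / (1.0 + j)))
    return min(D_MAX, d)


def save_sketches(sketches: list[Sketch], path: str | Path) -> None:
    payload = {"format": "eccomp-sketches", "sketches": [s.to_dict() for s in sketches]}
    Path(path).write_text(json.dumps(payload))


def load_sketches(path: str | Path) -> list[Sketch]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "eccomp-sketches":
        raise ValueError(f"{path}: not an eccomp sketch file")
    return [Sketch.from_dict(d) for d in payload["sketches"]]
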
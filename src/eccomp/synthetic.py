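"""Deterministic synthetic sequence families for testing and evaluation.

Families are built by drawing one i.i.d. uniform A/C/G/T ancestor per
family and mutating it independently per member with per-base substitution
(always to a different base) and single-base insertion/deletion events.
Independent 10 kb ancestors share essentially no 21-mers, so between-family
sketch distances sit at the cap while within-family distances stay near
the mutation divergence — the regime the clustering stage is built for.

Every operation draws from its own random stream derived from
(seed, operation tag, indices), so regenerating one member never perturbs
another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .fasta_io import SequenceRecord

__all__ = ["FamilySpec", "generate_ancestor", "mutate", "generate_dataset"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, tag: str, *indices: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode()), *indices])


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the regime the package targets: a handful of small
    families of closely related 10 kb sequences (within-family substitution
    rate 0.002/base with light single-base indels).
    """

    n_families: int = 3
    members_per_family: int = 4
    ancestor_length: int = 10_000
    sub_rate: float = 0.002
    ins_rate: float = 0.0005
    del_rate: float = 0.0005
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= rate < 0.5:
                raise ValueError("mutation rates must lie in [0, 0.5)")
        if self.ancestor_length < 1 and self.members_per_family > 0:
            raise ValueError("ancestor_length must be >= 1")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member")


def generate_ancestor(length: int, seed: int, *indices: int) -> SequenceRecord:
    """Uniform random A/C/G/T sequence of ``length`` bases; deterministic per seed."""
    rng = _rng(seed, "ancestor", *indices)
    residues = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    name = "ancestor" + ("_" + "_".join(map(str, indices)) if indices else "")
    return SequenceRecord.new(name, residues)


def mutate(
    ancestor: SequenceRecord,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    seed: int,
    *indices: int,
    name: str | None = None,
) -> SequenceRecord:
    """Independent per-position substitution / insertion / deletion draws.

    Substitutions always change the base; indels are single-base events
    (an insertion lands before the corresponding position; one extra slot
    covers appending at the end).
    """
    rng = _rng(seed, "mutate", *indices)
    codes = np.frombuffer(ancestor.residues.encode("ascii"), dtype=np.uint8)
    base_idx = np.searchsorted(_BASES, codes)
    L = codes.size

    sub_mask = rng.random(L) < sub_rate
    shifts = rng.integers(1, 4, size=L)
    mutated = np.where(sub_mask, (base_idx + shifts) % 4, base_idx)

    keep = rng.random(L) >= del_rate
    ins_mask = rng.random(L + 1) < ins_rate
    ins_bases = rng.integers(0, 4, size=L + 1)

    pieces: list[np.ndarray] = []
    ins_positions = np.flatnonzero(ins_mask)
    cursor = 0
    for p in ins_positions:
        seg = mutated[cursor:p][keep[cursor:p]]
        pieces.append(seg)
        pieces.append(np.array([ins_bases[p]], dtype=mutated.dtype))
        cursor = p
    pieces.append(mutated[cursor:][keep[cursor:]])
    out = _BASES[np.concatenate(pieces)] if pieces else np.empty(0, np.uint8)
    return SequenceRecord.new(
        name or (ancestor.id + "_mut"), out.tobytes().decode("ascii")
    )


def generate_dataset(spec: FamilySpec) -> tuple[list[SequenceRecord], list[int]]:
    """``n_families`` independent ancestors, each mutated ``members_per_family``
    times; returns the member records and their ground-truth family labels."""
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for f in range(spec.n_families):
        ancestor = generate_ancestor(spec.ancestor_length, spec.seed, f)
        for m in range(spec.members_per_family):
            rec = mutate(
                ancestor,
                spec.sub_rate,
                spec.ins_rate,
                spec.del_rate,
                spec.seed,
                f,
                m,
                name=f"fam{f}_member{m}",
            )
            records.append(rec)
            labels.append(f)
    return records, labels


def write_labels(labels: list[int], records: list[SequenceRecord], path) -> None:
    from pathlib import Path

    lines = ["index\tid\tfamily"]
    for i, (rec, lab) in enumerate(zip(records, labels)):
        lines.append(f"{i}\t{rec.id}\t{lab}")
    Path(path).write_text("\n".join(lines) + "\n")
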
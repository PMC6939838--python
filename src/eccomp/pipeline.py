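"""End-to-end pipeline: FASTA → sketches → distance matrix → clustering →
reference plan → archive, plus the fixed-reference baseline used for gain
evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from . import sketch as _sketch
from .archive import Archive, read_archive, write_archive
from .cluster import (
    DEFAULT_EPSILON,
    DEFAULT_MAX_ITER,
    Clustering,
    SubtractiveResult,
    kmedoids,
    subtractive_centroids,
)
from .codec import CodecConfig, compress_collection, decompress_collection
from .distmatrix import DistanceMatrix, build_distance_matrix
from .fasta_io import SequenceRecord, read_fasta, records_to_bytes, write_fasta
from .metrics import GainReport, compression_ratio
from .plan import (
    CompressionPlan,
    build_compression_plan,
    fixed_reference_plan,
    select_final_reference,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "sketch_records",
    "cluster_records",
    "plan_records",
    "compress_records",
    "compress_file",
    "decompress_file",
    "evaluate_records",
    "worst_reference_index",
    "best_reference_index",
]

log = logging.getLogger("eccomp")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables; serializable as a flat key=value file."""

    k: int = _sketch.DEFAULT_K
    q: int = _sketch.DEFAULT_Q
    seed: int = _sketch.DEFAULT_SEED
    epsilon: float = DEFAULT_EPSILON
    max_iter: int = DEFAULT_MAX_ITER
    min_match: int = 24
    index_k: int = 16
    backend: str = "bz2"
    workers: int = 1

    def codec(self) -> CodecConfig:
        return CodecConfig(
            min_match=self.min_match, index_k=self.index_k, backend=self.backend
        )

    def params(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{k}={v}\n" for k, v in self.params().items())
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        types = {f.name: f.type for f in fields(cls)}
        updates = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, val = line.partition("=")
            key = key.strip()
            if not sep or key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config entry {line!r}")
            current = getattr(cfg, key)
            updates[key] = type(current)(val.strip())
        return replace(cfg, **updates)


@dataclass
class PipelineResult:
    archive: Archive
    matrix: DistanceMatrix | None = None
    seeds: SubtractiveResult | None = None
    clustering: Clustering | None = None
    plan: CompressionPlan | None = None


def sketch_records(records: list[SequenceRecord], cfg: RunConfig) -> list[_sketch.Sketch]:
    return [_sketch.build_sketch(r, k=cfg.k, q=cfg.q, seed=cfg.seed) for r in records]


def cluster_records(
    records: list[SequenceRecord], cfg: RunConfig
) -> tuple[DistanceMatrix, SubtractiveResult, Clustering]:
    sketches = sketch_records(records, cfg)
    matrix = build_distance_matrix(sketches, workers=cfg.workers)
    seeds = subtractive_centroids(matrix, epsilon=cfg.epsilon)
    clustering = kmedoids(matrix, seeds, max_iter=cfg.max_iter)
    log.info(
        "clustered n=%d into K=%d (cost %.6f, %d iterations)",
        matrix.n,
        clustering.K,
        clustering.cost,
        clustering.iterations,
    )
    return matrix, seeds, clustering


def plan_records(
    records: list[SequenceRecord], cfg: RunConfig
) -> tuple[CompressionPlan, DistanceMatrix | None, SubtractiveResult | None, Clustering | None]:
    if len(records) == 1:
        log.warning("single-sequence input: archive holds only the root sequence")
        return CompressionPlan(n=1, root=0, ref_of={}), None, None, None
    matrix, seeds, clustering = cluster_records(records, cfg)
    root = select_final_reference(matrix, list(clustering.centroids))
    plan = build_compression_plan(clustering, root)
    return plan, matrix, seeds, clustering


def compress_records(
    records: list[SequenceRecord], cfg: RunConfig = RunConfig()
) -> PipelineResult:
    """Run the full pipeline on in-memory records."""
    plan, matrix, seeds, clustering = plan_records(records, cfg)
    archive = compress_collection(records, plan, cfg.codec(), params=cfg.params())
    return PipelineResult(
        archive=archive, matrix=matrix, seeds=seeds, clustering=clustering, plan=plan
    )


def compress_file(
    in_path: str | Path, out_path: str | Path, cfg: RunConfig = RunConfig()
) -> PipelineResult:
    records = read_fasta(in_path)
    log.info("read %d sequences from %s", len(records), in_path)
    result = compress_records(records, cfg)
    write_archive(result.archive, out_path)
    original = Path(in_path).stat().st_size
    compressed = Path(out_path).stat().st_size
    log.info(
        "wrote %s: %d -> %d bytes (%.2f folds)",
        out_path,
        original,
        compressed,
        compression_ratio(original, compressed),
    )
    return result


def decompress_file(archive_path: str | Path, out_path: str | Path) -> list[SequenceRecord]:
    archive = read_archive(archive_path)
    records = decompress_collection(archive)
    write_fasta(records, out_path)
    log.info("restored %d sequences to %s", len(records), out_path)
    return records


def worst_reference_index(matrix: DistanceMatrix) -> int:
    """The sequence maximizing its distance-row sum (most isolated choice)."""
    sums = matrix.d.sum(axis=1)
    return int(np.argmax(sums))


def best_reference_index(matrix: DistanceMatrix) -> int:
    """The global medoid (minimum row sum): the kindest single reference."""
    sums = matrix.d.sum(axis=1)
    return int(np.argmin(sums))


def _archive_bytes(archive: Archive, scratch: Path) -> int:
    path = scratch / "eval.ecc"
    write_archive(archive, path)
    return path.stat().st_size


def evaluate_records(
    records: list[SequenceRecord],
    cfg: RunConfig = RunConfig(),
    references: str | list[int] = "worst",
    scratch: str | Path | None = None,
) -> list[GainReport]:
    """Compare the clustered plan against fixed single references.

    ``references`` may be ``'worst'``, ``'best'``, ``'all'`` or a list of
    sequence indices.  Ratios are raw input FASTA bytes over archive file
    bytes for both modes.
    """
    import tempfile

    if len(records) < 2:
        raise ValueError("evaluation needs at least two sequences")
    original = len(records_to_bytes(records))
    plan, matrix, _seeds, clustering = plan_records(records, cfg)
    assert matrix is not None and clustering is not None
    if isinstance(references, str):
        if references == "worst":
            ref_list = [worst_reference_index(matrix)]
        elif references == "best":
            ref_list = [best_reference_index(matrix)]
        elif references == "all":
            ref_list = list(range(len(records)))
        else:
            raise ValueError(f"unknown reference mode {references!r}")
    else:
        ref_list = list(references)

    with tempfile.TemporaryDirectory(dir=scratch) as tmp:
        tmpdir = Path(tmp)
        ecc_archive = compress_collection(records, plan, cfg.codec(), cfg.params())
        c_e = compression_ratio(original, _archive_bytes(ecc_archive, tmpdir))
        reports = []
        for ref in ref_list:
            fixed = compress_collection(
                records, fixed_reference_plan(len(records), ref), cfg.codec(), cfg.params()
            )
            c_s = compression_ratio(original, _archive_bytes(fixed, tmpdir))
            reports.append(
                GainReport(reference_label=records[ref].id or str(ref), c_s=c_s, c_e=c_e)
            )
    return reports
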
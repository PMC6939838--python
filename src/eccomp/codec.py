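"""Lossless built-in codecs: reference-based match/literal streams and a
reference-free fallback for the root sequence.

The reference-based codec is a greedy LZ-style parser.  A hash index of all
``index_k``-mers of the reference is built; at each target position the
anchor k-mer is looked up, every candidate hit is extended maximally
forward and backward (backward extension may consume pending literal
characters), and the longest extension — ties to the smallest reference
position — is emitted as a MATCH(ref_pos, length) token when it reaches
``min_match``; otherwise the position joins the pending LITERAL.  Adjacent
literals are merged by construction, positions are absolute and 0-based,
exactly as in the classic "102 72" position/length encoding.

Serialized stream layout (before the entropy backend), all integers
LEB128 varints:

    varint meta_len | meta JSON (record layout metadata)
    16-byte reference digest (reference-based payloads only)
    varint target_len
    tokens:  0x00 varint(len) bytes...   literal
             0x01 varint(pos) varint(len)  match

The whole stream is then passed through a general-purpose byte compressor
(``bz2`` by default — a block-sorting codec — or ``zlib``).  Matching is
byte-exact on the raw residues, so case and ambiguity codes survive.
"""

from __future__ import annotations

import bz2
import hashlib
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

from .fasta_io import SequenceRecord, record_digest
from .plan import CompressionPlan
from .archive import Archive

__all__ = [
    "Token",
    "CodecConfig",
    "tokenize",
    "compress_against_reference",
    "decompress_against_reference",
    "compress_reference_free",
    "decompress_reference_free",
    "compress_collection",
    "decompress_collection",
    "external_backend_export",
    "import_manifest",
]

_MAX_ANCHOR_OCC = 64  # candidate positions kept per anchor k-mer

_BACKENDS = {
    "bz2": (lambda b: bz2.compress(b, 9), bz2.decompress),
    "zlib": (lambda b: zlib.compress(b, 9), zlib.decompress),
}


@dataclass(frozen=True)
class CodecConfig:
    """Tunables of the built-in codec.

    ``min_match`` is the shortest run worth a MATCH token; ``index_k`` the
    anchor k-mer length of the reference index; ``backend`` the entropy
    coder applied to serialized streams.
    """

    min_match: int = 24
    index_k: int = 16
    backend: str = "bz2"

    def __post_init__(self) -> None:
        if not self.min_match >= self.index_k >= 4:
            raise ValueError("require min_match >= index_k >= 4")
        if self.backend not in _BACKENDS:
            raise ValueError(f"unknown entropy backend {self.backend!r}")


@dataclass(frozen=True)
class Token:
    kind: str  # "M" or "L"
    pos: int = 0
    length: int = 0
    literal: bytes = b""


def _write_varint(out: bytearray, value: int) -> None:
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    result = shift = 0
    while True:
        if pos >= len(data):
            raise ValueError("malformed payload: truncated varint")
        byte = data[pos]
        pos += 1
        result |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return result, pos
        shift += 7


def _residue_digest(residues: bytes) -> bytes:
    return hashlib.blake2b(residues, digest_size=16).digest()


def _build_index(reference: bytes, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    for i in range(len(reference) - k + 1):
        hits = index.setdefault(reference[i : i + k], [])
        if len(hits) < _MAX_ANCHOR_OCC:
            hits.append(i)
    return index


def tokenize(target: bytes, reference: bytes, cfg: CodecConfig) -> list[Token]:
    """Greedy left-to-right match/literal parse of ``target`` against ``reference``."""
    tokens: list[Token] = []
    n, nref, ik = len(target), len(reference), cfg.index_k
    index = _build_index(reference, ik) if nref >= ik else {}
    pos = lit_start = 0
    while pos < n:
        best_len = 0
        best_start = -1
        best_back = 0
        if pos + ik <= n:
            for rp in index.get(target[pos : pos + ik], ()):
                f = ik
                while pos + f < n and rp + f < nref and target[pos + f] == reference[rp + f]:
                    f += 1
                b = 0
                while (
                    b < pos - lit_start
                    and rp - b - 1 >= 0
                    and target[pos - b - 1] == reference[rp - b - 1]
                ):
                    b += 1
                total = f + b
                if total > best_len or (total == best_len and rp - b < best_start):
                    best_len, best_start, best_back = total, rp - b, b
        if best_len >= cfg.min_match:
            if pos - best_back > lit_start:
                tokens.append(Token("L", literal=target[lit_start : pos - best_back]))
            tokens.append(Token("M", pos=best_start, length=best_len))
            pos += best_len - best_back
            lit_start = pos
        else:
            pos += 1
    if lit_start < n:
        tokens.append(Token("L", literal=target[lit_start:]))
    return tokens


def _encode_tokens(tokens: list[Token]) -> bytes:
    out = bytearray()
    for tok in tokens:
        if tok.kind == "L":
            out.append(0x00)
            _write_varint(out, len(tok.literal))
            out += tok.literal
        else:
            out.append(0x01)
            _write_varint(out, tok.pos)
            _write_varint(out, tok.length)
    return bytes(out)


def _decode_tokens(data: bytes, pos: int, reference: bytes, out_len: int) -> bytes:
    out = bytearray()
    while len(out) < out_len:
        if pos >= len(data):
            raise ValueError("malformed payload: token stream ends early")
        tag = data[pos]
        pos += 1
        if tag == 0x00:
            ln, pos = _read_varint(data, pos)
            if pos + ln > len(data):
                raise ValueError("malformed payload: literal overruns stream")
            out += data[pos : pos + ln]
            pos += ln
        elif tag == 0x01:
            rp, pos = _read_varint(data, pos)
            ln, pos = _read_varint(data, pos)
            if rp + ln > len(reference):
                raise ValueError("malformed payload: match overruns the reference")
            out += reference[rp : rp + ln]
        else:
            raise ValueError(f"malformed payload: unknown token tag {tag:#x}")
    if len(out) != out_len or pos != len(data):
        raise ValueError("malformed payload: decoded length mismatch")
    return bytes(out)


def _meta_dict(rec: SequenceRecord) -> dict:
    return {
        "description": rec.description,
        "line_lengths": list(rec.line_lengths),
        "final_newline": rec.final_newline,
        "preamble": rec.preamble,
    }


def _record_from_meta(meta: dict, residues: str) -> SequenceRecord:
    return SequenceRecord(
        description=meta["description"],
        residues=residues,
        line_lengths=tuple(meta["line_lengths"]),
        final_newline=meta["final_newline"],
        preamble=meta["preamble"],
    )


def compress_against_reference(
    target: SequenceRecord, reference: SequenceRecord, cfg: CodecConfig = CodecConfig()
) -> bytes:
    """Encode ``target`` as a match/literal stream over ``reference``.

    The payload embeds the target's layout metadata and a digest of the
    reference residues so decompression can detect a wrong reference.
    """
    t = target.residues.encode("latin-1")
    r = reference.residues.encode("latin-1")
    raw = bytearray()
    meta = json.dumps(_meta_dict(target), sort_keys=True).encode("utf-8")
    _write_varint(raw, len(meta))
    raw += meta
    raw += _residue_digest(r)
    _write_varint(raw, len(t))
    raw += _encode_tokens(tokenize(t, r, cfg))
    return _BACKENDS[cfg.backend][0](bytes(raw))


def decompress_against_reference(
    payload: bytes, reference: SequenceRecord, cfg: CodecConfig = CodecConfig()
) -> SequenceRecord:
    """Exact inverse of :func:`compress_against_reference`."""
    raw = _BACKENDS[cfg.backend][1](payload)
    meta_len, pos = _read_varint(raw, 0)
    meta = json.loads(raw[pos : pos + meta_len].decode("utf-8"))
    pos += meta_len
    stored_digest = raw[pos : pos + 16]
    pos += 16
    r = reference.residues.encode("latin-1")
    if stored_digest != _residue_digest(r):
        raise ValueError(
            f"wrong reference: payload was not compressed against {reference.id!r}"
        )
    out_len, pos = _read_varint(raw, pos)
    residues = _decode_tokens(raw, pos, r, out_len)
    return _record_from_meta(meta, residues.decode("latin-1"))


def compress_reference_free(
    record: SequenceRecord, cfg: CodecConfig = CodecConfig()
) -> bytes:
    """Self-contained payload for the root sequence (no reference needed)."""
    raw = bytearray()
    meta = json.dumps(_meta_dict(record), sort_keys=True).encode("utf-8")
    _write_varint(raw, len(meta))
    raw += meta
    residues = record.residues.encode("latin-1")
    _write_varint(raw, len(residues))
    raw += residues
    return _BACKENDS[cfg.backend][0](bytes(raw))


def decompress_reference_free(
    payload: bytes, cfg: CodecConfig = CodecConfig()
) -> SequenceRecord:
    raw = _BACKENDS[cfg.backend][1](payload)
    meta_len, pos = _read_varint(raw, 0)
    meta = json.loads(raw[pos : pos + meta_len].decode("utf-8"))
    pos += meta_len
    out_len, pos = _read_varint(raw, pos)
    if pos + out_len != len(raw):
        raise ValueError("malformed payload: residue length mismatch")
    return _record_from_meta(meta, raw[pos:].decode("latin-1"))


def compress_collection(
    records: list[SequenceRecord],
    plan: CompressionPlan,
    cfg: CodecConfig = CodecConfig(),
    params: dict | None = None,
) -> Archive:
    """Compress a whole collection along a plan into an :class:`Archive`.

    The root is stored reference-free; everything else against its plan
    reference.  Per-sequence digests of the serialized records make any
    later corruption detectable.
    """
    if plan.n != len(records):
        raise ValueError("plan size does not match record count")
    all_params = {
        "min_match": cfg.min_match,
        "index_k": cfg.index_k,
        "backend": cfg.backend,
    }
    if params:
        all_params.update(params)
    payloads: dict[int, bytes] = {}
    for i, rec in enumerate(records):
        if i == plan.root:
            payloads[i] = compress_reference_free(rec, cfg)
        else:
            payloads[i] = compress_against_reference(rec, records[plan.ref_of[i]], cfg)
    checksums = {i: record_digest(rec) for i, rec in enumerate(records)}
    return Archive(
        params=all_params,
        root=plan.root,
        ref_of=dict(plan.ref_of),
        levels=dict(plan.levels),
        checksums=checksums,
        payloads=payloads,
    )


def decompress_collection(archive: Archive) -> list[SequenceRecord]:
    """Reconstruct all records byte-identically, in original order.

    Decompression follows the plan levels: root, then cluster references,
    then members.  Every record is checked against its stored digest; a
    mismatch aborts naming the offending sequence.
    """
    cfg = CodecConfig(
        min_match=archive.params.get("min_match", 24),
        index_k=archive.params.get("index_k", 16),
        backend=archive.params.get("backend", "bz2"),
    )
    plan = archive.plan()
    records: dict[int, SequenceRecord] = {}
    for i in plan.decompression_order():
        if i == plan.root:
            records[i] = decompress_reference_free(archive.payloads[i], cfg)
        else:
            records[i] = decompress_against_reference(
                archive.payloads[i], records[plan.ref_of[i]], cfg
            )
        if record_digest(records[i]) != archive.checksums[i]:
            raise ValueError(
                f"checksum mismatch for sequence {records[i].id!r} (index {i})"
            )
    return [records[i] for i in range(plan.n)]


def external_backend_export(
    records: list[SequenceRecord], plan: CompressionPlan, out_dir: str | Path
) -> Path:
    """Write per-cluster work orders so an external reference-based tool can
    be driven by the plan: one directory per cluster reference holding the
    reference and target FASTAs, plus a root FASTA and a ``manifest.tsv``.
    No compression is performed here.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .fasta_io import write_fasta

    write_fasta([records[plan.root]], out / "root.fasta")
    lines = ["index\tid\treference\tlevel"]
    refs = sorted({plan.ref_of[i] for i in plan.ref_of})
    for ref in refs:
        cdir = out / f"cluster_{ref}"
        cdir.mkdir(exist_ok=True)
        write_fasta([records[ref]], cdir / "reference.fasta")
        for i in sorted(i for i, r in plan.ref_of.items() if r == ref):
            write_fasta([records[i]], cdir / f"target_{i}.fasta")
    for i in range(plan.n):
        ref = plan.ref_of.get(i)
        lines.append(
            f"{i}\t{records[i].id}\t{'-' if ref is None else ref}\t{plan.levels[i]}"
        )
    (out / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return out / "manifest.tsv"


def import_manifest(manifest_path: str | Path) -> CompressionPlan:
    """Rebuild the :class:`CompressionPlan` encoded in a ``manifest.tsv``."""
    lines = Path(manifest_path).read_text().splitlines()
    if not lines or lines[0] != "index\tid\treference\tlevel":
        raise ValueError(f"{manifest_path}: not an eccomp manifest")
    ref_of: dict[int, int] = {}
    levels: dict[int, int] = {}
    root = None
    for line in lines[1:]:
        idx_s, _sid, ref_s, lvl_s = line.split("\t")
        idx = int(idx_s)
        levels[idx] = int(lvl_s)
        if ref_s == "-":
            root = idx
        else:
            ref_of[idx] = int(ref_s)
    if root is None:
        raise ValueError(f"{manifest_path}: manifest has no root entry")
    return CompressionPlan(n=len(levels), root=root, ref_of=ref_of, levels=levels)
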
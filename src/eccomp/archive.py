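"""The ``.ecc`` archive container.

Single-file little-endian layout:

    bytes 0..3   magic ``ECC1``
    bytes 4..5   format version, uint16 LE
    bytes 6..9   compressed-header length H, uint32 LE
    H bytes      bz2-compressed JSON header (params, plan, checksums,
                 payload index: list of [sequence index, payload length])
    remainder    payload blobs, concatenated in payload-index order

Exactly one sequence (the final reference R) is stored reference-free;
``n − 1`` entries carry token-stream payloads.  Any trailing bytes,
truncation or version mismatch is rejected on read; per-sequence digests
in the header make silent corruption detectable at decompression.
"""

from __future__ import annotations

import bz2
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["Archive", "write_archive", "read_archive", "MAGIC", "FORMAT_VERSION"]

MAGIC = b"ECC1"
FORMAT_VERSION = 1


@dataclass
class Archive:
    """In-memory archive: parameters, reference plan, digests and payloads."""

    params: dict
    root: int
    ref_of: dict[int, int]
    levels: dict[int, int]
    checksums: dict[int, str]
    payloads: dict[int, bytes]
    version: int = FORMAT_VERSION

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.payloads)

    @property
    def root_payload(self) -> bytes:
        return self.payloads[self.root]

    @property
    def entries(self) -> dict[int, bytes]:
        """Payloads of the n − 1 reference-compressed sequences."""
        return {i: p for i, p in self.payloads.items() if i != self.root}

    def plan(self):
        from .plan import CompressionPlan

        return CompressionPlan(
            n=self.n, root=self.root, ref_of=dict(self.ref_of), levels=dict(self.levels)
        )

    def validate(self) -> None:
        if self.root in self.ref_of:
            raise ValueError("archive root must not have a reference")
        if len(self.ref_of) != self.n - 1:
            raise ValueError("archive must hold exactly n-1 referenced entries")
        for i, r in self.ref_of.items():
            if r not in self.payloads:
                raise ValueError(f"entry {i} references missing index {r}")
        if set(self.checksums) != set(self.payloads):
            raise ValueError("checksum set does not match payload set")


def write_archive(archive: Archive, path: str | Path) -> None:
    order = sorted(archive.payloads)
    header = {
        "version": archive.version,
        "params": archive.params,
        "root": archive.root,
        "ref_of": {str(i): r for i, r in archive.ref_of.items()},
        "levels": {str(i): v for i, v in archive.levels.items()},
        "checksums": {str(i): c for i, c in archive.checksums.items()},
        "payload_index": [[i, len(archive.payloads[i])] for i in order],
    }
    header_c = bz2.compress(json.dumps(header, sort_keys=True).encode("utf-8"), 9)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<H", archive.version))
        fh.write(struct.pack("<I", len(header_c)))
        fh.write(header_c)
        for i in order:
            fh.write(archive.payloads[i])


def read_archive(path: str | Path) -> Archive:
    data = Path(path).read_bytes()
    if len(data) < 10 or data[:4] != MAGIC:
        raise ValueError(f"{path}: not an ECC archive (bad magic)")
    version = struct.unpack("<H", data[4:6])[0]
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported archive version {version}")
    hlen = struct.unpack("<I", data[6:10])[0]
    if 10 + hlen > len(data):
        raise ValueError(f"{path}: truncated archive header")
    try:
        header = json.loads(bz2.decompress(data[10 : 10 + hlen]).decode("utf-8"))
    except (OSError, ValueError) as exc:
        raise ValueError(f"{path}: corrupt archive header ({exc})") from exc
    pos = 10 + hlen
    payloads: dict[int, bytes] = {}
    for i, length in header["payload_index"]:
        if pos + length > len(data):
            raise ValueError(f"{path}: truncated payload for sequence {i}")
        payloads[int(i)] = data[pos : pos + length]
        pos += length
    if pos != len(data):
        raise ValueError(f"{path}: {len(data) - pos} trailing bytes after payloads")
    return Archive(
        params=header["params"],
        root=int(header["root"]),
        ref_of={int(i): int(r) for i, r in header["ref_of"].items()},
        levels={int(i): int(v) for i, v in header["levels"].items()},
        checksums={int(i): c for i, c in header["checksums"].items()},
        payloads=payloads,
        version=version,
    )
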
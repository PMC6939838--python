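"""Reference-based and reference-free codecs: token streams, losslessness,
collection archives and external-backend export."""

import numpy as np
import pytest

from eccomp.codec import (
    CodecConfig,
    compress_against_reference,
    compress_collection,
    compress_reference_free,
    decompress_against_reference,
    decompress_collection,
    decompress_reference_free,
    external_backend_export,
    import_manifest,
    tokenize,
)
from eccomp.fasta_io import SequenceRecord, records_to_bytes
from eccomp.plan import CompressionPlan, fixed_reference_plan
from eccomp.synthetic import FamilySpec, generate_ancestor, generate_dataset, mutate

CFG = CodecConfig()


def rec(name: str, residues: str) -> SequenceRecord:
    return SequenceRecord.new(name, residues)


def test_config_validation():
    with pytest.raises(ValueError):
        CodecConfig(min_match=8, index_k=16)
    with pytest.raises(ValueError):
        CodecConfig(backend="lzma")


def test_self_compression_single_match():
    seq = generate_ancestor(500, seed=1).residues
    tokens = tokenize(seq.encode(), seq.encode(), CFG)
    assert len(tokens) == 1
    assert (tokens[0].kind, tokens[0].pos, tokens[0].length) == ("M", 0, 500)


def test_single_substitution_costs_one_literal_byte():
    reference = b"A" * 100
    target = b"A" * 50 + b"C" + b"A" * 49
    tokens = tokenize(target, reference, CFG)
    literal_bytes = b"".join(t.literal for t in tokens if t.kind == "L")
    assert literal_bytes == b"C"
    decoded = b"".join(
        reference[t.pos : t.pos + t.length] if t.kind == "M" else t.literal
        for t in tokens
    )
    assert decoded == target


def test_unrelated_target_is_one_literal():
    reference = generate_ancestor(300, seed=1).residues.encode()
    target = generate_ancestor(200, seed=2).residues.encode()
    tokens = tokenize(target, reference, CFG)
    assert [t.kind for t in tokens] == ["L"]
    assert tokens[0].literal == target


def test_no_adjacent_literals_and_min_match_respected():
    reference = generate_ancestor(1000, seed=3)
    target = mutate(reference, 0.02, 0.002, 0.002, seed=4)
    tokens = tokenize(target.residues.encode(), reference.residues.encode(), CFG)
    for a, b in zip(tokens, tokens[1:]):
        assert not (a.kind == "L" and b.kind == "L")
    assert all(t.length >= CFG.min_match for t in tokens if t.kind == "M")


@pytest.mark.parametrize("sub_rate", [0.001, 0.01, 0.1])
def test_reference_roundtrip_on_mutated_pairs(sub_rate):
    for seed in range(34):  # 3 rates x 34 > 100 seeded trials total
        ancestor = generate_ancestor(2000, seed, seed)
        target = mutate(ancestor, sub_rate, sub_rate / 4, sub_rate / 4, seed, 1)
        payload = compress_against_reference(target, ancestor, CFG)
        restored = decompress_against_reference(payload, ancestor, CFG)
        assert restored == target


def test_roundtrip_preserves_layout_metadata():
    target = SequenceRecord(
        description="odd record extra words",
        residues="acgtNACGTacgtNACGT" * 10,
        line_lengths=(100, 0, 50, 30),
        final_newline=False,
        preamble="\n",
    )
    reference = rec("ref", "ACGT" * 100)
    restored = decompress_against_reference(
        compress_against_reference(target, reference, CFG), reference, CFG
    )
    assert restored == target
    assert restored.to_bytes() == target.to_bytes()


def test_wrong_reference_detected():
    a = generate_ancestor(600, seed=5)
    b = generate_ancestor(600, seed=6)
    payload = compress_against_reference(mutate(a, 0.01, 0, 0, 7), a, CFG)
    with pytest.raises(ValueError, match="wrong reference"):
        decompress_against_reference(payload, b, CFG)


def test_malformed_match_rejected():
    import bz2

    from eccomp.codec import _residue_digest, _write_varint

    reference = rec("r", "ACGT" * 20)
    raw = bytearray()
    meta = b'{"description": "x", "final_newline": true, "line_lengths": [4], "preamble": ""}'
    _write_varint(raw, len(meta))
    raw += meta
    raw += _residue_digest(reference.residues.encode())
    _write_varint(raw, 4)
    raw += bytes([0x01])  # MATCH overrunning the reference
    _write_varint(raw, 79)
    _write_varint(raw, 10)
    with pytest.raises(ValueError, match="overruns the reference"):
        decompress_against_reference(bz2.compress(bytes(raw)), reference, CFG)


def test_payload_grows_with_divergence():
    sizes = []
    for sub_rate in (0.001, 0.01, 0.1):
        per_rate = []
        for seed in range(10):
            ancestor = generate_ancestor(3000, seed, 7)
            target = mutate(ancestor, sub_rate, 0, 0, seed, 8)
            per_rate.append(len(compress_against_reference(target, ancestor, CFG)))
        sizes.append(np.mean(per_rate))
    assert sizes[0] <= sizes[1] <= sizes[2]


def test_reference_free_roundtrips():
    low_entropy = rec("rep", "ACGT" * 1000)
    payload = compress_reference_free(low_entropy, CFG)
    assert len(payload) < len(low_entropy.residues)
    assert decompress_reference_free(payload, CFG) == low_entropy

    empty = rec("none", "")
    assert decompress_reference_free(compress_reference_free(empty, CFG), CFG) == empty

    noisy = generate_ancestor(500, seed=9)
    assert decompress_reference_free(compress_reference_free(noisy, CFG), CFG) == noisy


def test_collection_single_sequence():
    records = [rec("only", "ACGTACGTACGT")]
    archive = compress_collection(records, CompressionPlan(n=1, root=0, ref_of={}), CFG)
    assert archive.n == 1 and archive.entries == {}
    assert decompress_collection(archive) == records


def test_collection_roundtrip_two_families(two_family_records):
    records, _ = two_family_records
    from eccomp.pipeline import RunConfig, compress_records

    result = compress_records(records, RunConfig())
    assert decompress_collection(result.archive) == records
    assert records_to_bytes(decompress_collection(result.archive)) == records_to_bytes(
        records
    )
    # exactly one sequence stored without a reference
    assert len(result.archive.entries) == len(records) - 1


def test_clustered_plan_not_larger_than_worst_reference(two_family_records):
    records, _ = two_family_records
    from eccomp.archive import write_archive
    from eccomp.pipeline import RunConfig, compress_records, worst_reference_index

    result = compress_records(records, RunConfig())
    worst = worst_reference_index(result.matrix)
    fixed = compress_collection(
        records, fixed_reference_plan(len(records), worst), CFG
    )
    ecc_size = sum(len(p) for p in result.archive.payloads.values())
    fixed_size = sum(len(p) for p in fixed.payloads.values())
    assert ecc_size <= fixed_size


def test_corrupted_payload_detected(two_family_records):
    records, _ = two_family_records
    from eccomp.pipeline import RunConfig, compress_records

    archive = compress_records(records, RunConfig()).archive
    victim = max(archive.entries)
    blob = bytearray(archive.payloads[victim])
    blob[len(blob) // 2] ^= 0xFF
    archive.payloads[victim] = bytes(blob)
    with pytest.raises((ValueError, OSError)):
        decompress_collection(archive)


def test_external_export_and_manifest_import(tmp_path, two_family_records):
    records, _ = two_family_records
    from eccomp.pipeline import RunConfig, plan_records

    plan, _m, _s, _c = plan_records(records, RunConfig())
    manifest = external_backend_export(records, plan, tmp_path / "orders")
    cluster_dirs = sorted(p.name for p in (tmp_path / "orders").iterdir() if p.is_dir())
    assert len(cluster_dirs) == 2  # K=2 cluster directories
    assert (tmp_path / "orders" / "root.fasta").exists()
    for cdir in cluster_dirs:
        assert (tmp_path / "orders" / cdir / "reference.fasta").exists()
    assert import_manifest(manifest) == plan


def test_export_single_sequence(tmp_path):
    records = [rec("only", "ACGT" * 10)]
    plan = CompressionPlan(n=1, root=0, ref_of={})
    manifest = external_backend_export(records, plan, tmp_path / "one")
    assert import_manifest(manifest) == plan
    assert manifest.read_text().strip().splitlines()[1:] == ["0\tonly\t-\t0"]
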
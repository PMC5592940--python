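"""Mate-pair junction QC, duplicate/innie detection, clone coverage."""

import pytest

from draftkit import matepair, simulate
from draftkit._encode import revcomp
from draftkit.align import Placement, SeedIndex
from draftkit.errors import InvalidParameterError, MalformedRecordError, UndefinedRateError
from draftkit.matepair import NEXTERA_JUNCTION_ADAPTER as ADAPTER

from conftest import random_seq


def embed(rng, pos, total=151):
    """A read with the junction adapter starting at pos."""
    tail = total - pos - len(ADAPTER)
    return random_seq(rng, pos) + ADAPTER + random_seq(rng, tail)


def test_category_a_trims_both_reads_at_adapter(rng):
    qc = matepair.classify_junction((embed(rng, 60), embed(rng, 60)))
    assert qc.category == "A"
    assert qc.trimmed_lengths == (60, 60)


def test_category_d_when_adapter_absent(rng):
    r1, r2 = random_seq(rng, 151), random_seq(rng, 151)
    qc = matepair.classify_junction((r1, r2))
    assert qc.category == "D"
    assert qc.trimmed_lengths == (151, 151)


def test_single_read_categories(rng):
    plain = random_seq(rng, 151)
    assert matepair.classify_junction((embed(rng, 40), plain)).category == "B"
    assert matepair.classify_junction((plain, embed(rng, 40))).category == "C"


def test_adapter_found_with_one_mismatch_and_on_reverse_strand(rng):
    mutated = "G" + ADAPTER[1:] if ADAPTER[0] != "G" else "T" + ADAPTER[1:]
    read = random_seq(rng, 50) + mutated + random_seq(rng, 151 - 50 - len(ADAPTER))
    assert matepair.find_adapter(read, ADAPTER, max_mismatch=1) == 50
    assert matepair.find_adapter(read, ADAPTER, max_mismatch=0) == -1
    rc_read = random_seq(rng, 30) + revcomp(ADAPTER) + random_seq(rng, 60)
    assert matepair.find_adapter(rc_read, ADAPTER) == 30


def test_empty_read_is_malformed():
    with pytest.raises(MalformedRecordError):
        matepair.classify_junction(("", "ACGT"))


def test_category_d_filtering_counts(rng):
    qcs = [matepair.PairQC(c, (151, 151)) for c in "ABCDD"]
    kept, removed = matepair.filter_category_d(qcs)
    assert len(kept) == 3 and removed == 2
    kept, removed = matepair.filter_category_d(
        [matepair.PairQC("A", (151, 151)) for _ in range(4)]
    )
    assert removed == 0


def place(start, strand, contig="c1", length=100):
    return [Placement(contig, start, strand, length, length)]


def test_duplication_rate_all_distinct_and_forced_half():
    pairs = [("A" * 40, "C" * 40)] * 4
    distinct = [(place(i * 500, "+"), place(i * 500 + 4000, "-")) for i in range(4)]
    assert matepair.estimate_duplication_rate(pairs, distinct) == 0.0
    doubled = [distinct[i // 2] for i in range(8)]
    assert matepair.estimate_duplication_rate(pairs * 2, doubled) == 0.5


def test_duplication_rate_requires_pairs():
    with pytest.raises(UndefinedRateError):
        matepair.estimate_duplication_rate([], [])


def test_innie_geometry():
    # inward-facing, close: innie
    assert matepair.detect_innie(place(1000, "+"), place(1300, "-"), 1000)
    # outward-facing, far: true mate-pair geometry
    assert not matepair.detect_innie(place(1000, "-"), place(8900, "+"), 1000)
    # inward but far apart
    assert not matepair.detect_innie(place(1000, "+"), place(8900, "-"), 1000)
    # different contigs share no placement
    assert not matepair.detect_innie(place(0, "+"), place(300, "-", contig="c2"), 1000)


def test_clone_coverage_arithmetic():
    qcs = [matepair.PairQC("A", (151, 151), inferred_fragment_bp=8000) for _ in range(1000)]
    assert matepair.clone_coverage(qcs, 1_000_000) == pytest.approx(8.0)
    for qc in qcs[:500]:
        qc.duplicate = True
    assert matepair.clone_coverage(qcs, 1_000_000) == pytest.approx(4.0)
    with pytest.raises(InvalidParameterError):
        matepair.clone_coverage(qcs, 0)


def test_category_partition_is_exhaustive(small_truth):
    pairs, _ = simulate.simulate_matepair_reads(
        small_truth, n_pairs=2000, insert_mean=5000,
        dup_rate=0.1, innie_rate=0.1, adapterless_rate=0.1, seed=40,
    )
    lib = matepair.MatePairLibrary(name="t", nominal_insert_bp=5000, pairs=pairs)
    report, qcs, kept = matepair.qc_library(lib, {"g": small_truth.genome})
    assert sum(report.category_counts.values()) == len(pairs) == 2000
    assert report.category_counts["D"] == len(pairs) - len(kept)


def test_duplicate_estimator_bias_shrinks_with_n(small_truth):
    """Consistency check at n = 2k and n = 20k (registry truth 12%)."""
    errs = []
    for n, seed in ((2000, 41), (20_000, 42)):
        pairs, registry = simulate.simulate_matepair_reads(
            small_truth, n_pairs=n, insert_mean=5000, dup_rate=0.12, seed=seed,
        )
        lib = matepair.MatePairLibrary(name="t", nominal_insert_bp=5000, pairs=pairs)
        report, _, _ = matepair.qc_library(lib, {"g": small_truth.genome})
        truth_rate = registry[registry.category != "D"].is_dup.mean()
        errs.append(abs(report.duplication_rate - truth_rate))
    assert max(errs) < 0.01


def test_innie_recall_and_precision_on_separated_spans(small_truth):
    """Innies at <= 0.2x insert, true pairs >= 0.5x insert: perfect separation."""
    pairs, registry = simulate.simulate_matepair_reads(
        small_truth, n_pairs=3000, insert_mean=5000, insert_sd=400,
        innie_rate=0.15, seed=43,
    )
    lib = matepair.MatePairLibrary(name="t", nominal_insert_bp=5000, pairs=pairs)
    _, qcs, kept = matepair.qc_library(lib, {"g": small_truth.genome})
    for i in kept:
        assert qcs[i].innie == (registry.kind[i] == "innie")


def test_library_validation():
    with pytest.raises(InvalidParameterError):
        matepair.MatePairLibrary(name="x", nominal_insert_bp=0)
    with pytest.raises(InvalidParameterError):
        matepair.MatePairLibrary(name="x", nominal_insert_bp=100, junction_adapter="ACGT")


def test_qc_report_roundtrip(tmp_path, small_truth):
    pairs, _ = simulate.simulate_matepair_reads(
        small_truth, n_pairs=500, insert_mean=5000, seed=44,
    )
    lib = matepair.MatePairLibrary(name="demo", nominal_insert_bp=5000, pairs=pairs)
    report, _, _ = matepair.qc_library(
        lib, {"g": small_truth.genome}, genome_size_bp=small_truth.length
    )
    report.to_json(tmp_path / "qc.json")
    report.to_tsv(tmp_path / "qc.tsv")
    import json

    data = json.loads((tmp_path / "qc.json").read_text())
    assert data["n_pairs"] == 500
    assert data["clone_coverage_x"] > 0
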
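"""Synthetic-data generators: determinism, spectrum shape, registries."""

import numpy as np
import pytest

from draftkit import kmers, profile, simulate
from draftkit._encode import revcomp
from draftkit.errors import InvalidParameterError


def test_genome_determinism_and_length():
    a = simulate.generate_repeat_genome(50_000, 0.2, 2, 2, 0.1, seed=7)
    b = simulate.generate_repeat_genome(50_000, 0.2, 2, 2, 0.1, seed=7)
    c = simulate.generate_repeat_genome(50_000, 0.2, 2, 2, 0.1, seed=8)
    assert a.genome == b.genome and a.repeat_map == b.repeat_map
    assert a.genome != c.genome
    assert a.length == 50_000


def test_repeat_free_genome_is_all_unique_at_k31():
    truth = simulate.generate_repeat_genome(50_000, repeat_fraction=0.0, seed=1)
    hist = kmers.build_histogram(kmers.count_kmers([truth.genome], 31))
    assert set(hist.bins) == {1}


def test_exact_two_copy_family_puts_half_the_mass_at_depth_two():
    truth = simulate.generate_repeat_genome(
        100_000, repeat_fraction=0.5, n_families=1, copies_per_family=2,
        divergence=0.0, seed=2,
    )
    hist = kmers.build_histogram(kmers.count_kmers([truth.genome], 31))
    mass2 = 2 * hist.bins.get(2, 0) / hist.total_kmers
    assert mass2 == pytest.approx(0.5, abs=0.02)


def test_divergence_dissolves_shared_kmers():
    """At 10% per-copy divergence, shared 31-mers are (1-d)^2k ~ 0.1%."""
    truth = simulate.generate_repeat_genome(
        100_000, repeat_fraction=0.5, n_families=1, copies_per_family=2,
        divergence=0.1, seed=3,
    )
    hist = kmers.build_histogram(kmers.count_kmers([truth.genome], 31))
    mass2 = 2 * hist.bins.get(2, 0) / hist.total_kmers
    assert mass2 < 0.03


def test_infeasible_repeat_parameters_rejected():
    with pytest.raises(InvalidParameterError):
        simulate.generate_repeat_genome(1000, repeat_fraction=0.99, seed=1)
    with pytest.raises(InvalidParameterError):
        simulate.generate_repeat_genome(1000, repeat_fraction=-0.1, seed=1)


def test_error_free_reads_are_genome_substrings():
    truth = simulate.generate_repeat_genome(20_000, seed=4)
    rs = simulate.simulate_paired_reads(truth, coverage=5, seed=5)
    fwd = truth.genome
    for r1, r2 in rs.pairs[:200]:
        assert r1 in fwd
        assert revcomp(r2) in fwd


def test_read_volume_matches_coverage():
    truth = simulate.generate_repeat_genome(100_000, seed=6)
    rs = simulate.simulate_paired_reads(truth, coverage=30, seed=7)
    total = sum(len(r) for r in rs.reads())
    assert abs(total - 30 * truth.length) <= 2 * 151


def test_depth_is_poisson_like():
    truth = simulate.generate_repeat_genome(1_000_000, seed=8)
    rs = simulate.simulate_paired_reads(truth, coverage=30, seed=9)
    depth = np.zeros(truth.length + 1, dtype=np.int64)
    for (s, e), _ in zip(rs.fragments, rs.pairs):
        depth[s : s + 151] += 1
        depth[e - 151 : e] += 1
        depth[e] += 0
    body = depth[5000:-5001]
    assert body.mean() == pytest.approx(30, rel=0.02)
    assert body.var() == pytest.approx(body.mean(), rel=0.10)


def test_reads_determinism():
    truth = simulate.generate_repeat_genome(30_000, seed=10)
    a = simulate.simulate_paired_reads(truth, coverage=10, seed=11)
    b = simulate.simulate_paired_reads(truth, coverage=10, seed=11)
    assert a.pairs == b.pairs and a.fragments == b.fragments


def test_matepair_clean_library_recovers_zero_rates(small_truth):
    from draftkit import matepair

    pairs, registry = simulate.simulate_matepair_reads(
        small_truth, n_pairs=1500, insert_mean=5000, seed=12,
    )
    lib = matepair.MatePairLibrary(name="t", nominal_insert_bp=5000, pairs=pairs)
    report, _, _ = matepair.qc_library(lib, {"g": small_truth.genome})
    assert report.duplication_rate == 0.0
    assert report.innie_fraction == 0.0
    assert report.category_counts["D"] == 0
    assert set(registry.kind) == {"true"}


def test_matepair_registry_consistency_two_sample_sizes(small_truth):
    from draftkit import matepair

    for n in (2000, 8000):
        pairs, registry = simulate.simulate_matepair_reads(
            small_truth, n_pairs=n, insert_mean=5000,
            dup_rate=0.12, innie_rate=0.10, adapterless_rate=0.05, seed=13,
        )
        lib = matepair.MatePairLibrary(name="t", nominal_insert_bp=5000, pairs=pairs)
        report, _, kept = matepair.qc_library(lib, {"g": small_truth.genome})
        reg_kept = registry[registry.category != "D"]
        assert abs(report.duplication_rate - reg_kept.is_dup.mean()) < 0.01
        assert abs(report.innie_fraction - (reg_kept.kind == "innie").mean()) < 0.01


def test_gapped_assembly_identity_when_no_gaps(small_truth):
    scaffolds, gap_truth = simulate.make_gapped_assembly(small_truth, 0, seed=14)
    assert scaffolds["scaffold_1"] == small_truth.genome and gap_truth == {}


def test_gapped_assembly_preserves_length_and_records_truth(small_truth):
    scaffolds, gap_truth = simulate.make_gapped_assembly(
        small_truth, 1, (100, 100), seed=15
    )
    seq = scaffolds["scaffold_1"]
    assert len(seq) == small_truth.length
    assert seq.count("N") == 100
    [(gap_id, interior)] = gap_truth.items()
    sid, span = gap_id.split(":")
    s, e = map(int, span.split("-"))
    assert small_truth.genome[s:e] == interior
    assert seq[s:e] == "N" * 100


def test_gap_placement_respects_spacing():
    truth = simulate.generate_repeat_genome(2_000_000, seed=16)
    scaffolds, gap_truth = simulate.make_gapped_assembly(truth, 200, (50, 500), seed=17)
    intervals = sorted(
        tuple(map(int, gid.split(":")[1].split("-"))) for gid in gap_truth
    )
    assert len(intervals) == 200
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        assert s2 - e1 >= 400


def test_repeat_traps_duplicate_interior_near_flank():
    truth = simulate.generate_repeat_genome(500_000, seed=18)
    traps = simulate.plant_repeat_traps(truth, 3, seed=19)
    for s, e in traps:
        interior_repeat = truth.genome[s + 50 : s + 250]
        flank_copy = truth.genome[s - 205 : s - 5]
        assert interior_repeat == flank_copy


def test_histogram_shows_multi_copy_peaks_from_reads():
    """3-copy exact families: read spectrum peaks near 1x and 3x depth."""
    truth = simulate.generate_repeat_genome(
        400_000, repeat_fraction=0.3, n_families=2, copies_per_family=3,
        divergence=0.0, seed=20,
    )
    rs = simulate.simulate_paired_reads(truth, coverage=30, seed=21)
    hist = kmers.build_histogram(kmers.count_kmers(rs.reads(), 24))
    model = profile.fit_peak_model(hist)
    lam = 30 * (151 - 24 + 1) / 151
    assert abs(model.haploid_peak_depth - lam) <= 1.5
    dense = hist.dense().astype(float)
    lo3, hi3 = int(2.6 * lam), int(3.4 * lam)
    window3 = dense[lo3 : hi3 + 1]
    peak3 = lo3 + int(np.argmax(window3))
    assert abs(peak3 - 3 * lam) <= 1.5 * 3  # 3x peak within ~1 depth unit per copy
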
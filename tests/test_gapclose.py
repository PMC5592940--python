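"""Gap discovery, both closers, closure application and redundancy removal."""

import pytest

from draftkit import gapclose, simulate
from draftkit._encode import revcomp
from draftkit.errors import InvalidParameterError

from conftest import random_seq


def test_find_gaps_single_run():
    [job] = gapclose.find_gaps("s", "ACGT" + "N" * 50 + "ACGT")
    assert job.interval == (4, 54)
    assert job.estimated_gap_bp == 50
    assert job.left_flank == "ACGT" and job.right_flank == "ACGT"
    assert job.short_flank


def test_find_gaps_none():
    assert gapclose.find_gaps("s", "ACGTACGT") == []


def test_find_gaps_two_runs_with_one_bp_middle_flank():
    jobs = gapclose.find_gaps("s", "AAAA" + "N" * 5 + "G" + "N" * 5 + "TTTT")
    assert [j.interval for j in jobs] == [(4, 9), (10, 15)]
    assert jobs[0].right_flank == "G" and jobs[1].left_flank == "G"
    assert all(j.short_flank for j in jobs)


def make_gap_job(rng, gap_len, flank_len=200):
    left = random_seq(rng, flank_len)
    interior = random_seq(rng, gap_len)
    right = random_seq(rng, flank_len)
    job = gapclose.GapJob(
        scaffold_id="s", start=flank_len, end=flank_len + gap_len,
        left_flank=left, right_flank=right, estimated_gap_bp=gap_len,
    )
    return job, left + interior + right, interior


def test_spanning_closure_from_constructed_read(rng):
    job, region, interior = make_gap_job(rng, 20)
    read = job.left_flank[-65:] + interior + job.right_flank[:65]
    assert len(read) <= 151
    res = gapclose.close_gap_spanning(job, [read])
    assert res.status == "closed_span" and res.fill_sequence == interior


def test_spanning_closure_accepts_reverse_strand_reads(rng):
    job, region, interior = make_gap_job(rng, 15)
    read = revcomp(job.left_flank[-70:] + interior + job.right_flank[:70])
    res = gapclose.close_gap_spanning(job, [read])
    assert res.status == "closed_span" and res.fill_sequence == interior


def test_spanning_conflict_leaves_gap_open(rng):
    job, region, interior = make_gap_job(rng, 10)
    good = job.left_flank[-63:] + interior + job.right_flank[:63]
    bad = job.left_flank[-63:] + "A" * 12 + job.right_flank[:63]
    assert gapclose.close_gap_spanning(job, [good, bad]).status == "open"


def test_spanning_impossible_for_long_interiors(rng):
    """Interior + 2*63 beyond read length can never span."""
    job, region, interior = make_gap_job(rng, 120)
    reads = [region[i : i + 151] for i in range(0, len(region) - 151, 7)]
    assert gapclose.close_gap_spanning(job, reads).status == "open"


def test_assembly_closure_recovers_truth(rng):
    """300-bp gap, 40x error-free bin: exact fill."""
    job, region, interior = make_gap_job(rng, 300)
    reads = [region[i : i + 151] for i in range(0, len(region) - 150, 4)]
    job.read_bin = reads
    res = gapclose.close_gap_assembly(job)
    assert res.status == "closed_assembly"
    assert res.fill_sequence == interior
    assert 19 <= res.k_used <= 150


def test_assembly_closure_empty_bin_is_open(rng):
    job, _, _ = make_gap_job(rng, 100)
    assert gapclose.close_gap_assembly(job).status == "open"


def test_repeat_trap_gap_left_open(rng):
    """Interior repeats a nearby locus >= 150 bp: branch at every k."""
    repeat = random_seq(rng, 200)
    left = random_seq(rng, 100) + repeat + random_seq(rng, 5)  # repeat inside left flank
    interior = random_seq(rng, 50) + repeat + random_seq(rng, 50)
    right = random_seq(rng, 200)
    region = left + interior + right
    job = gapclose.GapJob(
        scaffold_id="s", start=len(left), end=len(left) + len(interior),
        left_flank=left[-200:], right_flank=right, estimated_gap_bp=len(interior),
    )
    job.read_bin = [region[i : i + 151] for i in range(0, len(region) - 150, 4)]
    assert gapclose.close_gap_assembly(job).status == "open"


def test_bin_reads_for_gap_includes_window_hits_and_mates():
    from draftkit.align import Placement

    job = gapclose.GapJob("s", 1000, 1100, "A" * 200, "C" * 200, 100)
    alignments = [
        ("READ_L", [Placement("s", 850, "+", 151, 151)]),   # in left window
        ("MATE_L", []),                                      # its unaligned mate
        ("READ_FAR", [Placement("s", 5000, "+", 151, 151)]),
        ("MATE_FAR", [Placement("s", 5400, "-", 151, 151)]),
    ]
    mates = {0: 1, 1: 0, 2: 3, 3: 2}
    bin_ = gapclose.bin_reads_for_gap(job, alignments, mates)
    assert bin_ == ["READ_L", "MATE_L"]


def test_bin_size_matches_coverage_arithmetic(rng):
    """Bin size tracks 2*(2*flank + read_len)*coverage/read_len."""
    truth = simulate.generate_repeat_genome(10_000, seed=50)
    scaffolds, _ = simulate.make_gapped_assembly(truth, 1, (200, 200), seed=51)
    reads = simulate.simulate_paired_reads(truth, coverage=40, insert_mean=400, seed=52)
    [job] = [
        j for sid, seq in scaffolds.items() for j in gapclose.find_gaps(sid, seq)
    ]
    gapclose.assign_read_bins(scaffolds, [job], reads.pairs)
    expected = 2 * (2 * 200 + 151) * 40 / 151
    assert expected * 0.8 <= len(job.read_bin) <= expected * 1.45


def test_apply_closures_bookkeeping(rng):
    scaffold = "A" * 300 + "N" * 50 + "C" * 300
    jobs = gapclose.find_gaps("s", scaffold)
    fill = random_seq(rng, 48)
    results = [gapclose.ClosureResult("closed_assembly", fill, k_used=63)]
    closed, report, regions = gapclose.apply_closures({"s": scaffold}, jobs, results)
    assert len(closed["s"]) == len(scaffold) - 2
    assert closed["s"] == "A" * 300 + fill + "C" * 300
    assert report.n_closed_assembly == 1 and report.filled_bp_assembly == 48
    assert regions == [("s", jobs[0].left_flank + fill + jobs[0].right_flank)]


def test_apply_closures_open_keeps_assembly_identical():
    scaffold = "ACGT" * 100 + "N" * 30 + "TGCA" * 100
    jobs = gapclose.find_gaps("s", scaffold)
    closed, report, _ = gapclose.apply_closures(
        {"s": scaffold}, jobs, [gapclose.ClosureResult("open")]
    )
    assert closed["s"] == scaffold and report.n_open == 1


def test_apply_closures_preserves_flanks(rng):
    truth = simulate.generate_repeat_genome(20_000, seed=53)
    scaffolds, _ = simulate.make_gapped_assembly(truth, 4, (50, 150), seed=54)
    sid, seq = next(iter(scaffolds.items()))
    jobs = gapclose.find_gaps(sid, seq)
    results = [
        gapclose.ClosureResult("closed_assembly", random_seq(rng, j.estimated_gap_bp - 3), k_used=31)
        if i % 2 == 0
        else gapclose.ClosureResult("open")
        for i, j in enumerate(jobs)
    ]
    closed, _, _ = gapclose.apply_closures(scaffolds, jobs, results)
    new = closed[sid]
    offset = 0
    for job, res in zip(jobs, results):  # flanks byte-identical at every site
        left = new[job.start + offset - len(job.left_flank) : job.start + offset]
        assert left == job.left_flank
        if res.status != "open":
            offset += len(res.fill_sequence) - job.estimated_gap_bp


def test_apply_closures_rejects_mismatched_results():
    with pytest.raises(InvalidParameterError):
        gapclose.apply_closures({"s": "AANAA"}, gapclose.find_gaps("s", "AANAA"), [])


def test_redundant_contig_removal(rng):
    fill = random_seq(rng, 1200)
    region = random_seq(rng, 200) + fill + random_seq(rng, 200)
    contained = fill[100:900]
    near_miss = list(contained)
    step = 10  # one substitution per 10 bp: ~90% identity
    for i in range(0, len(near_miss), step):
        near_miss[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near_miss[i]]
    assembly = {
        "big": random_seq(rng, 5000),
        "contained": contained,
        "contained_rc": revcomp(contained),
        "diverged": "".join(near_miss),
        "elsewhere": random_seq(rng, 800),
    }
    out, removed = gapclose.remove_redundant_contigs(assembly, [("s", region)])
    assert sorted(removed) == ["contained", "contained_rc"]
    assert "big" in out and "diverged" in out and "elsewhere" in out
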
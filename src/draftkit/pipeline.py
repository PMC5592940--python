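"""End-to-end demo pipeline tying the stages together in workflow order:

simulate genome and reads -> k-mer histogram and genome profile ->
assembly uniqueness curve -> mate-pair library QC -> gapped scaffolds ->
gap closing -> assembly statistics.

The pipeline exists to exercise every stage deterministically on a
desk-scale synthetic project; each report carries the configuration
hash and seed, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import gapclose, kmers, matepair, profile, simulate, stats, uniqueness
from .errors import InvalidParameterError

log = logging.getLogger("draftkit")


@dataclass
class RunConfig:
    """Parameters for every stage of the demo pipeline."""

    seed: int = 1
    genome_length_bp: int = 150_000
    repeat_fraction: float = 0.2
    n_repeat_families: int = 3
    copies_per_family: int = 3
    repeat_divergence: float = 0.15
    read_len: int = 151
    pe_coverage: float = 30.0
    pe_insert_mean: int = 400
    pe_insert_sd: float = 40.0
    pe_error_rate: float = 0.0
    histogram_k: int = 24
    uniqueness_k_list: list[int] = field(default_factory=lambda: [17, 25, 32])
    mp_n_pairs: int = 4000
    mp_insert_mean: int = 5000
    mp_insert_sd: float = 500.0
    mp_dup_rate: float = 0.12
    mp_innie_rate: float = 0.10
    mp_adapterless_rate: float = 0.05
    n_gaps: int = 15
    gap_len_min: int = 50
    gap_len_max: int = 400
    gc_coverage: float = 40.0
    gc_insert_mean: int = 600
    gc_insert_sd: float = 60.0
    flank_bp: int = 200
    k_exact: int = 63
    k_min: int = 19
    k_max: int = 150
    min_len_bp: int = 150
    version: str = "0.1.0"

    def validate(self) -> None:
        if self.k_exact > self.read_len:
            raise InvalidParameterError("k_exact exceeds read_len")
        if self.k_min > self.k_max:
            raise InvalidParameterError("k_min exceeds k_max")
        if not 0 <= self.repeat_fraction < 1:
            raise InvalidParameterError("repeat_fraction must be in [0, 1)")
        if self.genome_length_bp < 10 * self.mp_insert_mean:
            raise InvalidParameterError("genome too short for the mate-pair insert")
        for k in self.uniqueness_k_list:
            if k < 1:
                raise InvalidParameterError("uniqueness_k_list entries must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle under outdir.

    Returns a summary dict (also written as run_summary.json).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed, "version": config.version}
    t0 = time.monotonic()

    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    log.info("stage: simulate genome")
    truth = simulate.generate_repeat_genome(
        config.genome_length_bp,
        repeat_fraction=config.repeat_fraction,
        n_families=config.n_repeat_families,
        copies_per_family=config.copies_per_family,
        divergence=config.repeat_divergence,
        seed=config.seed,
    )

    log.info("stage: k-mer histogram and genome profile")
    pe = simulate.simulate_paired_reads(
        truth,
        coverage=config.pe_coverage,
        read_len=config.read_len,
        insert_mean=config.pe_insert_mean,
        insert_sd=config.pe_insert_sd,
        error_rate=config.pe_error_rate,
        seed=config.seed + 1,
    )
    hist = kmers.build_histogram(kmers.count_kmers(pe.reads(), config.histogram_k))
    hist.write(outdir / "kmer_histogram.txt")
    model = profile.fit_peak_model(hist)
    prof = profile.profile_report(hist, model)
    prof["meta"] = meta
    profile.write_profile_report(prof, outdir / "genome_profile.json")

    log.info("stage: uniqueness curve")
    curve = uniqueness.uniqueness_curve([truth.genome], config.uniqueness_k_list)
    curve.to_tsv(outdir / "uniqueness_curve.tsv")

    log.info("stage: mate-pair QC")
    mp_pairs, registry = simulate.simulate_matepair_reads(
        truth,
        n_pairs=config.mp_n_pairs,
        insert_mean=config.mp_insert_mean,
        insert_sd=config.mp_insert_sd,
        dup_rate=config.mp_dup_rate,
        innie_rate=config.mp_innie_rate,
        adapterless_rate=config.mp_adapterless_rate,
        read_len=config.read_len,
        seed=config.seed + 2,
    )
    library = matepair.MatePairLibrary(
        name="demo_mp", nominal_insert_bp=config.mp_insert_mean, pairs=mp_pairs
    )
    report, _, _ = matepair.qc_library(
        library, {"genome": truth.genome}, genome_size_bp=truth.length
    )
    report.to_json(outdir / "matepair_qc.json")
    report.to_tsv(outdir / "matepair_qc.tsv")
    registry.to_csv(outdir / "matepair_registry.tsv", sep="\t", index=False)

    log.info("stage: gap closing")
    scaffolds, gap_truth = simulate.make_gapped_assembly(
        truth,
        n_gaps=config.n_gaps,
        gap_len_range=(config.gap_len_min, config.gap_len_max),
        flank_bp=config.flank_bp,
        seed=config.seed + 3,
    )
    gc_reads = simulate.simulate_paired_reads(
        truth,
        coverage=config.gc_coverage,
        read_len=config.read_len,
        insert_mean=config.gc_insert_mean,
        insert_sd=config.gc_insert_sd,
        seed=config.seed + 4,
    )
    jobs = [
        job
        for sid, seq in scaffolds.items()
        for job in gapclose.find_gaps(sid, seq, flank_bp=config.flank_bp)
    ]
    gapclose.assign_read_bins(scaffolds, jobs, gc_reads.pairs, flank_bp=config.flank_bp)
    results = [
        gapclose.close_gap(job, k_exact=config.k_exact, k_min=config.k_min, k_max=config.k_max)
        for job in jobs
    ]
    closed, closure_report, regions = gapclose.apply_closures(scaffolds, jobs, results)
    gapclose.write_gap_table(outdir / "gap_closures.tsv", jobs, results)
    closure_report.to_json(outdir / "gap_summary.json")
    n_exact = sum(
        1
        for job, res in zip(jobs, results)
        if res.fill_sequence is not None
        and res.fill_sequence == gap_truth[f"{job.scaffold_id}:{job.start}-{job.end}"]
    )

    log.info("stage: assembly statistics")
    summaries = stats.summarize(closed, genome_size_bp=truth.length, min_len_bp=config.min_len_bp)
    stats.write_summary_tsv(summaries, outdir / "assembly_stats.tsv")

    summary = {
        "meta": meta,
        "genome_size_estimates_bp": {
            m: prof["estimates"][m]["genome_size_bp"] for m in prof["estimates"]
        },
        "uniqueness_curve": {p.k: p.ratio for p in curve.points},
        "matepair": {
            "duplication_rate": report.duplication_rate,
            "innie_fraction": report.innie_fraction,
            "category_counts": report.category_counts,
            "clone_coverage_x": report.clone_coverage_x,
        },
        "gaps": {
            "n_gaps": closure_report.n_gaps,
            "n_closed": closure_report.n_closed_span + closure_report.n_closed_assembly,
            "n_fill_exact": n_exact,
        },
        "scaffold_n50_bp": summaries["scaffolds"].n50_bp,
        "contig_n50_bp": summaries["contigs"].n50_bp,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline done in %.1f s", time.monotonic() - t0)
    return summary
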
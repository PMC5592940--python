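"""Assembly summary statistics with the genome-size-normalized N50.

The N50 here follows the NG50 convention: elements are sorted by
descending length and the N50 is the length at which the cumulative sum
first reaches half of an *estimated genome size* — not half of the
assembly span.  With genome_size equal to the assembly span this
reduces to the classical N50.  If the assembly never reaches half the
genome size, the smallest element length is returned and the summary is
flagged under-assembled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .errors import EmptyInputError, InvalidParameterError

DEFAULT_MIN_LEN_BP = 150


class ContigPiece(NamedTuple):
    """A maximal N-free run of a scaffold, with provenance."""

    scaffold: str
    offset: int
    seq: str


def split_scaffolds_to_contigs(
    assembly: dict[str, str] | Iterable[tuple[str, str]],
    min_gap_run: int = 1,
) -> list[ContigPiece]:
    """Split scaffolds into contigs at N-runs of length >= min_gap_run."""
    if isinstance(assembly, dict):
        assembly = assembly.items()
    splitter = re.compile("N{%d,}" % min_gap_run)
    pieces: list[ContigPiece] = []
    for name, seq in assembly:
        seq = seq.upper()
        pos = 0
        for m in splitter.finditer(seq):
            if m.start() > pos:
                pieces.append(ContigPiece(name, pos, seq[pos : m.start()]))
            pos = m.end()
        if pos < len(seq):
            pieces.append(ContigPiece(name, pos, seq[pos:]))
    return pieces


class N50Result(NamedTuple):
    value: int
    under_assembled: bool


def n50_detail(lengths: Sequence[int], genome_size_bp: int) -> N50Result:
    """N50 at half the estimated genome size, with an under-assembly flag."""
    if not lengths:
        raise EmptyInputError("n50 of an empty length list")
    if genome_size_bp <= 0:
        raise InvalidParameterError("genome_size_bp must be positive")
    half = genome_size_bp / 2
    cum = 0
    ordered = sorted(lengths, reverse=True)
    for length in ordered:
        cum += length
        if cum >= half:
            return N50Result(length, False)
    return N50Result(ordered[-1], True)


def n50(lengths: Sequence[int], genome_size_bp: int) -> int:
    """Length at which descending cumulative length first reaches G/2."""
    return n50_detail(lengths, genome_size_bp).value


@dataclass
class AssemblySummary:
    element_class: str
    n_elements: int
    max_bp: int
    total_bp: int
    n50_bp: int
    under_assembled: bool
    genome_size_used_bp: int
    min_len_bp: int


def _summarize_lengths(
    element_class: str, lengths: Sequence[int], genome_size_bp: int, min_len_bp: int
) -> AssemblySummary:
    kept = [x for x in lengths if x >= min_len_bp]
    if not kept:
        return AssemblySummary(element_class, 0, 0, 0, 0, False, genome_size_bp, min_len_bp)
    value, flag = n50_detail(kept, genome_size_bp)
    return AssemblySummary(
        element_class=element_class,
        n_elements=len(kept),
        max_bp=max(kept),
        total_bp=sum(kept),
        n50_bp=value,
        under_assembled=flag,
        genome_size_used_bp=genome_size_bp,
        min_len_bp=min_len_bp,
    )


def summarize(
    assembly: dict[str, str],
    genome_size_bp: int,
    min_len_bp: int = DEFAULT_MIN_LEN_BP,
    singleton_ids: set[str] | None = None,
    min_gap_run: int = 1,
) -> dict[str, AssemblySummary]:
    """Per-class summaries: contigs (scaffolds split at N-runs),
    scaffolds, and singletons.

    Singletons are an input label (contigs never scaffolded), not
    inferred; they are excluded from the scaffold class.  Elements
    shorter than min_len_bp are excluded everywhere.
    """
    singleton_ids = singleton_ids or set()
    scaffold_items = {k: v for k, v in assembly.items() if k not in singleton_ids}
    singleton_items = {k: v for k, v in assembly.items() if k in singleton_ids}
    contig_lengths = [len(p.seq) for p in split_scaffolds_to_contigs(scaffold_items, min_gap_run)]
    out: dict[str, AssemblySummary] = {}
    out["contigs"] = _summarize_lengths("contigs", contig_lengths, genome_size_bp, min_len_bp)
    out["scaffolds"] = _summarize_lengths(
        "scaffolds", [len(s) for s in scaffold_items.values()], genome_size_bp, min_len_bp
    )
    out["singletons"] = _summarize_lengths(
        "singletons", [len(s) for s in singleton_items.values()], genome_size_bp, min_len_bp
    )
    return out


def write_summary_tsv(summaries: dict[str, AssemblySummary], path: str | Path) -> None:
    """Table-shaped TSV: one row per statistic, one column per class."""
    classes = ["contigs", "scaffolds", "singletons"]
    rows = [
        ("n_elements", lambda s: s.n_elements),
        ("max_bp", lambda s: s.max_bp),
        ("total_bp", lambda s: s.total_bp),
        ("n50_bp", lambda s: s.n50_bp),
    ]
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(classes) + "\n")
        for label, getter in rows:
            vals = [str(getter(summaries[c])) if c in summaries else "" for c in classes]
            fh.write(label + "\t" + "\t".join(vals) + "\n")
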
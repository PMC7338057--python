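"""Mapped 3'-Seq read handling: cleavage-site extraction and mispriming filter.

A 3'-Seq read pins the transcript's cleavage/polyadenylation position; all
downstream stages work on those single-base positions.  Reads are stored
aggregated: one row per (chrom, pos, strand, library) with a count, which is
equivalent to, and far cheaper than, one row per read.

The internal-priming filter removes reads whose genomic context looks like an
oligo-dT annealing site rather than a real poly(A) tail: an A-rich stretch on
the transcript sense strand immediately 3' of the putative cleavage site
(equivalently, in read-mapping orientation, a T-rich stretch directly upstream
of the mapping position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import downstream_window, max_run

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "pos", "strand", "library", "count"]


@dataclass
class MappedReadSet:
    """Aggregated cleavage-site counts for one or more libraries."""

    counts: pd.DataFrame
    libraries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.empty:
            self.counts = pd.DataFrame(columns=READ_COLUMNS)
        missing = [c for c in READ_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"read frame missing columns {missing}")
        if not self.libraries:
            self.libraries = sorted(self.counts.library.unique())

    @property
    def n_reads(self) -> int:
        return int(self.counts["count"].sum())

    def reads_per_library(self) -> pd.Series:
        base = pd.Series(0, index=pd.Index(self.libraries, name="library"))
        got = self.counts.groupby("library")["count"].sum()
        return base.add(got, fill_value=0).astype(int)

    @staticmethod
    def concat(sets: list["MappedReadSet"]) -> "MappedReadSet":
        libs: list[str] = []
        for s in sets:
            libs.extend(l for l in s.libraries if l not in libs)
        frames = [s.counts for s in sets if not s.counts.empty]
        frame = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=READ_COLUMNS)
        )
        return MappedReadSet(frame, libs)


def extract_cleavage_sites(
    alignments, protocol: str, default_library: str = "library0"
) -> MappedReadSet:
    """Reduce alignments to per-read cleavage positions.

    ``alignments`` is a path to a SAM/BAM file or an open
    :class:`pysam.AlignmentFile`.  For the reverse 3' protocol the read is
    antisense to the transcript: the reported strand is flipped and the
    cleavage position is the read's 3'-most aligned base (alignment start for
    a reverse-strand alignment, alignment end - 1 otherwise).  For a forward
    protocol the read is transcript-sense and the cleavage position is again
    the read's 3'-most aligned base.  Library identity comes from the RG tag
    when present.
    """
    import pysam

    if protocol not in ("reverse", "forward"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
    else:
        handle = alignments

    rows = []
    for aln in handle.fetch(until_eof=True):
        if aln.is_unmapped:
            continue
        if aln.is_reverse:
            read3, aln_strand = aln.reference_start, "-"
        else:
            read3, aln_strand = aln.reference_end - 1, "+"
        if protocol == "reverse":
            strand = "+" if aln_strand == "-" else "-"
        else:
            strand = aln_strand
        lib = aln.get_tag("RG") if aln.has_tag("RG") else default_library
        rows.append((aln.reference_name, read3, strand, lib))

    frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "library"])
    frame = (
        frame.groupby(["chrom", "pos", "strand", "library"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return MappedReadSet(frame)


def read_bed_reads(paths: dict[str, str]) -> MappedReadSet:
    """Load per-library BED6 files of single-base 3'-end intervals."""
    frames = []
    for lib, path in paths.items():
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        frames.append(
            pd.DataFrame(
                dict(chrom=bed.chrom, pos=bed.start, strand=bed.strand, library=lib, count=1)
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    frame = frame.groupby(["chrom", "pos", "strand", "library"], as_index=False)["count"].sum()
    return MappedReadSet(frame, list(paths))


def _is_misprimed_window(window: str, min_run: int = 6, min_count: int = 7) -> bool:
    return max_run(window, "A") >= min_run or window.count("A") >= min_count


def filter_misprimed_reads(
    read_set: MappedReadSet, genome, window: int = 10
) -> MappedReadSet:
    """Drop reads whose downstream genomic context is A-rich.

    A read is removed iff the ``window`` transcript-sense bases immediately 3'
    of its cleavage position contain >= 6 consecutive A or >= 7 A in total.
    Reads too close to a chromosome end to evaluate are kept with a warning.
    """
    if read_set.counts.empty:
        return MappedReadSet(read_set.counts.copy(), list(read_set.libraries))

    sites = read_set.counts[["chrom", "pos", "strand"]].drop_duplicates()
    bad_keys = set()
    n_skipped = 0
    for row in sites.itertuples(index=False):
        w = downstream_window(genome, row.chrom, int(row.pos), row.strand, window)
        if len(w) < window:
            n_skipped += 1
            continue
        if _is_misprimed_window(w):
            bad_keys.add((row.chrom, int(row.pos), row.strand))
    if n_skipped:
        logger.warning(
            "%d cleavage sites within %d bp of a chromosome end were not "
            "evaluated by the mispriming filter", n_skipped, window,
        )

    if not bad_keys:
        return MappedReadSet(read_set.counts.copy(), list(read_set.libraries))
    keys = pd.MultiIndex.from_frame(read_set.counts[["chrom", "pos", "strand"]])
    keep = ~keys.isin(bad_keys)
    return MappedReadSet(
        read_set.counts[keep].reset_index(drop=True), list(read_set.libraries)
    )
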
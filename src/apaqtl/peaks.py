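"""PAS discovery: coverage peak calling, gene assignment, filters, usage.

Peaks are called on pooled libraries with an inclusive per-base rule: a base
qualifies when it has a nonzero count in at least 90% of libraries and a
cross-library mean count strictly greater than 2; maximal runs of qualifying
bases on one strand merge into a peak.  The PAS coordinate of a peak is its
transcript-sense 3'-most qualifying base.  Peaks are assigned to genes with a
fixed feature hierarchy (3'UTR > 5 kb downstream > exon > 5'UTR > intron),
screened once more for internal priming at the site level, and quantified as
per-gene usage ratios: reads at the PAS divided by reads at all PAS of the
gene in the same library.

All coordinates are 0-based half-open; GFF3 input is converted at the reader
boundary (see :mod:`apaqtl.io`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import downstream_window, max_run
from .reads import MappedReadSet

logger = logging.getLogger(__name__)

CATEGORY_PRIORITY = ("utr3", "downstream5kb", "exon", "utr5", "intron")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    strand: str
    per_library_counts: dict[str, int]
    pas_pos: int

    def __post_init__(self) -> None:
        if not (self.start <= self.pas_pos < self.end):
            raise ValueError("pas_pos must lie inside the peak span")


@dataclass
class UsageMatrix:
    """PAS x library counts and usage ratios with gene grouping.

    ``usage`` entries are NaN exactly where the gene total for that library is
    zero; within each (gene, library) with a nonzero total the usage column
    sums to 1.
    """

    counts: pd.DataFrame   # index pas_id, columns library_id
    usage: pd.DataFrame    # same shape; NaN where gene total == 0
    pas_meta: pd.DataFrame  # index pas_id: gene_id, category, chrom, strand, pas_pos, start, end
    sample_sheet: pd.DataFrame  # index library_id: individual, fraction, batch

    def libraries_for(self, fraction: str) -> list[str]:
        sel = self.sample_sheet.index[self.sample_sheet.fraction == fraction]
        return [l for l in self.usage.columns if l in set(sel)]

    def mean_usage(self, fraction: str) -> pd.Series:
        libs = self.libraries_for(fraction)
        return self.usage[libs].mean(axis=1, skipna=True)

    def subset(self, pas_ids) -> "UsageMatrix":
        pas_ids = [p for p in self.counts.index if p in set(pas_ids)]
        return UsageMatrix(
            self.counts.loc[pas_ids],
            self.usage.loc[pas_ids],
            self.pas_meta.loc[pas_ids],
            self.sample_sheet,
        )


def call_peaks(
    read_sets,
    min_nonzero_frac: float = 0.9,
    min_mean_count: float = 2.0,
) -> list[Peak]:
    """Merge per-base qualifying positions into peaks.

    ``read_sets`` is a :class:`MappedReadSet` or a list of them; libraries are
    pooled.  A base qualifies iff it is nonzero in at least
    ``ceil(min_nonzero_frac * L)`` of the L libraries and its cross-library
    mean count strictly exceeds ``min_mean_count``.
    """
    if isinstance(read_sets, MappedReadSet):
        read_sets = [read_sets]
    if not read_sets:
        return []
    combined = MappedReadSet.concat(list(read_sets))
    n_lib = len(combined.libraries)
    if n_lib < 2:
        raise ValueError("peak calling requires at least 2 libraries")
    if combined.counts.empty:
        return []

    per_base = combined.counts.groupby(["chrom", "strand", "pos"]).agg(
        n_nonzero=("library", "nunique"), total=("count", "sum")
    )
    need = math.ceil(min_nonzero_frac * n_lib - 1e-9)
    qual = per_base[
        (per_base.n_nonzero >= need) & (per_base.total / n_lib > min_mean_count)
    ].reset_index()
    if qual.empty:
        return []

    qual = qual.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
    new_run = (
        (qual.chrom != qual.chrom.shift())
        | (qual.strand != qual.strand.shift())
        | (qual.pos.diff() != 1)
    )
    qual["run"] = new_run.cumsum()

    counts = combined.counts.set_index(["chrom", "strand"]).sort_index()
    peaks: list[Peak] = []
    for _, run in qual.groupby("run"):
        chrom, strand = run.chrom.iloc[0], run.strand.iloc[0]
        start, end = int(run.pos.min()), int(run.pos.max()) + 1
        span = counts.loc[(chrom, strand)]
        span = span[(span.pos >= start) & (span.pos < end)]
        per_lib = span.groupby("library")["count"].sum().astype(int).to_dict()
        pas_pos = end - 1 if strand == "+" else start
        peaks.append(Peak(chrom, start, end, strand, per_lib, pas_pos))
    return peaks


def assign_gene(peak: Peak, annotation: pd.DataFrame):
    """Hierarchical gene/category assignment of one peak.

    Among same-strand features overlapping the peak span, the class highest in
    ``CATEGORY_PRIORITY`` wins; ties within a class break by larger overlap,
    then lexicographic gene id.  Returns ``(gene_id, category)`` or ``None``.
    """
    sub = annotation[
        (annotation.chrom == peak.chrom)
        & (annotation.strand == peak.strand)
        & (annotation.start < peak.end)
        & (annotation.end > peak.start)
    ]
    if sub.empty:
        return None
    for cat in CATEGORY_PRIORITY:
        hits = sub[sub.feature == cat]
        if hits.empty:
            continue
        overlap = (
            np.minimum(hits.end, peak.end) - np.maximum(hits.start, peak.start)
        )
        order = pd.DataFrame(
            dict(gene_id=hits.gene_id.to_numpy(), overlap=overlap.to_numpy())
        ).sort_values(["overlap", "gene_id"], ascending=[False, True])
        return str(order.gene_id.iloc[0]), cat
    return None


def build_catalog(peaks: list[Peak], annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign peaks to genes and tabulate them; unassigned peaks are dropped."""
    rows = []
    for pk in peaks:
        hit = assign_gene(pk, annotation)
        if hit is None:
            continue
        gene_id, cat = hit
        rows.append(
            dict(
                pas_id=f"{pk.chrom}:{pk.pas_pos}:{pk.strand}:{gene_id}",
                gene_id=gene_id,
                category=cat,
                chrom=pk.chrom,
                strand=pk.strand,
                pas_pos=pk.pas_pos,
                start=pk.start,
                end=pk.end,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["pas_id", "gene_id", "category", "chrom", "strand", "pas_pos", "start", "end"],
    )


def filter_misprimed_pas(
    catalog: pd.DataFrame, genome, window: int = 15, min_run: int = 6, min_count: int = 11
) -> pd.DataFrame:
    """Site-level internal-priming screen.

    A PAS is removed iff the 15 transcript-sense bases downstream of its
    cleavage coordinate contain >= 6 consecutive A or >= 11 A total (the
    smallest integer count of 15 exceeding 70%).  Windows truncated by a
    chromosome end are judged with a proportionally scaled count threshold.
    """
    keep = []
    for row in catalog.itertuples():
        w = downstream_window(genome, row.chrom, int(row.pas_pos), row.strand, window)
        if len(w) < window:
            logger.warning(
                "PAS %s: downstream window truncated to %d bases", row.pas_id, len(w)
            )
            thr = math.ceil(min_count / window * len(w)) if w else 1
        else:
            thr = min_count
        bad = (len(w) >= min_run and max_run(w, "A") >= min_run) or w.count("A") >= thr
        keep.append(not bad)
    return catalog[np.array(keep, dtype=bool)].reset_index(drop=True)


def quantify_usage(
    catalog: pd.DataFrame, read_set: MappedReadSet, sample_sheet: pd.DataFrame
) -> UsageMatrix:
    """Count reads per PAS span and normalize to per-gene usage ratios.

    A read counts toward every peak span containing its cleavage position
    (spans from the caller are disjoint, so in practice each read lands in at
    most one).  Usage entries are missing, not zero, for libraries with no
    reads at any of the gene's PAS.
    """
    sheet = sample_sheet.set_index("library_id") if "library_id" in sample_sheet else sample_sheet
    unknown = [l for l in read_set.libraries if l not in sheet.index]
    if unknown:
        raise KeyError(f"libraries missing from sample sheet: {unknown}")
    libraries = list(read_set.libraries)

    counts = pd.DataFrame(
        0, index=pd.Index(catalog.pas_id, name="pas_id"), columns=libraries, dtype=float
    )
    reads = read_set.counts
    for (chrom, strand), cat_sub in catalog.groupby(["chrom", "strand"]):
        sub = reads[(reads.chrom == chrom) & (reads.strand == strand)]
        if sub.empty:
            continue
        pos = sub.pos.to_numpy()
        for row in cat_sub.itertuples():
            mask = (pos >= row.start) & (pos < row.end)
            if not mask.any():
                continue
            got = sub[mask].groupby("library")["count"].sum()
            counts.loc[row.pas_id, got.index] += got.to_numpy()

    meta = catalog.set_index("pas_id")
    gene_totals = counts.groupby(meta.gene_id).transform("sum")
    usage = counts.where(gene_totals > 0) / gene_totals.where(gene_totals > 0)
    return UsageMatrix(counts, usage, meta, sheet)


def filter_low_usage(matrix: UsageMatrix, min_mean: float = 0.05) -> UsageMatrix:
    """Drop PAS whose mean usage is below ``min_mean`` in BOTH fractions.

    A site is retained as soon as either the nuclear or the total libraries
    support it at the threshold (comparison is ``>= min_mean``, i.e. removal
    requires strictly lower means in both fractions).
    """
    mean_nuc = matrix.mean_usage("nuclear")
    mean_tot = matrix.mean_usage("total")
    keep = (mean_nuc >= min_mean) | (mean_tot >= min_mean)
    keep = keep.fillna(False)
    kept_ids = matrix.counts.index[keep.reindex(matrix.counts.index, fill_value=False)]
    out = matrix.subset(kept_ids)
    out.pas_meta = out.pas_meta.assign(
        mean_usage_nuclear=mean_nuc.reindex(out.pas_meta.index),
        mean_usage_total=mean_tot.reindex(out.pas_meta.index),
    )
    return out
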
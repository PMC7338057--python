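"""Plain-text serialization of the synthetic study and pipeline outputs.

Formats: genome FASTA, annotation GFF3 (1-based, converted at this boundary)
plus per-feature BED, genotypes as minimal VCF 4.2 with GT fields, read
3'-ends as per-library BED6 (one length-1 interval per read, score 1), and
TSVs for the sample sheet and ground truth.  Reading goes through the
standard libraries (pyfaidx for FASTA, pysam for VCF, pandas for BED/TSV).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .reads import MappedReadSet

_GFF3_TYPES = {
    "utr5": "five_prime_UTR",
    "exon": "exon",
    "intron": "intron",
    "utr3": "three_prime_UTR",
}


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome, key=lambda c: (len(c), c)):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(path) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gff3(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in truth.gene_models:
            fh.write(
                f"{gm.chrom}\tapaqtl_sim\tgene\t{gm.start + 1}\t{gm.end}\t.\t"
                f"{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            for name, lo, hi in gm.feature_intervals():
                fh.write(
                    f"{gm.chrom}\tapaqtl_sim\t{_GFF3_TYPES[name]}\t{lo + 1}\t{hi}\t.\t"
                    f"{gm.strand}\t.\tParent={gm.gene_id}\n"
                )


def write_feature_bed(annotation: pd.DataFrame, path) -> None:
    out = annotation[["chrom", "start", "end", "gene_id", "feature", "strand"]].copy()
    out["name"] = out.gene_id + ":" + out.feature
    out[["chrom", "start", "end", "name"]].assign(score=0, strand=out.strand).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_feature_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    gene_feature = bed.name.str.rsplit(":", n=1, expand=True)
    return pd.DataFrame(
        dict(chrom=bed.chrom, start=bed.start, end=bed.end, strand=bed.strand,
             gene_id=gene_feature[0], feature=gene_feature[1])
    )


def read_annotation_gff3(path) -> pd.DataFrame:
    """GFF3 -> the stranded 0-based feature frame used by gene assignment."""
    inv = {v: k for k, v in _GFF3_TYPES.items()}
    rows = []
    gff = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    for row in gff.itertuples():
        if row.type not in inv:
            continue
        parent = dict(kv.split("=", 1) for kv in row.attrs.split(";"))["Parent"]
        rows.append(dict(chrom=row.chrom, start=row.start - 1, end=row.end,
                         strand=row.strand, gene_id=parent, feature=inv[row.type]))
    return pd.DataFrame(rows)


def write_vcf(genotypes, path) -> None:
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted(genotypes.variants.chrom.unique(), key=lambda c: (len(c), c))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        for i, row in enumerate(genotypes.variants.itertuples()):
            gts = "\t".join(gt_codes[int(d)] for d in genotypes.dosages[i])
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """VCF -> (variants frame, dosage matrix, individuals); alt-allele dosage."""
    import pysam

    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    rows, dosages = [], []
    for rec in vf.fetch():
        dos = [sum(a or 0 for a in rec.samples[s]["GT"]) for s in individuals]
        dosages.append(dos)
        m = np.mean(dos) / 2.0
        rows.append(dict(snp_id=rec.id, chrom=rec.chrom, pos=rec.pos - 1,
                         maf=np.nan, sample_maf=float(min(m, 1 - m))))
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf", "sample_maf"])
    from .simulate import GenotypeMatrix

    return GenotypeMatrix(variants, np.array(dosages, dtype=np.int8), individuals)


def write_read_beds(read_set: MappedReadSet, out_dir) -> dict[str, str]:
    """One BED6 per library; rows are expanded to one line per read."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lib in read_set.libraries:
        sub = read_set.counts[read_set.counts.library == lib]
        expanded = sub.loc[sub.index.repeat(sub["count"])]
        bed = pd.DataFrame(
            dict(chrom=expanded.chrom, start=expanded.pos, end=expanded.pos + 1,
                 name=lib, score=1, strand=expanded.strand)
        )
        path = out_dir / f"{lib}.bed"
        bed.to_csv(path, sep="\t", header=False, index=False)
        paths[lib] = str(path)
    return paths


def write_dataset(truth, genotypes, read_set, sample_sheet, out_dir, force=False):
    out_dir = Path(out_dir)
    targets = ["genome.fa", "annotation.gff3", "features.bed", "genotypes.vcf",
               "samples.tsv", "truth_pas.tsv", "truth_qtl.tsv", "reads"]
    if not force:
        clashes = [t for t in targets if (out_dir / t).exists()]
        if clashes:
            raise FileExistsError(
                f"{out_dir} already contains {clashes}; pass force=True to overwrite"
            )
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genome, out_dir / "genome.fa")
    write_gff3(truth, out_dir / "annotation.gff3")
    write_feature_bed(truth.annotation_frame(), out_dir / "features.bed")
    write_vcf(genotypes, out_dir / "genotypes.vcf")
    sample_sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    truth.true_pas.to_csv(out_dir / "truth_pas.tsv", sep="\t", index=False)
    truth.qtl_effects.to_csv(out_dir / "truth_qtl.tsv", sep="\t", index=False)
    bed_paths = write_read_beds(read_set, out_dir / "reads")
    return {
        "genome": str(out_dir / "genome.fa"),
        "gff3": str(out_dir / "annotation.gff3"),
        "features": str(out_dir / "features.bed"),
        "vcf": str(out_dir / "genotypes.vcf"),
        "samples": str(out_dir / "samples.tsv"),
        "truth_pas": str(out_dir / "truth_pas.tsv"),
        "truth_qtl": str(out_dir / "truth_qtl.tsv"),
        "reads": bed_paths,
    }
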
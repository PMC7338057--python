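"""Self-contained synthetic two-fraction 3'-Seq study with known ground truth.

The generator emulates the design this pipeline targets: tens of individuals,
each contributing one nuclear and one whole-cell ("total") 3'-Seq library, over
genes that carry several polyadenylation sites (PAS).  Per gene and library,
PAS choice follows a softmax over baseline logits; a planted cis variant adds
``beta * dosage`` to one PAS's logit (the apaQTL effect); in the total fraction
the isoforms ending at intronic PAS are subject to decay, modelled as a
survival factor applied to their expected proportion before renormalization.
Read 3'-end positions scatter around the true PAS with a truncated discrete
Gaussian so the peak caller sees realistic multi-base peaks.  A configurable
fraction of genes receives an A-rich internal-priming trap that emits reads at
a non-PAS position, exercising the mispriming filters.

Every gene follows the same transcript architecture (5'UTR, exon, intron,
exon, 3'UTR); the 3'-most PAS always sits in the 3'UTR and additional PAS fall
in the intron or 3'UTR.  Planted polyadenylation signal hexamers are written
15-45 bases upstream of true PAS with category-dependent probability, and the
sequence flanking each true PAS is kept A-poor so that, by construction, only
trap positions look internally primed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASE_LUT, codes_to_str, str_to_codes
from .reads import MappedReadSet

# transcript-sense feature layout shared by all simulated genes (lengths in bp)
_FEATURES = (
    ("utr5", 150),
    ("exon", 300),
    ("intron", 1000),
    ("exon", 300),
    ("utr3", 400),
)
GENE_SPAN = sum(n for _, n in _FEATURES)

# transcript-sense offsets (cleavage base) of the PAS slots a gene may use
_DISTAL_UTR3_T = GENE_SPAN - 30
_INTRON_SLOTS = (700, 1050)
_UTR3_PROXIMAL_SLOTS = (1830, 1950)
_TRAP_T = 1600  # middle of the second exon, well away from any PAS slot

SIGNAL_MOTIFS = (
    "AATAAA", "AATTAA", "AAAAAA", "AAAAAG", "AATACA", "AATAGA",
    "AATATA", "ACTAAA", "AGTAAA", "CATAAA", "GATAAA", "TATAAA",
)
CANONICAL_MOTIF = "AATAAA"

FRACTIONS = ("nuclear", "total")


@dataclass
class SyntheticConfig:
    """Study-design knobs for the synthetic dataset.

    Defaults are the conditions the pipeline is exercised under: 52
    individuals x 2 fractions, ~300 reads per gene and library, 10% of genes
    with a planted apaQTL of logit effect 1.5, intronic isoform survival of
    0.3 in the total fraction (strong decay, so intronic sites show the
    nuclear-enriched dPAU signature), and 10% of genes carrying an
    internal-priming trap.
    """

    n_individuals: int = 52
    n_genes: int = 300
    pas_per_gene: Mapping[int, float] = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    read_depth_per_gene: float = 300.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    qtl_fraction: float = 0.1
    effect_size_beta: float = 1.5
    intron_survival: float = 0.3
    artifact_rate: float = 0.1
    artifact_depth: float = 20.0
    intronic_pas_prob: float = 0.5
    signal_prob: Mapping[str, float] = field(
        default_factory=lambda: {"utr3": 0.75, "intron": 0.25, "utr5": 0.5,
                                 "exon": 0.5, "downstream5kb": 0.5}
    )
    peak_width: int = 7
    snps_per_gene: int = 12
    genes_per_chrom: int = 50
    gene_gap: int = 5200  # keeps each gene's 5 kb downstream region gene-free
    chrom_margin: int = 30000
    n_batches: int = 1
    batch_effect: float = 0.0
    dm_concentration: float | None = None  # Dirichlet-multinomial overdispersion, off by default
    mixed_strands: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for frac in (self.qtl_fraction, self.artifact_rate, self.intronic_pas_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 < self.intron_survival <= 1.0:
            raise ValueError("intron_survival must lie in (0, 1]")
        ks = list(self.pas_per_gene)
        if not ks or min(ks) < 1 or max(ks) > 1 + len(_INTRON_SLOTS) + len(_UTR3_PROXIMAL_SLOTS):
            raise ValueError("pas_per_gene counts cannot be placed inside the gene model")
        if abs(sum(self.pas_per_gene.values()) - 1.0) > 1e-9:
            raise ValueError("pas_per_gene probabilities must sum to 1")
        if self.peak_width < 1 or self.peak_width % 2 == 0:
            raise ValueError("peak_width must be a positive odd integer")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def t_to_genomic(self, t: int) -> int:
        """Map a transcript-sense offset to a genomic coordinate."""
        if self.strand == "+":
            return self.start + t
        return self.end - 1 - t

    def feature_intervals(self) -> list[tuple[str, int, int]]:
        out, t = [], 0
        for name, n in _FEATURES:
            lo = self.t_to_genomic(t + n - 1) if self.strand == "-" else self.t_to_genomic(t)
            out.append((name, lo, lo + n))
            t += n
        return out

    def downstream5kb_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.end, self.end + 5000
        return max(0, self.start - 5000), self.start


@dataclass
class SyntheticTruth:
    """Planted generative parameters, kept for recovery tests."""

    genome: dict[str, str]
    gene_models: list[GeneModel]
    true_pas: pd.DataFrame      # pas_index, gene_id, chrom, strand, pos, t, category, logit, survival, motif, motif_offset
    qtl_effects: pd.DataFrame   # gene_id, pas_index, snp_id, chrom, pos, beta
    artifact_sites: pd.DataFrame  # gene_id, chrom, strand, pos, kind
    config: SyntheticConfig

    def annotation_frame(self) -> pd.DataFrame:
        """Stranded feature intervals (incl. 5 kb downstream regions)."""
        rows = []
        for gm in self.gene_models:
            for name, lo, hi in gm.feature_intervals():
                rows.append((gm.chrom, lo, hi, gm.strand, gm.gene_id, name))
            lo, hi = gm.downstream5kb_interval()
            rows.append((gm.chrom, lo, hi, gm.strand, gm.gene_id, "downstream5kb"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "feature"])

    def introns_frame(self) -> pd.DataFrame:
        ann = self.annotation_frame()
        return ann[ann.feature == "intron"].reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Variant x individual dosage matrix (dosages in {0,1,2})."""

    variants: pd.DataFrame  # snp_id, chrom, pos, maf, sample_maf
    dosages: np.ndarray
    individuals: list[str]

    def dosage_row(self, snp_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants.snp_id == snp_id]
        if len(idx) == 0:
            raise KeyError(snp_id)
        return self.dosages[idx[0]]


def _plant(codes: np.ndarray, gm: GeneModel, t0: int, motif: str) -> None:
    """Write a transcript-sense motif whose 5'-most base is at offset t0."""
    m = str_to_codes(motif)
    if gm.strand == "+":
        g0 = gm.start + t0
        codes[g0 : g0 + len(m)] = m
    else:
        g_hi = gm.end - t0  # exclusive
        codes[g_hi - len(m) : g_hi] = (3 - m)[::-1]


def _scrub_a_rich(rng: np.random.Generator, n: int) -> np.ndarray:
    """Low-A transcript-sense sequence: P(A)=0.15 and runs of A capped at 2."""
    out = rng.choice(
        np.array([0, 1, 2, 3], dtype=np.uint8), size=n, p=[0.15, 0.30, 0.25, 0.30]
    )
    run = 0
    for i in range(n):
        if out[i] == 0:
            run += 1
            if run > 2:
                out[i] = 1
                run = 0
        else:
            run = 0
    return out


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Lay out genome, gene models, PAS, planted signals/QTLs/traps.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    pitch = GENE_SPAN + config.gene_gap
    n_chroms = math.ceil(config.n_genes / config.genes_per_chrom)

    gene_models: list[GeneModel] = []
    for g in range(config.n_genes):
        ci, gi = divmod(g, config.genes_per_chrom)
        start = config.chrom_margin + gi * pitch
        strand = "-" if (config.mixed_strands and g % 2 == 1) else "+"
        gene_models.append(
            GeneModel(f"gene{g:04d}", f"chr{ci + 1}", strand, start, start + GENE_SPAN)
        )

    genes_on = min(config.n_genes, config.genes_per_chrom)
    chrom_len = 2 * config.chrom_margin + genes_on * pitch
    chrom_codes = {
        f"chr{c + 1}": rng.integers(0, 4, chrom_len, dtype=np.uint8)
        for c in range(n_chroms)
    }

    ks = sorted(config.pas_per_gene)
    kp = np.array([config.pas_per_gene[k] for k in ks], dtype=float)

    pas_rows, artifact_rows = [], []
    pas_index = 0
    for gm in gene_models:
        k = int(rng.choice(ks, p=kp))
        slots = [( _DISTAL_UTR3_T, "utr3")]
        intron_avail = list(_INTRON_SLOTS)
        utr3_avail = list(_UTR3_PROXIMAL_SLOTS)
        for _ in range(k - 1):
            want_intron = rng.random() < config.intronic_pas_prob
            if want_intron and intron_avail or not utr3_avail:
                slots.append((intron_avail.pop(0), "intron"))
            else:
                slots.append((utr3_avail.pop(0), "utr3"))
        slots.sort()
        logits = rng.uniform(-0.8, 0.8, size=len(slots))
        for (t, cat), logit in zip(slots, logits):
            motif, offset = None, None
            if rng.random() < config.signal_prob.get(cat, 0.5):
                motif = (
                    CANONICAL_MOTIF
                    if rng.random() < 0.6
                    else SIGNAL_MOTIFS[1 + rng.integers(0, len(SIGNAL_MOTIFS) - 1)]
                )
                offset = int(rng.integers(15, 46))
            pas_rows.append(
                dict(
                    pas_index=pas_index,
                    gene_id=gm.gene_id,
                    chrom=gm.chrom,
                    strand=gm.strand,
                    pos=gm.t_to_genomic(t),
                    t=t,
                    category=cat,
                    logit=float(logit),
                    survival=config.intron_survival if cat == "intron" else 1.0,
                    motif=motif,
                    motif_offset=offset,
                )
            )
            pas_index += 1
        if rng.random() < config.artifact_rate:
            kind = "read" if rng.random() < 0.5 else "pas"
            artifact_rows.append(
                dict(
                    gene_id=gm.gene_id,
                    chrom=gm.chrom,
                    strand=gm.strand,
                    pos=gm.t_to_genomic(_TRAP_T),
                    t=_TRAP_T,
                    kind=kind,
                )
            )

    true_pas = pd.DataFrame(pas_rows)
    artifact_sites = pd.DataFrame(
        artifact_rows, columns=["gene_id", "chrom", "strand", "pos", "t", "kind"]
    )

    gm_by_id = {gm.gene_id: gm for gm in gene_models}
    # plant signal hexamers upstream of true PAS
    for row in true_pas.itertuples():
        if row.motif is not None:
            _plant(
                chrom_codes[row.chrom],
                gm_by_id[row.gene_id],
                int(row.t) - int(row.motif_offset),
                row.motif,
            )
    # keep flanks of true PAS A-poor so no true site looks internally primed
    for row in true_pas.itertuples():
        gmod = gm_by_id[row.gene_id]
        scrub = _scrub_a_rich(rng, 22)
        _plant(chrom_codes[row.chrom], gmod, row.t - 2, codes_to_str(scrub))
    # internal-priming traps: A-rich immediately downstream of the trap position
    for row in artifact_sites.itertuples():
        gmod = gm_by_id[row.gene_id]
        pattern = "A" * 12 if row.kind == "read" else "CACGC" + "A" * 10
        _plant(chrom_codes[row.chrom], gmod, row.t + 1, pattern)

    genome = {c: codes_to_str(codes) for c, codes in chrom_codes.items()}

    # planted apaQTLs: gene subset, one target PAS each, causal SNP within 10 kb
    n_qtl = int(round(config.qtl_fraction * config.n_genes))
    qtl_rows = []
    if n_qtl > 0:
        genes = rng.choice(config.n_genes, size=n_qtl, replace=False)
        for g in sorted(genes):
            gmod = gene_models[g]
            gene_pas = true_pas[true_pas.gene_id == gmod.gene_id]
            target = gene_pas.iloc[int(rng.integers(0, len(gene_pas)))]
            snp_pos = int(
                np.clip(
                    target.pos + rng.integers(-10000, 10001),
                    1,
                    len(genome[gmod.chrom]) - 2,
                )
            )
            beta = float(config.effect_size_beta * (1 if rng.random() < 0.5 else -1))
            qtl_rows.append(
                dict(
                    gene_id=gmod.gene_id,
                    pas_index=int(target.pas_index),
                    snp_id=f"{gmod.chrom}:{snp_pos}",
                    chrom=gmod.chrom,
                    pos=snp_pos,
                    beta=beta,
                )
            )
    qtl_effects = pd.DataFrame(
        qtl_rows, columns=["gene_id", "pas_index", "snp_id", "chrom", "pos", "beta"]
    )

    return SyntheticTruth(genome, gene_models, true_pas, qtl_effects, artifact_sites, config)


def generate_genotypes(truth: SyntheticTruth, config: SyntheticConfig) -> GenotypeMatrix:
    """Draw biallelic dosages for every individual.

    Allele frequencies are uniform on ``maf_range``; dosages are Binomial(2, f)
    per individual.  Rows whose realized sample MAF falls below 5% are redrawn,
    so the emitted matrix honors the MAF floor the QTL scan assumes.
    """
    rng = np.random.default_rng([config.seed, 1])
    individuals = [f"ind{i:03d}" for i in range(config.n_individuals)]

    positions: dict[tuple[str, int], bool] = {}
    for row in truth.qtl_effects.itertuples():
        positions[(row.chrom, row.pos)] = True
    for gm in truth.gene_models:
        lo = max(1, gm.start - 20000)
        hi = min(len(truth.genome[gm.chrom]) - 2, gm.end + 20000)
        for p in rng.integers(lo, hi + 1, size=config.snps_per_gene):
            positions.setdefault((gm.chrom, int(p)), False)

    keys = sorted(positions, key=lambda cp: (int(cp[0][3:]), cp[1]))
    lo_f, hi_f = config.maf_range
    rows, dosage_rows = [], []
    for chrom, pos in keys:
        for _ in range(200):
            f = rng.uniform(lo_f, hi_f)
            dos = rng.binomial(2, f, size=config.n_individuals)
            m = dos.mean() / 2.0
            if min(m, 1.0 - m) >= 0.05:
                break
        rows.append(dict(snp_id=f"{chrom}:{pos}", chrom=chrom, pos=pos,
                         maf=float(f), sample_maf=float(min(m, 1.0 - m))))
        dosage_rows.append(dos)

    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf", "sample_maf"])
    dosages = (
        np.vstack(dosage_rows).astype(np.int8)
        if dosage_rows
        else np.zeros((0, config.n_individuals), dtype=np.int8)
    )
    return GenotypeMatrix(variants, dosages, individuals)


def expected_proportions(
    logits: np.ndarray,
    survival: np.ndarray,
    fraction: str,
    beta: float = 0.0,
    target: int | None = None,
    dosage: float = 0.0,
) -> np.ndarray:
    """Expected PAS proportions for one gene under the generative model."""
    z = np.asarray(logits, dtype=float).copy()
    if target is not None:
        z[target] += beta * dosage
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    if fraction == "total":
        p = p * np.asarray(survival, dtype=float)
        p /= p.sum()
    return p


def _jitter_kernel(width: int) -> tuple[np.ndarray, np.ndarray]:
    half = width // 2
    offsets = np.arange(-half, half + 1)
    sigma = max(width / 4.0, 0.5)
    w = np.exp(-(offsets.astype(float) ** 2) / (2 * sigma**2))
    return offsets, w / w.sum()


def _gene_tables(truth: SyntheticTruth):
    """Per-gene arrays reused across libraries."""
    qtl = {r.gene_id: r for r in truth.qtl_effects.itertuples()}
    tables = []
    for gm in truth.gene_models:
        sub = truth.true_pas[truth.true_pas.gene_id == gm.gene_id]
        entry = dict(
            gene_id=gm.gene_id,
            chrom=gm.chrom,
            strand=gm.strand,
            pos=sub.pos.to_numpy(),
            logits=sub.logit.to_numpy(float),
            survival=sub.survival.to_numpy(float),
            category=sub.category.to_numpy(),
            target=None,
            snp_id=None,
            beta=0.0,
        )
        if gm.gene_id in qtl:
            q = qtl[gm.gene_id]
            entry["target"] = int(np.flatnonzero(sub.pas_index.to_numpy() == q.pas_index)[0])
            entry["snp_id"] = q.snp_id
            entry["beta"] = q.beta
        tables.append(entry)
    return tables


def simulate_library(
    truth: SyntheticTruth,
    genotypes: GenotypeMatrix,
    individual: str,
    fraction: str,
    config: SyntheticConfig,
    _tables=None,
    _snp_rows=None,
) -> MappedReadSet:
    """Simulate the aggregated 3'-end counts of one library."""
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}")
    if individual not in genotypes.individuals:
        raise KeyError(f"unknown individual {individual!r}")
    ind_idx = genotypes.individuals.index(individual)
    rng = np.random.default_rng(
        [config.seed, 2, ind_idx, FRACTIONS.index(fraction)]
    )
    library = f"{individual}_{fraction}"
    tables = _tables if _tables is not None else _gene_tables(truth)
    if _snp_rows is None:
        _snp_rows = {
            s: genotypes.dosages[i]
            for i, s in enumerate(genotypes.variants.snp_id)
            if s in set(truth.qtl_effects.snp_id)
        }
    offsets, kernel = _jitter_kernel(config.peak_width)
    batch_shift = 0.0
    if config.n_batches > 1 and config.batch_effect != 0.0:
        if ind_idx % config.n_batches != 0:
            batch_shift = config.batch_effect

    chroms, poss, strands, counts = [], [], [], []
    for tab in tables:
        depth = rng.poisson(config.read_depth_per_gene)
        if depth == 0:
            continue
        dosage = 0.0
        if tab["snp_id"] is not None:
            dosage = float(_snp_rows[tab["snp_id"]][ind_idx])
        logits = tab["logits"]
        if batch_shift:
            logits = logits.copy()
            logits[-1] += batch_shift  # shifts the distal-PAS balance for the batch
        p = expected_proportions(
            logits, tab["survival"], fraction, tab["beta"], tab["target"], dosage
        )
        if config.dm_concentration is not None:
            p = rng.dirichlet(np.maximum(p * config.dm_concentration, 1e-8))
        pas_counts = rng.multinomial(depth, p)
        for pas_pos, c in zip(tab["pos"], pas_counts):
            if c == 0:
                continue
            spread = rng.multinomial(c, kernel)
            nz = spread > 0
            n = int(nz.sum())
            chroms.extend([tab["chrom"]] * n)
            poss.extend((pas_pos + offsets[nz]).tolist())
            strands.extend([tab["strand"]] * n)
            counts.extend(spread[nz].tolist())

    for row in truth.artifact_sites.itertuples():
        c = rng.poisson(config.artifact_depth)
        if c > 0:
            chroms.append(row.chrom)
            poss.append(row.pos)
            strands.append(row.strand)
            counts.append(int(c))

    frame = pd.DataFrame(
        dict(chrom=chroms, pos=poss, strand=strands, library=library, count=counts)
    )
    return MappedReadSet(frame, [library])


def simulate_dataset(
    truth: SyntheticTruth,
    genotypes: GenotypeMatrix,
    config: SyntheticConfig,
) -> tuple[MappedReadSet, pd.DataFrame]:
    """All libraries (every individual x fraction) plus the sample sheet."""
    tables = _gene_tables(truth)
    planted = set(truth.qtl_effects.snp_id)
    snp_rows = {
        s: genotypes.dosages[i]
        for i, s in enumerate(genotypes.variants.snp_id)
        if s in planted
    }
    frames, sheet = [], []
    for i, ind in enumerate(genotypes.individuals):
        for fraction in FRACTIONS:
            rs = simulate_library(
                truth, genotypes, ind, fraction, config, _tables=tables, _snp_rows=snp_rows
            )
            frames.append(rs.counts)
            sheet.append(
                dict(
                    library_id=f"{ind}_{fraction}",
                    individual=ind,
                    fraction=fraction,
                    batch=f"batch{i % max(config.n_batches, 1)}",
                )
            )
    libraries = [r["library_id"] for r in sheet]
    combined = MappedReadSet(pd.concat(frames, ignore_index=True), libraries)
    return combined, pd.DataFrame(sheet)


def write_dataset(
    truth: SyntheticTruth,
    genotypes: GenotypeMatrix,
    read_set: MappedReadSet,
    sample_sheet: pd.DataFrame,
    out_dir,
    force: bool = False,
) -> dict[str, object]:
    """Emit the study as plain-text files (FASTA/GFF3/BED/VCF/TSVs)."""
    from . import io as _io

    return _io.write_dataset(truth, genotypes, read_set, sample_sheet, out_dir, force=force)
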
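"""Cross-dataset statistics: sharing (Storey pi1), concordance, enrichment.

These are the summary analyses run after QTL mapping: how many associations
ascertained in one dataset replicate in another (pi1 = 1 - pi0 from the
p-value distribution), whether effect sizes agree across datasets, whether
particular gene categories are enriched for small association p-values, how
external QTL gene-variant pairs overlap nominal associations after a per-gene
Bonferroni correction, and bootstrap confidence intervals on the annotation
classes QTL variants fall into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SharingEstimate:
    pi0: float
    pi1: float
    lambda_grid: np.ndarray
    n: int


def pi1_estimate(
    pvalues,
    lambda_grid: np.ndarray | None = None,
    method: str = "smoother",
) -> SharingEstimate:
    """Storey pi0/pi1 from a p-value vector.

    ``pi0(lambda) = #{p > lambda} / (n (1 - lambda))`` is evaluated on the
    grid (default 0.05..0.95 by 0.05); the final estimate is a cubic
    polynomial smooth of pi0(lambda) evaluated at the largest lambda
    ("smoother"), or the mean of the three largest-lambda values
    ("terminal"), clipped to [0, 1].  pi1 = 1 - pi0 measures the fraction of
    tests drawn from the non-null component, i.e. sharing when the p-values
    come from one dataset's lead associations re-tested in another.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 20:
        raise ValueError("pi1 estimation needs at least 20 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = (
        np.arange(0.05, 0.951, 0.05) if lambda_grid is None else np.asarray(lambda_grid, float)
    )
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])

    if method == "smoother" and grid.size >= 4:
        try:
            coeffs = np.polynomial.polynomial.polyfit(grid, pi0_l, deg=3)
            pi0 = float(np.polynomial.polynomial.polyval(grid.max(), coeffs))
        except np.linalg.LinAlgError:
            pi0 = float(np.mean(np.sort(pi0_l)[:3]))
    elif method == "terminal" or grid.size < 4:
        order = np.argsort(grid)
        pi0 = float(pi0_l[order[-3:]].mean()) if grid.size >= 3 else float(pi0_l[order[-1]])
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return SharingEstimate(pi0, 1.0 - pi0, grid, p.size)


def effect_concordance(slopes_a, slopes_b) -> tuple[float, float, float]:
    """Pearson r, OLS slope of B on A, and the slope's two-sided p."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired effect sizes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance effect vector")
    r = float(sps.pearsonr(a, b).statistic)
    fit = sps.linregress(a, b)
    return r, float(fit.slope), float(fit.pvalue)


def category_enrichment(
    pvalues: pd.Series, categories: pd.Series, background: str = "background"
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum tests of each category against background.

    Tests whether the category's association p-values are stochastically
    smaller (more significant) than the background group's.  Exact null
    distribution for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's default policy).
    """
    cats = pd.Series(categories)
    pv = pd.Series(pvalues)
    bg = pv[cats == background].to_numpy()
    if bg.size == 0:
        raise ValueError("empty background group")
    rows = []
    for cat in sorted(set(cats) - {background}):
        x = pv[cats == cat].to_numpy()
        if x.size == 0:
            raise ValueError(f"empty category {cat!r}")
        res = sps.mannwhitneyu(x, bg, alternative="less")
        rows.append(dict(category=cat, n=x.size, n_background=bg.size,
                         statistic=float(res.statistic), p_value=float(res.pvalue)))
    return pd.DataFrame(rows)


def gene_overlap_test(
    external_pairs: pd.DataFrame,
    nominal: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene overlap of external QTLs with nominal apaQTL associations.

    ``external_pairs`` has columns (gene_id, snp_id); ``nominal`` has columns
    (gene_id, pas_id, snp_id, nominal_p).  For each external pair the most
    significant nominal p across the gene's K tested PAS is Bonferroni
    corrected by K; the pair is flagged overlapping when the corrected p is
    below ``alpha``.  Genes with no tested PAS for the queried variant are
    returned unflagged with ``n_pas == 0``.
    """
    rows = []
    grouped = nominal.groupby(["gene_id", "snp_id"])
    for row in external_pairs.itertuples():
        try:
            sub = grouped.get_group((row.gene_id, row.snp_id))
        except KeyError:
            rows.append(dict(gene_id=row.gene_id, snp_id=row.snp_id, n_pas=0,
                             min_p=np.nan, p_adj=np.nan, overlapping=False))
            continue
        k = sub.pas_id.nunique()
        min_p = float(sub.nominal_p.min())
        p_adj = min(1.0, k * min_p)
        rows.append(dict(gene_id=row.gene_id, snp_id=row.snp_id, n_pas=k,
                         min_p=min_p, p_adj=p_adj, overlapping=p_adj < alpha))
    return pd.DataFrame(rows)


def annotation_overlap_bootstrap(
    variant_positions: pd.DataFrame,
    annotation: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Class membership proportions of a variant set with bootstrap CIs.

    ``variant_positions`` has columns (chrom, pos); ``annotation`` has columns
    (chrom, start, end, label).  Each variant takes the label of the first
    interval containing it ("none" if uncovered); percentile confidence
    intervals come from ``n_boot`` resamples of the variant set with
    replacement.
    """
    labels = []
    by_chrom = {c: sub.sort_values("start") for c, sub in annotation.groupby("chrom")}
    for row in variant_positions.itertuples():
        sub = by_chrom.get(row.chrom)
        lab = "none"
        if sub is not None:
            hit = sub[(sub.start <= row.pos) & (row.pos < sub.end)]
            if len(hit):
                lab = str(hit.label.iloc[0])
        labels.append(lab)
    labels = np.array(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("no variants given")
    classes = sorted(set(labels) | set(annotation.label.unique()))

    rng = np.random.default_rng(seed)
    boot = np.zeros((n_boot, len(classes)))
    for b in range(n_boot):
        res = labels[rng.integers(0, n, size=n)]
        for j, cls in enumerate(classes):
            boot[b, j] = (res == cls).mean()
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for j, cls in enumerate(classes):
        rows.append(
            dict(
                label=cls,
                proportion=float((labels == cls).mean()),
                ci_low=float(np.quantile(boot[:, j], lo_q)),
                ci_high=float(np.quantile(boot[:, j], hi_q)),
            )
        )
    return pd.DataFrame(rows)
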
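"""Nuclear vs total differential PAS usage via a Dirichlet-multinomial LRT.

Each gene's PAS counts across samples are modelled as Dirichlet-multinomial
(DM) with mean proportions ``p`` and concentration ``alpha0`` (larger
``alpha0`` means less sample-to-sample overdispersion; the multinomial is the
``alpha0 -> inf`` limit).  The null fit shares ``p`` across the two cellular
fractions; the alternative fits one ``p`` per fraction; ``alpha0`` is shared
under both, and twice the log-likelihood gain is referred to chi-square with
K-1 degrees of freedom.

Effect sizes are reported as dPAU = mean total usage - mean nuclear usage on
the raw usage-ratio scale, so a positive dPAU means the site is used more in
the total (steady-state) fraction and a negative dPAU marks nuclear-enriched
sites, the signature expected of isoforms that are degraded or retained
before export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .peaks import UsageMatrix


@dataclass
class DMFit:
    proportions: np.ndarray
    alpha0: float
    log_likelihood: float


@dataclass
class DifferentialResult:
    gene_id: str
    lrt_statistic: float
    p_value: float
    dpau: np.ndarray  # per PAS, total minus nuclear mean usage
    null_fit: DMFit | None
    alt_fits: dict[str, DMFit] | None
    converged: bool


def dm_loglik(counts, p, alpha0: float) -> float:
    """Log pmf of the Dirichlet-multinomial with alpha = alpha0 * p.

    ``counts`` may be a single K-vector or an (S, K) matrix of independent
    samples (rows are summed).  Categories with ``p == 0`` contribute
    ``-inf`` when their count is positive and nothing otherwise.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    p = np.asarray(p, dtype=float)
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    alpha = alpha0 * p
    n = counts.sum(axis=1)

    zero = p <= 0.0
    if np.any(zero):
        if np.any(counts[:, zero] > 0):
            return -np.inf
        counts = counts[:, ~zero]
        alpha = alpha[~zero]

    ll = (
        special.gammaln(n + 1).sum()
        - special.gammaln(counts + 1).sum()
        + counts.shape[0] * (special.gammaln(alpha0))
        - special.gammaln(n + alpha0).sum()
        + special.gammaln(counts + alpha).sum()
        - counts.shape[0] * special.gammaln(alpha).sum()
    )
    return float(ll)


_LOGITS_BOUND = 15.0
_LOG_A0_BOUNDS = (-3.0, 16.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _init_logits(counts: np.ndarray) -> np.ndarray:
    p = counts.sum(axis=0) + 0.5
    p = p / p.sum()
    z = np.log(p)
    return (z - z[-1])[:-1]


def _fit_dm(groups: list[np.ndarray]) -> tuple[list[DMFit], bool]:
    """Fit per-group proportions with one shared concentration.

    ``groups`` is a list of (S_g, K) count matrices.  Proportions are
    parametrized as softmax logits (last category pinned at 0) and the
    concentration on the log scale, optimized jointly by L-BFGS-B.
    """
    k = groups[0].shape[1]
    logits0 = np.concatenate([_init_logits(g) for g in groups])

    def unpack(x):
        zs = [
            np.concatenate([x[i * (k - 1) : (i + 1) * (k - 1)], [0.0]])
            for i in range(len(groups))
        ]
        return [_softmax(z) for z in zs], float(np.exp(x[-1]))

    def nll(x):
        ps, a0 = unpack(x)
        return -sum(dm_loglik(g, p, a0) for g, p in zip(groups, ps))

    bounds = [(-_LOGITS_BOUND, _LOGITS_BOUND)] * ((k - 1) * len(groups)) + [_LOG_A0_BOUNDS]
    # the likelihood is flat in log(alpha0) once the data look multinomial, so
    # start both at a moderate concentration and at the multinomial-limit bound
    best = None
    for log_a0 in (np.log(50.0), _LOG_A0_BOUNDS[1]):
        x0 = np.concatenate([logits0, [log_a0]])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options=dict(maxiter=500, ftol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    ps, a0 = unpack(best.x)
    fits = [DMFit(p, a0, dm_loglik(g, p, a0)) for g, p in zip(groups, ps)]
    return fits, bool(best.success)


def differential_usage_test(
    counts: np.ndarray, fractions: np.ndarray, gene_id: str = ""
) -> DifferentialResult:
    """DM likelihood-ratio test of fraction-dependent PAS proportions.

    ``counts`` is samples x K; ``fractions`` labels each row "nuclear" or
    "total" (at least two samples of each).  Returns the LRT against
    chi-square with K-1 df plus per-PAS dPAU computed from raw usage means.
    """
    counts = np.asarray(counts, dtype=float)
    fractions = np.asarray(fractions)
    k = counts.shape[1]
    if k < 2:
        raise ValueError("differential usage needs at least 2 PAS")
    nuc = counts[fractions == "nuclear"]
    tot = counts[fractions == "total"]
    if len(nuc) < 2 or len(tot) < 2:
        raise ValueError("need at least 2 samples per fraction")

    def mean_usage(block):
        totals = block.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(totals > 0, block / np.where(totals > 0, totals, 1), np.nan)
        return np.nanmean(u, axis=0)

    dpau = mean_usage(tot) - mean_usage(nuc)

    (null_fit,), ok0 = _fit_dm([counts])
    (fit_nuc, fit_tot), ok1 = _fit_dm([nuc, tot])
    ll0 = null_fit.log_likelihood
    lla = fit_nuc.log_likelihood + fit_tot.log_likelihood
    lrt = max(0.0, 2.0 * (lla - ll0))
    p = float(stats.chi2.sf(lrt, df=k - 1))
    converged = ok0 and ok1
    return DifferentialResult(
        gene_id, lrt, p, dpau,
        null_fit if converged else None,
        {"nuclear": fit_nuc, "total": fit_tot} if converged else None,
        converged,
    )


def fraction_differential_table(matrix: UsageMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the gene-level test over every multi-PAS gene of a usage matrix.

    Returns ``(gene_table, pas_table)``: per-gene LRT/p and per-PAS dPAU.
    """
    fractions = matrix.sample_sheet.loc[matrix.counts.columns, "fraction"].to_numpy()
    gene_rows, pas_rows = [], []
    for gene_id, sub in matrix.pas_meta.groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        block = matrix.counts.loc[sub.index].to_numpy().T  # samples x K
        res = differential_usage_test(block, fractions, gene_id=gene_id)
        gene_rows.append(
            dict(gene_id=gene_id, n_pas=len(sub), lrt=res.lrt_statistic,
                 p_value=res.p_value, converged=res.converged)
        )
        for pas_id, d in zip(sub.index, res.dpau):
            pas_rows.append(dict(pas_id=pas_id, gene_id=gene_id, dpau=float(d)))
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "n_pas", "lrt", "p_value", "converged"])
    pas_table = pd.DataFrame(pas_rows, columns=["pas_id", "gene_id", "dpau"])
    return gene_table, pas_table


def classify_differential(
    gene_table: pd.DataFrame,
    pas_table: pd.DataFrame,
    fdr: float = 0.1,
    dpau_cut: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH-correct gene p-values and label large-effect PAS.

    Within genes significant at ``fdr``, PAS with |dPAU| > ``dpau_cut`` are
    labelled "total-enriched" (positive) or "nuclear-enriched" (negative);
    everything else is unlabelled.
    """
    gene_table = gene_table.copy()
    if len(gene_table):
        rej, qvals, _, _ = multipletests(gene_table.p_value, alpha=fdr, method="fdr_bh")
    else:
        rej, qvals = np.array([], bool), np.array([])
    gene_table["q_value"] = qvals
    gene_table["significant"] = rej

    sig_genes = set(gene_table.gene_id[gene_table.significant])
    pas_table = pas_table.copy()

    def label(row):
        if row.gene_id not in sig_genes or abs(row.dpau) <= dpau_cut:
            return None
        return "total-enriched" if row.dpau > 0 else "nuclear-enriched"

    pas_table["label"] = [label(r) for r in pas_table.itertuples()]
    return gene_table, pas_table


def nuclear_enriched_pas(
    matrix: UsageMatrix,
    gene_table: pd.DataFrame,
    pas_table: pd.DataFrame,
    dpau_cut: float = 0.2,
    absent_cut: float = 0.01,
) -> pd.DataFrame:
    """PAS used at least ``dpau_cut`` more in the nuclear fraction.

    Restricted to FDR-significant genes; sites whose mean total usage is at
    most ``absent_cut`` are additionally flagged as near-absent from the
    steady-state pool (candidates for fully degraded/retained isoforms).
    """
    sig_genes = set(gene_table.gene_id[gene_table.get("significant", pd.Series(dtype=bool))])
    mean_total = matrix.mean_usage("total")
    rows = []
    for row in pas_table.itertuples():
        if row.gene_id not in sig_genes or row.dpau > -dpau_cut:
            continue
        mt = float(mean_total.get(row.pas_id, np.nan))
        rows.append(
            dict(pas_id=row.pas_id, gene_id=row.gene_id, dpau=row.dpau,
                 mean_total_usage=mt, near_absent_in_total=bool(mt <= absent_cut))
        )
    return pd.DataFrame(
        rows, columns=["pas_id", "gene_id", "dpau", "mean_total_usage", "near_absent_in_total"]
    )
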
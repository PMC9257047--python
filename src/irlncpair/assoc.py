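"""Downstream characterization of the risk signature.

Immune-infiltration and checkpoint contrasts between risk groups,
single-gene analyses (tumor-vs-normal contrast, median-split survival,
clinicopathological Cox), a weighted Kolmogorov-Smirnov gene-set
enrichment score with phenotype-permutation significance, and the
co-expression gene list exported for connectivity-map queries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix
from .stats import ConstantInputError, bh_adjust, pearson, rank_test, spearman
from .survival import cox_fit, km_curve, logrank
from .pairs import RiskSignature, _median_split_km_p

__all__ = [
    "EnrichmentResult",
    "infiltration_association",
    "checkpoint_contrast",
    "single_gene_analysis",
    "gsea_es",
    "gsea_permutation",
    "coexpression_list",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    n_hit: int


def infiltration_association(
    infil: pd.DataFrame,
    sig: RiskSignature,
    min_per_group: int = 10,
) -> pd.DataFrame:
    """Per cell type: rank-sum contrast between risk groups and Spearman
    correlation of riskScore with the fraction.

    Returns a table with the Mann-Whitney U, its p, the shift direction
    (high - low), the Spearman rho and p, and a BH fdr across cell types.
    Cell types where the correlation is undefined (e.g. constant
    fractions) get NaN rho rather than raising.
    """
    common = [s for s in infil.columns if s in sig.risk.index]
    risk = sig.risk.loc[common]
    n_high = int((risk == 1).sum())
    n_low = int((risk == 0).sum())
    if min(n_high, n_low) < min_per_group:
        raise ValueError(
            f"need >= {min_per_group} samples per risk group in the "
            f"infiltration table (got high={n_high}, low={n_low})"
        )
    rows = []
    for ct in infil.index:
        frac = infil.loc[ct, common].to_numpy(dtype=float)
        hi = frac[risk.to_numpy() == 1]
        lo = frac[risk.to_numpy() == 0]
        t = rank_test(hi, lo)
        try:
            c = spearman(risk.to_numpy(dtype=float), frac)
            rho, rho_p = c.r, c.p
        except ConstantInputError:
            rho, rho_p = np.nan, np.nan
        rows.append((ct, t.statistic, t.p, t.direction, rho, rho_p))
    out = pd.DataFrame(
        rows, columns=["cell_type", "U", "p", "direction", "spearman_rho", "spearman_p"]
    ).set_index("cell_type")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < 0.05
    return out


def checkpoint_contrast(
    expr: ExpressionMatrix, ic_gene_ids: list[str], sig: RiskSignature
) -> pd.DataFrame:
    """Rank-sum contrast of checkpoint-gene expression between risk groups.

    Missing genes are reported as absent (NaN row) and the rest processed.
    """
    tumor = [s for s in expr.tumor_samples if s in sig.risk.index]
    risk = sig.risk.loc[tumor].to_numpy()
    rows = []
    for gid in ic_gene_ids:
        if gid not in expr.values.index:
            rows.append((gid, np.nan, np.nan, 0, False))
            continue
        x = expr.values.loc[gid, tumor].to_numpy(dtype=float)
        t = rank_test(x[risk == 1], x[risk == 0])
        rows.append((gid, t.statistic, t.p, t.direction, True))
    out = pd.DataFrame(
        rows, columns=["gene_id", "U", "p", "direction", "present"]
    ).set_index("gene_id")
    return out


def single_gene_analysis(
    expr: ExpressionMatrix,
    gene_id: str,
    clinical: pd.DataFrame,
    covariates: list[str] = ("stage", "t", "n", "m"),
) -> dict:
    """One member gene's own association with the disease.

    (1) tumor-vs-normal rank-sum contrast of expression; (2) median-split
    Kaplan-Meier with log-rank (exact-median samples go to the low group);
    (3) univariate and multivariate Cox of the high/low indicator together
    with the clinicopathological covariates.
    """
    if gene_id not in expr.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    tum_x = expr.values.loc[gene_id, expr.tumor_samples].to_numpy(dtype=float)
    nor_x = expr.values.loc[gene_id, expr.normal_samples].to_numpy(dtype=float)
    if np.ptp(np.concatenate([tum_x, nor_x])) == 0:
        raise ValueError("constant expression; analysis undefined")
    contrast = rank_test(tum_x, nor_x)

    tumor = [s for s in expr.tumor_samples if s in clinical.index]
    x = expr.values.loc[gene_id, tumor].to_numpy(dtype=float)
    med = float(np.median(x))
    high = (x > med).astype(int)  # ties at the median -> low group
    clin = clinical.loc[tumor]
    time = clin["time"].to_numpy()
    event = clin["event"].to_numpy()
    lr = logrank(time, event, high)
    km_high = km_curve(time[high == 1], event[high == 1])
    km_low = km_curve(time[high == 0], event[high == 0])

    base = pd.DataFrame({"time": time, "event": event, "high_expression": high.astype(float)})
    for c in covariates:
        base[c] = clin[c].to_numpy(dtype=float)
    uni_rows = []
    for c in ["high_expression", *covariates]:
        if np.ptp(base[c].to_numpy()) == 0:
            uni_rows.append((c, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        fit = cox_fit(base[["time", "event", c]], [c])
        ci = fit.ci95
        uni_rows.append(
            (c, fit.beta[0], fit.hr[0], ci[0, 0], ci[0, 1], float(fit.wald_p[0]),
             fit.converged)
        )
    uni = pd.DataFrame(
        uni_rows,
        columns=["covariate", "beta", "HR", "ci_low", "ci_high", "p", "converged"],
    ).set_index("covariate")
    multi_covs = [c for c in ["high_expression", *covariates]
                  if np.ptp(base[c].to_numpy()) > 0]
    mfit = cox_fit(base, multi_covs)
    multi = mfit.to_frame()
    multi["converged"] = mfit.converged
    return {
        "tumor_vs_normal": contrast,
        "median_split_logrank": lr,
        "km_high": km_high,
        "km_low": km_low,
        "unicox": uni,
        "multicox": multi,
    }


def gsea_es(
    ranked_genes: list[str],
    metric: np.ndarray,
    gene_set: set[str] | list[str],
    weight_p: float = 1.0,
) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    ``ranked_genes`` must be sorted by decreasing ranking metric.  Hits
    step the running sum up by |metric|^p normalized over the hits; misses
    step it down by 1/(N - N_hit); the ES is the extremum (signed).
    """
    genes = list(ranked_genes)
    m = np.asarray(metric, dtype=float)
    if len(genes) != m.size:
        raise ValueError("ranked_genes and metric must align")
    if not np.all(np.isfinite(m)):
        raise ValueError("ranking metric must be finite")
    in_set = np.array([g in set(gene_set) for g in genes])
    n_hit = int(in_set.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list; ES degenerate")
    w = np.abs(m) ** weight_p
    hit_norm = w[in_set].sum()
    if hit_norm == 0:
        # all hit metrics zero: fall back to uniform hit steps
        steps = np.where(in_set, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(in_set, w / hit_norm, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext])


def _snr_metric(X: np.ndarray, labels: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Signal-to-noise ranking metric per gene.

    (mean_high - mean_low) / (sd_high + sd_low); the denominator is
    stabilized by ``eps`` so a zero-variance gene does not divide by zero.
    """
    hi = X[:, labels == 1]
    lo = X[:, labels == 0]
    num = hi.mean(axis=1) - lo.mean(axis=1)
    den = hi.std(axis=1, ddof=1) + lo.std(axis=1, ddof=1)
    return num / np.maximum(den, eps)


def gsea_permutation(
    expr: ExpressionMatrix,
    gene_id: str,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[EnrichmentResult]:
    """GSEA between the top-50% and bottom-50% expressors of one gene.

    Tumor samples are split at the median expression of ``gene_id`` (the
    top 50% form the high group).  The ranking metric is the per-gene
    signal-to-noise ratio, recomputed under each phenotype permutation.
    NES = ES / mean(|null ES| of matching sign);
    p = (1 + #{null at least as extreme, matching sign}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if gene_id not in expr.values.index:
        raise KeyError(gene_id)
    tumor = expr.tumor_samples
    x = expr.values.loc[gene_id, tumor].to_numpy(dtype=float)
    med = float(np.median(x))
    labels = (x > med).astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("median split produced an empty group")
    genes = [g for g in expr.values.index if g != gene_id]
    X = expr.values.loc[genes, tumor].to_numpy(dtype=float)

    def _all_es(lab: np.ndarray) -> dict[str, float]:
        metric = _snr_metric(X, lab)
        order = np.argsort(-metric, kind="mergesort")
        ranked = [genes[i] for i in order]
        met_sorted = metric[order]
        out = {}
        for name, members in gene_sets.items():
            out[name] = gsea_es(ranked, met_sorted, members, weight_p)
        return out

    obs = _all_es(labels)
    rng = np.random.default_rng(seed)
    null = {name: [] for name in gene_sets}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        es_p = _all_es(perm)
        for name, v in es_p.items():
            null[name].append(v)

    results = []
    for name, es in obs.items():
        nl = np.asarray(null[name])
        same_sign = nl[np.sign(nl) == np.sign(es)] if es != 0 else nl
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        if es >= 0:
            extreme = int(np.sum(nl >= es))
        else:
            extreme = int(np.sum(nl <= es))
        p = (1 + extreme) / (1 + n_perm)
        results.append(
            EnrichmentResult(
                set_name=name,
                es=float(es),
                nes=float(nes),
                p_perm=float(p),
                n_perm=n_perm,
                n_hit=len(set(gene_sets[name]) & set(genes)),
            )
        )
    return results


def coexpression_list(
    expr: ExpressionMatrix,
    pair: tuple[str, str],
    r_min: float = 0.5,
    p_max: float = 0.001,
) -> list[str]:
    """Genes co-expressed with BOTH signature lncRNAs.

    A gene qualifies when its Pearson correlation with each member exceeds
    ``r_min`` with p below ``p_max`` (all samples).  The two members
    themselves are excluded.  The list is what a connectivity-map query
    takes as input.
    """
    a, b = pair
    for g in pair:
        if g not in expr.values.index:
            raise KeyError(f"pair member {g!r} not in expression matrix")
    xa = expr.values.loc[a].to_numpy(dtype=float)
    xb = expr.values.loc[b].to_numpy(dtype=float)
    out = []
    for g in expr.values.index:
        if g in pair:
            continue
        xg = expr.values.loc[g].to_numpy(dtype=float)
        try:
            ca = pearson(xg, xa)
            cb = pearson(xg, xb)
        except ConstantInputError:
            continue
        if ca.r > r_min and ca.p < p_max and cb.r > r_min and cb.p < p_max:
            out.append(g)
    return out
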
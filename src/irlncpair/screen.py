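"""Candidate screening: immune-related, differentially expressed, prognostic.

Three successive filters reduce the lncRNA universe to the prognostic
candidates that feed the pair matrix:

1. immune correlation screen — a lncRNA is immune-related (irlncRNA) iff
   it correlates with at least one immune gene at r > 0.5 and p < 0.001;
2. differential-expression screen — moderated-t between tumor and normal,
   keep |logFC| >= 1.5 and p < 0.05 (direction recorded for the later
   same-trend rule);
3. survival screen — univariate Cox on continuous expression at p < 0.01,
   then a joint multivariate Cox keeping Wald p < 0.05.

Thresholds live in :class:`ScreenConfig`; strictness of each comparison
(>, <, >=) follows the stated convention exactly and is unit-tested at the
boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix
from .survival import CoxFit, cox_fit
from .stats import moderated_t_table

__all__ = ["ScreenConfig", "ScreenReport", "immune_correlation_screen", "de_screen", "survival_screen", "run_screen"]


@dataclass(frozen=True)
class ScreenConfig:
    r_min: float = 0.5
    p_corr_max: float = 0.001
    logfc_min: float = 1.5
    p_de_max: float = 0.05
    p_unicox_max: float = 0.01
    p_multicox_max: float = 0.05
    corr_tumor_only: bool = False

    def validate(self) -> None:
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError("r_min must lie in [-1, 1]")
        for name in ("p_corr_max", "p_de_max", "p_unicox_max", "p_multicox_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.logfc_min < 0:
            raise ValueError("logfc_min must be non-negative")


@dataclass
class ScreenReport:
    irlncrna_ids: list[str]
    de_records: pd.DataFrame
    unicox_table: pd.DataFrame
    unicox_survivors: list[str]
    multicox_table: pd.DataFrame
    multicox_survivors: list[str]
    flags: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "irlncrna": len(self.irlncrna_ids),
            "de_irlncrna": int(len(self.de_records)),
            "unicox": len(self.unicox_survivors),
            "multicox": len(self.multicox_survivors),
        }


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between the rows of A and the rows of B.

    Vectorized evaluation of the same product-moment formula as
    :func:`irlncpair.stats.pearson`; rows with zero variance yield NaN.
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac @ Bc.T) / np.outer(sa, sb)
    return np.clip(r, -1.0, 1.0)


def immune_correlation_screen(
    expr: ExpressionMatrix,
    lnc_ids: list[str],
    immune_gene_ids: list[str],
    config: ScreenConfig | None = None,
) -> list[str]:
    """Keep lncRNAs correlating with >= 1 immune gene at r > r_min, p < p_corr_max.

    By default the correlation runs over all samples (tumor + normal);
    ``config.corr_tumor_only`` restricts it to tumors.  Output is sorted
    by id and deterministic.
    """
    from scipy import stats as _spdist

    config = config or ScreenConfig()
    config.validate()
    present_imm = [g for g in immune_gene_ids if g in expr.values.index]
    if not present_imm:
        raise ValueError("no immune genes present in the expression matrix")
    overlap = set(lnc_ids) & set(present_imm)
    if overlap:
        raise ValueError(f"lncRNA and immune gene id sets overlap: {sorted(overlap)[:5]}")
    cols = expr.tumor_samples if config.corr_tumor_only else list(expr.values.columns)
    L = expr.values.loc[lnc_ids, cols].to_numpy(dtype=float)
    G = expr.values.loc[present_imm, cols].to_numpy(dtype=float)
    n = len(cols)
    r = _corr_matrix(L, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * _spdist.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    keep = np.any((r > config.r_min) & (p < config.p_corr_max) & np.isfinite(r), axis=1)
    return sorted(np.asarray(lnc_ids)[keep])


def de_screen(
    expr: ExpressionMatrix,
    irlncrna_ids: list[str],
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Differential-expression screen restricted to irlncRNAs.

    Keeps |logFC| >= logfc_min (inclusive) AND p < p_de_max (strict).
    Returns the significant DE records (may be empty; downstream stages
    halt explicitly on an empty set).
    """
    config = config or ScreenConfig()
    config.validate()
    if not irlncrna_ids:
        raise ValueError("irlncRNA id list is empty")
    table = moderated_t_table(expr.values.loc[irlncrna_ids], expr.groups)
    keep = (table["logFC"].abs() >= config.logfc_min) & (table["p"] < config.p_de_max)
    return table[keep].copy()


def survival_screen(
    expr: ExpressionMatrix,
    de_ids: list[str],
    clinical: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame, list[str], list[str]]:
    """Univariate then multivariate Cox screen on continuous expression.

    Returns (unicox_table, unicox_survivors, multicox_table,
    multicox_survivors, flags).  With fewer than two univariate survivors
    the multivariate step is skipped and survivors pass through, flagged.
    A non-converged multivariate fit (e.g. collinear lncRNAs) is flagged
    and its survivors are not trusted.
    """
    config = config or ScreenConfig()
    config.validate()
    if not de_ids:
        raise ValueError("no DE irlncRNAs to screen")
    tumor = [s for s in expr.tumor_samples if s in clinical.index]
    if len(tumor) < 10:
        raise ValueError("too few tumor samples matched to clinical data")
    clin = clinical.loc[tumor]
    flags: list[str] = []

    rows = []
    survivors = []
    for lid in de_ids:
        df = pd.DataFrame(
            {
                "time": clin["time"].to_numpy(),
                "event": clin["event"].to_numpy(),
                "x": expr.values.loc[lid, tumor].to_numpy(),
            }
        )
        try:
            fit = cox_fit(df, ["x"])
        except ValueError:
            flags.append(f"univariate Cox failed for {lid}")
            continue
        p = float(fit.wald_p[0]) if fit.converged else np.nan
        ci = fit.ci95
        rows.append((lid, fit.beta[0], fit.hr[0], ci[0, 0], ci[0, 1], p, fit.converged))
        if fit.converged and p < config.p_unicox_max:
            survivors.append(lid)
    uni_table = pd.DataFrame(
        rows, columns=["covariate", "beta", "HR", "ci_low", "ci_high", "p", "converged"]
    ).set_index("covariate")

    if len(survivors) < 2:
        flags.append("fewer than 2 univariate survivors; multivariate step skipped")
        return uni_table, survivors, uni_table.loc[survivors], list(survivors), flags

    df = pd.DataFrame(
        {lid: expr.values.loc[lid, tumor].to_numpy() for lid in survivors}
    )
    df["time"] = clin["time"].to_numpy()
    df["event"] = clin["event"].to_numpy()
    fit = cox_fit(df, survivors)
    multi_table = fit.to_frame()
    multi_table["converged"] = fit.converged
    if not fit.converged:
        flags.append("multivariate Cox did not converge (collinearity or separation)")
        return uni_table, survivors, multi_table, [], flags
    multi_survivors = [
        lid for lid, p in zip(survivors, fit.wald_p) if p < config.p_multicox_max
    ]
    return uni_table, survivors, multi_table, multi_survivors, flags


def run_screen(
    expr: ExpressionMatrix,
    lnc_ids: list[str],
    immune_gene_ids: list[str],
    clinical: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """Full three-stage screen; stage containment holds by construction."""
    config = config or ScreenConfig()
    ir = immune_correlation_screen(expr, lnc_ids, immune_gene_ids, config)
    if not ir:
        return ScreenReport(ir, pd.DataFrame(), pd.DataFrame(), [], pd.DataFrame(), [],
                            flags=["no immune-related lncRNAs"])
    de = de_screen(expr, ir, config)
    if de.empty:
        return ScreenReport(ir, de, pd.DataFrame(), [], pd.DataFrame(), [],
                            flags=["no differentially expressed irlncRNAs"])
    uni_t, uni_s, multi_t, multi_s, flags = survival_screen(
        expr, list(de.index), clinical, config
    )
    return ScreenReport(ir, de, uni_t, uni_s, multi_t, multi_s, flags=flags)
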
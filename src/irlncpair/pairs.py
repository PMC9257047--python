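"""The 0-or-1 pair matrix and the final single-pair risk signature.

The central construct: for every unordered pair {A, B} of prognostic
lncRNAs, each tumor sample gets a binary feature — 1 when A's expression
strictly exceeds B's within that sample (canonical orientation is
lexicographic id order; ties score 0).  Because the feature uses only the
within-sample expression order, it is robust to platform and
normalization differences between cohorts.

Pairs whose one-frequency falls outside [0.2, 0.8] cannot stratify the
cohort and are dropped.  The survivors pass a univariate Cox screen,
LASSO-Cox selection, a joint multivariate Cox, the same-expression-trend
rule, and a median-split Kaplan-Meier significance rule on the member
genes; the single remaining pair (smallest multivariate Wald p) becomes
the risk signature.  A sample is high-risk (riskScore 1) when the
hazardous member's expression is >= the protective member's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix
from .survival import cox_fit, km_curve, lasso_cox, logrank

__all__ = [
    "PairMatrix",
    "RiskSignature",
    "NoSignature",
    "build_pair_matrix",
    "frequency_filter",
    "pair_cox_screen",
    "select_final_pair",
    "evaluate_signature",
]


@dataclass
class PairMatrix:
    """Binary pairs x tumor-samples matrix.

    Rows are labelled "A|B" with A < B lexicographically; ``pairs`` maps
    the row label to the (A, B) tuple.  ``one_frequency`` is the mean of
    each row.
    """

    values: pd.DataFrame
    pairs: dict[str, tuple[str, str]]

    @property
    def one_frequency(self) -> pd.Series:
        return self.values.mean(axis=1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RiskSignature:
    """Final pair signature with per-sample binary risk labels."""

    pair: tuple[str, str]            # canonical orientation (A < B)
    hazardous: str                   # member whose dominance marks high risk
    protective: str
    rule: str
    risk: pd.Series                  # sample -> {0, 1}, 1 = high risk
    selection_table: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"high": int((self.risk == 1).sum()), "low": int((self.risk == 0).sum())}


@dataclass
class NoSignature:
    """Explicit empty result: no pair survived the selection rules."""

    reason: str
    flags: list[str] = field(default_factory=list)


def build_pair_matrix(expr: ExpressionMatrix, prognostic_ids: list[str]) -> PairMatrix:
    """All C(k, 2) pairs of prognostic lncRNAs over the tumor samples.

    value(A, B) = 1 iff expr_A > expr_B strictly (ties -> 0); pairs are
    stored with A < B so results do not depend on input id order.
    """
    ids = sorted(set(prognostic_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 prognostic lncRNAs to form pairs")
    missing = [i for i in ids if i not in expr.values.index]
    if missing:
        raise ValueError(f"ids missing from expression matrix: {missing}")
    tumor = expr.tumor_samples
    sub = expr.values.loc[ids, tumor].to_numpy(dtype=float)
    rows = {}
    pairs = {}
    for (ia, a), (ib, b) in combinations(enumerate(ids), 2):
        label = f"{a}|{b}"
        rows[label] = (sub[ia] > sub[ib]).astype(np.int8)
        pairs[label] = (a, b)
    return PairMatrix(values=pd.DataFrame(rows, index=tumor).T, pairs=pairs)


def frequency_filter(pm: PairMatrix, lo: float = 0.2, hi: float = 0.8) -> PairMatrix:
    """Keep pairs with lo <= one-frequency <= hi (closed interval).

    A pair that is 1 (or 0) in almost every sample cannot grade patients
    into groups; the 20-80% band keeps only pairs that split the cohort.
    """
    if len(pm) == 0:
        raise ValueError("empty pair matrix")
    freq = pm.one_frequency
    keep = freq.index[(freq >= lo) & (freq <= hi)]
    kept = PairMatrix(
        values=pm.values.loc[keep],
        pairs={k: pm.pairs[k] for k in keep},
    )
    return kept


def pair_cox_screen(
    pm: PairMatrix, clinical: pd.DataFrame, p_max: float = 0.05
) -> pd.DataFrame:
    """Univariate Cox on each binary pair feature; keep Wald p < p_max.

    Returns the full fit table (one row per pair, ``kept`` column marks
    survivors) so the forest-plot output can show every screened pair.
    """
    if len(pm) == 0:
        raise ValueError("empty pair matrix")
    samples = [s for s in pm.values.columns if s in clinical.index]
    clin = clinical.loc[samples]
    if clin["event"].sum() < 1:
        raise ValueError("pair screen requires at least one event")
    rows = []
    for label in pm.values.index:
        x = pm.values.loc[label, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(
                f"pair {label} is constant across samples (should have been "
                "removed by the frequency filter)"
            )
        df = pd.DataFrame(
            {"time": clin["time"].to_numpy(), "event": clin["event"].to_numpy(), "x": x}
        )
        fit = cox_fit(df, ["x"])
        ci = fit.ci95
        p = float(fit.wald_p[0])
        rows.append(
            (
                label,
                fit.beta[0],
                fit.hr[0],
                ci[0, 0],
                ci[0, 1],
                p,
                fit.converged,
                bool(fit.converged and p < p_max),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["pair", "beta", "HR", "ci_low", "ci_high", "p", "converged", "kept"],
    ).set_index("pair")


def _median_split_km_p(expr: ExpressionMatrix, gene: str, clinical: pd.DataFrame) -> float:
    """Log-rank p for the median-split of one gene's tumor expression.

    Samples exactly at the median go to the low group.
    """
    tumor = [s for s in expr.tumor_samples if s in clinical.index]
    x = expr.values.loc[gene, tumor].to_numpy(dtype=float)
    med = np.median(x)
    high = x > med
    if high.sum() == 0 or (~high).sum() == 0:
        return 1.0
    clin = clinical.loc[tumor]
    res = logrank(clin["time"].to_numpy(), clin["event"].to_numpy(), high.astype(int))
    return res.p


def select_final_pair(
    screened: pd.DataFrame,
    pm: PairMatrix,
    de_records: pd.DataFrame,
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "lambda.min",
    km_p_max: float = 0.05,
) -> RiskSignature | NoSignature:
    """Reduce the screened pairs to the single signature pair.

    Steps, in order: (1) LASSO-Cox over the binary pair covariates, active
    set at the CV-selected lambda (if the active set is empty, the nearest
    lambda with >= 1 active covariate is used, flagged); (2) joint
    multivariate Cox on the active set; (3) keep pairs whose two members
    share the same differential-expression direction; (4) keep pairs where
    at least one member has a significant median-split Kaplan-Meier
    log-rank (p < 0.05); (5) if several remain, smallest multivariate Wald
    p wins.  The high-risk orientation puts riskScore 1 on samples where
    the hazardous member's expression >= the protective member's.
    """
    flags: list[str] = []
    kept = list(screened.index[screened["kept"]])
    if not kept:
        return NoSignature(reason="no pair passed the univariate Cox screen")
    samples = [s for s in pm.values.columns if s in clinical.index]
    clin = clinical.loc[samples]

    # (1) LASSO over binary pair covariates
    if len(kept) >= 2:
        df = pm.values.loc[kept, samples].T.astype(float)
        df["time"] = clin["time"].to_numpy()
        df["event"] = clin["event"].to_numpy()
        try:
            path = lasso_cox(
                df, kept, n_folds=n_folds, seed=seed, selection=lambda_rule
            )
            active = path.active_set
            if not active:
                nz = [i for i in range(len(path.lambdas))
                      if np.any(path.coefs[i] != 0)]
                if nz:
                    fallback = min(nz, key=lambda i: abs(i - path.selected_index))
                    active = [
                        name
                        for name, b in zip(path.covariates, path.coefs[fallback])
                        if b != 0.0
                    ]
                    flags.append(
                        "LASSO active set empty at selected lambda; used nearest "
                        "lambda with a non-empty active set"
                    )
            if not active:
                return NoSignature(
                    reason="LASSO shrank every pair to zero along the whole path",
                    flags=flags,
                )
        except ValueError as exc:
            flags.append(f"LASSO skipped: {exc}")
            active = kept
    else:
        active = kept
        flags.append("single screened pair; LASSO step skipped")

    # (2) multivariate Cox on the active set
    df = pm.values.loc[active, samples].T.astype(float)
    df["time"] = clin["time"].to_numpy()
    df["event"] = clin["event"].to_numpy()
    fit = cox_fit(df, active)
    if not fit.converged:
        flags.append("multivariate Cox on the active set did not converge")
    multi = fit.to_frame()

    # (3) same expression trend of both members
    dirs = de_records["direction"]
    same_trend = [
        lbl
        for lbl in active
        if pm.pairs[lbl][0] in dirs.index
        and pm.pairs[lbl][1] in dirs.index
        and dirs[pm.pairs[lbl][0]] == dirs[pm.pairs[lbl][1]]
    ]
    if not same_trend:
        return NoSignature(
            reason="no candidate pair couples two lncRNAs with the same "
            "expression trend",
            flags=flags,
        )

    # (4) median-split KM significance of at least one member
    km_ok = []
    km_ps = {}
    for lbl in same_trend:
        a, b = pm.pairs[lbl]
        pa = _median_split_km_p(expr, a, clinical)
        pb = _median_split_km_p(expr, b, clinical)
        km_ps[lbl] = (pa, pb)
        if pa < km_p_max or pb < km_p_max:
            km_ok.append(lbl)
    if not km_ok:
        return NoSignature(
            reason="no same-trend pair has a member with a significant "
            "median-split Kaplan-Meier log-rank",
            flags=flags,
        )

    # (5) smallest multivariate Wald p
    winner = min(km_ok, key=lambda lbl: multi.loc[lbl, "p"])
    a, b = pm.pairs[winner]
    beta = float(multi.loc[winner, "beta"])
    # pair value is I[a > b]; beta > 0 means a-dominant samples are at risk
    hazardous, protective = (a, b) if beta >= 0 else (b, a)

    tumor = expr.tumor_samples
    hz = expr.values.loc[hazardous, tumor].to_numpy(dtype=float)
    pr = expr.values.loc[protective, tumor].to_numpy(dtype=float)
    risk = pd.Series((hz >= pr).astype(int), index=pd.Index(tumor, name="sample_id"),
                     name="riskScore")
    rule = (
        f"riskScore = 1 (high risk) iff expr[{hazardous}] >= expr[{protective}] "
        f"within the sample; higher {protective} marks the low-risk group"
    )
    return RiskSignature(
        pair=(a, b),
        hazardous=hazardous,
        protective=protective,
        rule=rule,
        risk=risk,
        selection_table=multi.assign(
            same_trend=[lbl in same_trend for lbl in multi.index],
            km_member_p=[min(km_ps.get(lbl, (1.0, 1.0))) for lbl in multi.index],
        ),
        flags=flags,
    )


def evaluate_signature(
    sig: RiskSignature,
    clinical: pd.DataFrame,
    covariates: list[str] = ("stage", "t", "n", "m"),
) -> dict:
    """Characterize the risk groups: KM + log-rank, then Cox models.

    Univariate Cox for riskScore and each clinicopathological covariate
    separately, then one multivariate Cox with all jointly; stage/T/N/M
    enter as ordinal integer codes.
    """
    samples = [s for s in sig.risk.index if s in clinical.index]
    risk = sig.risk.loc[samples]
    if risk.nunique() < 2:
        raise ValueError("riskScore is constant; evaluation undefined")
    clin = clinical.loc[samples]
    time = clin["time"].to_numpy()
    event = clin["event"].to_numpy()

    km_high = km_curve(time[risk.to_numpy() == 1], event[risk.to_numpy() == 1])
    km_low = km_curve(time[risk.to_numpy() == 0], event[risk.to_numpy() == 0])
    lr = logrank(time, event, risk.to_numpy())

    base = pd.DataFrame({"time": time, "event": event})
    base["riskScore"] = risk.to_numpy(dtype=float)
    for c in covariates:
        base[c] = clin[c].to_numpy(dtype=float)

    uni_rows = []
    for c in ["riskScore", *covariates]:
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
        uni_rows, columns=["covariate", "beta", "HR", "ci_low", "ci_high", "p", "converged"]
    ).set_index("covariate")

    multi_covs = [c for c in ["riskScore", *covariates] if np.ptp(base[c].to_numpy()) > 0]
    multi_fit = cox_fit(base, multi_covs)
    multi = multi_fit.to_frame()
    multi["converged"] = multi_fit.converged

    return {
        "km_high": km_high,
        "km_low": km_low,
        "logrank": lr,
        "unicox": uni,
        "multicox": multi,
        "group_sizes": sig.group_sizes,
    }
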
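"""Synthetic breast-cancer-like cohorts with planted structure.

The generator produces everything the pair-signature pipeline consumes —
a log2 expression matrix over tumor and normal samples, a clinical table
with right-censored overall survival and stage/T/N/M covariates, and an
immune-infiltration fraction table — together with a ground-truth record
of every planted effect, so that each downstream stage can be tested
against known structure.

Structure planted by default (the reference study conditions):

* a latent immune factor shared by the immune genes and a subset of
  lncRNAs, giving Pearson r > 0.5 couplings for the correlation screen;
* tumor-vs-normal shifts of ``de_shift`` log2 units on a subset of
  lncRNAs (mixed up/down directions);
* one ordered lncRNA pair (A, B), both immune-coupled and both shifted
  *up* in tumors, carrying opposite loadings on a dedicated pair factor so
  that the within-sample order I[expr_A > expr_B] splits the cohort
  roughly in half and drives a proportional hazard exp(planted_pair_beta);
* immune-checkpoint genes and one enriched gene set whose expression
  shifts with the pair-defined risk label;
* infiltration fractions on the simplex whose means shift between risk
  groups for designated cell types.

Expression is Gaussian on the log2 scale (baseline mean 6, sd 1 plus the
structured terms): the pipeline consumes processed log-scale values, so
count-level noise is deliberately not modeled.  All randomness flows from
one master seed through named sub-streams, so each stage can be
regenerated independently and identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_expression",
    "generate_survival",
    "generate_infiltration",
    "generate_cohort",
    "CELL_TYPES",
    "CHECKPOINT_GENES",
]

CHECKPOINT_GENES = {"CD27": "down", "PDCD1": "down", "IDO1": "down", "CD276": "up"}

CELL_TYPES = [
    "CD8 T cells",
    "CD4 T cells",
    "Neutrophils",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells plasmacytoid",
    "Cancer associated fibroblasts",
    "B cells",
    "NK cells",
    "Monocytes",
    "Other",
]

# directions of the mean infiltration shift in the HIGH-risk group
_DEFAULT_SHIFTED = {
    "CD8 T cells": "down",
    "CD4 T cells": "down",
    "Neutrophils": "down",
    "Macrophages M1": "down",
    "Dendritic cells plasmacytoid": "down",
    "Cancer associated fibroblasts": "up",
    "Macrophages M2": "up",
}

_BASE_FRACTIONS = np.array(
    [0.12, 0.15, 0.08, 0.07, 0.10, 0.05, 0.12, 0.08, 0.06, 0.07, 0.10]
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Counts are numbers of features/samples; effect sizes are in log2
    expression units; ``planted_pair_beta`` is the log hazard ratio of the
    pair indicator; ``baseline_scale`` is the mean of the exponential
    baseline event-time distribution in days.
    """

    n_tumor: int = 300
    n_normal: int = 50
    n_lncrna: int = 60
    n_gene: int = 120
    n_immune_gene: int = 30
    n_immune_lnc: int = 15
    n_de_lnc: int = 12
    de_shift: float = 2.0
    planted_pair_beta: float = float(np.log(2.5))
    baseline_scale: float = 2000.0
    censor_rate: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0
    # structural knobs beyond the core list
    latent_loading: float = 0.9
    pair_coupling: float = 0.47
    stage_risk_coupling: float = 1.0
    n_enriched_gene: int = 20
    enriched_shift: float = 0.8
    checkpoint_shift: float = 0.8
    infil_shift: float = 0.05
    infil_concentration: float = 200.0
    stage_betas: tuple[float, float, float, float] = (0.25, 0.15, 0.25, 1.05)
    # per-level log-hazard increments for stage, T, N and the M=1 indicator;
    # M gets a strong multiplier so metastasis behaves as an independent predictor.
    # stage_risk_coupling in [0, 1] shifts the staging distributions of
    # high-risk (pair-indicator 1) patients toward later stages, the way a
    # prognostic signature co-varies with clinicopathology in real cohorts.

    def validate(self) -> None:
        counts = {
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_lncrna": self.n_lncrna,
            "n_gene": self.n_gene,
            "n_immune_gene": self.n_immune_gene,
            "n_immune_lnc": self.n_immune_lnc,
            "n_de_lnc": self.n_de_lnc,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ValueError("need at least 3 tumor and 3 normal samples")
        if self.n_immune_lnc > self.n_lncrna:
            raise ValueError("n_immune_lnc cannot exceed n_lncrna")
        if self.n_de_lnc > self.n_lncrna:
            raise ValueError("n_de_lnc cannot exceed n_lncrna")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        reserved = len(CHECKPOINT_GENES) + self.n_enriched_gene
        if self.n_gene < self.n_immune_gene + reserved:
            raise ValueError(
                "n_gene must cover immune + checkpoint + enriched genes"
            )
        if min(self.n_immune_lnc, self.n_de_lnc) < 2:
            raise ValueError("need at least 2 immune-coupled DE lncRNAs for a pair")
        if self.n_immune_gene < 5:
            raise ValueError("need at least 5 immune genes (4 carry the pair factor)")


@dataclass(frozen=True)
class GroundTruth:
    """Record of every planted effect (never read by analysis stages)."""

    immune_lnc_ids: list[str]
    de_lnc_ids: dict[str, str]            # id -> "up" / "down"
    planted_pair: tuple[str, str]         # (A, B): expr_A > expr_B is hazardous
    true_beta: float
    risk_shifted_celltypes: dict[str, str] = field(default_factory=dict)
    checkpoint_genes: dict[str, str] = field(default_factory=dict)
    enriched_set_ids: list[str] = field(default_factory=list)
    immune_gene_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lid in self.immune_lnc_ids:
            rows.append(("immune_lnc", lid, ""))
        for lid, d in self.de_lnc_ids.items():
            rows.append(("de_lnc", lid, d))
        rows.append(("planted_pair_A", self.planted_pair[0], "up"))
        rows.append(("planted_pair_B", self.planted_pair[1], "up"))
        rows.append(("true_beta", f"{self.true_beta:.6g}", ""))
        for ct, d in self.risk_shifted_celltypes.items():
            rows.append(("shifted_celltype", ct, d))
        for gid, d in self.checkpoint_genes.items():
            rows.append(("checkpoint_gene", gid, d))
        for gid in self.enriched_set_ids:
            rows.append(("enriched_gene", gid, "up"))
        return pd.DataFrame(rows, columns=["kind", "id", "direction"])


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named sub-streams derived from one master seed."""
    root = np.random.SeedSequence(seed)
    names = ["expression", "survival", "infiltration"]
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with tumor/normal labels."""

    values: pd.DataFrame
    groups: pd.Series  # sample -> "tumor" / "normal"

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "normal"])

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]


def generate_expression(config: CohortConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the log2 expression matrix and the ground-truth record.

    Output shape is (n_lncrna + n_gene) x (n_tumor + n_normal); identical
    config + seed gives bit-identical output.
    """
    config.validate()
    rng = _streams(config.seed)["expression"]
    n_samp = config.n_tumor + config.n_normal
    samples = [f"T{i+1:04d}" for i in range(config.n_tumor)] + [
        f"N{i+1:04d}" for i in range(config.n_normal)
    ]
    is_tumor = np.zeros(n_samp, dtype=bool)
    is_tumor[: config.n_tumor] = True

    lnc_ids = [f"LNC{i+1:04d}" for i in range(config.n_lncrna)]
    ckpt_ids = list(CHECKPOINT_GENES)
    enr_ids = [f"ENR{i+1:03d}" for i in range(config.n_enriched_gene)]
    n_filler = config.n_gene - config.n_immune_gene - len(ckpt_ids) - config.n_enriched_gene
    gene_ids = (
        [f"IMMG{i+1:04d}" for i in range(config.n_immune_gene)]
        + ckpt_ids
        + enr_ids
        + [f"GENE{i+1:04d}" for i in range(n_filler)]
    )
    imm_gene_ids = gene_ids[: config.n_immune_gene]

    immune_lncs = lnc_ids[: config.n_immune_lnc]
    de_lncs = lnc_ids[: config.n_de_lnc]
    # planted pair: first two lncRNAs — immune-coupled, DE, both shifted up
    pair = (lnc_ids[0], lnc_ids[1])
    de_dirs: dict[str, str] = {}
    for k, lid in enumerate(de_lncs):
        if lid in pair:
            de_dirs[lid] = "up"
        else:
            de_dirs[lid] = "up" if k % 3 != 2 else "down"

    z = rng.normal(size=n_samp)          # immune latent factor
    u = rng.normal(size=n_samp)          # pair-order factor
    a = config.latent_loading
    c = config.pair_coupling

    base_means = rng.normal(6.0, 1.0, size=config.n_lncrna + config.n_gene)
    all_ids = lnc_ids + gene_ids
    mat = base_means[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(all_ids), n_samp)
    )
    idx = {g: i for i, g in enumerate(all_ids)}

    # Non-pair immune lncRNAs and most immune genes share the immune latent
    # factor z.  The pair members load mostly on the dedicated pair factor u
    # (with a small z component), and the first four immune genes carry u
    # with +/- loadings: the hazardous and protective members each stay
    # strongly correlated with an immune gene while the within-sample order
    # I[A > B] remains tightly coupled to each member's own expression —
    # which is what makes both members marginally prognostic.
    for lid in immune_lncs:
        if lid in pair:
            mat[idx[lid]] += 0.42 * a * z
        else:
            mat[idx[lid]] += a * z
    for k, gid in enumerate(imm_gene_ids):
        if k < 2:
            mat[idx[gid]] += a * u
        elif k < 4:
            mat[idx[gid]] -= a * u
        else:
            mat[idx[gid]] += a * z
        if k < 4:
            # the u-coupled immune genes share the members' tumor up-shift,
            # so the correlation screen sees the shift as covariance rather
            # than unexplained variance
            mat[idx[gid], is_tumor] += config.de_shift
    for lid, d in de_dirs.items():
        shift = config.de_shift if d == "up" else -config.de_shift
        mat[idx[lid], is_tumor] += shift
    # the pair members share the same baseline so I[A>B] splits ~50/50
    mean_ab = float(base_means[:2].mean())
    for lid in pair:
        mat[idx[lid]] = mean_ab + (mat[idx[lid]] - base_means[idx[lid]])
    mat[idx[pair[0]]] += c * u
    mat[idx[pair[1]]] -= c * u

    # risk label implied by the pair order (tumor samples)
    risk = (mat[idx[pair[0]]] > mat[idx[pair[1]]]) & is_tumor
    for gid, d in CHECKPOINT_GENES.items():
        s = config.checkpoint_shift if d == "up" else -config.checkpoint_shift
        mat[idx[gid], risk] += s
    for gid in enr_ids:
        mat[idx[gid], risk] += config.enriched_shift

    expr = ExpressionMatrix(
        values=pd.DataFrame(mat, index=all_ids, columns=samples),
        groups=pd.Series(
            np.where(is_tumor, "tumor", "normal"), index=samples, name="group"
        ),
    )
    truth = GroundTruth(
        immune_lnc_ids=list(immune_lncs),
        de_lnc_ids=de_dirs,
        planted_pair=pair,
        true_beta=config.planted_pair_beta,
        risk_shifted_celltypes=dict(_DEFAULT_SHIFTED) if config.infil_shift > 0 else {},
        checkpoint_genes=dict(CHECKPOINT_GENES) if config.checkpoint_shift > 0 else {},
        enriched_set_ids=list(enr_ids),
        immune_gene_ids=list(imm_gene_ids),
    )
    return expr, truth


def _solve_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+h_i) = target (bisection)."""
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, float(hazards.max())
    while np.mean(hi / (hi + hazards)) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(mid / (mid + hazards)) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(
    expr: ExpressionMatrix, truth: GroundTruth, config: CohortConfig
) -> pd.DataFrame:
    """Clinical table for the tumor samples.

    Event times are exponential with hazard
    ``(1/baseline_scale) * exp(true_beta * I[expr_A > expr_B] + stage effects)``;
    censoring is independent exponential with its rate solved numerically to
    achieve the requested censoring fraction.  Stage/T/N/M are categorical
    (4/4/3/2 levels) with log-linear hazard increments; metastasis (M=1)
    carries a strong multiplier.

    Returns a DataFrame indexed by sample with columns
    ``time, event, stage, t, n, m`` (integer-coded stages).
    """
    config.validate()
    if config.censor_rate >= 1.0:
        raise ValueError("censor_rate = 1 leaves no events; Cox is undefined")
    a_id, b_id = truth.planted_pair
    if a_id not in expr.values.index or b_id not in expr.values.index:
        raise ValueError("planted pair members missing from expression matrix")
    rng = _streams(config.seed)["survival"]
    tumor = expr.tumor_samples
    nt = len(tumor)

    ind = (
        expr.values.loc[a_id, tumor].to_numpy()
        > expr.values.loc[b_id, tumor].to_numpy()
    ).astype(float)

    # staging distributions for low-risk patients and (when coupled) the
    # later-stage mix high-risk patients are drawn from
    dists = {
        "stage": ([1, 2, 3, 4], [0.22, 0.58, 0.17, 0.03], [0.08, 0.42, 0.38, 0.12]),
        "t": ([1, 2, 3, 4], [0.28, 0.55, 0.13, 0.04], [0.12, 0.52, 0.26, 0.10]),
        "n": ([0, 1, 2], [0.55, 0.33, 0.12], [0.30, 0.40, 0.30]),
        "m": ([0, 1], [0.97, 0.03], [0.85, 0.15]),
    }
    q = config.stage_risk_coupling * ind  # per-sample mixing weight
    drawn = {}
    for name, (levels, p_lo, p_hi) in dists.items():
        p_lo = np.asarray(p_lo)
        p_hi = np.asarray(p_hi)
        out = np.empty(nt, dtype=int)
        for i in range(nt):
            p = (1.0 - q[i]) * p_lo + q[i] * p_hi
            out[i] = rng.choice(levels, p=p)
        drawn[name] = out
    stage, t_stage, n_stage, m_stage = (
        drawn["stage"], drawn["t"], drawn["n"], drawn["m"],
    )
    bs, bt, bn, bm = config.stage_betas
    lp = (
        config.planted_pair_beta * ind
        + bs * (stage - 1)
        + bt * (t_stage - 1)
        + bn * n_stage
        + bm * m_stage
    )
    hazard = np.exp(lp) / config.baseline_scale
    t_event = rng.exponential(1.0 / hazard)
    c_rate = _solve_censor_rate(hazard, config.censor_rate)
    if c_rate > 0:
        t_cens = rng.exponential(1.0 / c_rate, size=nt)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(nt, dtype=int)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "stage": stage,
            "t": t_stage,
            "n": n_stage,
            "m": m_stage,
        },
        index=pd.Index(tumor, name="sample_id"),
    )


def generate_infiltration(
    truth: GroundTruth, risk_labels: pd.Series, config: CohortConfig
) -> pd.DataFrame:
    """Immune-cell fraction table (cell types x tumor samples).

    Fractions are Dirichlet draws whose mean vector is shifted by
    ``infil_shift`` (renormalized) in the high-risk group for the cell
    types listed in the ground truth; each sample's fractions sum to 1.
    """
    config.validate()
    risk = risk_labels.astype(int)
    if set(risk.unique()) - {0, 1}:
        raise ValueError("risk labels must be 0/1")
    if (risk == 1).sum() == 0 or (risk == 0).sum() == 0:
        raise ValueError("both risk groups must be non-empty")
    rng = _streams(config.seed)["infiltration"]
    base = _BASE_FRACTIONS / _BASE_FRACTIONS.sum()
    shifted = base.copy()
    for k, ct in enumerate(CELL_TYPES):
        d = truth.risk_shifted_celltypes.get(ct)
        if d == "down":
            shifted[k] = max(base[k] - config.infil_shift, 1e-3)
        elif d == "up":
            shifted[k] = base[k] + config.infil_shift
    shifted /= shifted.sum()

    out = np.empty((len(CELL_TYPES), risk.size))
    for si, s in enumerate(risk.index):
        mean = shifted if risk.loc[s] == 1 else base
        out[:, si] = rng.dirichlet(mean * config.infil_concentration)
    return pd.DataFrame(out, index=CELL_TYPES, columns=risk.index)


def generate_cohort(config: CohortConfig):
    """Convenience wrapper: expression + truth + clinical in one call."""
    expr, truth = generate_expression(config)
    clinical = generate_survival(expr, truth, config)
    return expr, truth, clinical
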
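"""Negative-binomial differential expression with evolutionary replicates.

Implements the variance-modelling route to calling developmental
up-regulation: median-of-ratios size factors, per-unit method-of-moments
dispersion with a 1/mean trend and a conservative maximum rule, per-stage
Wald contrasts against growth (t0) under NB(mu, mu + alpha*mu^2), and
Benjamini-Hochberg control at 10 % FDR.

Two designs reuse the same engine:

* Method B — one-per-species ortholog families as units, the four species
  as biological replicates ("evolutionary replicates");
* Method C — DD genes as units, two laboratory strains (NC4, AX4) as
  replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import DEV_STAGES, SPECIES, STAGES, OrthologFamily, StageCountTable

ALPHA_FLOOR = 1e-8
_MEAN_FLOOR = 1e-8


@dataclass
class ReplicateDesign:
    """Units x samples count matrix with (replicate, stage) sample labels."""

    units: list[str]
    samples: list[tuple[str, str]]  # (replicate label, stage label)
    count_matrix: np.ndarray  # units x samples, non-negative integers

    def __post_init__(self) -> None:
        self.count_matrix = np.asarray(self.count_matrix)
        if self.count_matrix.shape != (len(self.units), len(self.samples)):
            raise ValidationError(
                "ReplicateDesign: count_matrix shape does not match units x samples"
            )
        if (self.count_matrix < 0).any():
            raise ValidationError("ReplicateDesign: negative counts")

    @property
    def stages(self) -> np.ndarray:
        return np.array([s for _, s in self.samples])


@dataclass
class DispersionEstimate:
    unit_id: str
    raw_alpha: float
    fitted_alpha: float
    final_alpha: float


@dataclass
class DEResult:
    unit_id: str
    stage: str
    base_mean: float
    log2_fold_change: float
    p_value: float
    q_value: float
    called_up: bool
    flagged: bool = False


@dataclass
class MethodCallResult:
    """Outcome of a DE method: called units plus the full per-stage table."""

    called: frozenset[str]
    results: pd.DataFrame  # unit_id, stage, base_mean, lfc, p, q, called
    dispersions: list[DispersionEstimate]
    size_factors: dict[str, float]


# ---------------------------------------------------------------------------
# normalization and dispersion


def size_factors(count_matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios sample size factors.

    For each unit with all-positive counts, compute its geometric mean over
    samples; each sample's factor is the median over such units of
    count / geometric mean.
    """
    k = np.asarray(count_matrix, dtype=float)
    if k.ndim != 2:
        raise ValidationError("size_factors: expected a 2-D matrix")
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "size_factors: no unit has positive counts in every sample; "
            "filter all-zero/partially-observed units first"
        )
    logk = np.log(k[positive])
    loggeo = logk.mean(axis=1, keepdims=True)
    return np.exp(np.median(logk - loggeo, axis=0))


def estimate_dispersion(
    normalized_counts: np.ndarray,
    condition_labels: list[str] | np.ndarray,
    unit_ids: list[str] | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> list[DispersionEstimate]:
    """Per-unit NB dispersion: method of moments, 1/mean trend, maximum rule.

    Within each condition with >= 2 replicates the moments contribute to a
    pooled raw estimate ``alpha = max(0, sum (n_c-1)(s_c^2 - m_c) /
    sum (n_c-1) m_c^2)``.  A trend ``alpha(mu) = a0 + a1/mu`` is fitted by
    least squares over units; the final value is the maximum of the raw and
    trend estimates, floored at ``alpha_floor`` (conservative sharing rule).
    """
    y = np.asarray(normalized_counts, dtype=float)
    labels = np.asarray(condition_labels)
    if unit_ids is None:
        unit_ids = [f"unit{i}" for i in range(y.shape[0])]
    conditions = [c for c in np.unique(labels) if (labels == c).sum() >= 2]
    if not conditions:
        raise ValidationError(
            "estimate_dispersion: no condition has >= 2 replicates; "
            "dispersion is not estimable"
        )
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for c in conditions:
        yc = y[:, labels == c]
        n_c = yc.shape[1]
        m = yc.mean(axis=1)
        v = yc.var(axis=1, ddof=1)
        num += (n_c - 1) * (v - m)
        den += (n_c - 1) * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, np.maximum(0.0, num / np.maximum(den, _MEAN_FLOOR)), 0.0)

    base_mean = y.mean(axis=1)
    ok = base_mean > 0
    if ok.sum() >= 2:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(x, raw[ok], rcond=None)
        with np.errstate(divide="ignore"):
            fitted = np.where(ok, coef[0] + coef[1] / np.maximum(base_mean, _MEAN_FLOOR), 0.0)
        fitted = np.maximum(fitted, 0.0)
    else:
        fitted = np.zeros_like(raw)

    final = np.maximum(np.maximum(raw, fitted), alpha_floor)
    return [
        DispersionEstimate(uid, float(r), float(f), float(a))
        for uid, r, f, a in zip(unit_ids, raw, fitted, final)
    ]


# ---------------------------------------------------------------------------
# the Wald contrast


def _fit_group_mean(k: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """MLE of the per-unit group mean m solving
    sum_j (k_ij - s_j m_i) / (1 + alpha_i s_j m_i) = 0 (Newton, vectorized).

    ``k``: units x samples counts of one condition; ``s``: size factors;
    ``alpha``: per-unit dispersions.  With alpha -> 0 this is sum k / sum s.
    """
    m = k.sum(axis=1) / s.sum()
    m = np.maximum(m, _MEAN_FLOOR)
    a = alpha[:, None]
    for _ in range(50):
        mu = s[None, :] * m[:, None]
        denom = 1.0 + a * mu
        f = ((k - mu) / denom).sum(axis=1)
        fprime = (-s[None, :] * (1.0 + a * k) / denom**2).sum(axis=1)
        step = np.where(fprime != 0.0, f / fprime, 0.0)
        m_new = np.maximum(m - step, _MEAN_FLOOR)
        if np.max(np.abs(m_new - m) / np.maximum(m, 1.0)) < 1e-12:
            m = m_new
            break
        m = m_new
    return m


def _wald_stage_matrix(
    counts: np.ndarray,
    sf: np.ndarray,
    stages: np.ndarray,
    stage: str,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Wald contrast stage-vs-t0 over all units.

    Returns (lfc, p, base_mean, flagged).  The two group means are profiled
    NB MLEs; the Wald statistic uses the Fisher information of a log-link
    group mean, Var(log m_g) = 1 / sum_j mu_j / (1 + alpha*mu_j).
    """
    mask0 = stages == "t0"
    masks = stages == stage
    k0, s0 = counts[:, mask0], sf[mask0]
    ks, ss = counts[:, masks], sf[masks]

    m0 = _fit_group_mean(k0, s0, alpha)
    ms = _fit_group_mean(ks, ss, alpha)

    zero_both = (k0.sum(axis=1) == 0) & (ks.sum(axis=1) == 0)

    mu0 = s0[None, :] * m0[:, None]
    mus = ss[None, :] * ms[:, None]
    a = alpha[:, None]
    info0 = (mu0 / (1.0 + a * mu0)).sum(axis=1)
    infos = (mus / (1.0 + a * mus)).sum(axis=1)
    with np.errstate(divide="ignore"):
        var = 1.0 / np.maximum(info0, 1e-300) + 1.0 / np.maximum(infos, 1e-300)
    beta = np.log(ms) - np.log(m0)
    z = beta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))

    lfc = beta / np.log(2.0)
    base_mean = (counts[:, mask0 | masks] / sf[mask0 | masks]).mean(axis=1)
    lfc[zero_both] = 0.0
    p[zero_both] = 1.0
    p = np.clip(p, 0.0, 1.0)
    return lfc, p, base_mean, zero_both


def nb_stage_test(
    unit_counts: np.ndarray,
    sf: np.ndarray,
    stages: list[str] | np.ndarray,
    stage: str,
    alpha: float,
    unit_id: str = "unit",
) -> DEResult:
    """Wald test of one unit, one developmental stage against growth."""
    if stage not in DEV_STAGES:
        raise ValidationError(f"nb_stage_test: stage must be one of {DEV_STAGES}")
    counts = np.asarray(unit_counts, dtype=float)[None, :]
    lfc, p, base, flagged = _wald_stage_matrix(
        counts, np.asarray(sf, dtype=float), np.asarray(stages), stage,
        np.array([alpha]),
    )
    return DEResult(
        unit_id=unit_id,
        stage=stage,
        base_mean=float(base[0]),
        log2_fold_change=float(lfc[0]),
        p_value=float(p[0]),
        q_value=float("nan"),
        called_up=False,
        flagged=bool(flagged[0]),
    )


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# method-level drivers


def call_method(design: ReplicateDesign, fdr: float = 0.10) -> MethodCallResult:
    """Run the full NB engine on a design and call up-regulated units.

    Per-stage Wald contrasts (t1..t4 each against t0) are corrected by BH
    across all (unit, stage) pairs; a unit is called iff its smallest q is
    at most ``fdr`` with a positive log2 fold change at the minimising
    stage (latest such stage on q ties).
    """
    counts = design.count_matrix.astype(float)
    sf = size_factors(counts)
    stages = design.stages
    if not (stages == "t0").any():
        raise ValidationError("call_method: design has no growth (t0) samples")
    tested_stages = [s for s in DEV_STAGES if (stages == s).any()]
    if not tested_stages:
        raise ValidationError("call_method: design has no developmental samples")
    norm = counts / sf[None, :]
    disp = estimate_dispersion(norm, stages, unit_ids=design.units)
    alpha = np.array([d.final_alpha for d in disp])

    rows: list[dict] = []
    p_all = []
    for stage in tested_stages:
        lfc, p, base, flagged = _wald_stage_matrix(counts, sf, stages, stage, alpha)
        p_all.append(p)
        for i, uid in enumerate(design.units):
            rows.append(
                dict(unit_id=uid, stage=stage, base_mean=base[i],
                     log2_fold_change=lfc[i], p_value=p[i], flagged=bool(flagged[i]))
            )
    q_all = bh_adjust(np.concatenate(p_all))
    df = pd.DataFrame(rows)
    df["q_value"] = q_all

    called: set[str] = set()
    for uid, sub in df.groupby("unit_id", sort=False):
        qmin = sub["q_value"].min()
        best = sub[sub["q_value"] == qmin].iloc[-1]  # later stage on ties
        if qmin <= fdr and best["log2_fold_change"] > 0:
            called.add(uid)
    df["called_up"] = [
        (row.unit_id in called) and (row.q_value <= fdr) and (row.log2_fold_change > 0)
        for row in df.itertuples()
    ]
    df = df[["unit_id", "stage", "base_mean", "log2_fold_change",
             "p_value", "q_value", "called_up", "flagged"]]
    sf_map = {f"{rep}:{st}": float(s) for (rep, st), s in zip(design.samples, sf)}
    return MethodCallResult(
        called=frozenset(called), results=df, dispersions=disp, size_factors=sf_map
    )


def build_method_b_design(
    families: list[OrthologFamily],
    counts_by_species: dict[str, StageCountTable],
) -> ReplicateDesign:
    """Method B: one-per-species families as units, species as replicates.

    Only families with exactly one member in every species, all members
    present in their species' count table, are admitted.
    """
    samples = [(sp, st) for sp in SPECIES for st in STAGES]
    units: list[str] = []
    rows: list[np.ndarray] = []
    for fam in families:
        if not fam.is_one_per_species(SPECIES):
            continue
        member = {sp: fam.members[sp][0] for sp in SPECIES}
        if any(
            sp not in counts_by_species
            or member[sp] not in counts_by_species[sp].counts.index
            for sp in SPECIES
        ):
            continue
        row = np.concatenate(
            [counts_by_species[sp].counts.loc[member[sp]].to_numpy() for sp in SPECIES]
        )
        units.append(fam.family_id)
        rows.append(row)
    matrix = np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=int)
    return ReplicateDesign(units=units, samples=samples, count_matrix=matrix)


def build_method_c_design(
    counts_nc4: StageCountTable,
    counts_ax4: StageCountTable,
) -> ReplicateDesign:
    """Method C: DD genes as units, the NC4 and AX4 strains as replicates."""
    shared = [g for g in counts_nc4.counts.index if g in counts_ax4.counts.index]
    samples = [(strain, st) for strain in ("NC4", "AX4") for st in STAGES]
    matrix = np.hstack(
        [
            counts_nc4.counts.loc[shared].to_numpy(),
            counts_ax4.counts.loc[shared].to_numpy(),
        ]
    ) if shared else np.zeros((0, len(samples)), dtype=int)
    return ReplicateDesign(units=list(shared), samples=samples, count_matrix=matrix)
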
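"""Protein conservation versus expression peak stage.

Global (Needleman-Wunsch) alignment of DD proteins against their DF
orthologs yields a percent identity per gene; genes are grouped by the
developmental stage at which their expression peaks, and the late-peaking
groups (t3, t4 — fruiting-body stages) are compared against early
aggregation (t1) with a one-sided Mann-Whitney U test (alternative: the
late group's identities are stochastically greater).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .expression import ExpressionProfile
from .types import OrthologFamily

#: Alignment scoring for identity computation: match +1, mismatch -1,
#: linear gap -2.  Identity, not score, is the downstream quantity.
NW_MATCH, NW_MISMATCH, NW_GAP = 1.0, -1.0, -2.0


@dataclass
class ConservationRecord:
    dd_gene_id: str
    df_gene_id: str
    percent_identity: float  # in [0, 1]: identical columns / alignment length
    peak_stage: str


@dataclass
class ConservationTest:
    u_statistic: float
    p_value: float
    median_late: float
    median_early: float
    n_late: int
    n_early: int
    exact: bool


def needleman_wunsch(
    seq_a: str,
    seq_b: str,
    match: float = NW_MATCH,
    mismatch: float = NW_MISMATCH,
    gap: float = NW_GAP,
) -> tuple[float, str, str]:
    """Optimal global alignment with linear gap costs.

    Returns (score, aligned_a, aligned_b).  The traceback tie-break is
    fixed: diagonal > up (gap in b) > left (gap in a), so the alignment is
    deterministic.
    """
    if not seq_a or not seq_b:
        raise ValidationError("needleman_wunsch: empty sequence")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    n, m = a.size, b.size
    h = np.empty((n + 1, m + 1))
    h[0, :] = gap * np.arange(m + 1)
    h[:, 0] = gap * np.arange(n + 1)
    ramp = gap * np.arange(m + 1)  # gap*j, j = 0..m
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], match, mismatch)
        cand = np.maximum(h[i - 1, :-1] + sub, h[i - 1, 1:] + gap)
        # resolve the in-row (left) dependency with a prefix scan:
        # h[i,j] = gap*j + max_{k<=j} (u[k] - gap*k), u = [h[i,0], cand...]
        u = np.concatenate(([h[i, 0]], cand))
        h[i, :] = ramp + np.maximum.accumulate(u - ramp)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(
            h[i, j] - (h[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch))
        ) < eps:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and abs(h[i, j] - (h[i - 1, j] + gap)) < eps:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
    return float(h[n, m]), "".join(reversed(out_a)), "".join(reversed(out_b))


def align_percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical columns / alignment length
    (gap columns included in the length)."""
    _, aln_a, aln_b = needleman_wunsch(seq_a, seq_b)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    return matches / len(aln_a)


def build_conservation_records(
    dd_genes: frozenset[str] | set[str],
    families: list[OrthologFamily],
    proteins: dict[str, str],
    peak_stage_of: dict[str, str] | dict[str, ExpressionProfile],
) -> list[ConservationRecord]:
    """DD-DF identity records for genes with a unique DF ortholog.

    ``peak_stage_of`` maps DD gene id to a stage label (or to an
    :class:`ExpressionProfile`, whose ``peak_stage`` is used).
    """
    fam_of: dict[str, OrthologFamily] = {}
    for fam in families:
        for g in fam.members.get("DD", ()):
            fam_of[g] = fam
    records: list[ConservationRecord] = []
    for g in sorted(dd_genes):
        fam = fam_of.get(g)
        if fam is None:
            continue
        df_members = fam.members.get("DF", ())
        if len(df_members) != 1:
            continue  # ambiguous or absent ortholog
        peak = peak_stage_of.get(g)
        if peak is None:
            continue
        if isinstance(peak, ExpressionProfile):
            peak = peak.peak_stage
        records.append(
            ConservationRecord(
                dd_gene_id=g,
                df_gene_id=df_members[0],
                percent_identity=align_percent_identity(
                    proteins[g], proteins[df_members[0]]
                ),
                peak_stage=peak,
            )
        )
    return records


def conservation_by_peak(
    records: list[ConservationRecord],
    late_stages: tuple[str, ...] = ("t3", "t4"),
    early_stage: str = "t1",
) -> ConservationTest:
    """One-sided Mann-Whitney U: are late-peaking genes more conserved?

    Exact null enumeration when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie
    correction.
    """
    late = [r.percent_identity for r in records if r.peak_stage in late_stages]
    early = [r.percent_identity for r in records if r.peak_stage == early_stage]
    if not late or not early:
        raise ValidationError(
            "conservation_by_peak: both peak-stage groups must be non-empty"
        )
    values = late + early
    no_ties = len(set(values)) == len(values)
    method = "exact" if (len(values) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(late, early, alternative="greater", method=method)
    return ConservationTest(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_late=float(np.median(late)),
        median_early=float(np.median(early)),
        n_late=len(late),
        n_early=len(early),
        exact=method == "exact",
    )
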
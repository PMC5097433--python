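"""RPKM profiles and the threshold-based up-regulation caller (Method A).

Method A calls a gene developmentally up-regulated when its RPKM at any
stage after growth is at least ``min_fold`` (default 3) times the growth
value and the gene clears a raw-read floor (default 20 reads in at least
one stage).  The DD-anchored Method-A set additionally requires the call to
be conserved: the gene's cross-species matched group must be called in at
least ``min_species`` species (DD included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .types import DEV_STAGES, SPECIES, STAGES, OrthologFamily, StageCountTable

#: RPKM floor used as fold-change denominator for silent growth stages.
EPSILON_RPKM = 0.5


@dataclass
class ExpressionProfile:
    """Per-gene stage-wise RPKM with derived peak and fold-change summary."""

    gene_id: str
    rpkm: np.ndarray  # length 5, ordered as STAGES
    peak_stage: str  # argmax of rpkm over t1..t4, ties toward later stage
    max_fold_vs_t0: float
    max_count: int  # largest raw count over the 5 stages
    passes_read_floor: bool


@dataclass
class MethodACall:
    """Per-species threshold calls plus the DD-anchored conserved set."""

    per_species_upregulated: dict[str, frozenset[str]]
    dd_anchored_set: frozenset[str]


def compute_rpkm(
    table: StageCountTable,
    min_reads: int = 20,
    epsilon: float = EPSILON_RPKM,
) -> dict[str, ExpressionProfile]:
    """RPKM per gene and stage: 1e9 * count / (length_nt * column_total).

    The peak stage is the argmax of RPKM over t1..t4 with ties broken
    toward the later stage; ``max_fold_vs_t0`` is the largest RPKM ratio of
    any developmental stage over growth, with the growth RPKM floored at
    ``epsilon`` to keep silent-at-growth genes finite.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    for s, tot in zip(STAGES, totals):
        if tot == 0:
            raise ValidationError(f"compute_rpkm: stage {s} has zero total reads")
    lengths = np.array([table.gene_lengths[g] for g in table.counts.index], dtype=float)
    rpkm = 1e9 * counts / (lengths[:, None] * totals[None, :])

    profiles: dict[str, ExpressionProfile] = {}
    for i, gene in enumerate(table.counts.index):
        dev = rpkm[i, 1:]
        # argmax with later-stage tie-break: scan reversed
        peak_idx = 4 - int(np.argmax(dev[::-1]))
        denom = max(rpkm[i, 0], epsilon)
        max_count = int(table.counts.iloc[i].max())
        profiles[gene] = ExpressionProfile(
            gene_id=gene,
            rpkm=rpkm[i].copy(),
            peak_stage=STAGES[peak_idx],
            max_fold_vs_t0=float(dev.max() / denom),
            max_count=max_count,
            passes_read_floor=max_count >= min_reads,
        )
    return profiles


def call_upregulated_a(
    profiles: dict[str, ExpressionProfile],
    min_reads: int = 20,
    min_fold: float = 3.0,
) -> frozenset[str]:
    """Genes with >= ``min_reads`` raw reads in some stage and a
    developmental RPKM at least ``min_fold`` times the growth RPKM."""
    return frozenset(
        g
        for g, p in profiles.items()
        if p.max_count >= min_reads and p.max_fold_vs_t0 >= min_fold
    )


def _log_profile(p: ExpressionProfile) -> np.ndarray:
    return np.log2(p.rpkm + 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; zero-variance profiles correlate 0 by definition."""
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def match_family_patterns(
    family: OrthologFamily,
    profiles_by_species: dict[str, dict[str, ExpressionProfile]],
    min_similarity: float = 0.5,
) -> list[tuple[str, ...]]:
    """Group family members with similar expression patterns across species.

    Families with at most one member per species form a single group.
    Larger families are resolved greedily on the Pearson correlation of the
    members' log2(RPKM+1) stage profiles: each member of the anchor species
    (DD when present, otherwise the species with most members) seeds a
    group, and the remaining members are attached to the seed they
    correlate best with, in descending correlation order with a
    lexicographic gene-id tie-break, under the constraint of at most one
    member per species per group.  Members left over (correlation below
    ``min_similarity``, or their species slot taken in every seed group)
    are then pair-merged among themselves under the same rule.  Every gene
    ends up in exactly one group (possibly a singleton group).

    Seeding on the anchor species keeps a conserved family from being
    split by near-tied correlations: in a family whose members all share
    one expression pattern, naive pairwise merging can strand the anchor
    gene with near-identical correlations deciding arbitrarily.
    """
    members: list[tuple[str, str]] = []  # (gene, species)
    for sp in sorted(family.members):
        sp_profiles = profiles_by_species.get(sp, {})
        for g in family.members[sp]:
            if g in sp_profiles:
                members.append((g, sp))
    if not members:
        return []
    by_sp: dict[str, list[str]] = {}
    for g, sp in members:
        by_sp.setdefault(sp, []).append(g)
    if all(len(v) == 1 for v in by_sp.values()):
        return [tuple(sorted(g for g, _ in members))]

    species_lookup = dict(members)

    def corr_of(ga: str, gb: str) -> float:
        return _pearson(
            _log_profile(profiles_by_species[species_lookup[ga]][ga]),
            _log_profile(profiles_by_species[species_lookup[gb]][gb]),
        )

    anchor = "DD" if "DD" in by_sp else max(
        sorted(by_sp), key=lambda sp: len(by_sp[sp])
    )
    seeds = sorted(by_sp[anchor])
    groups: dict[str, set[str]] = {s: {s} for s in seeds}
    assigned: set[str] = set(seeds)

    attachments = [
        (corr_of(seed, g), seed, g)
        for seed in seeds
        for g, sp in members
        if sp != anchor
    ]
    attachments.sort(key=lambda t: (-t[0], t[1], t[2]))
    for corr, seed, g in attachments:
        if corr < min_similarity or g in assigned:
            continue
        taken = {species_lookup[m] for m in groups[seed]}
        if species_lookup[g] in taken:
            continue
        groups[seed].add(g)
        assigned.add(g)

    # leftovers: greedy pair merging among themselves
    rest = [g for g, _ in members if g not in assigned]
    pairs = []
    for i, a in enumerate(sorted(rest)):
        for b in sorted(rest)[i + 1:]:
            if species_lookup[a] == species_lookup[b]:
                continue
            c = corr_of(a, b)
            if c >= min_similarity:
                pairs.append((c, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    group_of = {g: frozenset([g]) for g in rest}
    for _, a, b in pairs:
        ga, gb = group_of[a], group_of[b]
        if ga is gb:
            continue
        merged = ga | gb
        sps = [species_lookup[g] for g in merged]
        if len(sps) != len(set(sps)):
            continue
        for g in merged:
            group_of[g] = merged
    out = [tuple(sorted(grp)) for grp in groups.values()]
    out.extend({id(grp): tuple(sorted(grp)) for grp in group_of.values()}.values())
    return sorted(set(out))


def assemble_method_a(
    called_by_species: dict[str, frozenset[str]],
    families: list[OrthologFamily],
    profiles_by_species: dict[str, dict[str, ExpressionProfile]],
    min_species: int = 3,
    min_similarity: float = 0.5,
) -> MethodACall:
    """DD-anchored conserved Method-A set.

    A DD gene enters the set iff it is called in DD and its matched group
    is fully called in at least ``min_species`` species (counting DD): a
    species supports the group when every group member from that species is
    called there.
    """
    dd_called = called_by_species.get("DD", frozenset())
    dd_anchored: set[str] = set()
    for family in families:
        groups = match_family_patterns(family, profiles_by_species, min_similarity)
        for group in groups:
            sp_members: dict[str, list[str]] = {}
            for g in group:
                for sp in family.members:
                    if g in family.members[sp]:
                        sp_members.setdefault(sp, []).append(g)
            supported = {
                sp
                for sp, genes in sp_members.items()
                if all(g in called_by_species.get(sp, frozenset()) for g in genes)
            }
            if "DD" not in supported or len(supported) < min_species:
                continue
            for g in sp_members.get("DD", []):
                if g in dd_called:
                    dd_anchored.add(g)
    return MethodACall(
        per_species_upregulated=dict(called_by_species),
        dd_anchored_set=frozenset(dd_anchored),
    )


def run_method_a(
    counts_by_species: dict[str, StageCountTable],
    families: list[OrthologFamily],
    min_reads: int = 20,
    min_fold: float = 3.0,
    min_species: int = 3,
    min_similarity: float = 0.5,
) -> tuple[MethodACall, dict[str, dict[str, ExpressionProfile]]]:
    """Full Method A on per-species count tables: RPKM, per-species calls,
    family pattern matching, DD-anchored assembly."""
    profiles = {
        sp: compute_rpkm(counts_by_species[sp], min_reads=min_reads)
        for sp in SPECIES
        if sp in counts_by_species
    }
    called = {
        sp: call_upregulated_a(p, min_reads=min_reads, min_fold=min_fold)
        for sp, p in profiles.items()
    }
    call = assemble_method_a(called, families, profiles, min_species, min_similarity)
    return call, profiles
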
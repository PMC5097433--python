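"""Core-set assembly and mutant-catalogue overlap statistics.

The three callers produce DD-anchored gene sets A (threshold), B (species
as replicates) and C (strains as replicates); their 7-region Venn partition
summarises agreement, and the triple intersection is the conserved core set
of developmentally up-regulated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError
from .types import SPECIES, GeneRecord, OrthologFamily, TruthSet

#: Fixed region labels of the 3-set Venn partition (exclusive regions).
VENN_REGIONS = (
    "A only",
    "B only",
    "C only",
    "A∩B only",
    "A∩C only",
    "B∩C only",
    "A∩B∩C",
)


@dataclass
class CoreSetReport:
    set_a: frozenset[str]
    set_b: frozenset[str]
    set_c: frozenset[str]
    venn_counts: dict[str, int]
    union_size: int
    core: frozenset[str]


@dataclass
class MutantOverlap:
    """Overlap of a phenotype catalogue with deep-conserved orthologs."""

    n_catalogue: int
    n_with_orthologs_all: int
    pct_with_orthologs_all: int
    n_all_genes: int
    n_genes_ortholog_all: int
    pct_genome_baseline: int
    n_dev_upregulated_in_catalogue: int


def integer_percent(numerator: int, denominator: int) -> int:
    """100 * ratio rounded half-up to an integer percent (0 when empty)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def anchor_to_dd(
    units: frozenset[str] | set[str],
    families: list[OrthologFamily],
) -> tuple[frozenset[str], int]:
    """Map called units to DD gene ids.

    Family ids resolve to their unique DD member (an admitted Method-B unit
    with several DD members is a consistency error); anything else is
    treated as a DD gene id and passes through.  Units without a DD member
    are dropped; the dropped count is returned alongside the set.
    """
    by_id = {f.family_id: f for f in families}
    anchored: set[str] = set()
    dropped = 0
    for unit in sorted(units):
        fam = by_id.get(unit)
        if fam is None:
            anchored.add(unit)
            continue
        dd = fam.members.get("DD", ())
        if len(dd) > 1:
            raise ConsistencyError(
                f"anchor_to_dd: family {unit} has {len(dd)} DD members; "
                "admitted units must have exactly one"
            )
        if dd:
            anchored.add(dd[0])
        else:
            dropped += 1
    return frozenset(anchored), dropped


def venn_partition(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    set_c: frozenset[str] | set[str],
) -> CoreSetReport:
    """Exact 7-region partition of three DD-anchored gene sets."""
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    abc = a & b & c
    counts = {
        "A only": len(a - b - c),
        "B only": len(b - a - c),
        "C only": len(c - a - b),
        "A∩B only": len((a & b) - c),
        "A∩C only": len((a & c) - b),
        "B∩C only": len((b & c) - a),
        "A∩B∩C": len(abc),
    }
    return CoreSetReport(
        set_a=a,
        set_b=b,
        set_c=c,
        venn_counts=counts,
        union_size=len(a | b | c),
        core=abc,
    )


def mutant_overlap(
    catalogue_genes: frozenset[str] | set[str],
    dd_upregulated: frozenset[str] | set[str],
    families: list[OrthologFamily],
    n_all_dd_genes: int,
) -> MutantOverlap:
    """Overlap statistics of a DD phenotype catalogue.

    A gene "has orthologs in all species" when its family contains at least
    one member in each of the three non-DD species.  The genome baseline is
    the same fraction over all DD genes.
    """
    others = tuple(sp for sp in SPECIES if sp != "DD")
    deep: set[str] = set()
    for fam in families:
        if all(fam.members.get(sp) for sp in others):
            deep.update(fam.members.get("DD", ()))
    cat = frozenset(catalogue_genes)
    n_cat_deep = len(cat & deep)
    return MutantOverlap(
        n_catalogue=len(cat),
        n_with_orthologs_all=n_cat_deep,
        pct_with_orthologs_all=integer_percent(n_cat_deep, len(cat)),
        n_all_genes=n_all_dd_genes,
        n_genes_ortholog_all=len(deep),
        pct_genome_baseline=integer_percent(len(deep), n_all_dd_genes),
        n_dev_upregulated_in_catalogue=len(cat & frozenset(dd_upregulated)),
    )


def sample_mutant_catalogue(
    truth: TruthSet,
    catalogue: list[GeneRecord],
    seed: int,
    frac_core: float = 0.6,
    n_noise: int = 40,
) -> frozenset[str]:
    """Synthetic stand-in for a curated mutant-phenotype catalogue.

    Samples ``frac_core`` of the planted DD core genes (genes whose
    manipulation would plausibly disturb development) plus ``n_noise``
    other DD genes, so the overlap statistics are exercisable without any
    curated external resource.
    """
    rng = np.random.default_rng([seed, 7])
    dd_core = sorted(truth.per_species_upregulated.get("DD", frozenset()))
    dd_other = sorted(
        r.gene_id for r in catalogue if r.species == "DD" and r.gene_id not in dd_core
    )
    n_core = int(round(frac_core * len(dd_core)))
    picked = set(rng.choice(dd_core, size=n_core, replace=False)) if n_core else set()
    n_noise = min(n_noise, len(dd_other))
    if n_noise:
        picked |= set(rng.choice(dd_other, size=n_noise, replace=False))
    return frozenset(picked)
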
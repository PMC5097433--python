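"""Core in-memory containers used throughout the pipeline.

Species codes follow the field's usage: DD = *Dictyostelium discoideum*,
DL = *D. lacteum*, PP = *Polysphondylium pallidum*, DF = *D. fasciculatum*.
The five sampled stages are ordinal: t0 vegetative growth, t1 early
aggregation, t2 mound, t3 early fruiting body, t4 late fruiting body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

#: The four species, in canonical order (DD first: the anchor species).
SPECIES: tuple[str, ...] = ("DD", "DL", "PP", "DF")

#: Ordered developmental stages including vegetative growth (t0).
STAGES: tuple[str, ...] = ("t0", "t1", "t2", "t3", "t4")

#: Stages eligible as expression peaks (growth excluded).
DEV_STAGES: tuple[str, ...] = ("t1", "t2", "t3", "t4")


@dataclass(eq=True)
class GeneRecord:
    """One gene: identity, coding length, protein, annotations and — for
    simulated genes — the planted truth labels (``None`` on real inputs)."""

    gene_id: str
    species: str
    cds_length_nt: int
    protein: str
    go_terms: frozenset[str] = field(default_factory=frozenset)
    truth_family: str | None = None
    truth_core_dev: bool | None = None
    truth_peak_stage: str | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown species {self.species!r}"
            )
        if self.cds_length_nt < 3 or self.cds_length_nt % 3:
            raise ValidationError(
                f"gene {self.gene_id}: cds_length_nt must be a positive multiple of 3"
            )
        if len(self.protein) != self.cds_length_nt // 3:
            raise ValidationError(
                f"gene {self.gene_id}: protein length {len(self.protein)} != "
                f"cds_length_nt/3 = {self.cds_length_nt // 3}"
            )
        if not isinstance(self.go_terms, frozenset):
            self.go_terms = frozenset(self.go_terms)


@dataclass(eq=True)
class TruthSet:
    """Planted ground truth of a simulation.

    ``core_dev_families``: families whose members are developmentally
    up-regulated in every species; ``per_species_upregulated``: the member
    gene ids by species; ``peak_stage``: planted peak stage per core gene.
    """

    core_dev_families: frozenset[str]
    per_species_upregulated: dict[str, frozenset[str]]
    peak_stage: dict[str, str]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.per_species_upregulated.values():
            out |= genes
        return frozenset(out)


@dataclass
class StageCountTable:
    """Per-species raw read counts, genes x the five ordered stages."""

    species: str
    counts: pd.DataFrame  # index: gene ids; columns: STAGES; integer counts
    gene_lengths: dict[str, int]  # gene id -> CDS length in nt

    def __post_init__(self) -> None:
        if tuple(self.counts.columns) != STAGES:
            raise ValidationError(
                f"count table for {self.species}: columns must be {STAGES}, "
                f"got {tuple(self.counts.columns)}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError(f"count table for {self.species}: negative counts")
        missing = [g for g in self.counts.index if g not in self.gene_lengths]
        if missing:
            raise ValidationError(
                f"count table for {self.species}: no CDS length for gene {missing[0]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass(eq=True)
class OrthologFamily:
    """A cluster of genes across one or more species (a gene family)."""

    family_id: str
    members: dict[str, tuple[str, ...]]  # species -> member gene ids (sorted)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for sp in sorted(self.members):
            out.extend(self.members[sp])
        return tuple(out)

    @property
    def n_species(self) -> int:
        return sum(1 for v in self.members.values() if v)

    def is_one_per_species(self, species: tuple[str, ...] = SPECIES) -> bool:
        return all(len(self.members.get(sp, ())) == 1 for sp in species)


@dataclass(eq=True)
class FamilyStats:
    """Summary statistics of a family set (families with >= 2 members)."""

    n_families_ge2: int
    n_one_per_species: int
    n_present_in_all: int
    largest_family_size: int
    largest_family_per_species: dict[str, int]
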
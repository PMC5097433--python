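"""Readers for the plain-text exchange formats of the pipeline.

Formats: protein FASTA per species; ``gene_info.tsv`` (gene_id, species,
cds_length_nt); count TSVs (gene_id, t0..t4); GAF-like annotation TSV
(gene_id, term_id); ontology is_a edge TSV (child_term, parent_term);
families TSV (family_id, gene_id, species); truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import ValidationError
from .types import SPECIES, STAGES, GeneRecord, OrthologFamily, StageCountTable, TruthSet


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {gene_id: protein sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_info(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species": str})
    required = {"gene_id", "species", "cds_length_nt"}
    if not required.issubset(df.columns):
        raise ValidationError(f"gene info {path}: missing columns {required - set(df.columns)}")
    return df


def read_counts_tsv(path: str | Path, species: str,
                    gene_lengths: dict[str, int]) -> StageCountTable:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if tuple(df.columns) != STAGES:
        raise ValidationError(f"count table {path}: columns must be {STAGES}")
    return StageCountTable(species=species, counts=df.astype("int64"),
                           gene_lengths={g: gene_lengths[g] for g in df.index})


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Annotation TSV -> {gene_id: set of directly annotated terms}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in out.items()}


def read_ontology_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(zip(df["child_term"], df["parent_term"]))


def read_truth(path: str | Path) -> tuple[TruthSet, dict[str, str]]:
    """truth JSON -> (TruthSet, gene -> family provenance map)."""
    with open(path) as fh:
        payload = json.load(fh)
    truth = TruthSet(
        core_dev_families=frozenset(payload["core_dev_families"]),
        per_species_upregulated={
            sp: frozenset(v) for sp, v in payload["per_species_upregulated"].items()
        },
        peak_stage=dict(payload["peak_stage"]),
    )
    return truth, dict(payload.get("gene_families", {}))


def load_fixture(fixture_dir: str | Path
                 ) -> tuple[list[GeneRecord], dict[str, StageCountTable], TruthSet]:
    """Load a directory written by :func:`dictycore.simulate.write_fixture`.

    Reconstructs the catalogue (including truth labels), all count tables
    present (``counts_*.tsv``) and the truth set.
    """
    d = Path(fixture_dir)
    info = read_gene_info(d / "gene_info.tsv")
    proteins: dict[str, str] = {}
    for sp in SPECIES:
        proteins.update(read_protein_fasta(d / f"proteins_{sp}.fasta"))
    annotations = read_annotations(d / "annotations.tsv") \
        if (d / "annotations.tsv").exists() else {}
    truth, gene_families = read_truth(d / "truth.json")
    core_genes = truth.all_genes()

    catalogue: list[GeneRecord] = []
    for row in info.itertuples(index=False):
        fam = gene_families.get(row.gene_id)
        catalogue.append(
            GeneRecord(
                gene_id=row.gene_id,
                species=row.species,
                cds_length_nt=int(row.cds_length_nt),
                protein=proteins[row.gene_id],
                go_terms=annotations.get(row.gene_id, frozenset()),
                truth_family=fam,
                truth_core_dev=row.gene_id in core_genes,
                truth_peak_stage=truth.peak_stage.get(row.gene_id),
            )
        )

    lengths = {r.gene_id: r.cds_length_nt for r in catalogue}
    counts: dict[str, StageCountTable] = {}
    for path in sorted(d.glob("counts_*.tsv")):
        key = path.stem[len("counts_"):]
        species = key.split("_")[0]
        counts[key] = read_counts_tsv(path, species, lengths)
    return catalogue, counts, truth


def write_families_tsv(families: list[OrthologFamily], path: str | Path) -> None:
    rows = [
        (f.family_id, g, sp)
        for f in families
        for sp in sorted(f.members)
        for g in f.members[sp]
    ]
    pd.DataFrame(rows, columns=["family_id", "gene_id", "species"]).to_csv(
        path, sep="\t", index=False
    )


def read_families_tsv(path: str | Path) -> list[OrthologFamily]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams: dict[str, dict[str, list[str]]] = {}
    for fam, gene, sp in zip(df["family_id"], df["gene_id"], df["species"]):
        fams.setdefault(fam, {}).setdefault(sp, []).append(gene)
    return [
        OrthologFamily(
            family_id=fid,
            members={sp: tuple(sorted(genes)) for sp, genes in members.items()},
        )
        for fid, members in sorted(fams.items())
    ]
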
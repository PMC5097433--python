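"""End-to-end pipeline on a simulated four-species study.

Chains the full procedure: simulate catalogue and counts, build ortholog
families (similarity graph + MCL), run the three up-regulation callers,
assemble the DD-anchored Venn partition and core set, test GO enrichment of
the defined set, run the conservation-versus-peak analysis, and compute
mutant-catalogue overlap statistics against a sampled synthetic catalogue.

Every artefact is a deterministic function of the
:class:`~dictycore.config.SimulationConfig`, so two runs with the same
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .config import SimulationConfig
from .conservation import (
    ConservationRecord,
    ConservationTest,
    build_conservation_records,
    conservation_by_peak,
)
from .coreset import (
    CoreSetReport,
    MutantOverlap,
    anchor_to_dd,
    mutant_overlap,
    sample_mutant_catalogue,
    venn_partition,
)
from .diffexpr import (
    MethodCallResult,
    build_method_b_design,
    build_method_c_design,
    call_method,
)
from .enrichment import EnrichmentResult, OntologyDAG, hypergeometric_enrichment, propagate_annotations
from .errors import ValidationError
from .expression import MethodACall, run_method_a
from .io import write_families_tsv
from .orthology import MclResult, family_stats, mcl_cluster, similarity_graph
from .simulate import DEMO_ONTOLOGY_EDGES, simulate_counts, simulate_families, write_fixture
from .types import SPECIES, FamilyStats, GeneRecord, StageCountTable, TruthSet


@dataclass
class PipelineResult:
    config: SimulationConfig
    catalogue: list[GeneRecord]
    truth: TruthSet
    counts: dict[str, StageCountTable]
    mcl: MclResult
    stats: FamilyStats
    method_a: MethodACall
    method_b: MethodCallResult
    method_c: MethodCallResult
    set_a: frozenset[str]
    set_b: frozenset[str]
    set_c: frozenset[str]
    report: CoreSetReport
    enrichment: list[EnrichmentResult]
    conservation_records: list[ConservationRecord]
    conservation: ConservationTest | None
    mutant_catalogue: frozenset[str]
    overlap: MutantOverlap

    def truth_dd_core(self) -> frozenset[str]:
        return self.truth.per_species_upregulated.get("DD", frozenset())

    def set_metrics(self, called: frozenset[str]) -> dict[str, float]:
        """Recall / precision / observed FDR of a DD-anchored set vs truth."""
        truth_set = self.truth_dd_core()
        tp = len(called & truth_set)
        recall = tp / len(truth_set) if truth_set else float("nan")
        precision = tp / len(called) if called else 1.0
        return {
            "recall": recall,
            "precision": precision,
            "observed_fdr": 1.0 - precision,
            "n_called": len(called),
            "n_truth": len(truth_set),
        }


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    fdr: float = 0.10,
    mutant_frac_core: float = 0.6,
    mutant_n_noise: int = 40,
) -> PipelineResult:
    """Run the whole analysis on a freshly simulated study."""
    catalogue, truth = simulate_families(config)
    counts = simulate_counts(catalogue, truth, config, include_ax4=True)
    species_counts = {sp: counts[sp] for sp in SPECIES}

    edges = similarity_graph(catalogue)
    species_of = {r.gene_id: r.species for r in catalogue}
    mcl = mcl_cluster(edges, species_of=species_of)
    stats = family_stats(mcl.families)

    method_a, profiles = run_method_a(species_counts, mcl.families)
    set_a = method_a.dd_anchored_set

    design_b = build_method_b_design(mcl.families, species_counts)
    method_b = call_method(design_b, fdr=fdr)
    set_b, _ = anchor_to_dd(method_b.called, mcl.families)

    design_c = build_method_c_design(counts["DD"], counts["DD_AX4"])
    method_c = call_method(design_c, fdr=fdr)
    # Method C keeps only genes with a detectable ortholog in another species
    with_ortholog = {
        g
        for fam in mcl.families
        if any(fam.members.get(sp) for sp in SPECIES if sp != "DD")
        for g in fam.members.get("DD", ())
    }
    set_c = frozenset(g for g in method_c.called if g in with_ortholog)

    report = venn_partition(set_a, set_b, set_c)
    defined_set = set_a | set_b | set_c

    dag = OntologyDAG.from_edges(list(DEMO_ONTOLOGY_EDGES))
    direct = {
        r.gene_id: r.go_terms for r in catalogue if r.species == "DD" and r.go_terms
    }
    annotations = propagate_annotations(dag, direct)
    population = frozenset(annotations)
    study = frozenset(defined_set) & population
    enrich = hypergeometric_enrichment(study, population, annotations, fdr=fdr)

    proteins = {r.gene_id: r.protein for r in catalogue}
    records = build_conservation_records(
        defined_set, mcl.families, proteins, profiles.get("DD", {})
    )
    try:
        conservation = conservation_by_peak(records)
    except ValidationError:
        conservation = None

    mutants = sample_mutant_catalogue(
        truth, catalogue, config.seed, frac_core=mutant_frac_core, n_noise=mutant_n_noise
    )
    n_dd = sum(1 for r in catalogue if r.species == "DD")
    overlap = mutant_overlap(mutants, defined_set, mcl.families, n_dd)

    result = PipelineResult(
        config=config,
        catalogue=catalogue,
        truth=truth,
        counts=counts,
        mcl=mcl,
        stats=stats,
        method_a=method_a,
        method_b=method_b,
        method_c=method_c,
        set_a=set_a,
        set_b=set_b,
        set_c=set_c,
        report=report,
        enrichment=enrich,
        conservation_records=records,
        conservation=conservation,
        mutant_catalogue=mutants,
        overlap=overlap,
    )
    if out_dir is not None:
        write_pipeline_outputs(result, out_dir)
    return result


def _dump_json(payload, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write every pipeline artefact as deterministic plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = write_fixture(result.catalogue, result.counts, result.truth, out)

    path = out / "families.tsv"
    write_families_tsv(result.mcl.families, path)
    written.append(path)

    path = out / "family_stats.json"
    _dump_json(asdict(result.stats), path)
    written.append(path)

    path = out / "method_a.tsv"
    with open(path, "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(result.set_a):
            fh.write(g + "\n")
    written.append(path)

    for name, method in (("method_b", result.method_b), ("method_c", result.method_c)):
        path = out / f"{name}_results.tsv"
        method.results.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    path = out / "coreset.json"
    _dump_json(
        {
            "set_a": sorted(result.set_a),
            "set_b": sorted(result.set_b),
            "set_c": sorted(result.set_c),
            "venn_counts": result.report.venn_counts,
            "union_size": result.report.union_size,
            "core": sorted(result.report.core),
        },
        path,
    )
    written.append(path)

    path = out / "enrichment.tsv"
    with open(path, "w") as fh:
        fh.write("term_id\tk_study\tn_study\tk_pop\tn_pop\tp_value\tq_value\n")
        for r in result.enrichment:
            fh.write(
                f"{r.term_id}\t{r.k_study}\t{r.n_study}\t{r.k_pop}\t{r.n_pop}"
                f"\t{r.p_value:.10g}\t{r.q_value:.10g}\n"
            )
    written.append(path)

    path = out / "conservation.tsv"
    with open(path, "w") as fh:
        fh.write("dd_gene_id\tdf_gene_id\tpercent_identity\tpeak_stage\n")
        for r in result.conservation_records:
            fh.write(
                f"{r.dd_gene_id}\t{r.df_gene_id}\t{r.percent_identity:.10g}\t{r.peak_stage}\n"
            )
    written.append(path)

    if result.conservation is not None:
        path = out / "conservation_test.json"
        _dump_json(asdict(result.conservation), path)
        written.append(path)

    path = out / "mutant_overlap.json"
    _dump_json(asdict(result.overlap), path)
    written.append(path)
    return written
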
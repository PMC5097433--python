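"""Synthetic four-species developmental transcriptomes with planted truth.

The generator emulates the data landscape of a four-species comparative
developmental RNA-seq study:

* conserved gene families evolved from an ancestral protein down the fixed
  species topology ((DF,PP),(DL,DD)), with per-branch duplication/loss and
  Poisson-sampled amino-acid substitutions whose rate depends on the gene's
  planted expression peak (late-peaking genes evolve more slowly),
* species-specific singleton genes with no homolog anywhere,
* negative-binomial read counts over five ordered stages (growth t0 through
  late fruiting t4), with a planted peak fold change for core developmental
  genes and adjacent-stage signal mixing that models imperfectly
  synchronised development ("asynchrony quenching"),
* GO annotations over a small fixed is_a DAG, with developmental terms
  enriched among planted core genes,
* a machine-readable truth set for recall/precision evaluation downstream.

All randomness derives from ``SimulationConfig.seed`` through fixed,
documented substreams (families & sequences, counts, annotations), so every
artefact is byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConsistencyError
from .types import DEV_STAGES, SPECIES, STAGES, GeneRecord, StageCountTable, TruthSet

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

#: Fixed species topology: two main branches, (DF,PP) and (DL,DD).
#: Each tuple is (node name, children); leaves have no children.
_TREE = (
    "LCA",
    (
        ("anc_DF_PP", (("DF", ()), ("PP", ()))),
        ("anc_DL_DD", (("DL", ()), ("DD", ()))),
    ),
)

#: Small fixed is_a ontology used for simulated annotations (child, parent).
#: GO:0006935 (chemotaxis) has two parents, exercising the diamond case.
DEMO_ONTOLOGY_EDGES: tuple[tuple[str, str], ...] = (
    ("GO:0032502", "GO:0008150"),  # developmental process -> biological_process
    ("GO:0030154", "GO:0032502"),  # cell differentiation
    ("GO:0031154", "GO:0032502"),  # culmination during sorocarp development
    ("GO:0007165", "GO:0008150"),  # signal transduction
    ("GO:0007186", "GO:0007165"),  # GPCR signaling pathway
    ("GO:0007154", "GO:0008150"),  # cell communication
    ("GO:0040011", "GO:0008150"),  # locomotion
    ("GO:0006935", "GO:0007154"),  # chemotaxis (is_a cell communication ...)
    ("GO:0006935", "GO:0040011"),  # ... and is_a locomotion
    ("GO:0008152", "GO:0008150"),  # metabolic process
    ("GO:0006096", "GO:0008152"),  # glycolysis
    ("GO:0019538", "GO:0008152"),  # protein metabolism
    ("GO:0006412", "GO:0019538"),  # translation
)

#: Leaf terms characteristic of development, over-assigned to core genes.
DEV_LEAF_TERMS = ("GO:0030154", "GO:0031154", "GO:0007186", "GO:0006935")
#: Housekeeping-flavoured leaf terms, assigned uniformly at random.
BACKGROUND_LEAF_TERMS = ("GO:0030154", "GO:0031154", "GO:0007186", "GO:0006935",
                         "GO:0006096", "GO:0006412")


def _evolve(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One branch (length 1.0): Poisson-sampled uniform replacements."""
    n_sub = rng.poisson(rate * seq.size)
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.integers(0, seq.size, size=n_sub)
    for p in pos:
        r = rng.integers(0, 19)
        if r >= out[p]:
            r += 1
        out[p] = r
    return out


def _descend(node, lineages: list[np.ndarray], rate: float,
             cfg: SimulationConfig, rng: np.random.Generator,
             leaves: dict[str, list[np.ndarray]]) -> None:
    name, children = node
    if not children:
        leaves[name] = lineages
        return
    for child in children:
        child_lineages: list[np.ndarray] = []
        for seq in lineages:
            if rng.random() < cfg.loss_prob:
                continue
            copies = 2 if rng.random() < cfg.duplication_prob else 1
            for _ in range(copies):
                child_lineages.append(_evolve(seq, rate, rng))
        _descend(child, child_lineages, rate, cfg, rng, leaves)


def _random_protein(n_aa: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 20, size=n_aa).astype(np.uint8)


def _to_str(seq: np.ndarray) -> str:
    return _AA[seq].tobytes().decode()


def simulate_families(config: SimulationConfig) -> tuple[list[GeneRecord], TruthSet]:
    """Generate the four-species gene catalogue and its planted truth.

    Returns the catalogue (records grouped by family, then species-specific
    singletons) and the :class:`TruthSet`.  Deterministic for a given seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo_aa = max(1, (config.cds_length_range[0] + 2) // 3)
    hi_aa = config.cds_length_range[1] // 3

    n_core = int(round(config.frac_core_dev * config.n_families_conserved))
    records: list[GeneRecord] = []
    counters = {sp: 0 for sp in SPECIES}
    core_families: set[str] = set()
    peak_by_gene: dict[str, str] = {}
    up_by_species: dict[str, set[str]] = {sp: set() for sp in SPECIES}

    def new_gene(sp: str, seq: np.ndarray, fam: str | None, core: bool,
                 peak: str | None) -> GeneRecord:
        counters[sp] += 1
        gid = f"{sp}_g{counters[sp]:04d}"
        rec = GeneRecord(
            gene_id=gid,
            species=sp,
            cds_length_nt=3 * seq.size,
            protein=_to_str(seq),
            truth_family=fam,
            truth_core_dev=core,
            truth_peak_stage=peak,
        )
        if core:
            up_by_species[sp].add(gid)
            peak_by_gene[gid] = peak  # type: ignore[arg-type]
        return rec

    for i in range(config.n_families_conserved):
        fam = f"F{i + 1:04d}"
        core = i < n_core
        peak = DEV_STAGES[rng.integers(0, 4)] if core else None
        rate = (
            config.substitution_rate_late_peak
            if peak in ("t3", "t4")
            else config.substitution_rate_early_peak
        )
        n_aa = int(rng.integers(lo_aa, hi_aa + 1))
        ancestor = _random_protein(n_aa, rng)
        leaves: dict[str, list[np.ndarray]] = {}
        _descend(_TREE, [ancestor], rate, config, rng, leaves)
        if core:
            core_families.add(fam)
        for sp in SPECIES:
            for seq in leaves.get(sp, []):
                records.append(new_gene(sp, seq, fam, core, peak))

    for sp in SPECIES:
        for _ in range(config.n_species_specific_per_species):
            n_aa = int(rng.integers(lo_aa, hi_aa + 1))
            records.append(new_gene(sp, _random_protein(n_aa, rng), None, False, None))

    # GO annotations: background terms everywhere, developmental leaf terms
    # preferentially on planted core genes.
    rng_go = np.random.default_rng([config.seed, 3])
    for rec in records:
        terms: set[str] = set()
        for _ in range(rng_go.poisson(0.8)):
            terms.add(BACKGROUND_LEAF_TERMS[rng_go.integers(0, len(BACKGROUND_LEAF_TERMS))])
        if rec.truth_core_dev and rng_go.random() < 0.85:
            terms.add(DEV_LEAF_TERMS[rng_go.integers(0, len(DEV_LEAF_TERMS))])
        rec.go_terms = frozenset(terms)

    truth = TruthSet(
        core_dev_families=frozenset(core_families),
        per_species_upregulated={sp: frozenset(up_by_species[sp]) for sp in SPECIES},
        peak_stage=dict(sorted(peak_by_gene.items())),
    )
    return records, truth


def expected_fold_profile(fold: float, peak_stage: str, post_peak_fraction: float
                          ) -> np.ndarray:
    """Expected fold-over-growth at each stage for a planted core gene.

    Linear rise from 1 at t0 to ``fold`` at the peak stage, then a decay to
    ``1 + (fold - 1) * post_peak_fraction`` so the planted peak is unique.
    """
    p = STAGES.index(peak_stage)
    prof = np.ones(5)
    for s in range(1, 5):
        if s <= p:
            prof[s] = 1.0 + (fold - 1.0) * s / p
        else:
            prof[s] = 1.0 + (fold - 1.0) * post_peak_fraction
    return prof


def mix_adjacent_stages(expected: np.ndarray, mix: float) -> np.ndarray:
    """Quench developmental stages by mixing with their neighbours' signal.

    Imperfectly synchronised development blurs the plated stages into each
    other: for s in t1..t4, ``out[s] = (1-mix)*e[s] + mix/2*(e[s-1] +
    e[s+1])``, with t4 (one neighbour) mixing at ``mix/2`` only.  The
    growth sample t0 is left untouched — it is harvested before plating,
    when the population is uniformly vegetative, so developmental
    asynchrony cannot blur it (t1 still borrows from the t0 signal, since
    lagging cells in an early-aggregation sample look vegetative).
    """
    if mix == 0.0:
        return expected.copy()
    out = expected.copy()
    out[:, 1:] *= 1.0 - mix
    out[:, 1:-1] += 0.5 * mix * (expected[:, :-2] + expected[:, 2:])
    out[:, -1] += 0.5 * mix * expected[:, -2]
    return out


def _sample_table(mu: np.ndarray, lib: int, alpha: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Counts for one replicate series with NB mean-variance, columns = lib.

    The overdispersion alpha acts at the replicate-series level, as in the
    evolutionary-replicates design it is later estimated from: each gene
    draws one series-level expression offset u ~ Gamma(1/alpha, alpha)
    (mean 1, CV^2 = alpha) shared by its five stages, and stage counts are
    multinomial around the offset-scaled expectations (Poisson-like
    counting noise, stage totals fixed at the library size).  Marginally a
    count has mean ~mu and variance ~mu + alpha*mu**2; across independent
    series (species, strains) counts of one gene are overdispersed with
    shape alpha, while within one series the stage-to-stage ratios carry
    only counting noise — the structure a single developmental time course
    per biological sample actually has.  With alpha == 0 the noise-free
    limit (rounded expectations) is returned.
    """
    if alpha == 0.0:
        return np.rint(mu).astype(np.int64)
    u = rng.gamma(1.0 / alpha, alpha, size=mu.shape[0])
    lam = mu * u[:, None]
    counts = np.empty_like(mu, dtype=np.int64)
    for s in range(mu.shape[1]):
        col = lam[:, s]
        counts[:, s] = rng.multinomial(lib, col / col.sum())
    return counts


def simulate_counts(
    catalogue: list[GeneRecord],
    truth: TruthSet,
    config: SimulationConfig,
    include_ax4: bool = False,
) -> dict[str, StageCountTable]:
    """Simulate per-species stage count tables for a generated catalogue.

    Core genes rise to a family-shared planted fold change at their truth
    peak stage; all expected signals undergo adjacent-stage mixing; each
    stage column is scaled to ``library_size_per_stage`` and sampled with
    negative-binomial noise (see :func:`_sample_table`).

    With ``include_ax4`` a second DD strain table (key ``"DD_AX4"``) is
    produced: same expected profiles times a per-gene log-normal strain
    offset, independent sampling noise.
    """
    ids = {r.gene_id for r in catalogue}
    missing = truth.all_genes() - ids
    if missing:
        raise ConsistencyError(
            f"truth lists gene(s) absent from the catalogue, e.g. {sorted(missing)[0]}"
        )
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.fold_change_range

    fold_by_family = {
        fam: rng.uniform(lo, hi) for fam in sorted(truth.core_dev_families)
    }
    # Ortholog expression levels are conserved: one baseline per family,
    # jittered per member; singletons draw their own baseline.
    family_ids = sorted({r.truth_family for r in catalogue if r.truth_family})
    family_baseline = {
        fam: rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
        for fam in family_ids
    }
    baselines: dict[str, float] = {}
    for r in catalogue:
        if r.truth_family is not None:
            baselines[r.gene_id] = family_baseline[r.truth_family] * rng.lognormal(
                0.0, config.ortholog_baseline_jitter_sd
            )
        else:
            baselines[r.gene_id] = rng.lognormal(
                config.baseline_log_mean, config.baseline_log_sd
            )

    def expected_matrix(records: list[GeneRecord]) -> np.ndarray:
        e = np.empty((len(records), 5))
        for i, r in enumerate(records):
            if r.gene_id in truth.peak_stage:
                prof = expected_fold_profile(
                    fold_by_family[r.truth_family],  # type: ignore[index]
                    truth.peak_stage[r.gene_id],
                    config.post_peak_fraction,
                )
            else:
                prof = np.ones(5)
            # expected read mass ~ rpkm * length
            e[i] = baselines[r.gene_id] * prof * r.cds_length_nt
        return e

    def build_table(records: list[GeneRecord], e: np.ndarray, species: str
                    ) -> StageCountTable:
        mixed = mix_adjacent_stages(e, config.asynchrony_mix)
        mu = config.library_size_per_stage * mixed / mixed.sum(axis=0)
        counts = _sample_table(mu, config.library_size_per_stage,
                               config.dispersion, rng)
        df = pd.DataFrame(counts, index=[r.gene_id for r in records],
                          columns=list(STAGES))
        lengths = {r.gene_id: r.cds_length_nt for r in records}
        return StageCountTable(species=species, counts=df, gene_lengths=lengths)

    out: dict[str, StageCountTable] = {}
    by_species = {sp: [r for r in catalogue if r.species == sp] for sp in SPECIES}
    for sp in SPECIES:
        recs = by_species[sp]
        out[sp] = build_table(recs, expected_matrix(recs), sp)
    if include_ax4:
        recs = by_species["DD"]
        e = expected_matrix(recs)
        strain = rng.lognormal(0.0, config.strain_effect_sd, size=(len(recs), 1))
        out["DD_AX4"] = build_table(recs, e * strain, "DD")
    return out


# ---------------------------------------------------------------------------
# fixture writer


def write_fixture(
    catalogue: list[GeneRecord],
    counts: dict[str, StageCountTable],
    truth: TruthSet,
    out_dir: str | Path,
) -> list[Path]:
    """Write the simulated study to plain-text files.

    Produces one protein FASTA per species, ``gene_info.tsv``, one count TSV
    per table, ``annotations.tsv`` (gene, GO term), ``ontology_edges.tsv``
    (child, parent) and ``truth.json``.  Round-trips losslessly through
    :func:`dictycore.io.load_fixture`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for sp in SPECIES:
        path = out / f"proteins_{sp}.fasta"
        with open(path, "w") as fh:
            for r in catalogue:
                if r.species == sp:
                    fh.write(f">{r.gene_id}\n{r.protein}\n")
        written.append(path)

    path = out / "gene_info.tsv"
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in catalogue],
            "species": [r.species for r in catalogue],
            "cds_length_nt": [r.cds_length_nt for r in catalogue],
        }
    ).to_csv(path, sep="\t", index=False)
    written.append(path)

    for key in sorted(counts):
        path = out / f"counts_{key}.tsv"
        counts[key].counts.rename_axis("gene_id").to_csv(path, sep="\t")
        written.append(path)

    path = out / "annotations.tsv"
    rows = sorted(
        (r.gene_id, t) for r in catalogue for t in r.go_terms
    )
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )
    written.append(path)

    path = out / "ontology_edges.tsv"
    pd.DataFrame(list(DEMO_ONTOLOGY_EDGES), columns=["child_term", "parent_term"]
                 ).to_csv(path, sep="\t", index=False)
    written.append(path)

    path = out / "truth.json"
    payload = {
        "core_dev_families": sorted(truth.core_dev_families),
        "per_species_upregulated": {
            sp: sorted(truth.per_species_upregulated.get(sp, ())) for sp in SPECIES
        },
        "peak_stage": dict(sorted(truth.peak_stage.items())),
        "gene_families": {
            r.gene_id: r.truth_family for r in catalogue if r.truth_family
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)
    return written
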
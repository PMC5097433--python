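"""Simulation parameters.

The defaults define the study conditions exercised throughout the test
suite: 100 conserved families of which 10 % are planted as conserved
developmentally up-regulated (peak fold change uniform on [4, 20]),
negative-binomial dispersion 0.2, stage-asynchrony mixing 0.3, and a
sequence-divergence gradient in which late-peaking genes evolve more slowly
than early-peaking ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the four-species developmental transcriptome simulator.

    Parameters
    ----------
    seed
        Master seed; every random stream is derived from it.
    n_families_conserved
        Families present in the last common ancestor and evolved down the
        fixed topology ((DF,PP),(DL,DD)).
    n_species_specific_per_species
        Additional singleton genes per species with no homolog anywhere.
    frac_core_dev
        Fraction of conserved families planted as conserved developmentally
        up-regulated (all members share peak stage and fold change).
    fold_change_range
        (low, high) of the uniform draw for the planted peak fold change.
    dispersion
        Negative-binomial shape alpha: Var = mu + alpha * mu**2.  Zero means
        the noise-free limit (counts are rounded expectations).
    library_size_per_stage
        Total reads per stage column (sequencing depth).
    asynchrony_mix
        Proportion of a stage's expected signal borrowed from its adjacent
        stages, emulating imperfectly synchronised development.
    substitution_rate_early_peak, substitution_rate_late_peak
        Expected amino-acid substitutions per site per branch for genes
        peaking early (t1/t2, and all non-core genes) versus late (t3/t4).
        The late rate must be lower: late-peaking genes are more conserved.
    duplication_prob, loss_prob
        Per-branch, per-lineage birth/death probabilities.
    cds_length_range
        CDS lengths drawn uniformly from this range in multiples of 3 nt.
    baseline_log_mean, baseline_log_sd
        Log-normal baseline expression (natural-log scale, rpkm units).
    post_peak_fraction
        After the peak, the expected fold decays to
        1 + (fold - 1) * post_peak_fraction (keeps the peak unique).
    ortholog_baseline_jitter_sd
        Log-normal sd of each family member's baseline around the shared
        family baseline: ortholog expression levels are conserved but not
        identical across species.
    strain_effect_sd
        Log-normal sd of the per-gene expression offset of the second DD
        laboratory strain (AX4) relative to NC4.
    """

    seed: int = 42
    n_families_conserved: int = 100
    n_species_specific_per_species: int = 30
    frac_core_dev: float = 0.10
    fold_change_range: tuple[float, float] = (4.0, 20.0)
    dispersion: float = 0.2
    library_size_per_stage: int = 500_000
    asynchrony_mix: float = 0.3
    substitution_rate_early_peak: float = 0.15
    substitution_rate_late_peak: float = 0.05
    duplication_prob: float = 0.05
    loss_prob: float = 0.05
    cds_length_range: tuple[int, int] = (300, 3000)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    post_peak_fraction: float = 0.3
    ortholog_baseline_jitter_sd: float = 0.3
    strain_effect_sd: float = 0.1

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid {name}: {why}")

        if not isinstance(self.seed, int) or self.seed < 0:
            raise bad("seed", "must be a non-negative integer")
        for name in ("n_families_conserved", "n_species_specific_per_species"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise bad(name, "must be a non-negative integer")
        if self.n_families_conserved == 0 and self.n_species_specific_per_species == 0:
            raise bad("n_families_conserved", "simulation would contain no genes")
        for name in ("frac_core_dev",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, "must be a fraction in [0, 1]")
        lo, hi = self.fold_change_range
        if not (0 < lo <= hi):
            raise bad("fold_change_range", "need 0 < low <= high")
        if self.dispersion < 0:
            raise bad("dispersion", "must be >= 0")
        if self.library_size_per_stage <= 0:
            raise bad("library_size_per_stage", "must be a positive integer")
        if not 0.0 <= self.asynchrony_mix < 1.0:
            raise bad("asynchrony_mix", "must be in [0, 1)")
        for name in ("substitution_rate_early_peak", "substitution_rate_late_peak"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        if self.substitution_rate_late_peak > self.substitution_rate_early_peak:
            raise bad(
                "substitution_rate_late_peak",
                "must not exceed substitution_rate_early_peak "
                "(late-peaking genes are the conserved ones)",
            )
        for name in ("duplication_prob", "loss_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise bad(name, "must be a fraction in [0, 1]")
        lo, hi = self.cds_length_range
        if not (3 <= lo <= hi):
            raise bad("cds_length_range", "need 3 <= low <= high")
        if self.baseline_log_sd < 0:
            raise bad("baseline_log_sd", "must be >= 0")
        if not 0.0 <= self.post_peak_fraction <= 1.0:
            raise bad("post_peak_fraction", "must be a fraction in [0, 1]")
        if self.ortholog_baseline_jitter_sd < 0:
            raise bad("ortholog_baseline_jitter_sd", "must be >= 0")
        if self.strain_effect_sd < 0:
            raise bad("strain_effect_sd", "must be >= 0")
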
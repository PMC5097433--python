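"""Negative-binomial DE engine: normalization, dispersion, Wald test, BH."""

from __future__ import annotations

import numpy as np
import pytest

import dictycore as dc
from dictycore.diffexpr import ReplicateDesign, _wald_stage_matrix
from dictycore.errors import ValidationError

from _oracles import bh_step_up


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        k = np.tile(np.array([[10], [55], [200]]), (1, 2))
        assert dc.size_factors(k) == pytest.approx([1.0, 1.0])

    def test_doubled_sample_splits_sqrt2(self):
        k = np.array([[10, 20], [55, 110], [200, 400]])
        assert dc.size_factors(k) == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_toy_matrix_matches_median_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        k = rng.integers(1, 500, size=(5, 3)).astype(float)
        got = dc.size_factors(k)
        for j in range(3):
            ratios = sorted(
                k[i, j] / np.prod(k[i]) ** (1 / 3) for i in range(5)
            )
            assert got[j] == pytest.approx(ratios[2])  # median of 5

    def test_scaling_a_sample_scales_its_relative_factor(self):
        # median-of-ratios factors are defined up to the per-unit geometric
        # mean, so tripling one library triples its factor relative to the
        # other samples
        rng = np.random.default_rng(6)
        k = rng.integers(1, 500, size=(20, 4)).astype(float)
        base = dc.size_factors(k)
        k2 = k.copy()
        k2[:, 1] *= 3.0
        got = dc.size_factors(k2)
        assert (got[1] / got[0]) / (base[1] / base[0]) == pytest.approx(3.0)

    def test_no_all_positive_unit_is_error(self):
        with pytest.raises(ValidationError, match="filter"):
            dc.size_factors(np.array([[0, 5], [3, 0]]))


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(7)
        mu = rng.uniform(50, 500, size=(500, 1))
        k = rng.poisson(np.tile(mu, (1, 8)))
        labels = ["t0"] * 4 + ["t1"] * 4
        est = dc.estimate_dispersion(k, labels)
        assert np.median([d.raw_alpha for d in est]) < 0.02

    def test_nb_alpha_is_recovered(self):
        rng = np.random.default_rng(8)
        alpha = 0.2
        mu = rng.uniform(50, 500, size=(500, 1))
        lam = rng.gamma(1 / alpha, alpha * np.tile(mu, (1, 8)))
        k = rng.poisson(lam)
        labels = ["t0"] * 4 + ["t1"] * 4
        est = dc.estimate_dispersion(k, labels)
        assert 0.1 <= np.median([d.final_alpha for d in est]) <= 0.4

    def test_constant_counts_fall_back_to_trend(self):
        k = np.array([[100, 100, 100, 100], [10, 10, 30, 30], [50, 60, 80, 90]])
        labels = ["t0", "t0", "t1", "t1"]
        est = dc.estimate_dispersion(k, labels, unit_ids=["u0", "u1", "u2"])
        assert est[0].raw_alpha == 0.0
        assert est[0].final_alpha == pytest.approx(
            max(est[0].fitted_alpha, 1e-8)
        )

    def test_single_replicate_everywhere_is_error(self):
        with pytest.raises(ValidationError, match="replicate"):
            dc.estimate_dispersion(np.ones((5, 2)), ["t0", "t1"])


class TestNbStageTest:
    def test_identical_groups_give_null_result(self):
        counts = np.array([50, 60, 55, 50, 60, 55], dtype=float)
        res = dc.nb_stage_test(
            counts, np.ones(6), ["t0"] * 3 + ["t2"] * 3, "t2", alpha=0.1
        )
        assert abs(res.log2_fold_change) < 1e-8
        assert res.p_value == pytest.approx(1.0)

    def test_doubled_counts_give_lfc_one(self):
        counts = np.array([100, 100, 100, 200, 200, 200], dtype=float)
        res = dc.nb_stage_test(
            counts, np.ones(6), ["t0"] * 3 + ["t3"] * 3, "t3", alpha=1e-8
        )
        assert res.log2_fold_change == pytest.approx(1.0, abs=1e-6)
        assert res.p_value < 1e-6

    def test_all_zero_unit_is_flagged_null(self):
        counts = np.zeros(6)
        res = dc.nb_stage_test(
            counts, np.ones(6), ["t0"] * 3 + ["t1"] * 3, "t1", alpha=0.1
        )
        assert res.flagged
        assert res.p_value == 1.0
        assert res.log2_fold_change == 0.0

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValidationError):
            dc.nb_stage_test(np.ones(4), np.ones(4), ["t0", "t0", "t1", "t1"],
                             "t0", alpha=0.1)


class TestBhAdjust:
    def test_hand_step_up_example(self):
        q = dc.bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        assert dc.bh_adjust([0.2]) == pytest.approx([0.2])
        assert dc.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            dc.bh_adjust([0.5, 1.5])

    def test_matches_independent_step_up_oracle_and_dominates_p(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            q = dc.bh_adjust(p)
            assert q == pytest.approx(bh_step_up(p))
            assert np.all(q >= p - 1e-12)


def _nb_design(rng, n_units, alpha, fold=None, frac_planted=0.0,
               n_reps=4, mu_range=(50, 500)):
    """Direct NB design: n_reps replicates at t0 and t3."""
    mu = rng.uniform(*mu_range, size=(n_units, 1))
    mu_mat = np.tile(mu, (1, 2 * n_reps))
    planted = np.zeros(n_units, dtype=bool)
    if fold is not None:
        planted[: int(frac_planted * n_units)] = True
        mu_mat[planted, n_reps:] *= fold
    lam = rng.gamma(1 / alpha, alpha * mu_mat)
    k = rng.poisson(lam)
    samples = [("r%d" % i, "t0") for i in range(n_reps)] + [
        ("r%d" % i, "t3") for i in range(n_reps)
    ]
    design = ReplicateDesign(
        units=[f"u{i}" for i in range(n_units)], samples=samples, count_matrix=k
    )
    return design, planted


class TestCallMethod:
    def test_planted_signal_recovered_at_controlled_fdr(self):
        rng = np.random.default_rng(10)
        design, planted = _nb_design(
            rng, 1000, alpha=0.2, fold=8.0, frac_planted=0.10
        )
        res = dc.call_method(design, fdr=0.10)
        truth = {u for u, flag in zip(design.units, planted) if flag}
        called = res.called
        recall = len(called & truth) / len(truth)
        fdr_obs = len(called - truth) / max(len(called), 1)
        assert recall >= 0.8
        assert fdr_obs <= 0.2

    def test_up_direction_filter_excludes_downregulated(self):
        rng = np.random.default_rng(11)
        design, planted = _nb_design(
            rng, 400, alpha=0.05, fold=1 / 8.0, frac_planted=0.10
        )
        res = dc.call_method(design, fdr=0.10)
        truth = {u for u, flag in zip(design.units, planted) if flag}
        assert not (res.called & truth)

    def test_q_values_never_below_p_values(self):
        rng = np.random.default_rng(12)
        design, _ = _nb_design(rng, 100, alpha=0.1)
        res = dc.call_method(design)
        assert np.all(
            res.results["q_value"].to_numpy() >= res.results["p_value"].to_numpy() - 1e-12
        )


class TestNullCalibration:
    def test_p_values_uniform_under_null(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        design, _ = _nb_design(rng, 2000, alpha=0.1)
        counts = design.count_matrix.astype(float)
        sf = dc.size_factors(counts)
        disp = dc.estimate_dispersion(counts / sf, design.stages,
                                      unit_ids=design.units)
        alpha = np.array([d.final_alpha for d in disp])
        _, p, _, _ = _wald_stage_matrix(counts, sf, design.stages, "t3", alpha)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05


class TestReplicateDesigns:
    def test_method_b_admits_only_complete_families(self, default_pipeline):
        res = default_pipeline
        design = dc.build_method_b_design(
            res.mcl.families, {sp: res.counts[sp] for sp in dc.SPECIES}
        )
        by_id = {f.family_id: f for f in res.mcl.families}
        for unit in design.units:
            assert by_id[unit].is_one_per_species()

    def test_species_as_replicates_needs_shared_regulation(self):
        # regulation planted in the DD replicate only: the cross-species
        # test must lose it, while the DD-only threshold view keeps it
        rng = np.random.default_rng(14)
        n_units, n_reps = 300, 4
        mu = np.tile(rng.uniform(100, 500, size=(n_units, 1)), (1, 2 * n_reps))
        planted = np.zeros(n_units, dtype=bool)
        planted[:30] = True
        mu_dd_only = mu.copy()
        mu_dd_only[planted, n_reps] *= 8.0  # DD is replicate 0 of stage t3
        mu_shared = mu.copy()
        mu_shared[planted, n_reps:] *= 8.0
        samples = [(sp, "t0") for sp in dc.SPECIES] + [(sp, "t3") for sp in dc.SPECIES]
        recalls = {}
        for name, m in (("dd_only", mu_dd_only), ("shared", mu_shared)):
            lam = rng.gamma(1 / 0.2, 0.2 * m)
            design = ReplicateDesign(
                units=[f"u{i}" for i in range(n_units)],
                samples=samples, count_matrix=rng.poisson(lam),
            )
            res = dc.call_method(design, fdr=0.10)
            truth = {f"u{i}" for i in range(30)}
            recalls[name] = len(res.called & truth) / 30
        assert recalls["shared"] >= 0.8
        assert recalls["dd_only"] < recalls["shared"]
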
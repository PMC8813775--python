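"""Trait model: FW linearity, effect calibration, covariates, phenotyping."""

import numpy as np
import pytest

from stagegate import (
    InsufficientVariationError,
    InvalidNoiseError,
    StageNoise,
    VarianceComponents,
    allele_effect,
    genetic_value,
    sample_architecture,
    sample_env_covariates,
)
from stagegate.traits import (
    TraitArchitecture,
    _expand_population,
    genetic_scores,
    export_architecture,
    import_architecture,
    phenotype,
)
from stagegate.founders import Individual
from stagegate.scheme import EvaluationDecisions, SelectionDecisions, StageDefinition


def make_stage(name, locs, reps):
    return StageDefinition(
        name=name,
        year=1,
        evaluation=EvaluationDecisions(n_locations=locs, reps_per_location=reps),
        selection=SelectionDecisions(n_entries_in=0, n_selected_out=0),
    )


class TestVarianceComponents:
    def test_interaction_is_always_the_sum(self):
        vc = VarianceComponents(var_G=1, var_GxY=2, var_GxL=1)
        assert vc.var_GxYxL == 3.0
        assert VarianceComponents(var_GxY=0.5, var_GxL=0.25).var_GxYxL == 0.75

    def test_nonpositive_main_variance_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(var_G=0.0)


class TestAlleleEffect:
    def test_hand_value_and_linearity(self):
        arch = TraitArchitecture(
            site_indices=np.array([0]),
            chromosomes=np.array([0]),
            b=np.array([0.5]),
            m=np.array([-0.2]),
            vc=VarianceComponents(),
        )
        assert allele_effect(arch, 0, 1.5) == pytest.approx(0.2)
        assert allele_effect(arch, 0, 0.0) == 0.5
        # linearity: equal increments of w give equal increments of effect
        a0, a1, a2 = (allele_effect(arch, 0, w) for w in (0.0, 0.7, 1.4))
        assert a2 - a1 == pytest.approx(a1 - a0)


class TestArchitecture:
    def test_qtn_count(self, small_founders, small_arch):
        founders, _ = small_founders
        assert small_arch.n_qtn == 30 * founders.genetic_map.n_chromosomes
        # QTN sites all exist and are segregating in the founders
        assert founders.segregating_mask()[small_arch.site_indices].all()

    def test_too_many_qtn_requested(self, small_founders):
        founders, _ = small_founders
        with pytest.raises(InsufficientVariationError):
            sample_architecture(founders, VarianceComponents(), 10_000,
                                np.random.default_rng(0))

    def test_csv_round_trip(self, small_arch, tmp_path):
        p = tmp_path / "arch.csv"
        export_architecture(small_arch, p)
        back = import_architecture(p, small_arch.vc)
        assert np.array_equal(back.site_indices, small_arch.site_indices)
        assert np.allclose(back.b, small_arch.b)
        assert np.allclose(back.m, small_arch.m)


class TestGeneticValue:
    def test_all_zero_dosage_is_zero(self, small_arch, small_founders):
        _, gmap = small_founders
        ind = Individual(id="z", haplotypes=np.zeros((2, gmap.n_sites), np.uint8))
        assert genetic_value(ind, small_arch, w=1.3) == 0.0

    def test_fw_regression_recovers_scores_exactly(self, small_founders, small_arch):
        """Regressing g(w) on w returns sum(x*m), sum(x*b) to machine precision."""
        founders, _ = small_founders
        ind = founders.individuals()[0]
        ws = np.linspace(-2, 2, 9)
        gs = np.array([genetic_value(ind, small_arch, w) for w in ws])
        slope, intercept = np.polyfit(ws, gs, 1)
        x = ind.dosage[small_arch.site_indices].astype(float)
        assert slope == pytest.approx(float(x @ small_arch.m), rel=1e-12, abs=1e-12)
        assert intercept == pytest.approx(float(x @ small_arch.b), rel=1e-12, abs=1e-12)

    def test_clones_identical_everywhere(self, small_founders, small_arch):
        founders, _ = small_founders
        ind = founders.individuals()[1]
        clone = Individual(id="c", haplotypes=ind.haplotypes.copy())
        for w in (-1.0, 0.0, 2.5):
            assert genetic_value(ind, small_arch, w) == genetic_value(clone, small_arch, w)

    def test_zero_slopes_remove_gxe(self, small_founders, small_arch):
        founders, _ = small_founders
        arch = TraitArchitecture(
            site_indices=small_arch.site_indices,
            chromosomes=small_arch.chromosomes,
            b=small_arch.b,
            m=np.zeros_like(small_arch.m),
            vc=small_arch.vc,
        )
        ind = founders.individuals()[2]
        vals = {genetic_value(ind, arch, w) for w in (-3.0, 0.0, 3.0)}
        assert len(vals) == 1


class TestCalibration:
    def test_scaling_is_exact_on_calibration_population(self, small_founders):
        """Rescaled effects give variance var_G on the population they
        were calibrated against — exact by construction."""
        founders, _ = small_founders
        rng = np.random.default_rng(17)
        vc = VarianceComponents(var_G=2.5)
        arch = sample_architecture(founders, vc, 30, rng, calibration_size=600)
        # replay the calibration draw: same rng stream position
        rng2 = np.random.default_rng(17)
        for c in range(founders.genetic_map.n_chromosomes):
            rng2.choice(int(founders.genetic_map.sites_per_chromosome[c]), size=30,
                        replace=False)
        rng2.standard_normal(arch.n_qtn)
        rng2.standard_normal(arch.n_qtn)
        pop = _expand_population(founders, 600, rng2)
        X = pop.sum(axis=1)[:, arch.site_indices].astype(float)
        g, s = genetic_scores(X, arch)
        assert np.var(g) == pytest.approx(2.5, rel=1e-9)
        assert np.var(s) == pytest.approx(1.0, rel=1e-9)

    def test_generalises_to_fresh_population(self, small_founders):
        """An independent expansion of the founders lands near the target.

        At this deliberately tiny scale (4 chromosomes, 30 QTN each, a
        single 8-haplotype founder base) linkage makes realised variance
        wobble between populations, so the bound is loose; the tight
        10% check runs at the full default scale elsewhere."""
        founders, _ = small_founders
        rng = np.random.default_rng(17)
        vc = VarianceComponents(var_G=1.0)
        arch = sample_architecture(founders, vc, 30, rng, calibration_size=600)
        fresh = _expand_population(founders, 1000, rng)
        X = fresh.sum(axis=1)[:, arch.site_indices].astype(float)
        g, s = genetic_scores(X, arch)
        assert np.var(g) == pytest.approx(1.0, rel=0.35)
        assert np.var(s) == pytest.approx(1.0, rel=0.35)


class TestEnvCovariates:
    def test_matrix_shape_and_decomposition(self, small_arch):
        rng = np.random.default_rng(3)
        env = sample_env_covariates(12, 4, small_arch.vc, small_arch, rng)
        assert env.w.shape == (12, 4)
        assert np.allclose(env.w, env.u[:, None] + env.v)

    def test_zero_variance_gives_zero_covariates(self, small_arch):
        vc = VarianceComponents(var_G=1.0, var_GxY=0.0, var_GxL=0.0)
        env = sample_env_covariates(5, 3, vc, small_arch, np.random.default_rng(0))
        assert np.all(env.w == 0)


class TestStageNoise:
    def test_error_variance_closed_form(self):
        vc = VarianceComponents(var_G=1.0, var_GxY=2.0, var_GxL=1.0)
        noise = StageNoise(h2={"CE": 0.2})
        assert noise.var_e("CE", vc) == pytest.approx(16.0)

    def test_h2_of_one_means_no_error(self):
        vc = VarianceComponents(var_G=1.0, var_GxY=0.0, var_GxL=0.0)
        noise = StageNoise(h2={"AYT": 1.0})
        assert noise.var_e("AYT", vc) == 0.0

    def test_degenerate_h2_rejected(self):
        noise = StageNoise(h2={"CE": 0.0})
        with pytest.raises(InvalidNoiseError):
            noise.var_e("CE", VarianceComponents())

    def test_unknown_stage_rejected(self):
        with pytest.raises(InvalidNoiseError):
            StageNoise().var_e("nowhere", VarianceComponents())


class TestPhenotype:
    def test_perfect_heritability_no_gxe_reproduces_genetic_values(
        self, small_founders
    ):
        founders, _ = small_founders
        vc = VarianceComponents(var_G=1.0, var_GxY=0.0, var_GxL=0.0)
        rng = np.random.default_rng(23)
        arch = sample_architecture(founders, vc, 30, rng)
        env = sample_env_covariates(3, 2, vc, arch, rng)
        cohort = founders.individuals()
        stage = make_stage("AYT", locs=2, reps=3)
        noise = StageNoise(h2={"AYT": 1.0})
        _, means = phenotype(cohort, stage, env, noise, 0, rng, arch=arch)
        truth = [genetic_value(ind, arch, 0.0) for ind in cohort]
        assert np.allclose(means, truth)
        assert cohort[0].entry_mean("AYT") == pytest.approx(truth[0])

    def test_plot_record_shape(self, small_founders, small_arch):
        founders, _ = small_founders
        rng = np.random.default_rng(29)
        env = sample_env_covariates(2, 2, small_arch.vc, small_arch, rng)
        cohort = founders.individuals()
        stage = make_stage("PYT", locs=2, reps=2)
        records, means = phenotype(
            cohort, stage, env, StageNoise(), 1, rng, arch=small_arch
        )
        assert len(records) == 4 * 2 * 2
        assert len(means) == 4
        by_entry = records.groupby("entry")["value"].mean()
        assert np.allclose(sorted(by_entry), sorted(means))

    def test_entry_mean_error_shrinks_with_replication(self, small_founders):
        """Entry-mean regression on truth approaches slope 1 as plots grow.

        In the no-GxE limit the entry mean is the genetic value plus an
        error with variance var_e / (locations x reps), so the slope of
        truth on entry means rises toward 1 as replication increases.
        """
        founders, gmap = small_founders
        vc = VarianceComponents(var_G=1.0, var_GxY=0.0, var_GxL=0.0)
        rng = np.random.default_rng(31)
        arch = sample_architecture(founders, vc, 30, rng)
        pop = _expand_population(founders, 400, rng)
        cohort = [
            Individual(id=f"i{k}", haplotypes=pop[k]) for k in range(400)
        ]
        env = sample_env_covariates(1, 8, vc, arch, rng)
        truth = np.array([genetic_value(i, arch, 0.0) for i in cohort])
        noise = StageNoise(h2={"T": 0.25})

        slopes = []
        for locs, reps in [(1, 1), (8, 8)]:
            stage = make_stage("T", locs, reps)
            _, means = phenotype(cohort, stage, env, noise, 0, rng, arch=arch,
                                 record=False)
            slopes.append(np.polyfit(means, truth, 1)[0])
        # theoretical attenuation: var_g / (var_g + var_e / n_plots)
        assert slopes[1] > slopes[0]
        assert slopes[1] == pytest.approx(1.0, abs=0.1)

    def test_covariate_matrix_must_cover_request(self, small_founders, small_arch):
        founders, _ = small_founders
        rng = np.random.default_rng(7)
        env = sample_env_covariates(2, 1, small_arch.vc, small_arch, rng)
        stage = make_stage("PYT", locs=2, reps=1)
        with pytest.raises(ValueError, match="does not cover"):
            phenotype(founders.individuals(), stage, env, StageNoise(), 0, rng,
                      arch=small_arch)
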
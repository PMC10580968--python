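import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from microassembly import assembly, synth
from microassembly.assembly import (community_similarity, distance_decay_fit,
                                    fit_ncm, haversine_km, ncm_predicted_freq)

from conftest import make_table


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km((21.0, 110.0), (21.0, 110.0)) == 0.0

    def test_quarter_great_circle(self):
        # equator to 90 degrees east: pi * R / 2
        assert haversine_km((0, 0), (0, 90)) == pytest.approx(
            np.pi * 6371.0 / 2, abs=0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((91, 0), (0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
                    min_size=3, max_size=3))
    def test_metric_properties(self, pts):
        a, b, c = pts
        dab, dba = haversine_km(a, b), haversine_km(b, a)
        assert dab == pytest.approx(dba, abs=1e-9)
        assert (haversine_km(a, c)
                <= dab + haversine_km(b, c) + 1e-6)


class TestCommunitySimilarity:
    def test_identical_samples_similarity_one(self):
        sim = community_similarity(make_table([[5, 5, 5], [5, 5, 5]]))
        assert sim.iloc[0, 1] == pytest.approx(1.0)

    def test_disjoint_samples_similarity_zero(self):
        sim = community_similarity(make_table([[5, 0], [0, 7]]))
        assert sim.iloc[0, 1] == pytest.approx(0.0)

    def test_hand_computed_bray_curtis(self):
        # (10,0,5) vs (0,10,5): 1 - 20/30 = 1/3
        sim = community_similarity(make_table([[10, 0, 5], [0, 10, 5]]))
        assert sim.iloc[0, 1] == pytest.approx(1.0 / 3.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        sim = community_similarity(make_table(rng.integers(1, 50, (5, 8))))
        np.testing.assert_allclose(sim, sim.T)
        np.testing.assert_allclose(np.diag(sim), 1.0)


def _gradient_dataset(seed, n_samples=60, strength=2e-3):
    spec = synth.NeutralSimSpec(n_taxa=300, n_samples=n_samples, depth=2000,
                                Nm=2000, seed=seed)
    table = synth.simulate_neutral_table(spec)
    meta = synth.coastline_metadata(n_samples, seed=seed)
    table = synth.plant_gradient(table, meta, strength, seed=seed + 10)
    return (community_similarity(table),
            assembly.geographic_distance_matrix(meta))


class TestDistanceDecay:
    def test_degenerate_identical_communities(self):
        t = make_table(np.tile([5, 3, 2], (4, 1)))
        sim = community_similarity(t)
        dist = pd.DataFrame(np.arange(16).reshape(4, 4) * 1.0,
                            index=sim.index, columns=sim.index)
        fit = distance_decay_fit(sim, dist, n_perm=19)
        assert fit.degenerate
        assert fit.slope == 0.0 and fit.r == 0.0

    def test_planted_gradient_negative_slope(self):
        sim, dist = _gradient_dataset(seed=0)
        fit = distance_decay_fit(sim, dist, n_perm=199, seed=0)
        assert fit.slope < 0
        assert fit.p_ols < 0.05 and fit.p_mantel < 0.05

    def test_permutation_destroys_signal(self, rng):
        sim, dist = _gradient_dataset(seed=1)
        fit = distance_decay_fit(sim, dist, n_perm=99, seed=1)
        n = sim.shape[0]
        perm_slopes = []
        for _ in range(30):
            perm = rng.permutation(n)
            sim_p = pd.DataFrame(sim.to_numpy()[np.ix_(perm, perm)],
                                 index=sim.index, columns=sim.columns)
            perm_slopes.append(abs(
                distance_decay_fit(sim_p, dist, n_perm=0, seed=0).slope))
        assert np.mean(perm_slopes) < abs(fit.slope)

    def test_similarity_vs_dissimilarity_slope_sign(self):
        sim, dist = _gradient_dataset(seed=2)
        fit_s = distance_decay_fit(sim, dist, n_perm=0)
        fit_d = distance_decay_fit(1.0 - sim, dist, n_perm=0)
        # note 1-sim flips the intercept too; only the slope mirrors
        assert fit_d.slope == pytest.approx(-fit_s.slope, rel=1e-9)


class TestNCMPredictedFreq:
    def test_closed_form_beta_1_b(self):
        # Nm*p = 1: F = (1-d)^(Nm(1-p))
        assert ncm_predicted_freq(0.01, 100, 1e-4) == pytest.approx(
            0.990149, abs=1e-6)

    def test_matches_numeric_integration(self):
        # independent oracle: quadrature of the beta density on (d, 1)
        grid_p = np.linspace(0.001, 0.2, 10)
        grid_nm = [10, 100, 1000]
        for nm in grid_nm:
            for p in grid_p:
                a, b = nm * p, nm * (1 - p)
                val, _ = integrate.quad(
                    lambda x: stats.beta.pdf(x, a, b), 1e-4, 1.0)
                assert ncm_predicted_freq(p, nm, 1e-4) == pytest.approx(
                    val, abs=1e-8)

    def test_monotone_in_p(self):
        p = np.linspace(1e-4, 0.5, 200)
        f = ncm_predicted_freq(p, 500, 1e-4)
        assert (np.diff(f) >= -1e-12).all()

    def test_limits(self):
        assert ncm_predicted_freq(0.2, 1e9, 1e-4) == pytest.approx(1.0)
        assert ncm_predicted_freq(0.0, 100, 1e-4) == 0.0


class TestFitNCM:
    def test_parameter_recovery_single_seed(self):
        spec = synth.NeutralSimSpec(n_taxa=500, n_samples=200, depth=10_000,
                                    Nm=1000, seed=0)
        fit = fit_ncm(synth.simulate_neutral_table(spec))
        assert fit.Nm == pytest.approx(1000, rel=0.2)
        assert fit.R2 >= 0.8
        assert fit.m == pytest.approx(fit.Nm / 10_000)

    def test_invariant_to_ordering(self, rng):
        spec = synth.NeutralSimSpec(n_taxa=80, n_samples=60, depth=2000,
                                    Nm=500, seed=3)
        table = synth.simulate_neutral_table(spec)
        fit1 = fit_ncm(table)
        shuffled = table.counts.sample(frac=1, axis=0, random_state=1)\
                               .sample(frac=1, axis=1, random_state=2)
        fit2 = fit_ncm(make_table(shuffled.to_numpy(),
                                  sample_ids=list(shuffled.index),
                                  otu_ids=list(shuffled.columns)))
        assert fit1.Nm == pytest.approx(fit2.Nm, rel=1e-6)
        assert fit1.R2 == pytest.approx(fit2.R2, rel=1e-6)

    def test_shuffling_within_otus_leaves_fit_unchanged(self, rng):
        spec = synth.NeutralSimSpec(n_taxa=80, n_samples=60, depth=2000,
                                    Nm=500, seed=4)
        table = synth.simulate_neutral_table(spec)
        counts = table.counts.to_numpy().copy()
        for j in range(counts.shape[1]):
            counts[:, j] = counts[rng.permutation(counts.shape[0]), j]
        d = np.log(2) / 2000  # fix d so only (p_mean, F_obs) matter
        fit1, fit2 = fit_ncm(table, d=d), fit_ncm(make_table(counts), d=d)
        assert fit1.Nm == pytest.approx(fit2.Nm, rel=1e-6)

    def test_specialist_table_fits_badly(self, rng):
        # taxa confined to single habitats: occupancy is flat in abundance
        n_samples, n_taxa = 60, 100
        hab = np.repeat(np.arange(5), 12)
        counts = np.zeros((n_samples, n_taxa), int)
        for j in range(n_taxa):
            idx = np.where(hab == j % 5)[0]
            counts[idx, j] = rng.integers(50, 200, size=len(idx))
        fit = fit_ncm(make_table(counts))
        assert fit.R2 < 0.1

    def test_ci_envelope_brackets_prediction(self):
        spec = synth.NeutralSimSpec(n_taxa=100, n_samples=50, depth=2000,
                                    Nm=500, seed=5)
        fit = fit_ncm(synth.simulate_neutral_table(spec))
        assert (fit.per_otu.CI_lo <= fit.per_otu.F_pred + 1e-12).all()
        assert (fit.per_otu.F_pred <= fit.per_otu.CI_hi + 1e-12).all()
        assert fit.n_above + fit.n_within + fit.n_below == len(fit.per_otu)
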
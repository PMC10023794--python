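"""Synthetic cohort generator: determinism, state mixture, planted links."""

import numpy as np
import pytest

from nspnet import (
    GeneSpec,
    ScoreLink,
    SimulationSpec,
    pearson_fc,
    si_components,
    simulate_cohort,
    simulate_expression,
    simulate_scores,
    static_regional_features,
)


class TestSimulateCohort:
    def test_bit_identical_under_same_seed(self):
        spec = SimulationSpec(n_regions=14, n_subjects_per_group=3,
                              n_frames=40, seed=5)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for g in a.series:
            for ta, tb in zip(a.series[g], b.series[g]):
                assert np.array_equal(ta.values, tb.values)
        assert all(
            ra.fd == rb.fd and ra.age == rb.age
            for ra, rb in zip(a.records, b.records)
        )

    def test_different_seed_differs(self):
        s1 = SimulationSpec(n_regions=14, n_subjects_per_group=2,
                            n_frames=40, seed=1)
        s2 = SimulationSpec(n_regions=14, n_subjects_per_group=2,
                            n_frames=40, seed=2)
        a, b = simulate_cohort(s1), simulate_cohort(s2)
        assert not np.array_equal(
            a.series["HC"][0].values, b.series["HC"][0].values
        )

    def test_non_psd_covariance_rejected_naming_parameter(self):
        with pytest.raises(ValueError, match="within_block_corr"):
            SimulationSpec(
                n_regions=30, n_systems=3, n_subjects_per_group=2,
                within_block_corr=0.0, between_block_corr=0.9,
            )

    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError, match="dwell"):
            SimulationSpec(dwell_integrated={"HC": 1.2, "SCH": 0.3})

    def test_system_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationSpec(n_regions=20, n_systems=2, system_sizes=(5, 5))

    def test_always_integrated_matches_uniform_closed_form(self):
        """dwell = 1 for both groups: static FC is a noisy uniform-c matrix,
        so H_In approaches (1+(N-1)c)^2/N^2 and H_Se its complement value."""
        n, c = 12, 0.6
        spec = SimulationSpec(
            n_regions=n, n_systems=3, n_subjects_per_group=2, n_frames=3000,
            dwell_integrated={"HC": 1.0, "SCH": 1.0}, integrated_corr=c, seed=9,
        )
        cohort = simulate_cohort(spec)
        prof = si_components(pearson_fc(cohort.series["HC"][0]))
        expected = (1 + (n - 1) * c) ** 2 / n**2
        assert prof.h_in == pytest.approx(expected, rel=0.05)

    def test_planted_dwell_difference_orders_group_means(self):
        """Lower integrated dwell in the patient-like group lowers H_In and
        raises H_Se for nearly every seed."""
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            spec = SimulationSpec(
                n_regions=21, n_systems=7, n_subjects_per_group=6,
                n_frames=100, seed=seed,
            )
            cohort = simulate_cohort(spec)
            means = {}
            for g in ("HC", "SCH"):
                profs = [
                    si_components(pearson_fc(ts)) for ts in cohort.series[g]
                ]
                means[g] = (
                    np.mean([p.h_in for p in profs]),
                    np.mean([p.h_se for p in profs]),
                )
            if means["HC"][0] > means["SCH"][0] and means["HC"][1] < means["SCH"][1]:
                wins += 1
        assert wins >= n_seeds - 1

    def test_empirical_covariance_converges_to_mixture(self):
        """Frobenius distance to the dwell-weighted state mixture shrinks
        as the record lengthens."""
        dists = {}
        for frames in (150, 3000):
            spec = SimulationSpec(
                n_regions=12, n_systems=3, n_subjects_per_group=1,
                n_frames=frames, dwell_integrated={"HC": 0.5, "SCH": 0.5},
                seed=3,
            )
            cohort = simulate_cohort(spec)
            x = cohort.series["HC"][0].values
            emp = np.cov(x, rowvar=False)
            target = 0.5 * spec.integrated_cov() + 0.5 * spec.segregated_cov()
            dists[frames] = np.linalg.norm(emp - target)
        assert dists[3000] < dists[150] / 2

    def test_patient_system_override_boosts_one_system(self):
        spec = SimulationSpec(
            n_regions=21, n_systems=7, n_subjects_per_group=2,
            patient_system_corr={"LIM": 0.9},
        )
        seg_hc = spec.segregated_cov()
        seg_sch = spec.segregated_cov(patient=True)
        lim = spec.atlas().indices("LIM")
        off = ~np.eye(21, dtype=bool)
        block = np.ix_(lim, lim)
        assert np.all(seg_sch[block][~np.eye(3, dtype=bool)] == 0.9)
        outside = seg_sch.copy()
        outside[block] = seg_hc[block]
        assert np.array_equal(outside[off], seg_hc[off])


class TestSimulateScores:
    def _cohort(self, seed=11, link=None):
        spec = SimulationSpec(
            n_regions=14, n_systems=7, n_subjects_per_group=10,
            n_frames=60, seed=seed, score_link=link or (),
        )
        return simulate_cohort(spec)

    def test_noiseless_link_near_perfect_correlation(self):
        link = (ScoreLink("saps.hallucinations", "H_In", (0, 1), slope=25.0,
                          noise_sd=0.0, baseline=40.0),)
        cohort = simulate_scores(self._cohort(link=link))
        feats = static_regional_features(cohort, "SCH", "H_In")[:, [0, 1]].mean(axis=1)
        scores = np.array([r.saps["hallucinations"] for r in cohort.records_of("SCH")])
        r = np.corrcoef(feats, scores)[0, 1]
        assert r > 0.99  # only integer rounding separates it from 1

    def test_scores_nonnegative_integers_and_totals(self):
        cohort = simulate_scores(self._cohort())
        for rec in cohort.records_of("SCH"):
            vals = list(rec.sans.values()) + list(rec.saps.values())
            assert all(v >= 0 and float(v).is_integer() for v in vals)
            assert rec.sans_total == sum(rec.sans.values())

    def test_controls_have_no_scores(self):
        cohort = simulate_scores(self._cohort())
        assert all(r.sans is None for r in cohort.records_of("HC"))

    def test_region_outside_atlas_rejected(self):
        link = (ScoreLink("sans.avolition", "H_Se", (99,), slope=1.0),)
        with pytest.raises(ValueError, match="region"):
            simulate_scores(self._cohort(link=link))


class TestSimulateExpression:
    def _cohort(self):
        spec = SimulationSpec(
            n_regions=30, n_systems=3, n_subjects_per_group=2, n_frames=40,
            gene_spec=GeneSpec(n_genes=200, n_planted=10, planted_noise_sd=0.0),
            seed=13,
        )
        return simulate_cohort(spec)

    def test_zero_noise_planted_genes_perfectly_correlated(self, rng):
        cohort = self._cohort()
        eff = rng.standard_normal(30)
        cohort = simulate_expression(cohort, effect_vector=eff)
        for g in cohort.ground_truth["planted_genes"]:
            r = np.corrcoef(cohort.expression[g], eff)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-10)

    def test_ledger_records_planted_identities(self, rng):
        cohort = simulate_expression(self._cohort(), rng.standard_normal(30))
        assert len(cohort.ground_truth["planted_genes"]) == 10
        assert cohort.expression.shape == (30, 200)

    def test_too_many_planted_rejected(self):
        with pytest.raises(ValueError, match="n_planted"):
            SimulationSpec(gene_spec=GeneSpec(n_genes=10, n_planted=11))

    def test_effect_vector_length_checked(self, rng):
        with pytest.raises(ValueError, match="length"):
            simulate_expression(self._cohort(), rng.standard_normal(29))
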
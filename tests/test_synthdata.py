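"""Synthetic-study generator: covariance construction, condition effects,
time-series sampling and study assembly."""

import numpy as np
import pytest

from sedanet.graphs import correlation_matrix
from sedanet.hubs import hub_disruption, strength_table
from sedanet.synthdata import (
    apply_condition_effect,
    attenuate_club,
    generate_covariance,
    generate_study,
    generate_timeseries,
    nearest_psd_correlation,
    power_like_parcellation,
    write_study,
)


class TestGenerateCovariance:
    def test_exact_two_block_construction(self):
        m = generate_covariance(6, (3, 3), 0.6, 0.0)
        expected = np.full((6, 6), 0.0)
        expected[:3, :3] = 0.6
        expected[3:, 3:] = 0.6
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(m.cov, expected, atol=1e-12)
        np.testing.assert_array_equal(m.partition, [0, 0, 0, 1, 1, 1])

    def test_zero_correlations_give_identity(self):
        m = generate_covariance(8, (4, 4), 0.0, 0.0)
        np.testing.assert_allclose(m.cov, np.eye(8), atol=1e-12)

    def test_psd_after_repair(self, block_model_40):
        assert np.linalg.eigvalsh(block_model_40.cov).min() >= -1e-10
        np.testing.assert_allclose(np.diag(block_model_40.cov), 1.0, atol=1e-12)

    def test_hub_designation_top_decile_per_block(self, block_model_40):
        # 10-node blocks: ceil(1) = 1 hub each, the last node of the block
        np.testing.assert_array_equal(block_model_40.hub_nodes, [9, 19, 29, 39])

    def test_hub_hub_entries_boosted_twice(self):
        m = generate_covariance(40, (10, 10, 10, 10), 0.5, 0.1, hub_boost=0.2)
        # hub (9) to off-block non-hub: 0.1 + 0.2; hub to off-block hub: 0.1 + 0.4
        assert m.cov[9, 10] == pytest.approx(0.3, abs=1e-12)
        assert m.cov[9, 19] == pytest.approx(0.5, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_covariance(6, (3, 3), 0.2, 0.5)  # between > within
        with pytest.raises(ValueError):
            generate_covariance(6, (3, 2), 0.5, 0.1)  # sizes do not sum


class TestNearestPsd:
    def test_repairs_indefinite_matrix(self):
        a = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        out = nearest_psd_correlation(a)
        assert np.linalg.eigvalsh(out).min() >= -1e-12
        np.testing.assert_allclose(np.diag(out), 1.0)

    def test_psd_input_returned_exactly(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(nearest_psd_correlation(a), a)


class TestConditionEffect:
    def test_zero_kappa_keeps_strengths(self, block_model_40):
        out = apply_condition_effect(block_model_40, 0.0)
        np.testing.assert_allclose(
            out.strengths(), block_model_40.strengths(), atol=1e-6
        )

    def test_planted_slope_recovered(self, block_model_40):
        out = apply_condition_effect(block_model_40, -0.3)
        assert -0.35 <= out.achieved_kappa <= -0.25
        s0, s1 = block_model_40.strengths(), out.strengths()
        dx = s0 - s0.mean()
        slope = dx @ (s1 - s0) / (dx @ dx)
        assert -0.35 <= slope <= -0.25

    def test_double_application_is_more_negative(self, block_model_40):
        once = apply_condition_effect(block_model_40, -0.3)
        twice = apply_condition_effect(once, -0.3)
        s0 = block_model_40.strengths()
        dx = s0 - s0.mean()
        slope_once = dx @ (once.strengths() - s0) / (dx @ dx)
        slope_twice = dx @ (twice.strengths() - s0) / (dx @ dx)
        assert slope_twice < slope_once

    def test_kappa_bound_enforced(self, block_model_40):
        with pytest.raises(ValueError):
            apply_condition_effect(block_model_40, -1.0)


class TestAttenuateClub:
    def test_hub_pair_entries_reduced(self, block_model_40):
        out = attenuate_club(block_model_40, 0.3)
        h = block_model_40.hub_nodes
        orig = block_model_40.cov[h[0], h[1]]
        assert out.cov[h[0], h[1]] <= orig
        assert np.linalg.eigvalsh(out.cov).min() >= -1e-10


class TestGenerateTimeseries:
    def test_identity_covariance_off_diagonals_small(self):
        m = generate_covariance(20, (10, 10), 0.0, 0.0)
        panel = generate_timeseries(m, 2000, seed=0)
        r = np.corrcoef(panel.signals)
        off = r[np.triu_indices(20, 1)]
        # Fisher-z bound: |r| < 3/sqrt(T) for ~99% of entries
        assert np.mean(np.abs(off) < 3 / np.sqrt(2000)) >= 0.95

    def test_duplicated_node_perfectly_correlated(self):
        cov = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        m_cov = nearest_psd_correlation(cov)
        from sedanet.synthdata import CovarianceModel

        m = CovarianceModel(
            cov=m_cov, partition=np.zeros(3, dtype=int), hub_nodes=np.array([]),
            r_within=0.2, r_between=0.0,
        )
        panel = generate_timeseries(m, 200, seed=1)
        r = np.corrcoef(panel.signals)
        assert r[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_per_seed(self, block_model_40):
        a = generate_timeseries(block_model_40, 100, seed=5)
        b = generate_timeseries(block_model_40, 100, seed=5)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_mean_sample_correlation_converges(self, block_model_40):
        acc = np.zeros((40, 40))
        n_rep = 50
        for seed in range(n_rep):
            panel = generate_timeseries(block_model_40, 500, seed=seed)
            acc += np.corrcoef(panel.signals)
        err = np.abs(acc / n_rep - block_model_40.cov)
        assert err.max() < 0.05


class TestGenerateStudy:
    def _models(self, n=16):
        base = generate_covariance(n, (n // 2, n // 2), 0.5, 0.1, hub_boost=0.3)
        return [base, base, apply_condition_effect(base, -0.2)]

    def test_structure_and_determinism(self):
        models = self._models()
        a = generate_study(5, ["B", "L", "M"], models, 40, -0.5, seed=3)
        b = generate_study(5, ["B", "L", "M"], models, 40, -0.5, seed=3)
        assert set(a.panels) == {
            (s, c) for s in a.design.subjects for c in ["B", "L", "M"]
        }
        for key in a.panels:
            np.testing.assert_array_equal(a.panels[key].signals, b.panels[key].signals)
        assert a.design.to_frame().equals(b.design.to_frame())

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            generate_study(2, ["B", "L", "M"], self._models(), 40, 0.0, seed=0)

    def test_perfect_negative_target_is_deterministic_map(self):
        models = self._models()
        study = generate_study(
            12, ["B", "L", "M"], models, 40, -1.0, seed=9, delta_error_sd=6.0,
            base_error_mean=20.0,
        )
        z = np.array(study.ground_truth["club_change_z"])
        de = np.array(study.ground_truth["delta_errors"])
        r = np.corrcoef(z, de)[0, 1]
        assert r == pytest.approx(-1.0, abs=0.03)  # exact up to integer rounding

    def test_null_behaviour_target_unbiased(self):
        """behaviour_target_r = 0: mean observed correlation over replicate
        studies sits in [-0.07, 0.07]."""
        models = self._models()
        rs = []
        for seed in range(200):
            study = generate_study(19, ["B", "L", "M"], models, 8, 0.0, seed=seed)
            z = np.array(study.ground_truth["club_change_z"])
            de = (study.design.errors["M"] - study.design.errors["L"]).to_numpy()
            if de.std() > 0:
                rs.append(np.corrcoef(z, de)[0, 1])
        assert abs(np.mean(rs)) <= 0.07

    def test_target_r_within_fisher_band(self):
        """behaviour_target_r = -0.7 at n = 19: the observed correlation lands
        inside the 95% Fisher-z sampling band in >= 93% of replicates."""
        models = self._models()
        lo = np.tanh(np.arctanh(-0.7) - 1.96 / 4)
        hi = np.tanh(np.arctanh(-0.7) + 1.96 / 4)
        inside = 0
        n_rep = 200
        for seed in range(n_rep):
            study = generate_study(19, ["B", "L", "M"], models, 8, -0.7, seed=seed)
            z = np.array(study.ground_truth["club_change_z"])
            de = (study.design.errors["M"] - study.design.errors["L"]).to_numpy()
            r = np.corrcoef(z, de)[0, 1]
            if lo <= r <= hi:
                inside += 1
        assert inside / n_rep >= 0.93

    def test_plasma_levels_ordered_and_nonnegative(self):
        study = generate_study(6, ["B", "L", "M"], self._models(), 40, 0.0, seed=2)
        p = study.design.plasma
        assert (p["B"] == 0).all()
        assert (p["L"] > 0).all() and (p["M"] > p["L"]).all()


@pytest.mark.parametrize("planted", [-0.4, -0.2, 0.0])
def test_kappa_plumbing_group_recovery(planted):
    """Planted condition-effect slopes are recovered by the downstream hub
    disruption index within +-0.07 at group level (19 subjects, T = 300)."""
    base = generate_covariance(60, (15, 15, 15, 15), 0.5, 0.1, hub_boost=0.25)
    mod = apply_condition_effect(base, planted) if planted != 0 else base
    study = generate_study(19, ["B", "L"], [base, mod], 300, 0.0, seed=21)
    mats = {k: correlation_matrix(p) for k, p in study.panels.items()}
    g = hub_disruption(strength_table(mats), "B", "L", level="group")
    assert g.kappa == pytest.approx(planted, abs=0.07)


class TestParcellation:
    def test_roi_bookkeeping(self):
        tab = power_like_parcellation()
        assert len(tab) == 258  # 264 - 6 removed
        assert tab["network"].nunique() == 14


class TestStudyIO:
    def test_write_study_round_trip(self, tmp_path):
        base = generate_covariance(10, (5, 5), 0.5, 0.1)
        study = generate_study(3, ["B", "L"], [base, base], 20, 0.0, seed=0)
        write_study(study, tmp_path)
        from sedanet.pipeline import RunConfig, load_study

        cfg = RunConfig(mode="load", in_dir=str(tmp_path))
        panels, design = load_study(cfg)
        assert set(panels) == set(study.panels)
        for key in panels:
            np.testing.assert_allclose(
                panels[key].signals, study.panels[key].signals, atol=1e-12
            )
        assert design.to_frame().equals(study.design.to_frame())
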
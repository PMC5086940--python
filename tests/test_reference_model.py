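import warnings

import numpy as np
import pandas as pd
import pytest

from rawkit.errors import ConfigurationError, ValidationError
from rawkit.probe_data_io import ProbeAnnotation
from rawkit.reference_model import (
    MdsModel,
    RefConfig,
    build_reference,
    fit_mds,
    fit_probe_functions,
    fit_snp_clusters,
    load_reference,
    models_equal,
    save_reference,
)


def flat_annotation(n, snp=True):
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chromosome": "1",
        "position": np.arange(1, n + 1) * 10,
        "probe_class": "SNP" if snp else "NONSNP",
        "gc_content": 0.5,
        "fragment_length": 500,
    }))


class TestProbeFunctions:
    def test_recovers_known_coefficients(self, rng):
        m, p = 24, 300
        mh = rng.normal(9.0, 0.5, m)
        rm = rng.uniform(0.2, 0.5, m)
        y = 0.5 * mh[:, None] + np.zeros((m, p))
        funcs = fit_probe_functions(y, mh, rm, flat_annotation(p))
        # ordinary least squares oracle on one probe
        beta = np.linalg.lstsq(np.column_stack([np.ones(m), mh, rm]), y[:, 0], rcond=None)[0]
        assert beta[1] == pytest.approx(0.5, abs=1e-8)
        np.testing.assert_allclose(funcs.coef_median_hyb, 0.5, atol=1e-6)
        np.testing.assert_allclose(funcs.coef_raw_mapd, 0.0, atol=1e-6)

    def test_identical_samples_fall_back_to_location(self, rng):
        m, p = 12, 50
        mh = np.full(m, 9.0)
        rm = np.full(m, 0.3)
        y = np.tile(rng.normal(0, 1, p), (m, 1))
        with pytest.warns(UserWarning, match="degenerate predictor"):
            funcs = fit_probe_functions(y, mh, rm, flat_annotation(p))
        np.testing.assert_allclose(funcs.intercept, y[0], atol=1e-12)
        np.testing.assert_allclose(funcs.coef_median_hyb, 0.0)

    def test_outlier_resistance_beats_plain_least_squares(self, rng):
        m, p = 20, 200
        mh = rng.normal(9.0, 0.4, m)
        rm = rng.uniform(0.2, 0.5, m)
        y = mh[:, None] + rng.normal(0, 0.05, (m, p))
        # one sample carries a large deviation (simulated CNV) at every probe
        y[3] += 2.0
        funcs = fit_probe_functions(y, mh, rm, flat_annotation(p))
        clean_oracle = np.median(np.delete(y - mh[:, None], 3, axis=0), axis=0)
        fitted_at_centroid = funcs.evaluate(mh.mean(), rm.mean()) - mh.mean()
        robust_err = np.abs(fitted_at_centroid - clean_oracle)
        x = np.column_stack([np.ones(m), mh, rm])
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        ols_at_centroid = np.array([1, mh.mean(), rm.mean()]) @ ols - mh.mean()
        ols_err = np.abs(ols_at_centroid - clean_oracle)
        assert np.median(robust_err) < 0.02
        assert np.median(robust_err) < 0.5 * np.median(ols_err)

    def test_breakdown_bound_under_20pct_contamination(self, rng):
        m, p = 20, 100
        mh = rng.normal(9.0, 0.4, m)
        rm = rng.uniform(0.2, 0.5, m)
        amplitude = 1.0
        y = rng.normal(0, 0.05, (m, p))
        y[:4] += amplitude  # 20% of samples deviated
        funcs = fit_probe_functions(y, mh, rm, flat_annotation(p))
        shift = np.abs(funcs.evaluate(mh.mean(), rm.mean()))
        assert np.all(shift < amplitude / 2)

    def test_small_panel_rejected(self, rng):
        m, p = 5, 10
        y = rng.normal(0, 1, (m, p))
        with pytest.raises(ConfigurationError, match="panel"):
            fit_probe_functions(y, np.ones(m), np.ones(m), flat_annotation(p))

    def test_x_chromosome_needs_enough_females(self, rng):
        n = 20
        ann = ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chromosome": ["1"] * 10 + ["X"] * 10,
            "position": list(range(1, 11)) * 2,
            "probe_class": "SNP",
            "gc_content": 0.5,
            "fragment_length": 500,
        }))
        m = 12
        y = rng.normal(0, 1, (m, n))
        sexes = ["M"] * 10 + ["F"] * 2
        with pytest.raises(ConfigurationError, match="female"):
            fit_probe_functions(y, rng.normal(9, 0.5, m), rng.uniform(0.2, 0.4, m),
                                ann, sexes)


class TestMds:
    def test_rank_one_structure_recovered(self, rng):
        m, p = 16, 2000
        s_true = rng.normal(0, 1, m)
        w = rng.normal(0, 1, p)
        x = np.outer(s_true, w) * 0.1 + rng.normal(0, 0.1, (m, p))
        model = fit_mds(x, rng.uniform(0.2, 0.4, m), n_components=6)
        r = np.corrcoef(model.scores[:, 0], s_true)[0, 1]
        assert abs(r) > 0.95

    def test_pure_noise_loadings_are_small(self, rng):
        m, p = 16, 2000
        sigma = 0.1
        x = rng.normal(0, sigma, (m, p))
        model = fit_mds(x, rng.uniform(0.2, 0.4, m), n_components=6)
        # Monte-Carlo oracle for the per-probe regression noise scale:
        # slope sd ~ sigma / ||scores|| for random scores of the fitted norm
        contributions = np.abs(model.scores).max(axis=0)
        # a noise component explains only noise: its per-sample contribution
        # must stay well below the noise scale itself
        assert np.all(contributions < 3 * sigma)

    def test_duplicating_samples_keeps_geometry(self, rng):
        m, p = 10, 800
        x = np.outer(rng.normal(0, 1, m), rng.normal(0, 1, p)) * 0.1
        x += rng.normal(0, 0.02, (m, p))
        rm = rng.uniform(0.2, 0.4, m)
        m1 = fit_mds(x, rm, n_components=3)
        m2 = fit_mds(np.vstack([x, x]), np.concatenate([rm, rm]), n_components=3)
        r = np.corrcoef(m1.scores[:, 0], m2.scores[:m, 0])[0, 1]
        assert abs(r) > 0.999

    def test_scores_are_centered(self, rng):
        x = rng.normal(0, 0.1, (12, 500))
        model = fit_mds(x, rng.uniform(0.2, 0.4, 12), n_components=4)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_mds(rng.normal(0, 1, (6, 100)), rng.uniform(0, 1, 6), n_components=6)


class TestSnpClusters:
    def panel_baf(self, rng, m, centers, freqs, spread=0.01):
        g = rng.choice(3, size=m, p=freqs)
        baf = np.array(centers)[g] + rng.normal(0, spread, m)
        return baf, g

    def test_clean_clusters_high_quality(self, rng):
        m, s = 30, 40
        baf = np.zeros((m, s))
        for j in range(s):
            baf[:, j], _ = self.panel_baf(rng, m, [0.05, 0.5, 0.93], [0.3, 0.4, 0.3])
        logr = rng.normal(9, 0.3, (m, s))
        model = fit_snp_clusters(baf, logr, np.arange(s))
        assert model.quality_high.all()
        lines = model.evaluate_lines(np.full(s, 9.0))
        np.testing.assert_allclose(lines[:, 0], 0.05, atol=0.02)
        np.testing.assert_allclose(lines[:, 1], 0.50, atol=0.02)
        np.testing.assert_allclose(lines[:, 2], 0.93, atol=0.02)

    def test_monomorphic_snp_uses_mirror_and_half_line(self, rng):
        m = 30
        baf = np.column_stack([
            rng.normal(0.06, 0.01, m),          # all AA
            self.panel_baf(rng, m, [0.05, 0.5, 0.93], [0.3, 0.4, 0.3])[0],
        ])
        logr = rng.normal(9, 0.3, (m, 2))
        model = fit_snp_clusters(baf, logr, np.arange(2))
        assert not model.quality_high[0]
        lines = model.evaluate_lines(np.full(2, 9.0))
        assert lines[0, 0] == pytest.approx(0.06, abs=0.02)   # fitted AA
        assert lines[0, 1] == pytest.approx(0.5, abs=1e-9)    # constant AB
        assert lines[0, 2] == pytest.approx(1 - lines[0, 0], abs=1e-9)  # mirror

    def test_quality_flips_exactly_at_score_threshold(self, rng):
        """The high/low decision follows the cluster sum of squares per
        reference sample crossing 0.018, computed by an independent oracle."""
        m = 40
        logr = rng.normal(9, 0.2, (m, 1))
        for half_sep in [0.01, 0.03, 0.05, 0.08, 0.12, 0.2, 0.35]:
            centers = [0.5 - half_sep, 0.5, 0.5 + half_sep]
            baf = self.panel_baf(rng, m, centers, [1 / 3, 1 / 3, 1 / 3], spread=0.004)[0]
            model = fit_snp_clusters(baf[:, None], logr, np.arange(1))
            oracle_score = float(np.sum((baf - baf.mean()) ** 2) / m)
            if model.quality_high[0]:
                assert oracle_score >= 0.018
            # separation below the gap floor must be low-quality regardless
            if 2 * half_sep < 0.15:
                assert not model.quality_high[0]

    def test_split_single_cluster_not_called_high(self, rng):
        # het + one homozygote only: 3-means would split a real cluster
        m = 30
        baf = np.where(rng.random(m) < 0.6, rng.normal(0.85, 0.03, m),
                       rng.normal(0.5, 0.02, m))
        model = fit_snp_clusters(baf[:, None], rng.normal(8, 0.3, (m, 1)), np.arange(1))
        assert not model.quality_high[0]
        lines = model.evaluate_lines(np.array([8.0]))
        assert lines[0, 1] == pytest.approx(0.5)
        assert lines[0, 2] == pytest.approx(1 - lines[0, 0])

    def test_lines_monotone_in_logr(self, rng):
        m, s = 30, 20
        baf = np.zeros((m, s))
        for j in range(s):
            baf[:, j], _ = self.panel_baf(rng, m, [0.08, 0.5, 0.92], [0.3, 0.4, 0.3])
        logr = rng.normal(8, 0.8, (m, s))
        model = fit_snp_clusters(baf, logr, np.arange(s))
        grid = np.linspace(4, 11, 40)
        for x0, x1 in zip(grid[:-1], grid[1:]):
            v0 = model.evaluate_lines(np.full(s, x0))
            v1 = model.evaluate_lines(np.full(s, x1))
            # AA line decreases from 0.5, BB increases toward its asymptote
            assert np.all(v1[:, 0] <= v0[:, 0] + 1e-9)
            assert np.all(v1[:, 2] >= v0[:, 2] - 1e-9)


class TestBuildAndPersist:
    def test_round_trip_and_determinism(self, panel, model, tmp_path):
        path = tmp_path / "ref.h5"
        save_reference(model, path)
        loaded = load_reference(path)
        assert models_equal(model, loaded)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = build_reference(panel.samples, panel.sexes, panel.annotation)
        assert models_equal(model, again)

    def test_every_probe_has_a_function(self, panel, model):
        assert model.probe_functions.intercept.shape[0] == panel.annotation.n_probes
        assert np.isfinite(model.probe_functions.intercept).all()

    def test_fingerprint_mismatch_is_hard_error(self, model, panel):
        other = ProbeAnnotation(panel.annotation.table.assign(position=lambda d: d.position + 1))
        with pytest.raises(ValidationError, match="fingerprint"):
            model.check_annotation(other)

    def test_mds_loadings_reproduce_panel_regression(self, model):
        mds = model.mds
        # loadings have unit RMS per component (scores carry the amplitude)
        rms = np.sqrt((mds.loadings ** 2).mean(axis=0))
        np.testing.assert_allclose(rms[rms > 0], 1.0, atol=1e-6)
        assert mds.score_intervals.shape == (mds.n_components, 2)
        assert np.all(mds.score_intervals[:, 0] <= mds.score_intervals[:, 1])
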
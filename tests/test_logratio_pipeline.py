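import numpy as np
import pandas as pd
import pytest

from rawkit.errors import ConfigurationError, ValidationError
from rawkit.probe_data_io import ProbeAnnotation
from rawkit.reference_model import MdsModel
from rawkit.logratio_pipeline import (
    adjust_genotype_correlation,
    apply_mds_correction,
    compute_raw_logR,
    correct_gc_fraglen,
    median_center,
    process_sample,
    raw_logr_from_intensities,
    subtract_local_reference,
    subtract_reference,
    raw_sample_stats,
)
from rawkit.segmentation_metrics import mapd
from rawkit.synthetic_data import CnvSpec, generate_sample
from tests.conftest import FIXED_QUERY


class TestRawLogR:
    def test_three_four_five_triangle(self):
        assert compute_raw_logR(3.0, 4.0) == pytest.approx(np.log2(5))

    def test_equal_alleles(self):
        assert compute_raw_logR(np.sqrt(2), np.sqrt(2)) == pytest.approx(1.0)

    def test_one_allele_dominates(self):
        assert compute_raw_logR(1024.0, 1e-9) == pytest.approx(10.0, abs=1e-6)

    def test_non_snp_uses_plain_log2(self):
        assert compute_raw_logR(8.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("a,b", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_rejected(self, a, b):
        with pytest.raises(ValidationError):
            compute_raw_logR(a, b)


class TestReferenceSubtraction:
    def test_clean_sample_centers_every_chromosome(self, gen_config, panel, model):
        iset, _ = generate_sample(gen_config, panel.truth.shared, seed=41,
                                  sample_id="q", **FIXED_QUERY)
        track, _ = process_sample(iset, panel.annotation, model)
        for chrom in np.unique(panel.annotation.chromosomes):
            med = np.nanmedian(track.logratio[panel.annotation.chromosomes == chrom])
            assert abs(med) < 0.02

    def test_constant_shift_is_absorbed(self, gen_config, panel, model):
        iset, _ = generate_sample(gen_config, panel.truth.shared, seed=42,
                                  sample_id="q", **FIXED_QUERY)
        raw = raw_logr_from_intensities(iset, panel.annotation)
        mh, rm = raw_sample_stats(raw, panel.annotation)
        base = subtract_reference(raw, mh, rm, model)
        mh2, rm2 = raw_sample_stats(raw + 0.5, panel.annotation)
        shifted = subtract_reference(raw + 0.5, mh2, rm2, model)
        # the shift moves median_hyb by 0.5 and the per-probe functions track
        # it through their median-hyb coefficient; residual per-probe error
        # reflects coefficient estimation accuracy
        assert abs(np.nanmedian(shifted - base)) < 0.005
        assert np.nanpercentile(np.abs(shifted - base), 95) < 0.05
        assert abs(mapd(shifted[panel.annotation.autosome_mask])
                   - mapd(base[panel.annotation.autosome_mask])) < 0.01

    def test_cnv_chromosome_matches_calibration_anchor(self):
        # one altered chromosome out of ten, so the genome-median centering
        # is anchored by the unaltered majority
        from dataclasses import replace
        from rawkit.reference_model import build_reference
        from rawkit.synthetic_data import GeneratorConfig, generate_panel

        cfg = GeneratorConfig(n_probes=3000, n_reference_samples=12,
                              n_chromosomes=10, seed=19)
        pan = generate_panel(cfg)
        mod = build_reference(pan.samples, pan.sexes, pan.annotation)
        cnv = CnvSpec("5", 1, 10**8, h_a=1, h_b=2)  # 1.5x abundance
        iset, _ = generate_sample(cfg, pan.truth.shared, seed=43,
                                  sample_id="q", cnvs=(cnv,), **FIXED_QUERY)
        track, _ = process_sample(iset, pan.annotation, mod)
        med = np.nanmedian(track.logratio[pan.annotation.chromosomes == "5"])
        assert med == pytest.approx(0.35, abs=0.05)


class TestGcFraglenCorrection:
    def make_annotation(self, rng, n=6000):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chromosome": "1",
            "position": np.arange(1, n + 1),
            "probe_class": "SNP",
            "gc_content": rng.uniform(0.3, 0.7, n),
            "fragment_length": rng.integers(100, 2000, n),
        }))

    def bin_medians(self, values, cov, n_bins=20):
        order = np.argsort(np.argsort(cov))
        bins = (order * n_bins / len(cov)).astype(int)
        return np.array([np.median(values[bins == b]) for b in range(n_bins)])

    def test_sinusoidal_gc_bias_removed(self, rng):
        ann = self.make_annotation(rng)
        gc = ann.gc_content
        bias = 0.3 * np.sin(2 * np.pi * (gc - 0.3) / 0.4)
        lr = rng.normal(0, 0.05, ann.n_probes) + bias
        out = correct_gc_fraglen(lr, ann)
        assert np.max(np.abs(self.bin_medians(out, gc))) < 0.01

    def test_bias_free_input_nearly_untouched(self, rng):
        ann = self.make_annotation(rng)
        lr = rng.normal(0, 0.1, ann.n_probes)
        out = correct_gc_fraglen(lr, ann)
        assert abs(mapd(out) - mapd(lr)) < 0.005

    def test_fraglen_only_bias_leaves_gc_structure_alone(self, rng):
        ann = self.make_annotation(rng)
        fl = ann.fragment_length.astype(float)
        bias = 0.25 * np.sin(2 * np.pi * (fl - fl.min()) / (fl.max() - fl.min()))
        lr = rng.normal(0, 0.05, ann.n_probes) + bias
        out = correct_gc_fraglen(lr, ann)
        assert np.max(np.abs(self.bin_medians(out, fl))) < 0.01
        assert np.max(np.abs(self.bin_medians(out, ann.gc_content))) < 0.01

    def test_small_bins_are_merged_with_warning(self, rng):
        ann = self.make_annotation(rng, n=300)
        with pytest.warns(UserWarning, match="bins"):
            correct_gc_fraglen(rng.normal(0, 0.1, 300), ann, n_bins=100)


class TestGenotypeAdjustment:
    class FakeModel:
        def __init__(self, n, slope):
            self.genotype_slope = np.full(n, slope)
            self.genotype_baf_center = np.full(n, 0.5)

    def test_zero_slope_is_identity(self, rng):
        lr = rng.normal(0, 0.1, 100)
        baf = rng.uniform(0, 1, 100)
        out = adjust_genotype_correlation(lr, baf, self.FakeModel(100, 0.0))
        np.testing.assert_array_equal(out, lr)

    def test_linear_coupling_removed(self, rng):
        n = 5000
        baf = rng.choice([0.05, 0.5, 0.95], n)
        lr = 0.2 * (baf - 0.5) + rng.normal(0, 0.05, n)
        out = adjust_genotype_correlation(lr, baf, self.FakeModel(n, 0.2))
        assert abs(np.corrcoef(out, baf)[0, 1]) < 0.05

    def test_heterozygous_probes_unchanged_at_center(self, rng):
        n = 50
        lr = rng.normal(0, 0.1, n)
        out = adjust_genotype_correlation(lr, np.full(n, 0.5), self.FakeModel(n, 0.7))
        np.testing.assert_allclose(out, lr)


class TestMdsCorrection:
    def make_model(self, w, intervals):
        p, k = w.shape
        return MdsModel(
            n_components=k,
            scores=np.zeros((2, k)),
            loadings=w,
            loading_intercept=np.zeros(p),
            score_intervals=np.asarray(intervals, dtype=float),
            probe_index=np.arange(p),
        )

    def flat_annotation(self, n):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chromosome": "1",
            "position": np.arange(1, n + 1),
            "probe_class": "NONSNP",
            "gc_content": 0.5,
            "fragment_length": 500,
        }))

    def test_known_score_recovered_and_mapd_reduced(self, rng):
        n = 8000
        w = rng.normal(0, 1, (n, 1))
        w /= np.sqrt((w ** 2).mean())
        model = self.make_model(w, [[-1.0, 1.0]])
        ann = self.flat_annotation(n)
        lr = rng.normal(0, 0.1, n) + 0.4 * w[:, 0]
        before = mapd(lr)
        out, scores, _ = apply_mds_correction(lr, model, ann)
        assert scores[0] == pytest.approx(0.4, abs=0.1)
        assert mapd(out) < before

    def test_zero_score_sample_barely_touched(self, rng):
        n = 8000
        w = rng.normal(0, 1, (n, 1))
        w /= np.sqrt((w ** 2).mean())
        model = self.make_model(w, [[-1.0, 1.0]])
        ann = self.flat_annotation(n)
        lr = rng.normal(0, 0.1, n)
        out, scores, _ = apply_mds_correction(lr, model, ann)
        assert abs(scores[0]) < 2.0 / 20  # |s| < interval width / 20
        assert mapd(out) < mapd(lr) * 1.01

    def test_edge_argmin_warns(self, rng):
        n = 4000
        w = rng.normal(0, 1, (n, 1))
        w /= np.sqrt((w ** 2).mean())
        model = self.make_model(w, [[-0.1, 0.1]])
        ann = self.flat_annotation(n)
        lr = rng.normal(0, 0.05, n) + 0.5 * w[:, 0]  # true score outside interval
        with pytest.warns(UserWarning, match="interval edge"):
            _, scores, at_edge = apply_mds_correction(lr, model, ann)
        assert at_edge[0]

    def test_each_component_cannot_increase_mapd_beyond_resolution(self, rng):
        n = 6000
        w = rng.normal(0, 1, (n, 2))
        w /= np.sqrt((w ** 2).mean(axis=0))
        model = self.make_model(w, [[-0.5, 0.5], [-0.5, 0.5]])
        ann = self.flat_annotation(n)
        lr = rng.normal(0, 0.1, n) + 0.2 * w[:, 0] - 0.3 * w[:, 1]
        out, _, _ = apply_mds_correction(lr, model, ann)
        assert mapd(out) <= mapd(lr) + 1e-9


class TestLocalReferenceAndCentering:
    def test_replicated_panel_zeroes_the_sample(self, rng):
        lr = rng.normal(0, 0.2, 500)
        out = subtract_local_reference(lr, [lr.copy()] * 3)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_too_few_local_samples(self, rng):
        lr = rng.normal(0, 0.2, 100)
        with pytest.raises(ConfigurationError):
            subtract_local_reference(lr, [lr, lr])

    def test_shared_waviness_removed_cnv_kept(self, rng):
        n = 4000
        wav = 0.3 * np.sin(np.arange(n) / 2)  # probe-scale shared waviness
        cnv = np.zeros(n)
        cnv[1000:1400] = 0.5
        query = wav + cnv + rng.normal(0, 0.05, n)
        local = [wav + rng.normal(0, 0.05, n) for _ in range(4)]
        out = subtract_local_reference(query, local)
        assert mapd(out) < mapd(median_center(query))
        amp = np.median(out[1000:1400]) - np.median(out[:1000])
        assert amp == pytest.approx(0.5, abs=0.02)

    def test_median_centering_idempotent(self, rng):
        lr = rng.normal(0.3, 0.2, 999)
        once = median_center(lr)
        np.testing.assert_allclose(median_center(once), once, atol=1e-15)


class TestProcessSample:
    def test_ledger_records_all_steps_in_order(self, gen_config, panel, model):
        iset, _ = generate_sample(gen_config, panel.truth.shared, seed=44,
                                  sample_id="q", **FIXED_QUERY)
        track, ledger = process_sample(iset, panel.annotation, model)
        names = [s.name for s in ledger.steps]
        assert names[0] == "reference_subtraction"
        assert names[1] == "gc_fraglen"
        assert names[2] == "genotype_adjust"
        assert names[3:9] == [f"mds_component_{k}" for k in range(1, 7)]
        assert names[-1] == "median_center"
        assert track.mapd == ledger.steps[-1].mapd_after
        restored = type(ledger).from_json(ledger.to_json())
        assert [s.name for s in restored.steps] == names

    def test_cnv_breakpoint_position_survives_normalization(self, gen_config, panel, model):
        ann = panel.annotation
        on = ann.chromosomes == "3"
        pos = ann.positions[on]
        start, end = int(pos[len(pos) // 3]), int(pos[2 * len(pos) // 3])
        cnv = CnvSpec("3", start, end, h_a=2, h_b=2)  # 2x gain
        iset, _ = generate_sample(gen_config, panel.truth.shared, seed=45,
                                  sample_id="q", cnvs=(cnv,), **FIXED_QUERY)
        track, _ = process_sample(iset, panel.annotation, model)
        inside = on & (ann.positions >= start) & (ann.positions <= end)
        outside = on & ~inside
        assert np.nanmedian(track.logratio[inside]) > np.nanmedian(track.logratio[outside]) + 0.4
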
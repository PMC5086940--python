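"""Per-sample log ratio normalization.

A sample's raw allele intensities are turned into a normalized log ratio by
an ordered sequence of corrections:

1. subtraction of the per-probe reference expectation given the sample's
   median hybridization and raw MAPD,
2. median-centering within GC-content and fragment-length percentile bins,
3. linear adjustment for the genotype/log-ratio correlation seen in the
   reference panel,
4. sequential subtraction of the reference-panel MDS components at the
   per-sample score minimizing MAPD,
5. optional subtraction of a local reference panel's per-probe median,
6. final genome-wide median centering.

Every step records its before/after MAPD in a :class:`CorrectionLedger`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import ConfigurationError, ValidationError
from .probe_data_io import IntensitySet, ProbeAnnotation, SampleTrack
from .segmentation_metrics import mapd

if TYPE_CHECKING:  # pragma: no cover
    from .reference_model import MdsModel, ReferenceModel


# ---------------------------------------------------------------------------
# Raw quantities
# ---------------------------------------------------------------------------

def compute_raw_logR(intensity_a, intensity_b=None):
    """Raw log R: log2 of the Euclidean sum of the allele-A and allele-B
    intensities for SNP probes; log2 of the single intensity otherwise.

    NaN entries (missing probes, or absent B channel for non-SNP probes)
    propagate; zero or negative intensities are rejected.
    """
    a = np.asarray(intensity_a, dtype=float)
    if np.nanmin(a, initial=np.inf) <= 0:
        raise ValidationError("allele intensities must be strictly positive")
    if intensity_b is None:
        return np.log2(a)
    b = np.asarray(intensity_b, dtype=float)
    if np.nanmin(b, initial=np.inf) <= 0:
        raise ValidationError("allele intensities must be strictly positive")
    r = np.where(np.isnan(b), a, np.sqrt(a * a + b * b))
    return np.log2(r)


def raw_logr_from_intensities(iset: IntensitySet, annotation: ProbeAnnotation) -> np.ndarray:
    """Per-probe raw log R for a sample: Euclidean log R on SNP probes,
    plain log2 intensity on non-SNP probes."""
    snp = annotation.snp_mask
    out = np.full(annotation.n_probes, np.nan)
    valid = ~np.isnan(iset.a)
    sv = valid & snp
    nv = valid & ~snp
    if sv.any():
        out[sv] = compute_raw_logR(iset.a[sv], iset.b[sv])
    if nv.any():
        out[nv] = compute_raw_logR(iset.a[nv])
    return out


def raw_sample_stats(raw_logr: np.ndarray, annotation: ProbeAnnotation) -> tuple[float, float]:
    """(median_hyb, raw_mapd) of a sample.

    Median hybridization is the genome-wide median raw log R; raw MAPD is
    computed on the genome-ordered raw log R of autosomal probes only, to
    avoid sex-chromosome confounding.
    """
    median_hyb = float(np.nanmedian(raw_logr))
    auto = annotation.autosome_mask
    raw_mapd = mapd(raw_logr[auto], annotation.chromosomes[auto])
    return median_hyb, raw_mapd


def median_center(logratio: np.ndarray) -> np.ndarray:
    """Center the genome-wide median log ratio at 0 (idempotent)."""
    return logratio - np.nanmedian(logratio)


# ---------------------------------------------------------------------------
# Correction ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerStep:
    name: str
    mapd_before: float
    mapd_after: float
    params: dict = field(default_factory=dict)


@dataclass
class CorrectionLedger:
    """Audit trail of the correction steps applied to one sample."""

    sample_id: str
    steps: list[LedgerStep] = field(default_factory=list)

    def record(self, name: str, before: float, after: float, **params) -> None:
        self.steps.append(LedgerStep(name, float(before), float(after), dict(params)))

    def mapd_after(self, name: str) -> float:
        for step in self.steps:
            if step.name == name:
                return step.mapd_after
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "steps": [
                    {"name": s.name, "mapd_before": s.mapd_before,
                     "mapd_after": s.mapd_after, "params": s.params}
                    for s in self.steps
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionLedger":
        obj = json.loads(text)
        ledger = cls(sample_id=obj["sample_id"])
        for s in obj["steps"]:
            ledger.record(s["name"], s["mapd_before"], s["mapd_after"], **s["params"])
        return ledger


# ---------------------------------------------------------------------------
# Correction steps
# ---------------------------------------------------------------------------

def subtract_reference(raw_logr: np.ndarray, median_hyb: float, raw_mapd: float,
                       model: "ReferenceModel") -> np.ndarray:
    """Subtract each probe's reference expectation at the sample's
    (median_hyb, raw_mapd), then re-center the genome median at 0."""
    pf = model.probe_functions
    expected = pf.intercept + pf.coef_median_hyb * median_hyb + pf.coef_raw_mapd * raw_mapd
    return median_center(raw_logr - expected)


def correct_gc_fraglen(logratio: np.ndarray, annotation: ProbeAnnotation,
                       n_bins: int = 100, min_bin_probes: int = 50,
                       max_rounds: int = 5, tol: float = 1e-6) -> np.ndarray:
    """Equalize the median log ratio within GC-content and fragment-length
    percentile bins, alternating between the two covariates to joint
    convergence.

    Bins are equal-count percentile bins; the bin count is reduced (bins
    merged) when it would leave fewer than ``min_bin_probes`` probes per bin.
    """
    lr = logratio.copy()
    valid = ~np.isnan(lr)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return lr
    eff_bins = max(1, min(n_bins, n_valid // min_bin_probes))
    if eff_bins < n_bins:
        warnings.warn(
            f"reduced GC/fragment-length bins from {n_bins} to {eff_bins} "
            f"to keep >= {min_bin_probes} probes per bin",
            stacklevel=2,
        )

    def bin_ids(cov: np.ndarray) -> np.ndarray:
        ranks = np.empty(n_valid)
        order = np.argsort(cov[valid], kind="stable")
        ranks[order] = np.arange(n_valid)
        return np.minimum((ranks * eff_bins / n_valid).astype(int), eff_bins - 1)

    gc_bins = bin_ids(annotation.gc_content)
    fl_bins = bin_ids(annotation.fragment_length.astype(float))

    def pass_once(vals: np.ndarray, bins: np.ndarray) -> float:
        worst = 0.0
        for b in range(eff_bins):
            m = bins == b
            if m.any():
                med = np.median(vals[m])
                vals[m] -= med
                worst = max(worst, abs(med))
        return worst

    vals = lr[valid]
    for _ in range(max_rounds):
        w1 = pass_once(vals, gc_bins)
        w2 = pass_once(vals, fl_bins)
        if max(w1, w2) < tol:
            break
    lr[valid] = vals
    return lr


def adjust_genotype_correlation(logratio: np.ndarray, raw_baf: np.ndarray,
                                model: "ReferenceModel") -> np.ndarray:
    """Remove the linear genotype/log-ratio coupling seen in the reference
    panel: per SNP, subtract slope x (raw BAF - panel-mean raw BAF)."""
    lr = logratio.copy()
    slope = model.genotype_slope
    center = model.genotype_baf_center
    snp = ~np.isnan(raw_baf) & ~np.isnan(slope)
    lr[snp] = lr[snp] - slope[snp] * (raw_baf[snp] - center[snp])
    return lr


def _mapd_objective(lr_auto: np.ndarray, chroms_auto: np.ndarray,
                    loading: np.ndarray, s: float) -> float:
    return mapd(lr_auto - s * loading, chroms_auto)


def _grid_argmin(f, lo: float, hi: float, tol: float, n_grid: int = 33) -> float:
    """Deterministic zooming grid minimization.

    The empirical MAPD objective is piecewise linear with small-scale
    wiggles, so bracketing searches can lock onto a local dip; an argmin over
    successively zoomed grids is robust and deterministic.
    """
    a, b = lo, hi
    best_s, best_v = lo, np.inf
    while True:
        grid = np.linspace(a, b, n_grid)
        vals = np.array([f(s) for s in grid])
        i = int(np.argmin(vals))
        if vals[i] < best_v:
            best_v, best_s = float(vals[i]), float(grid[i])
        if (b - a) / (n_grid - 1) <= tol:
            return best_s
        a = max(lo, grid[max(0, i - 1)])
        b = min(hi, grid[min(n_grid - 1, i + 1)])


def apply_mds_correction(logratio: np.ndarray, model: "MdsModel",
                         annotation: ProbeAnnotation, resolution: float = 1e-3
                         ) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Sequentially subtract each MDS component at the per-sample score
    minimizing MAPD.

    For each component the admissible score interval is the span observed in
    the reference panel; the argmin is located by a deterministic zooming
    grid search with resolution ``resolution`` x interval width.  Returns the
    corrected log ratio, the chosen scores and a per-component flag marking
    argmins at an interval edge.
    """
    lr = logratio.copy()
    auto = annotation.autosome_mask & ~np.isnan(lr) & model.autosome_model_mask(annotation)
    chroms_auto = annotation.chromosomes[auto]
    lr_auto = lr[auto]
    loadings = model.loadings_for(annotation)
    scores = np.zeros(model.n_components)
    at_edge: list[bool] = []
    for k in range(model.n_components):
        w = loadings[auto, k]
        lo, hi = model.score_intervals[k]
        width = hi - lo
        if width <= 0:
            at_edge.append(False)
            continue
        s_best = _grid_argmin(
            lambda s: _mapd_objective(lr_auto, chroms_auto, w, s),
            lo, hi, tol=resolution * width,
        )
        edge = s_best <= lo + resolution * width or s_best >= hi - resolution * width
        if edge:
            warnings.warn(
                f"MDS component {k + 1}: minimizing score at interval edge "
                "(possible out-of-panel sample)",
                stacklevel=2,
            )
        at_edge.append(edge)
        scores[k] = s_best
        lr_auto = lr_auto - s_best * w
    lr[auto] = lr_auto
    return lr, scores, at_edge


def subtract_local_reference(logratio: np.ndarray, local_logratios: list[np.ndarray]) -> np.ndarray:
    """Subtract the per-probe median log ratio of a local reference panel
    (>= 3 samples processed through the identical preceding steps)."""
    if len(local_logratios) < 3:
        raise ConfigurationError("local reference requires at least 3 samples")
    panel = np.vstack(local_logratios)
    med = np.nanmedian(panel, axis=0)
    return median_center(logratio - med)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def process_sample(iset: IntensitySet, annotation: ProbeAnnotation,
                   model: "ReferenceModel", *,
                   local_logratios: list[np.ndarray] | None = None,
                   include_low_quality: bool = False,
                   n_bins: int = 100,
                   stop_after: str | None = None) -> tuple[SampleTrack, CorrectionLedger]:
    """Run the full per-sample normalization and return the SampleTrack and
    its correction ledger.

    ``stop_after`` truncates the pipeline after the named step
    (``reference_subtraction``, ``gc_fraglen``, ``genotype_adjust``,
    ``mds``, ``local_reference``), which is useful for step-wise QC.
    """
    from .baf_pipeline import compute_raw_baf_track, normalize_baf

    model.check_annotation(annotation)
    ledger = CorrectionLedger(sample_id=iset.sample_id)
    chroms = annotation.chromosomes
    auto = annotation.autosome_mask

    raw_logr = raw_logr_from_intensities(iset, annotation)
    raw_baf = compute_raw_baf_track(iset, annotation)
    median_hyb, raw_mapd = raw_sample_stats(raw_logr, annotation)

    def cur_mapd(x):
        return mapd(x[auto], chroms[auto])

    lr = subtract_reference(raw_logr, median_hyb, raw_mapd, model)
    ledger.record("reference_subtraction", raw_mapd, cur_mapd(lr),
                  median_hyb=median_hyb, raw_mapd=raw_mapd)

    def finish(lr_final: np.ndarray) -> tuple[SampleTrack, CorrectionLedger]:
        before = cur_mapd(lr_final)
        lr_c = median_center(lr_final)
        final_mapd = cur_mapd(lr_c)
        ledger.record("median_center", before, final_mapd)
        baf = normalize_baf(raw_baf, raw_logr, model,
                            include_low_quality=include_low_quality)
        track = SampleTrack(
            sample_id=iset.sample_id, logratio=lr_c, baf=baf,
            mapd=final_mapd, raw_mapd=raw_mapd, median_hyb=median_hyb,
            mds_scores=np.asarray(scores, dtype=float),
        )
        return track, ledger

    scores = np.zeros(model.mds.n_components if model.mds is not None else 0)
    if stop_after == "reference_subtraction":
        return finish(lr)

    before = cur_mapd(lr)
    lr = correct_gc_fraglen(lr, annotation, n_bins=n_bins)
    ledger.record("gc_fraglen", before, cur_mapd(lr), n_bins=n_bins)
    if stop_after == "gc_fraglen":
        return finish(lr)

    before = cur_mapd(lr)
    lr = adjust_genotype_correlation(lr, raw_baf, model)
    ledger.record("genotype_adjust", before, cur_mapd(lr))
    if stop_after == "genotype_adjust":
        return finish(lr)

    if model.mds is not None:
        before = cur_mapd(lr)
        lr, scores, at_edge = apply_mds_correction(lr, model.mds, annotation)
        after = cur_mapd(lr)
        for k in range(model.mds.n_components):
            ledger.record(f"mds_component_{k + 1}", before if k == 0 else float("nan"),
                          after if k == model.mds.n_components - 1 else float("nan"),
                          score=float(scores[k]), at_edge=bool(at_edge[k]))
    if stop_after == "mds":
        return finish(lr)

    if local_logratios is not None:
        before = cur_mapd(lr)
        lr = subtract_local_reference(lr, local_logratios)
        ledger.record("local_reference", before, cur_mapd(lr),
                      n_local=len(local_logratios))

    return finish(lr)
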
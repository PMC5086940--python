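"""Reference-panel model: everything fitted once from a panel of normal
samples and reused to normalize new samples.

Three fitted parts:

* **per-probe intensity functions** — robust linear fits of each probe's
  panel raw log R on the panel samples' median hybridization and raw MAPD;
  X-chromosome probes are fitted from female samples only and Y from male
  samples only;
* **MDS component model** — classical metric MDS (principal coordinates) of
  the panel's autosomal residual log ratio, six components by default, with
  per-probe loadings obtained by regressing the panel on the scores;
* **per-SNP genotype-cluster functions** — for each SNP, the raw BAF of the
  AA/AB/BB genotype clusters expressed as a monotone characteristic function
  of raw log R, with a cluster-separation quality label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ConfigurationError, ValidationError
from .probe_data_io import IntensitySet, ProbeAnnotation
from .logratio_pipeline import (
    adjust_genotype_correlation,
    correct_gc_fraglen,
    median_center,
    raw_logr_from_intensities,
    raw_sample_stats,
)

FORMAT_VERSION = 1

# characteristic-function decay-rate grid (per log2 unit of raw log R)
_RATE_GRID = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0])


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeReferenceFunctions:
    """Per-probe linear reference functions of (median_hyb, raw_mapd)."""

    intercept: np.ndarray
    coef_median_hyb: np.ndarray
    coef_raw_mapd: np.ndarray

    def evaluate(self, median_hyb: float, raw_mapd: float) -> np.ndarray:
        return self.intercept + self.coef_median_hyb * median_hyb + self.coef_raw_mapd * raw_mapd


@dataclass
class MdsModel:
    """MDS component scores, per-probe loadings and admissible score spans.

    Loadings are scaled to unit per-probe RMS within each component, so a
    score is read directly in log2 units of per-probe contribution.
    """

    n_components: int
    scores: np.ndarray              # panel samples x components, column mean 0
    loadings: np.ndarray            # autosomal probes x components
    loading_intercept: np.ndarray   # autosomal probes
    score_intervals: np.ndarray     # components x 2 (panel span)
    probe_index: np.ndarray         # indices of the modelled autosomal probes

    def autosome_model_mask(self, annotation: ProbeAnnotation) -> np.ndarray:
        mask = np.zeros(annotation.n_probes, dtype=bool)
        mask[self.probe_index] = True
        return mask

    def loadings_for(self, annotation: ProbeAnnotation) -> np.ndarray:
        full = np.zeros((annotation.n_probes, self.n_components))
        full[self.probe_index] = self.loadings
        return full


@dataclass
class SnpClusterModel:
    """Per-SNP genotype characteristic functions
    g(x) = mu + (0.5 - mu) * min(exp(-k*(x - x0)), 1).

    Each genotype line runs from the background raw BAF (0.5, reached at and
    below the background hybridization level x0) to the genotype asymptote
    mu at high log R.  The decay rate ``rate`` and the offset of x0 from the
    per-SNP panel log R origin are chip-global (fitted on all SNPs pooled);
    the asymptote is per SNP and genotype.  ``amp`` stores 0.5 - mu.
    Arrays are aligned to ``probe_index`` (SNP probes in annotation order);
    the genotype axis is ordered AA, AB, BB.
    """

    probe_index: np.ndarray   # indices of SNP probes into the annotation
    mu: np.ndarray            # n_snp x 3 asymptotes (raw BAF units)
    amp: np.ndarray           # n_snp x 3 amplitudes (0.5 - mu)
    rate: np.ndarray          # n_snp x 3 decay rates (>= 0, chip-global value)
    x_ref: np.ndarray         # n_snp background origin x0 (log2 units)
    occupancy: np.ndarray     # n_snp x 3 cluster counts
    score: np.ndarray         # n_snp quality scores (total SS / panel size)
    quality_high: np.ndarray  # n_snp bool
    monomorphic: np.ndarray   # n_snp bool
    quality_threshold: float = 0.018

    def evaluate_lines(self, raw_logr_snp: np.ndarray) -> np.ndarray:
        """Genotype line values v_AA, v_AB, v_BB at the given raw log R
        (one value per SNP probe), bounded to [-0.25, 1.25]."""
        dx = raw_logr_snp[:, None] - self.x_ref[:, None]
        e = np.minimum(np.exp(np.clip(-self.rate * dx, -60.0, 60.0)), 1.0)
        return np.clip(self.mu + self.amp * e, -0.25, 1.25)


@dataclass
class ReferenceModel:
    """Complete fitted reference model for one annotation."""

    fingerprint: str
    probe_functions: ProbeReferenceFunctions
    mds: MdsModel | None
    snp: SnpClusterModel
    genotype_slope: np.ndarray       # n_probes (0 for non-SNP)
    genotype_baf_center: np.ndarray  # n_probes (panel-mean raw BAF; 0.5 default)
    n_samples: int
    sexes: list[str] = field(default_factory=list)

    def check_annotation(self, annotation: ProbeAnnotation) -> None:
        if annotation.fingerprint() != self.fingerprint:
            raise ValidationError(
                "annotation fingerprint does not match the reference model"
            )


@dataclass
class RefConfig:
    n_components: int = 6
    quality_threshold: float = 0.018
    n_bins: int = 100
    min_panel: int = 10
    min_sex_panel: int = 5
    irls_iterations: int = 4
    irls_tuning: float = 4.685
    backfit_rounds: int = 2


# ---------------------------------------------------------------------------
# Robust per-probe regression
# ---------------------------------------------------------------------------

def _irls_matrix(Y: np.ndarray, X: np.ndarray, iterations: int = 4,
                 tuning: float = 4.685, moderate_slopes: bool = True) -> np.ndarray:
    """Iteratively reweighted least squares with Tukey-bisquare weights,
    fitted independently for every column of ``Y`` (probes) on the shared
    design ``X`` (samples x predictors).  NaN responses get zero weight.

    With ``moderate_slopes`` the non-intercept coefficients are shrunk
    toward their across-probe mean in proportion to their per-probe sampling
    variance (empirical Bayes): a small panel cannot support a free slope
    per probe, and unmoderated slope noise would be re-injected into every
    sample normalized against the model.  The intercept is never shrunk.
    """
    m, d = X.shape
    valid = ~np.isnan(Y)
    yf = np.nan_to_num(Y)
    w = valid.astype(float)
    eye = np.eye(d)
    beta = None
    a = None
    for it in range(iterations + 1):
        a = np.einsum("mp,mi,mj->pij", w, X, X)
        b = np.einsum("mp,mi,mp->pi", w, X, yf)
        deficient = w.sum(axis=0) < d
        if deficient.any():
            a[deficient] += eye  # keeps the solve well-posed; outputs ~0 there
        beta = np.linalg.solve(a + 1e-10 * eye, b[:, :, None])[:, :, 0]
        if it == iterations:
            break
        resid = yf - X @ beta.T
        absr = np.where(valid, np.abs(resid), np.nan)
        scale = 1.4826 * np.nanmedian(absr, axis=0)
        scale = np.maximum(scale, 1e-8)
        u = resid / (tuning * scale)
        w = valid * np.clip(1.0 - u * u, 0.0, None) ** 2
        # guard against all weights collapsing at a probe
        dead = w.sum(axis=0) < d
        if dead.any():
            w[:, dead] = valid[:, dead].astype(float)
    if moderate_slopes and d > 1:
        resid = yf - X @ beta.T
        dof = np.maximum(w.sum(axis=0) - d, 1.0)
        sigma2 = (w * resid ** 2).sum(axis=0) / dof
        ainv = np.linalg.inv(a + 1e-10 * eye)
        for j in range(1, d):
            v = np.maximum(sigma2 * ainv[:, j, j], 1e-12)
            bj = beta[:, j]
            prior = float(np.median(bj))
            tau2 = max(float(np.var(bj) - np.mean(v)), 0.0)
            shrink = tau2 / (tau2 + v)
            delta = bj - (prior + shrink * (bj - prior))
            beta[:, j] -= delta
            # keep the fit at the panel's predictor centroid unchanged
            xbar = (w * X[:, j][:, None]).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-9)
            beta[:, 0] += delta * xbar
    return beta


def _robust_location(Y: np.ndarray) -> np.ndarray:
    return np.nanmedian(Y, axis=0)


def fit_probe_functions(raw_logr: np.ndarray, median_hyb: np.ndarray,
                        raw_mapd: np.ndarray, annotation: ProbeAnnotation,
                        sexes: list[str] | None = None,
                        config: RefConfig | None = None) -> ProbeReferenceFunctions:
    """Robust per-probe linear fit of panel raw log R on the panel samples'
    (median_hyb, raw_mapd).

    Robust (redescending) weights limit the influence of the minority of
    panel samples carrying a copy number variant at any given probe.
    X-chromosome probes use female samples only, Y probes male only.
    """
    config = config or RefConfig()
    m, p = raw_logr.shape
    if m < config.min_panel:
        raise ConfigurationError(
            f"reference panel of {m} samples is below the minimum {config.min_panel}"
        )
    sexes = sexes or ["F"] * m
    chroms = np.array([c.removeprefix("chr") for c in annotation.chromosomes])
    sample_masks = {
        "auto": np.ones(m, dtype=bool),
        "X": np.array([s.upper().startswith("F") for s in sexes]),
        "Y": np.array([s.upper().startswith("M") for s in sexes]),
    }
    probe_groups = {
        "auto": ~np.isin(chroms, ["X", "Y"]),
        "X": chroms == "X",
        "Y": chroms == "Y",
    }
    intercept = np.zeros(p)
    c_mh = np.zeros(p)
    c_rm = np.zeros(p)
    for name, probes in probe_groups.items():
        if not probes.any():
            continue
        smask = sample_masks[name]
        if name != "auto" and smask.sum() < config.min_sex_panel:
            raise ConfigurationError(
                f"need >= {config.min_sex_panel} {'female' if name == 'X' else 'male'} "
                f"samples to fit chromosome {name} probes"
            )
        mh, rm = median_hyb[smask], raw_mapd[smask]
        y = raw_logr[smask][:, probes]
        degenerate = np.std(mh) < 1e-9 or np.std(rm) < 1e-9
        if degenerate:
            warnings.warn(
                "degenerate predictor variance across the panel; "
                "falling back to a robust per-probe location",
                stacklevel=2,
            )
            intercept[probes] = _robust_location(y)
            continue
        x = np.column_stack([np.ones(smask.sum()), mh, rm])
        beta = _irls_matrix(y, x, iterations=config.irls_iterations,
                            tuning=config.irls_tuning)
        intercept[probes] = beta[:, 0]
        c_mh[probes] = beta[:, 1]
        c_rm[probes] = beta[:, 2]
    return ProbeReferenceFunctions(intercept=intercept, coef_median_hyb=c_mh,
                                   coef_raw_mapd=c_rm)


# ---------------------------------------------------------------------------
# MDS component model
# ---------------------------------------------------------------------------

def fit_mds(resid_auto: np.ndarray, raw_mapd: np.ndarray,
            n_components: int = 6, probe_index: np.ndarray | None = None) -> MdsModel:
    """Classical metric MDS (principal coordinates on Euclidean distances) of
    the panel residual matrix, followed by per-probe regression of the panel
    on the scores.

    Scores and loadings are rescaled so each component's loading vector has
    unit per-probe RMS; component signs are fixed so that the score's
    correlation with the panel raw MAPD is non-negative.
    """
    m, p = resid_auto.shape
    if m < n_components + 1:
        raise ConfigurationError(
            f"MDS with {n_components} components needs at least {n_components + 1} panel samples"
        )
    col_mean = np.nanmean(resid_auto, axis=0)
    xc = np.nan_to_num(resid_auto - col_mean)
    gram = xc @ xc.T  # PCoA: double-centered squared-distance matrix equals this Gram matrix
    lam, vec = np.linalg.eigh(gram)
    order = np.argsort(lam)[::-1][:n_components]
    lam = np.clip(lam[order], 0.0, None)
    scores = vec[:, order] * np.sqrt(lam)
    loadings = np.zeros((p, n_components))
    for k in range(n_components):
        s = scores[:, k]
        ss = float(s @ s)
        if ss < 1e-12:
            continue
        slope = xc.T @ s / ss
        rms = float(np.sqrt(np.mean(slope ** 2)))
        if rms < 1e-12:
            continue
        loadings[:, k] = slope / rms
        scores[:, k] = s * rms
        r = np.corrcoef(scores[:, k], raw_mapd)[0, 1] if np.std(raw_mapd) > 0 else 0.0
        if np.isfinite(r) and r < 0:
            scores[:, k] = -scores[:, k]
            loadings[:, k] = -loadings[:, k]
    intervals = np.column_stack([scores.min(axis=0), scores.max(axis=0)])
    if probe_index is None:
        probe_index = np.arange(p)
    return MdsModel(
        n_components=n_components, scores=scores, loadings=loadings,
        loading_intercept=col_mean, score_intervals=intervals,
        probe_index=np.asarray(probe_index, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Per-SNP genotype clusters
# ---------------------------------------------------------------------------

def _three_means(baf: np.ndarray, max_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-D 3-means over SNP columns, deterministic quantile init.

    Returns (centers (3 x s), assignment (m x s), ) with centers sorted
    ascending; empty clusters keep their initial center and zero occupancy.
    """
    valid = ~np.isnan(baf)
    centers = np.nanpercentile(baf, [5, 50, 95], axis=0)
    assign = np.zeros(baf.shape, dtype=np.int8)
    for _ in range(max_iter):
        dist = np.abs(baf[None, :, :] - centers[:, None, :])
        new_assign = np.nanargmin(np.where(np.isnan(dist), np.inf, dist), axis=0).astype(np.int8)
        new_assign[~valid] = -1
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
        for g in range(3):
            mask = assign == g
            cnt = mask.sum(axis=0)
            with np.errstate(invalid="ignore"):
                means = np.where(mask, np.nan_to_num(baf), 0.0).sum(axis=0) / np.maximum(cnt, 1)
            centers[g] = np.where(cnt > 0, means, centers[g])
    # sort genotype order by center
    order = np.argsort(centers, axis=0, kind="stable")
    centers = np.take_along_axis(centers, order, axis=0)
    remap = np.argsort(order, axis=0)
    pos = np.clip(assign, 0, 2)
    assign = np.where(assign >= 0, np.take_along_axis(remap, pos, axis=0), -1).astype(np.int8)
    return centers, assign


_OFFSET_GRID = np.array([-3.0, -2.5, -2.0, -1.5, -1.0, -0.5, 0.0])


def _fit_cluster_asymptotes(baf: np.ndarray, logr: np.ndarray, assign: np.ndarray,
                            x_min: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Fit the genotype characteristic functions for all SNPs jointly.

    The shape 1 - min(exp(-k*(x - x_min - d)), 1) is chip-global: one decay
    rate k and one offset d of the background level below the per-SNP panel
    log R minimum, chosen on a grid by pooled least squares.  The genotype
    asymptote mu is per SNP and cluster, solved in closed form given the
    shape.  A single free parameter per cluster keeps small panels from
    overfitting; the line is pinned to raw BAF 0.5 at the background level.
    """
    yv = np.nan_to_num(baf)
    best = (np.inf, None, 1.0, 0.0)
    for k in _RATE_GRID[1:]:
        for d in _OFFSET_GRID:
            e = np.minimum(np.exp(np.clip(-k * (logr - x_min[None, :] - d), -60.0, 60.0)), 1.0)
            shape = 1.0 - np.nan_to_num(e)
            resid_target = yv - 0.5 * np.nan_to_num(e)
            total_sse = 0.0
            mu = np.full((baf.shape[1], 3), 0.5)
            for g in range(3):
                w = (assign == g).astype(float)
                sww = (w * shape * shape).sum(axis=0)
                swy = (w * shape * resid_target).sum(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    mu_g = np.where(sww > 1e-9, swy / np.maximum(sww, 1e-9), 0.5)
                mu_g = np.clip(mu_g, -0.25, 1.25)
                mu[:, g] = mu_g
                resid = w * (resid_target - mu_g[None, :] * shape)
                total_sse += float((resid ** 2).sum())
            if total_sse < best[0] - 1e-12:
                best = (total_sse, mu, float(k), float(d))
    _, mu, k, d = best
    return mu, k, d


def fit_snp_clusters(raw_baf: np.ndarray, raw_logr: np.ndarray,
                     probe_index: np.ndarray,
                     quality_threshold: float = 0.018) -> SnpClusterModel:
    """Fit the per-SNP genotype-cluster model from panel raw BAF and raw log R.

    Panel samples are assigned to three genotype clusters by deterministic
    1-D 3-means on raw BAF; each cluster's characteristic function is fitted
    by least squares.  A SNP is high-quality when all three clusters are
    occupied and the total cluster sum of squares per reference sample is at
    least ``quality_threshold``; for low-quality SNPs the mirror image around
    0.5 of the better-defined homozygous cluster replaces the missing
    homozygote and a constant 0.5 line is used for AB.
    """
    m, s = raw_baf.shape
    valid = ~np.isnan(raw_baf)
    n_valid = valid.sum(axis=0)
    centers, assign = _three_means(raw_baf)
    occupancy = np.stack([(assign == g).sum(axis=0) for g in range(3)], axis=1)

    grand = np.where(valid, np.nan_to_num(raw_baf), 0.0).sum(axis=0) / np.maximum(n_valid, 1)
    total_ss = (np.where(valid, (np.nan_to_num(raw_baf) - grand) ** 2, 0.0)).sum(axis=0)
    score = total_ss / np.maximum(n_valid, 1)

    spread = np.nanmax(raw_baf, axis=0) - np.nanmin(raw_baf, axis=0)
    monomorphic = spread < 1e-6

    # genuine 3-cluster structure: adjacent centers must be separated well
    # beyond the within-cluster spread, otherwise 3-means has split a single
    # genotype cluster (e.g. a homozygote missing from the panel)
    within_ss = np.zeros(s)
    for g in range(3):
        mask = assign == g
        d = np.where(mask, np.nan_to_num(raw_baf) - centers[g], 0.0)
        within_ss += (d ** 2).sum(axis=0)
    within_sd = np.sqrt(within_ss / np.maximum(n_valid, 1))
    # genotype clusters sit several tenths of raw BAF apart; gaps below an
    # absolute floor are splits of a single cluster, not genotype structure
    min_gap = np.maximum(4.0 * within_sd, 0.15)
    separated = ((centers[1] - centers[0]) > min_gap) & ((centers[2] - centers[1]) > min_gap)
    quality_high = (
        (occupancy > 0).all(axis=1) & (score >= quality_threshold)
        & separated & ~monomorphic
    )

    # low-quality SNPs: genotype identity from the 3-means split is not
    # trustworthy; re-assign by raw BAF bands around the global anchors
    low = ~quality_high
    if low.any():
        thresh_assign = np.where(raw_baf < 0.3, 0, np.where(raw_baf > 0.7, 2, 1)).astype(np.int8)
        thresh_assign[~valid] = -1
        assign = np.where(low[None, :], thresh_assign, assign).astype(np.int8)

    x_min = np.nanmin(raw_logr, axis=0)
    x_min = np.where(np.isnan(x_min), 0.0, x_min)
    mu, k_global, d_global = _fit_cluster_asymptotes(raw_baf, raw_logr, assign, x_min)
    x_ref = x_min + d_global
    rate = np.full((s, 3), k_global)

    # low-quality fallback: mirror the better-defined homozygous cluster
    # around 0.5 for the missing homozygote, constant 0.5 for AB
    if low.any():
        occ0 = ((assign == 0) & low[None, :]).sum(axis=0)
        occ2 = ((assign == 2) & low[None, :]).sum(axis=0)
        for i in np.flatnonzero(low):
            if occ0[i] == 0 and occ2[i] == 0:
                mu[i] = [0.05, 0.5, 0.95]
                continue
            a_g = 2 if occ2[i] > occ0[i] else 0
            mu[i, 2 - a_g] = 1.0 - mu[i, a_g]
            mu[i, 1] = 0.5
    amp = 0.5 - mu

    return SnpClusterModel(
        probe_index=np.asarray(probe_index, dtype=np.int64),
        mu=mu, amp=amp, rate=rate, x_ref=x_ref,
        occupancy=occupancy.astype(np.int64), score=score,
        quality_high=quality_high, monomorphic=monomorphic,
        quality_threshold=quality_threshold,
    )


def fit_genotype_slopes(resid: np.ndarray, raw_baf: np.ndarray,
                        annotation: ProbeAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP least-squares slope of panel residual log ratio on panel raw
    BAF, plus the panel-mean raw BAF used as the centering constant.

    Per-probe slopes from a small panel are noisy, so they are moderated:
    each slope is shrunk toward the panel-wide mean slope in proportion to
    its sampling variance relative to the between-probe slope variance
    (empirical-Bayes posterior mean).  Without moderation the adjustment
    would re-inject estimation noise into otherwise clean probes.
    """
    p = annotation.n_probes
    slope = np.zeros(p)
    center = np.full(p, 0.5)
    valid = ~np.isnan(raw_baf) & ~np.isnan(resid)
    n = valid.sum(axis=0)
    bafz = np.where(valid, np.nan_to_num(raw_baf), 0.0)
    residz = np.where(valid, np.nan_to_num(resid), 0.0)
    mean_b = bafz.sum(axis=0) / np.maximum(n, 1)
    mean_y = residz.sum(axis=0) / np.maximum(n, 1)
    db = (bafz - mean_b * valid)
    dy = (residz - mean_y * valid)
    cov = (db * dy).sum(axis=0)
    var = (db ** 2).sum(axis=0)
    ok = (n >= 4) & (var > 1e-8)
    if not ok.any():
        return slope, center
    b_hat = cov[ok] / var[ok]
    sse = (dy ** 2).sum(axis=0)[ok] - b_hat * cov[ok]
    sigma2 = np.maximum(sse / np.maximum(n[ok] - 2, 1), 1e-12)
    v_hat = sigma2 / var[ok]  # sampling variance of each slope estimate
    prior_mean = float(np.median(b_hat))
    tau2 = max(float(np.var(b_hat) - np.mean(v_hat)), 0.0)
    shrink = tau2 / (tau2 + v_hat)
    idx = np.flatnonzero(ok)
    slope[idx] = prior_mean + shrink * (b_hat - prior_mean)
    center[idx] = mean_b[idx]
    return slope, center


# ---------------------------------------------------------------------------
# Build / persist
# ---------------------------------------------------------------------------

def build_reference(panel: list[IntensitySet], sexes: list[str],
                    annotation: ProbeAnnotation,
                    config: RefConfig | None = None) -> ReferenceModel:
    """Fit the complete reference model from a panel of samples.

    The panel residual space used for genotype slopes and MDS is produced by
    the same ordered steps later applied to new samples: reference
    subtraction, GC/fragment-length centering, genotype adjustment.
    """
    from .baf_pipeline import compute_raw_baf_track

    config = config or RefConfig()
    m = len(panel)
    if m < config.min_panel:
        raise ConfigurationError(
            f"reference panel of {m} samples is below the minimum {config.min_panel}"
        )
    if len(sexes) != m:
        raise ConfigurationError("one sex label per panel sample required")
    p = annotation.n_probes
    raw = np.empty((m, p))
    baf = np.empty((m, p))
    median_hyb = np.empty(m)
    raw_mapd = np.empty(m)
    for i, iset in enumerate(panel):
        raw[i] = raw_logr_from_intensities(iset, annotation)
        baf[i] = compute_raw_baf_track(iset, annotation)
        median_hyb[i], raw_mapd[i] = raw_sample_stats(raw[i], annotation)

    probe_funcs = fit_probe_functions(raw, median_hyb, raw_mapd, annotation,
                                      sexes, config)

    resid = np.empty_like(raw)
    for i in range(m):
        expected = probe_funcs.evaluate(median_hyb[i], raw_mapd[i])
        resid[i] = median_center(raw[i] - expected)
        resid[i] = correct_gc_fraglen(resid[i], annotation, n_bins=config.n_bins)

    slope, center = fit_genotype_slopes(resid, baf, annotation)

    snp_idx = np.flatnonzero(annotation.snp_mask)
    snp_model = fit_snp_clusters(baf[:, snp_idx], raw[:, snp_idx], snp_idx,
                                 quality_threshold=config.quality_threshold)

    model_stub = ReferenceModel(
        fingerprint=annotation.fingerprint(), probe_functions=probe_funcs,
        mds=None, snp=snp_model, genotype_slope=slope,
        genotype_baf_center=center, n_samples=m, sexes=list(sexes),
    )
    for i in range(m):
        resid[i] = adjust_genotype_correlation(resid[i], baf[i], model_stub)

    auto_idx = np.flatnonzero(annotation.autosome_mask)
    mds = fit_mds(resid[:, auto_idx], raw_mapd,
                  n_components=config.n_components, probe_index=auto_idx)
    model_stub.mds = mds

    # backfit rounds: remove each panel sample's fitted component
    # contribution and refit the per-probe reference functions on the
    # cleaned panel, so the intercepts are not inflated by the panel's own
    # systematic variation; then refit slopes and the component model on the
    # improved residual space
    for _ in range(config.backfit_rounds):
        contrib = model_stub.mds.scores @ model_stub.mds.loadings.T
        raw_clean = raw.copy()
        raw_clean[:, auto_idx] -= contrib
        model_stub.probe_functions = fit_probe_functions(
            raw_clean, median_hyb, raw_mapd, annotation, sexes, config)
        for i in range(m):
            expected = model_stub.probe_functions.evaluate(median_hyb[i], raw_mapd[i])
            resid[i] = median_center(raw[i] - expected)
            resid[i] = correct_gc_fraglen(resid[i], annotation, n_bins=config.n_bins)
            resid[i] = adjust_genotype_correlation(resid[i], baf[i], model_stub)
        slope, center = fit_genotype_slopes(resid, baf, annotation)
        model_stub.genotype_slope = slope
        model_stub.genotype_baf_center = center
        model_stub.mds = fit_mds(resid[:, auto_idx], raw_mapd,
                                 n_components=config.n_components, probe_index=auto_idx)
    return model_stub


def save_reference(model: ReferenceModel, path) -> None:
    """Persist a reference model to a single versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "rawkit-reference"
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["fingerprint"] = model.fingerprint
        f.attrs["n_samples"] = model.n_samples
        f.attrs["sexes"] = ",".join(model.sexes)
        g = f.create_group("probe_functions")
        g["intercept"] = model.probe_functions.intercept
        g["coef_median_hyb"] = model.probe_functions.coef_median_hyb
        g["coef_raw_mapd"] = model.probe_functions.coef_raw_mapd
        f["genotype_slope"] = model.genotype_slope
        f["genotype_baf_center"] = model.genotype_baf_center
        if model.mds is not None:
            g = f.create_group("mds")
            g.attrs["n_components"] = model.mds.n_components
            g["scores"] = model.mds.scores
            g["loadings"] = model.mds.loadings
            g["loading_intercept"] = model.mds.loading_intercept
            g["score_intervals"] = model.mds.score_intervals
            g["probe_index"] = model.mds.probe_index
        g = f.create_group("snp")
        g.attrs["quality_threshold"] = model.snp.quality_threshold
        for name in ("probe_index", "mu", "amp", "rate", "x_ref", "occupancy",
                     "score", "quality_high", "monomorphic"):
            g[name] = getattr(model.snp, name)


def load_reference(path) -> ReferenceModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "rawkit-reference":
            raise ValidationError(f"{path} is not a rawkit reference container")
        if int(f.attrs["version"]) > FORMAT_VERSION:
            raise ValidationError("reference container from a newer format version")
        pf = ProbeReferenceFunctions(
            intercept=f["probe_functions/intercept"][:],
            coef_median_hyb=f["probe_functions/coef_median_hyb"][:],
            coef_raw_mapd=f["probe_functions/coef_raw_mapd"][:],
        )
        mds = None
        if "mds" in f:
            g = f["mds"]
            mds = MdsModel(
                n_components=int(g.attrs["n_components"]),
                scores=g["scores"][:], loadings=g["loadings"][:],
                loading_intercept=g["loading_intercept"][:],
                score_intervals=g["score_intervals"][:],
                probe_index=g["probe_index"][:],
            )
        g = f["snp"]
        snp = SnpClusterModel(
            probe_index=g["probe_index"][:], mu=g["mu"][:], amp=g["amp"][:],
            rate=g["rate"][:], x_ref=g["x_ref"][:], occupancy=g["occupancy"][:],
            score=g["score"][:], quality_high=g["quality_high"][:].astype(bool),
            monomorphic=g["monomorphic"][:].astype(bool),
            quality_threshold=float(g.attrs["quality_threshold"]),
        )
        sexes_attr = str(f.attrs["sexes"])
        return ReferenceModel(
            fingerprint=str(f.attrs["fingerprint"]),
            probe_functions=pf, mds=mds, snp=snp,
            genotype_slope=f["genotype_slope"][:],
            genotype_baf_center=f["genotype_baf_center"][:],
            n_samples=int(f.attrs["n_samples"]),
            sexes=sexes_attr.split(",") if sexes_attr else [],
        )


def models_equal(a: ReferenceModel, b: ReferenceModel) -> bool:
    """Exact equality of two reference models (used for round-trip checks)."""
    def eq(x, y):
        return np.array_equal(np.asarray(x), np.asarray(y))

    if a.fingerprint != b.fingerprint or a.n_samples != b.n_samples or a.sexes != b.sexes:
        return False
    if not (eq(a.probe_functions.intercept, b.probe_functions.intercept)
            and eq(a.probe_functions.coef_median_hyb, b.probe_functions.coef_median_hyb)
            and eq(a.probe_functions.coef_raw_mapd, b.probe_functions.coef_raw_mapd)
            and eq(a.genotype_slope, b.genotype_slope)
            and eq(a.genotype_baf_center, b.genotype_baf_center)):
        return False
    if (a.mds is None) != (b.mds is None):
        return False
    if a.mds is not None:
        for name in ("scores", "loadings", "loading_intercept", "score_intervals", "probe_index"):
            if not eq(getattr(a.mds, name), getattr(b.mds, name)):
                return False
    for name in ("probe_index", "mu", "amp", "rate", "x_ref", "occupancy",
                 "score", "quality_high", "monomorphic"):
        if not eq(getattr(a.snp, name), getattr(b.snp, name)):
            return False
    return True
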
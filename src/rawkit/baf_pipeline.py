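"""B-allele frequency estimation.

Raw BAF (allele-B fraction of total allele intensity) is normalized against
the per-SNP genotype-cluster model: the three genotype characteristic
functions are evaluated at the sample's raw log R, and the observation is
mapped piecewise-linearly with anchors AA -> 0, AB -> 0.5, BB -> 1.  Values
outside the outer lines extrapolate with the adjacent segment's slope, so
normalized BAF is intentionally not truncated to [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ValidationError
from .probe_data_io import IntensitySet, ProbeAnnotation
from .reference_model import ReferenceModel

GLOBAL_ANCHORS = np.array([0.05, 0.5, 0.95])


def compute_raw_baf(intensity_a, intensity_b):
    """Raw BAF = B / (A + B) per SNP probe, in (0, 1). NaN propagates."""
    a = np.asarray(intensity_a, dtype=float)
    b = np.asarray(intensity_b, dtype=float)
    if np.nanmin(a, initial=np.inf) <= 0 or np.nanmin(b, initial=np.inf) <= 0:
        raise ValidationError("allele intensities must be strictly positive")
    return b / (a + b)


def compute_raw_baf_track(iset: IntensitySet, annotation: ProbeAnnotation) -> np.ndarray:
    """Per-probe raw BAF aligned to the annotation (NaN for non-SNP/missing)."""
    out = np.full(annotation.n_probes, np.nan)
    snp = annotation.snp_mask & ~np.isnan(iset.a) & ~np.isnan(iset.b)
    if snp.any():
        out[snp] = compute_raw_baf(iset.a[snp], iset.b[snp])
    return out


def select_quality(model: ReferenceModel, annotation: ProbeAnnotation,
                   include_low_quality: bool = False) -> np.ndarray:
    """Boolean mask over annotation probes of SNPs entering BAF analysis."""
    mask = np.zeros(annotation.n_probes, dtype=bool)
    if include_low_quality:
        mask[model.snp.probe_index] = True
    else:
        mask[model.snp.probe_index[model.snp.quality_high]] = True
    return mask


def normalize_baf(raw_baf: np.ndarray, raw_logr: np.ndarray,
                  model: ReferenceModel, include_low_quality: bool = False) -> np.ndarray:
    """Normalize raw BAF against the genotype-cluster lines at the observed
    raw log R.

    For each SNP the AA/AB/BB line values v_AA < v_AB < v_BB are anchors of a
    piecewise-linear map to 0 / 0.5 / 1.  A raw BAF on the AB line maps to
    exactly 0.5; midway between the AB and BB lines to 0.75; slightly below
    the AA line to a slightly negative value (no truncation).  SNPs whose
    lines are non-monotone at this log R fall back to the global anchors
    (0.05, 0.5, 0.95); low-quality SNPs are NaN unless included.
    """
    out = np.full(raw_baf.shape, np.nan)
    snp_model = model.snp
    idx = snp_model.probe_index
    keep = snp_model.quality_high if not include_low_quality else np.ones(idx.size, dtype=bool)
    idx = idx[keep]
    rb = raw_baf[idx]
    x = raw_logr[idx]
    observed = ~np.isnan(rb) & ~np.isnan(x)
    v = _evaluate_subset(snp_model, keep, np.nan_to_num(x))
    non_monotone = ~((v[:, 0] < v[:, 1]) & (v[:, 1] < v[:, 2]))
    if (non_monotone & observed).any():
        warnings.warn(
            f"{int((non_monotone & observed).sum())} SNPs with non-monotone "
            "genotype lines fell back to global anchors",
            stacklevel=2,
        )
        v[non_monotone] = GLOBAL_ANCHORS
    lower = rb < v[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(
            lower,
            0.5 * (rb - v[:, 0]) / (v[:, 1] - v[:, 0]),
            0.5 + 0.5 * (rb - v[:, 1]) / (v[:, 2] - v[:, 1]),
        )
    val[~observed] = np.nan
    out[idx] = val
    return out


def _evaluate_subset(snp_model, keep: np.ndarray, x: np.ndarray) -> np.ndarray:
    dx = x[:, None] - snp_model.x_ref[keep, None]
    e = np.minimum(np.exp(np.clip(-snp_model.rate[keep] * dx, -60.0, 60.0)), 1.0)
    return np.clip(snp_model.mu[keep] + snp_model.amp[keep] * e, -0.25, 1.25)
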
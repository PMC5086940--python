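"""Sample identity matching and trio-based prediction accuracy.

BAF is discretized into B-allele presence bits (1 if BAF >= 0.2); pairwise
normalized Hamming dissimilarities between samples' presence vectors form a
distogram that reveals duplicates, relatives, label swaps and contamination.
Trio validation classifies child segments as gain/loss by median-log-ratio
thresholds and checks for a same-direction parental alteration covering at
least 90% of the child alteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

PRESENCE_THRESHOLD = 0.2


@dataclass
class PresenceVector:
    """Per-SNP B-allele presence bits for one sample (NaN where BAF missing)."""

    sample_id: str
    bits: np.ndarray  # float array of 0.0 / 1.0 / NaN


def presence(baf: np.ndarray, threshold: float = PRESENCE_THRESHOLD,
             sample_id: str = "") -> PresenceVector:
    """Discretize BAF into presence bits: 1 if BAF >= threshold else 0.

    The comparison is inclusive at the threshold; non-truncated BAF outside
    [0, 1] discretizes like any other value.  Missing BAF stays NaN and is
    excluded from comparisons.
    """
    baf = np.asarray(baf, dtype=float)
    bits = np.where(np.isnan(baf), np.nan, (baf >= threshold).astype(float))
    return PresenceVector(sample_id=sample_id, bits=bits)


@dataclass
class DissimilarityMatrix:
    """Pairwise sample dissimilarities from presence bits.

    ``normalized`` is the fraction of compared SNPs that differ (the
    distogram statistic); ``raw`` is the plain sum of differences;
    ``informative`` flags pairs sharing enough SNPs to be meaningful.
    """

    sample_ids: list[str]
    normalized: np.ndarray
    raw: np.ndarray
    n_shared: np.ndarray
    informative: np.ndarray
    related_threshold: float = 0.15
    unrelated_threshold: float = 0.25

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.normalized, index=self.sample_ids,
                            columns=self.sample_ids)


def dissimilarity_matrix(vectors: list[PresenceVector], min_shared: int = 100,
                         related_threshold: float = 0.15,
                         unrelated_threshold: float = 0.25) -> DissimilarityMatrix:
    """Normalized Hamming dissimilarity between all sample pairs.

    Only SNPs non-missing in both samples of a pair are compared; pairs with
    fewer than ``min_shared`` shared SNPs are flagged uninformative.
    """
    if len(vectors) < 2:
        raise ValidationError("dissimilarity_matrix needs at least 2 samples")
    bits = np.vstack([v.bits for v in vectors])
    n = bits.shape[0]
    valid = ~np.isnan(bits)
    b = np.nan_to_num(bits)
    # pairwise counts via matrix products on the 0/1 encoding
    shared = (valid.astype(float) @ valid.T.astype(float))
    agree_ones = b @ b.T
    agree_zeros = ((1 - b) * valid) @ ((1 - b) * valid).T
    raw = shared - agree_ones - agree_zeros
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(shared > 0, raw / shared, np.nan)
    np.fill_diagonal(norm, 0.0)
    np.fill_diagonal(raw, 0.0)
    return DissimilarityMatrix(
        sample_ids=[v.sample_id for v in vectors],
        normalized=norm, raw=raw, n_shared=shared.astype(np.int64),
        informative=shared >= min_shared,
        related_threshold=related_threshold,
        unrelated_threshold=unrelated_threshold,
    )


# ---------------------------------------------------------------------------
# Trio validation
# ---------------------------------------------------------------------------

@dataclass
class TrioValidation:
    n_detected: int
    n_validated: int
    validated: list[bool] = field(default_factory=list)
    directions: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        if self.n_detected == 0:
            return float("nan")
        return self.n_validated / self.n_detected


def _classify(segments: pd.DataFrame, gain_thr: float, loss_thr: float) -> pd.DataFrame:
    seg = segments.copy()
    med = seg["median_logratio"]
    seg["direction"] = np.where(med > gain_thr, "gain",
                                np.where(med < loss_thr, "loss", "neutral"))
    return seg[seg["direction"] != "neutral"]


def trio_validate(child_segments: pd.DataFrame, parent1_segments: pd.DataFrame,
                  parent2_segments: pd.DataFrame, gain_thr: float = 0.2,
                  loss_thr: float = -0.3, overlap: float = 0.9) -> TrioValidation:
    """Validate the child's copy number alterations against its parents.

    A child alteration (segment median log ratio > ``gain_thr`` for gains or
    < ``loss_thr`` for losses) is validated when a same-direction parental
    alteration covers at least ``overlap`` of the child alteration's
    base-pair length (in either parent; reciprocal overlap is not required).
    """
    child = _classify(child_segments, gain_thr, loss_thr)
    parts = [
        _classify(seg, gain_thr, loss_thr)
        for seg in (parent1_segments, parent2_segments) if len(seg)
    ]
    parts = [p for p in parts if len(p)]
    parents = (pd.concat(parts, ignore_index=True) if parts
               else _classify(parent1_segments.head(0), gain_thr, loss_thr))
    flags: list[bool] = []
    dirs: list[str] = []
    for _, seg in child.iterrows():
        length = seg["end"] - seg["start"] + 1
        cand = parents[
            (parents["chromosome"] == seg["chromosome"])
            & (parents["direction"] == seg["direction"])
        ]
        ok = False
        for _, par in cand.iterrows():
            ov = min(seg["end"], par["end"]) - max(seg["start"], par["start"]) + 1
            if ov / length >= overlap:
                ok = True
                break
        flags.append(ok)
        dirs.append(seg["direction"])
    return TrioValidation(
        n_detected=len(flags), n_validated=int(np.sum(flags)),
        validated=flags, directions=dirs,
    )
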
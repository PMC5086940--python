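"""Genome segmentation and derived statistics.

Implements circular binary segmentation (CBS) with permutation p-values,
the MAPD / SAPD noise metrics, the two-means allelic-imbalance statistic,
the log-ratio to DNA-abundance calibration, and segment annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .probe_data_io import (
    SEGMENT_COLUMNS,
    ProbeAnnotation,
    SampleTrack,
    empty_segment_table,
)

# ---------------------------------------------------------------------------
# Noise metrics
# ---------------------------------------------------------------------------

def mapd(values: np.ndarray, chromosomes: np.ndarray | None = None) -> float:
    """Median of absolute pairwise differences between genomically adjacent probes.

    ``values`` must be ordered by genome position.  Adjacency never crosses a
    chromosome boundary; NaN probes are dropped before forming pairs.
    """
    values = np.asarray(values, dtype=float)
    if chromosomes is None:
        x = values[~np.isnan(values)]
        if x.size < 2:
            raise ValidationError("MAPD needs at least 2 non-missing probes")
        return float(np.median(np.abs(np.diff(x))))
    diffs = []
    chromosomes = np.asarray(chromosomes)
    # groups of equal chromosome, preserving genome order
    change = np.flatnonzero(chromosomes[1:] != chromosomes[:-1]) + 1
    for chunk in np.split(values, change):
        x = chunk[~np.isnan(chunk)]
        if x.size >= 2:
            diffs.append(np.abs(np.diff(x)))
    if not diffs:
        raise ValidationError("MAPD needs at least 2 non-missing probes on one chromosome")
    return float(np.median(np.concatenate(diffs)))


def per_chromosome_medians(values: np.ndarray, chromosomes: np.ndarray,
                           autosomes_only: bool = True) -> dict[str, float]:
    from .probe_data_io import is_autosome

    out: dict[str, float] = {}
    for chrom in pd.unique(chromosomes):
        if autosomes_only and not is_autosome(str(chrom)):
            continue
        x = values[chromosomes == chrom]
        x = x[~np.isnan(x)]
        if x.size:
            out[str(chrom)] = float(np.median(x))
    return out


def delta_from_extreme_chromosomes(chrom_medians: dict[str, float] | np.ndarray) -> float:
    """Copy-number effect size: spread between the most extreme autosome medians."""
    vals = np.asarray(list(chrom_medians.values()) if isinstance(chrom_medians, dict)
                      else chrom_medians, dtype=float)
    if vals.size < 1:
        raise ValidationError("no chromosome medians")
    return float(np.max(vals) - np.min(vals))


@dataclass
class SapdResult:
    value: float
    excluded: bool = False
    undefined: bool = False


def sapd(mapd_value: float, delta: float, mean_delta: float,
         exclusion_threshold: float = 0.2) -> SapdResult:
    """Signal-adjusted pairwise difference: MAPD scaled by Δ relative to the
    cross-tool mean Δ̄.

    Samples whose mean Δ̄ across tools falls below the exclusion threshold
    carry too little copy-number signal for the adjustment and are excluded.
    """
    if mean_delta < exclusion_threshold:
        return SapdResult(value=float("nan"), excluded=True)
    if delta <= 0:
        return SapdResult(value=float("nan"), undefined=True)
    return SapdResult(value=float(mapd_value * mean_delta / delta))


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _max_arc_stat(x: np.ndarray, min_probes: int) -> tuple[float, int, int]:
    """Maximal mean-shift statistic over circular arcs of ``x``.

    Returns (statistic, i, j) for the arc x[i:j].  The statistic is the
    |arc sum - expected| / sqrt(k(n-k)/n) form, a monotone transform of the
    two-sample t statistic under fixed total variance, which is sufficient
    for a permutation test.
    """
    n = x.size
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]
    best = (-1.0, 0, n)
    kmin = max(1, min_probes)
    for k in range(kmin, n - kmin + 1):
        d = s[k:] - s[:n - k + 1]          # arc sums of length k, start i=0..n-k
        z = np.abs(d - total * (k / n)) / np.sqrt(k * (n - k) / n)
        i = int(np.argmax(z))
        if z[i] > best[0]:
            best = (float(z[i]), i, i + k)
    return best


def _arc_significant(x: np.ndarray, min_probes: int, alpha: float,
                     n_perm: int, rng: np.random.Generator) -> tuple[bool, int, int]:
    n = x.size
    if n < 2 * max(1, min_probes):
        return False, 0, n
    obs, i, j = _max_arc_stat(x, min_probes)
    if obs <= 0:
        return False, 0, n
    # permutation p-value with early stopping: once enough permuted maxima
    # exceed the observed one, p < alpha is no longer reachable
    max_exceed = int(np.floor(alpha * (n_perm + 1))) - 1  # exceed count must stay <= this
    exceed = 0
    for _ in range(n_perm):
        perm_stat, _, _ = _max_arc_stat(rng.permutation(x), min_probes)
        if perm_stat >= obs:
            exceed += 1
            if exceed > max_exceed:
                return False, i, j
    p = (1 + exceed) / (n_perm + 1)
    return p < alpha, i, j


def _cbs_recurse(x: np.ndarray, offset: int, min_probes: int, alpha: float,
                 n_perm: int, rng: np.random.Generator, out: list[int]) -> None:
    sig, i, j = _arc_significant(x, min_probes, alpha, n_perm, rng)
    if not sig:
        return
    cuts = [c for c in (i, j) if 0 < c < x.size]
    pieces = np.split(x, cuts)
    for c in cuts:
        out.append(offset + c)
    start = 0
    for piece in pieces:
        _cbs_recurse(piece, offset + start, min_probes, alpha, n_perm, rng, out)
        start += piece.size


def cbs_segment(values: np.ndarray, alpha: float = 0.01, min_probes: int = 10,
                n_perm: int = 100, seed: int | np.random.Generator = 0) -> list[int]:
    """Breakpoint indices from circular binary segmentation of one chromosome.

    Recursively finds the arc maximizing the mean-shift statistic and keeps
    the split when a within-segment permutation test gives p < ``alpha``.
    Splits that would create a segment shorter than ``min_probes`` are not
    considered, and a final merge pass removes any remaining short segment.
    A breakpoint index b means a change between probes b-1 and b.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("cbs_segment requires a gap-free (non-NaN) vector")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bps: list[int] = []
    _cbs_recurse(x, 0, min_probes, alpha, n_perm, rng, bps)
    bps = sorted(set(bps))
    return _merge_short_segments(x, bps, min_probes)


def _merge_short_segments(x: np.ndarray, bps: list[int], min_probes: int) -> list[int]:
    bps = list(bps)
    while True:
        bounds = [0] + bps + [x.size]
        lengths = np.diff(bounds)
        short = np.flatnonzero(lengths < min_probes)
        if short.size == 0 or not bps:
            return bps
        k = int(short[0])
        # drop the boundary towards the neighbour with the closer median
        seg = x[bounds[k]:bounds[k + 1]]
        med = np.median(seg)
        left = abs(np.median(x[bounds[k - 1]:bounds[k]]) - med) if k > 0 else np.inf
        right = abs(np.median(x[bounds[k + 1]:bounds[k + 2]]) - med) if k < len(lengths) - 1 else np.inf
        drop = bounds[k] if left <= right else bounds[k + 1]
        bps.remove(drop)


# ---------------------------------------------------------------------------
# Allelic imbalance and abundance calibration
# ---------------------------------------------------------------------------

def _two_means(v: np.ndarray, max_iter: int = 100) -> tuple[float, float, bool]:
    """Deterministic 1-D 2-means initialized at the 25th/75th percentiles.

    Returns (low, high, split) where split is False when the data collapse
    into a single cluster.
    """
    c1, c2 = np.percentile(v, [25, 75])
    if c2 - c1 <= 1e-12:
        return float(c1), float(c2), False
    for _ in range(max_iter):
        assign = np.abs(v - c1) <= np.abs(v - c2)
        if assign.all() or not assign.any():
            return float(np.mean(v)), float(np.mean(v)), False
        n1, n2 = float(np.mean(v[assign])), float(np.mean(v[~assign]))
        if abs(n1 - c1) < 1e-12 and abs(n2 - c2) < 1e-12:
            break
        c1, c2 = n1, n2
    return (c1, c2, True) if c1 <= c2 else (c2, c1, True)


@dataclass
class AiResult:
    value: float
    reliable: bool
    c_het: float = float("nan")
    c_hom: float = float("nan")


def allelic_imbalance(baf: np.ndarray, min_snps: int = 20) -> AiResult:
    """Allelic imbalance of a segment from its SNP BAF values.

    |BAF - 0.5| is clustered on two means (heterozygous and homozygous
    bands); AI is the ratio of the heterozygous to the homozygous center.
    Balanced segments give values just above 0, fully homozygous segments 1.
    """
    baf = np.asarray(baf, dtype=float)
    baf = baf[~np.isnan(baf)]
    if baf.size == 0:
        raise ValidationError("allelic_imbalance: empty BAF input")
    v = np.abs(baf - 0.5)
    c_het, c_hom, split = _two_means(v)
    reliable = baf.size >= min_snps
    if split:
        # guard against splitting a single band in half: merge when the
        # center separation is within the within-cluster spread
        assign = np.abs(v - c_het) <= np.abs(v - c_hom)
        within = np.concatenate([v[assign] - c_het, v[~assign] - c_hom])
        within_sd = float(np.sqrt(np.mean(within ** 2)))
        if c_hom - c_het <= 3.0 * within_sd:
            split = False
            c_het = c_hom = float(np.mean(v))
    if not split:
        # single band: homozygous-only segments sit near 0.5, balanced
        # het-only degenerate input sits near 0
        value = 1.0 if c_hom >= 0.25 else 0.0
        return AiResult(value=value, reliable=reliable, c_het=c_het, c_hom=c_hom)
    if c_hom <= 1e-12:
        return AiResult(value=0.0, reliable=reliable, c_het=c_het, c_hom=c_hom)
    return AiResult(value=float(c_het / c_hom), reliable=reliable, c_het=c_het, c_hom=c_hom)


def expected_allelic_imbalance(h_a: float, h_b: float) -> float:
    """Expected AI for parental homologue copy numbers (H_A, H_B)."""
    if h_a < 0 or h_b < 0 or (h_a + h_b) == 0:
        raise ValidationError("homologue copy numbers must be >= 0 and not both 0")
    return abs(h_a - h_b) / (h_a + h_b)


_CAL_LOGR = np.array([-0.6, 0.0, 0.35, 0.6])
_CAL_ABUND = np.array([0.5, 1.0, 1.5, 2.0])


def calibrate_abundance(median_logratio):
    """Relative DNA abundance from segment median log ratio.

    Monotone piecewise-linear interpolation through the empirical anchors
    50% loss -> log ratio -0.6, neutral -> 0, 50% gain -> 0.35, 100% gain ->
    0.6; linear extrapolation with the edge slopes beyond the outer anchors.
    """
    x = np.asarray(median_logratio, dtype=float)
    y = np.interp(x, _CAL_LOGR, _CAL_ABUND)
    lo_slope = (_CAL_ABUND[1] - _CAL_ABUND[0]) / (_CAL_LOGR[1] - _CAL_LOGR[0])
    hi_slope = (_CAL_ABUND[-1] - _CAL_ABUND[-2]) / (_CAL_LOGR[-1] - _CAL_LOGR[-2])
    y = np.where(x < _CAL_LOGR[0], _CAL_ABUND[0] + (x - _CAL_LOGR[0]) * lo_slope, y)
    y = np.where(x > _CAL_LOGR[-1], _CAL_ABUND[-1] + (x - _CAL_LOGR[-1]) * hi_slope, y)
    return float(y) if np.isscalar(median_logratio) else y


# ---------------------------------------------------------------------------
# Track segmentation and annotation
# ---------------------------------------------------------------------------

def segment_track(track: SampleTrack, annotation: ProbeAnnotation,
                  alpha: float = 0.01, min_probes: int = 10, n_perm: int = 100,
                  seed: int = 0, snp_mask: np.ndarray | None = None,
                  min_ai_snps: int = 20) -> pd.DataFrame:
    """Segment a normalized track chromosome by chromosome and annotate
    each segment with its median log ratio, probe count and allelic imbalance."""
    rng = np.random.default_rng(seed)
    chroms = annotation.chromosomes
    positions = annotation.positions
    lr = track.logratio
    baf = track.baf
    if snp_mask is None:
        snp_mask = annotation.snp_mask
    rows = []
    change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = np.concatenate(([0], change, [len(chroms)]))
    for ci in range(len(starts) - 1):
        lo, hi = int(starts[ci]), int(starts[ci + 1])
        chrom = chroms[lo]
        idx = np.arange(lo, hi)
        valid = ~np.isnan(lr[idx])
        idx = idx[valid]
        if idx.size < 2:
            continue
        x = lr[idx]
        bps = cbs_segment(x, alpha=alpha, min_probes=min_probes, n_perm=n_perm, seed=rng)
        bounds = [0] + bps + [idx.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_idx = idx[a:b]
            seg_baf = baf[seg_idx][snp_mask[seg_idx]]
            seg_baf = seg_baf[~np.isnan(seg_baf)]
            ai = allelic_imbalance(seg_baf, min_snps=min_ai_snps).value if seg_baf.size else float("nan")
            rows.append(
                {
                    "sample_id": track.sample_id,
                    "chromosome": str(chrom),
                    "start": int(positions[seg_idx[0]]),
                    "end": int(positions[seg_idx[-1]]),
                    "n_probes": int(seg_idx.size),
                    "median_logratio": float(np.median(lr[seg_idx])),
                    "allelic_imbalance": ai,
                    "genes": "",
                    "cytoband": "",
                }
            )
    if not rows:
        return empty_segment_table()
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def fixed_window_segments(track: SampleTrack, annotation: ProbeAnnotation,
                          window_bp: int = 1_000_000,
                          snp_mask: np.ndarray | None = None,
                          min_ai_snps: int = 20) -> pd.DataFrame:
    """Fixed genomic windows (~1 Mb) with median log ratio and AI, used for
    the per-chromosome scatter statistics."""
    chroms = annotation.chromosomes
    positions = annotation.positions
    if snp_mask is None:
        snp_mask = annotation.snp_mask
    win = np.floor_divide(positions - 1, window_bp)
    rows = []
    df = pd.DataFrame({"chrom": chroms, "win": win, "idx": np.arange(len(chroms))})
    for (chrom, w), grp in df.groupby(["chrom", "win"], sort=False):
        seg_idx = grp["idx"].to_numpy()
        lr = track.logratio[seg_idx]
        lr = lr[~np.isnan(lr)]
        if lr.size == 0:
            continue
        seg_baf = track.baf[seg_idx][snp_mask[seg_idx]]
        seg_baf = seg_baf[~np.isnan(seg_baf)]
        ai = allelic_imbalance(seg_baf, min_snps=min_ai_snps).value if seg_baf.size else float("nan")
        rows.append(
            {
                "sample_id": track.sample_id,
                "chromosome": str(chrom),
                "start": int(w * window_bp + 1),
                "end": int((w + 1) * window_bp),
                "n_probes": int(lr.size),
                "median_logratio": float(np.median(lr)),
                "allelic_imbalance": ai,
                "genes": "",
                "cytoband": "",
            }
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS) if rows else empty_segment_table()


def annotate_segments(segments: pd.DataFrame, gene_bed: pd.DataFrame | None = None,
                      cytoband_bed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fill the ``genes`` and ``cytoband`` columns from 1-based annotation tables
    (as returned by :func:`rawkit.probe_data_io.read_bed`).

    Genes overlapping a segment by any amount are listed; a gene straddling a
    breakpoint appears in both segments.  The cytoband field renders the
    band range of the segment as e.g. ``p11.2-q21.1``.
    """
    out = segments.copy()
    genes_col = []
    cyto_col = []
    for _, seg in out.iterrows():
        genes = ""
        cyto = ""
        if gene_bed is not None and len(gene_bed):
            hit = gene_bed[
                (gene_bed["chromosome"] == seg["chromosome"])
                & (gene_bed["start"] <= seg["end"])
                & (gene_bed["end"] >= seg["start"])
            ]
            genes = ",".join(hit["name"].tolist())
        if cytoband_bed is not None and len(cytoband_bed):
            hit = cytoband_bed[
                (cytoband_bed["chromosome"] == seg["chromosome"])
                & (cytoband_bed["start"] <= seg["end"])
                & (cytoband_bed["end"] >= seg["start"])
            ].sort_values("start")
            if len(hit):
                first, last = hit["name"].iloc[0], hit["name"].iloc[-1]
                cyto = first if first == last else f"{first}-{last}"
        genes_col.append(genes)
        cyto_col.append(cyto)
    out["genes"] = genes_col
    out["cytoband"] = cyto_col
    return out
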
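"""Data model and tabular I/O for probe annotation, intensities, tracks and segments.

All genomic coordinates are 1-based inclusive internally.  BED inputs
(genes, cytobands) are converted from 0-based half-open on read.  Probes
missing from a sample are carried as NaN and excluded from medians and
pairwise differences downstream, never imputed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, FormatError, ValidationError

SNP = "SNP"
NONSNP = "NONSNP"

_AUTOSOMES = {str(i) for i in range(1, 23)}


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X, Y, then anything else lexically."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (int(c), "")
    order = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (order.get(c, 26), c)


def is_autosome(chrom) -> bool | np.ndarray:
    if isinstance(chrom, str):
        return chrom.removeprefix("chr") in _AUTOSOMES
    return np.array([str(c).removeprefix("chr") in _AUTOSOMES for c in chrom])


@dataclass
class ProbeAnnotation:
    """Static per-probe genomic and chemistry metadata.

    The backing frame is sorted by (chromosome, position) and carries columns
    ``probe_id, chromosome, position, probe_class, gc_content,
    fragment_length, is_autosome``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        if (t["position"] < 1).any():
            row = int(np.argmax(t["position"].to_numpy() < 1))
            raise ValidationError(f"position < 1 at row {row}")
        gc = t["gc_content"].to_numpy()
        if ((gc < 0) | (gc > 1)).any():
            row = int(np.argmax((gc < 0) | (gc > 1)))
            raise ValidationError(f"gc_content outside [0, 1] at row {row}")
        if (t["fragment_length"] < 1).any():
            row = int(np.argmax(t["fragment_length"].to_numpy() < 1))
            raise ValidationError(f"fragment_length < 1 at row {row}")
        bad = ~t["probe_class"].isin([SNP, NONSNP])
        if bad.any():
            raise ValidationError(
                f"unknown probe_class {t.loc[bad, 'probe_class'].iloc[0]!r}"
            )
        key = t["chromosome"].map(chromosome_sort_key)
        order = np.lexsort((t["position"].to_numpy(), key.to_numpy()))
        t = t.iloc[order].reset_index(drop=True)
        t["is_autosome"] = is_autosome(t["chromosome"].to_numpy())
        self.table = t

    # -- convenience views -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def snp_mask(self) -> np.ndarray:
        return (self.table["probe_class"] == SNP).to_numpy()

    @property
    def autosome_mask(self) -> np.ndarray:
        return self.table["is_autosome"].to_numpy()

    @property
    def gc_content(self) -> np.ndarray:
        return self.table["gc_content"].to_numpy()

    @property
    def fragment_length(self) -> np.ndarray:
        return self.table["fragment_length"].to_numpy()

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update("\n".join(self.probe_ids).encode())
        h.update(self.positions.astype(np.int64).tobytes())
        h.update("\n".join(self.chromosomes).encode())
        return h.hexdigest()

    def index_of(self, probe_ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Series(np.arange(self.n_probes), index=self.probe_ids)
        return lookup.reindex(probe_ids).to_numpy()

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeAnnotation) and self.table.equals(other.table)


@dataclass
class IntensitySet:
    """One sample's raw allele intensities aligned to a :class:`ProbeAnnotation`.

    ``a`` holds allele-A intensity for SNP probes and the single intensity
    for non-SNP probes; ``b`` holds allele-B intensity (NaN for non-SNP).
    Missing probes are NaN in both.
    """

    sample_id: str
    a: np.ndarray
    b: np.ndarray

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.a)


@dataclass
class SampleTrack:
    """A sample's normalized log ratio and BAF, aligned to the annotation."""

    sample_id: str
    logratio: np.ndarray
    baf: np.ndarray
    mapd: float = float("nan")
    raw_mapd: float = float("nan")
    median_hyb: float = float("nan")
    mds_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["probe_id", "chromosome", "position", "class", "gc", "fragment_length"]


def read_annotation(path) -> ProbeAnnotation:
    """Read a tab-separated probe annotation table.

    Expected header: ``probe_id  chromosome  position  class  gc
    fragment_length``.  Rows are re-sorted by (chromosome, position).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} missing columns {missing}")
    table = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "chromosome": df["chromosome"],
            "position": df["position"].astype(np.int64),
            "probe_class": df["class"],
            "gc_content": df["gc"].astype(float),
            "fragment_length": df["fragment_length"].astype(np.int64),
        }
    )
    return ProbeAnnotation(table)


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    t = annotation.table
    out = pd.DataFrame(
        {
            "probe_id": t["probe_id"],
            "chromosome": t["chromosome"],
            "position": t["position"],
            "class": t["probe_class"],
            "gc": t["gc_content"],
            "fragment_length": t["fragment_length"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_intensities(path, annotation: ProbeAnnotation, sample_id: str | None = None,
                     min_coverage: float = 0.99) -> IntensitySet:
    """Read a tab-separated intensity table ``probe_id  A  B``.

    ``B`` is empty for non-SNP probes.  Probes absent from the table are
    flagged missing (NaN); unknown probe ids are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    for col in ("probe_id", "A"):
        if col not in df.columns:
            raise FormatError(f"intensity file {path} missing column {col!r}")
    if "B" not in df.columns:
        df["B"] = np.nan
    if sample_id is None:
        sample_id = str(getattr(path, "stem", None) or str(path).rsplit("/", 1)[-1].removesuffix(".tsv"))
    return intensities_from_frame(df, annotation, sample_id, min_coverage=min_coverage)


def intensities_from_frame(df: pd.DataFrame, annotation: ProbeAnnotation,
                           sample_id: str, min_coverage: float = 0.99) -> IntensitySet:
    a_vals = df["A"].astype(float).to_numpy()
    b_vals = df["B"].astype(float).to_numpy()
    if (a_vals <= 0).any() or (np.nan_to_num(b_vals, nan=1.0) <= 0).any():
        bad = np.flatnonzero((a_vals <= 0) | (np.nan_to_num(b_vals, nan=1.0) <= 0))[0]
        raise ValidationError(f"non-positive intensity at row {int(bad)}")
    idx = annotation.index_of(df["probe_id"].to_numpy())
    unknown = np.isnan(idx)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} intensity rows with unknown probe ids ignored",
            stacklevel=2,
        )
        idx, a_vals, b_vals = idx[~unknown], a_vals[~unknown], b_vals[~unknown]
    a = np.full(annotation.n_probes, np.nan)
    b = np.full(annotation.n_probes, np.nan)
    ii = idx.astype(int)
    a[ii] = a_vals
    b[ii] = b_vals
    snp = annotation.snp_mask
    if np.isnan(b[ii][snp[ii]]).any():
        raise ValidationError("SNP probe with missing B intensity")
    b[~snp] = np.nan
    coverage = 1.0 - np.isnan(a).mean()
    if coverage < min_coverage:
        raise CoverageError(
            f"sample {sample_id}: coverage {coverage:.3f} below {min_coverage}"
        )
    return IntensitySet(sample_id=sample_id, a=a, b=b)


def write_intensities(iset: IntensitySet, annotation: ProbeAnnotation, path) -> None:
    keep = ~iset.missing_mask
    out = pd.DataFrame(
        {
            "probe_id": annotation.probe_ids[keep],
            "A": iset.a[keep],
            "B": iset.b[keep],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- vendor raw-file adapter hook ------------------------------------------

_INTENSITY_READERS: dict[str, Callable[..., IntensitySet]] = {"tsv": read_intensities}


def register_intensity_reader(name: str, reader: Callable[..., IntensitySet]) -> None:
    """Register an adapter producing an IntensitySet from a vendor file.

    Any callable ``reader(path, annotation, sample_id=None)`` may be
    registered; vendor binary parsing itself is out of scope here.
    """
    _INTENSITY_READERS[name] = reader


def load_intensities(path, annotation: ProbeAnnotation, fmt: str = "tsv", **kw) -> IntensitySet:
    try:
        reader = _INTENSITY_READERS[fmt]
    except KeyError:
        raise FormatError(f"no intensity reader registered for format {fmt!r}") from None
    return reader(path, annotation, **kw)


# -- sample tracks ----------------------------------------------------------

def write_track(track: SampleTrack, annotation: ProbeAnnotation, path) -> None:
    """Write a SampleTrack to TSV with its QC scalars in ``#`` header lines."""
    meta = {
        "sample_id": track.sample_id,
        "mapd": track.mapd,
        "raw_mapd": track.raw_mapd,
        "median_hyb": track.median_hyb,
        "mds_scores": list(np.asarray(track.mds_scores, dtype=float)),
    }
    with open(path, "w") as fh:
        fh.write(f"#rawkit_track {json.dumps(meta)}\n")
        pd.DataFrame(
            {
                "probe_id": annotation.probe_ids,
                "chromosome": annotation.chromosomes,
                "position": annotation.positions,
                "logratio": track.logratio,
                "baf": track.baf,
            }
        ).to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_track(path, annotation: ProbeAnnotation | None = None) -> SampleTrack:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#rawkit_track "):
            raise FormatError(f"{path} is not a rawkit track file")
        meta = json.loads(header[len("#rawkit_track "):])
        df = pd.read_csv(fh, sep="\t", dtype={"probe_id": str, "chromosome": str})
    if annotation is not None and not np.array_equal(df["probe_id"].to_numpy(), annotation.probe_ids):
        raise ValidationError("track probe ids do not match annotation")
    return SampleTrack(
        sample_id=meta["sample_id"],
        logratio=df["logratio"].to_numpy(float),
        baf=df["baf"].to_numpy(float),
        mapd=float(meta["mapd"]),
        raw_mapd=float(meta["raw_mapd"]),
        median_hyb=float(meta["median_hyb"]),
        mds_scores=np.asarray(meta["mds_scores"], dtype=float),
    )


def track_chromosomes(path) -> pd.DataFrame:
    """Return the positional columns of a track file (probe_id, chromosome, position)."""
    with open(path) as fh:
        fh.readline()
        df = pd.read_csv(fh, sep="\t", dtype={"probe_id": str, "chromosome": str})
    return df


# -- segment tables ---------------------------------------------------------

SEGMENT_COLUMNS = [
    "sample_id", "chromosome", "start", "end", "n_probes",
    "median_logratio", "allelic_imbalance", "genes", "cytoband",
]


def empty_segment_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        SEGMENT_COLUMNS,
        [str, str, np.int64, np.int64, np.int64, float, float, str, str],
    )})


def write_segment_table(segments: pd.DataFrame, path) -> None:
    """Write a segment table to TSV; empty gene/cytoband fields stay empty."""
    out = segments.copy()
    for col in SEGMENT_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col in ("genes", "cytoband") else np.nan
    out = out[SEGMENT_COLUMNS]
    out["genes"] = out["genes"].fillna("")
    out["cytoband"] = out["cytoband"].fillna("")
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segment_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "chromosome": str, "genes": str, "cytoband": str},
        keep_default_na=False, na_values=["nan", "NaN"],
    )
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment table {path} missing columns {missing}")
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["n_probes"] = df["n_probes"].astype(np.int64)
        df["median_logratio"] = df["median_logratio"].astype(float)
        df["allelic_imbalance"] = df["allelic_imbalance"].astype(float)
    else:
        df = empty_segment_table()
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive coordinates.

    Returns columns ``chromosome, start, end, name``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chromosome", "start", "end", "name"],
                         dtype={"chromosome": str, "name": str})
    except ValueError as exc:
        raise FormatError(f"malformed BED file {path}: {exc}") from exc
    if len(df) and ((df["end"] <= df["start"]).any() or (df["start"] < 0).any()):
        raise FormatError(f"malformed BED intervals in {path}")
    df["start"] = df["start"].astype(np.int64) + 1  # 0-based half-open -> 1-based incl.
    df["end"] = df["end"].astype(np.int64)
    return df
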
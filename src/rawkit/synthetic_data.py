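"""Synthetic SNP-array data with full ground truth.

The generator emulates the statistical structure the pipeline corrects or
estimates: three-cluster genotype structure of raw BAF whose clusters
converge toward 0.5 as hybridization drops (background hybridization),
saturating hybridization linking DNA abundance to intensity, GC-content and
fragment-length waviness, sample-specific latent noise components, and
allele-specific copy number alterations at arbitrary cell fractions.

Intensity model per probe: the total concentration (abundance x probe
affinity) passes through a Hill saturation curve with additive background;
the default Hill parameters are calibrated so the log2 intensity response at
0.5x / 1.5x / 2x abundance matches the standard empirical calibration
anchors (-0.6 / 0.35 / 0.6).  Allele intensities split the total Euclidean
magnitude on the quarter circle, so the genotype affects raw BAF without
mechanically coupling into log R; genotype/log-ratio coupling is injected as
its own explicit term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .probe_data_io import NONSNP, SNP, IntensitySet, ProbeAnnotation


@dataclass(frozen=True)
class CnvSpec:
    """One allele-specific copy number alteration: homologue copy numbers
    (h_a, h_b) over [start, end] on a chromosome, at a cell fraction."""

    chromosome: str
    start: int
    end: int
    h_a: float = 1.0
    h_b: float = 1.0
    cell_fraction: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    n_probes: int = 20_000
    snp_fraction: float = 0.85
    n_reference_samples: int = 20
    n_chromosomes: int = 4
    chromosome_length: int = 100_000_000
    include_x: bool = False
    # raw BAF genotype structure
    baf_cluster_centers: tuple[float, float, float] = (0.05, 0.5, 0.95)
    baf_cluster_spread: float = 0.015  # raw-BAF sd of the het cluster at high signal
    background_imbalance: float = 0.4   # per-probe A/B split range of background hybridization
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    # saturating hybridization (Hill curve), calibrated to the abundance anchors
    saturation_imax: float = 2000.0
    saturation_k: float = 20.0
    saturation_hill: float = 0.8192
    saturation_background: float = 0.0228  # fraction of I_max
    affinity_log2_sd: float = 0.5
    # sample-specific systematic variation
    gc_bias_amplitude: float = 0.3
    fraglen_bias_amplitude: float = 0.2
    n_latent_components: int = 2
    latent_score_sd: float = 0.1         # typical query samples
    panel_latent_score_sd: float = 0.3   # reference panels span wider technical variation
    genotype_lr_slope: float = 0.1
    brightness_sd: float = 0.2
    noise_sd: float = 0.10
    # alterations applied to query samples
    cnvs: tuple[CnvSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in ("baf_cluster_spread", "gc_bias_amplitude", "noise_sd",
                     "fraglen_bias_amplitude", "latent_score_sd", "brightness_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if not 0 < self.snp_fraction <= 1:
            raise ConfigurationError("snp_fraction must be in (0, 1]")
        for cnv in self.cnvs:
            if not 0 < cnv.cell_fraction <= 1:
                raise ConfigurationError("cell fraction must be in (0, 1]")
            if cnv.h_a < 0 or cnv.h_b < 0:
                raise ConfigurationError("homologue copy numbers must be >= 0")


@dataclass
class SharedTruth:
    """Latent structure shared by every sample drawn from one configuration."""

    annotation: ProbeAnnotation
    snp_index: np.ndarray          # indices of SNP probes
    allele_freq: np.ndarray        # per SNP B-allele population frequency
    affinity: np.ndarray           # per-probe concentration multiplier
    latent_loadings: np.ndarray    # n_probes x k, unit per-probe RMS
    gc_shape: np.ndarray           # per-probe GC bias shape in [-1, 1]
    fraglen_shape: np.ndarray      # per-probe fragment-length bias shape
    bg_split: np.ndarray           # per SNP probe: B-channel share of background


@dataclass
class SampleTruth:
    sample_id: str
    sex: str
    genotypes: np.ndarray          # per SNP: number of B alleles (0/1/2)
    phase: np.ndarray              # per SNP: homologue carrying B when het (0/1)
    brightness: float
    scores: np.ndarray
    gc_coef: float
    fraglen_coef: float
    noise_scale: float
    cnvs: tuple[CnvSpec, ...]
    abundance: np.ndarray          # per-probe true relative DNA abundance (diploid = 2)


@dataclass
class GroundTruth:
    shared: SharedTruth
    samples: list[SampleTruth] = field(default_factory=list)


@dataclass
class PanelResult:
    annotation: ProbeAnnotation
    samples: list[IntensitySet]
    sexes: list[str]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Shared structure
# ---------------------------------------------------------------------------

def make_shared(config: GeneratorConfig, rng: np.random.Generator) -> SharedTruth:
    config.validate()
    n = config.n_probes
    n_chrom = config.n_chromosomes
    chrom_names = [str(i + 1) for i in range(n_chrom)]
    if config.include_x:
        chrom_names[-1] = "X"
    per_chrom = np.full(n_chrom, n // n_chrom)
    per_chrom[: n % n_chrom] += 1
    chroms, positions, gc = [], [], []
    for name, cnt in zip(chrom_names, per_chrom):
        pos = np.sort(rng.choice(config.chromosome_length, size=cnt, replace=False)) + 1
        phase = rng.uniform(0, 2 * np.pi)
        g = 0.45 + 0.12 * np.sin(2 * np.pi * pos / 3.0e7 + phase) + rng.normal(0, 0.02, cnt)
        chroms.append(np.full(cnt, name))
        positions.append(pos)
        gc.append(np.clip(g, 0.25, 0.68))
    chroms = np.concatenate(chroms)
    positions = np.concatenate(positions)
    gc = np.concatenate(gc)
    fraglen = np.clip(np.round(np.exp(rng.normal(np.log(700), 0.45, n))), 100, 4000).astype(int)
    is_snp = rng.random(n) < config.snp_fraction
    classes = np.where(is_snp, SNP, NONSNP)
    annotation = ProbeAnnotation(pd.DataFrame({
        "probe_id": [f"P{i:07d}" for i in range(n)],
        "chromosome": chroms, "position": positions, "probe_class": classes,
        "gc_content": gc, "fragment_length": fraglen,
    }))
    # generation shuffled annotation into genome order; recover aligned arrays
    snp_index = np.flatnonzero(annotation.snp_mask)
    n_snp = snp_index.size
    a, b = config.allele_freq_beta
    allele_freq = np.clip(rng.beta(a, b, n_snp), 0.005, 0.995)
    affinity = 2.0 ** rng.normal(0.0, config.affinity_log2_sd, n)
    k = config.n_latent_components
    loadings = rng.normal(0.0, 1.0, (n, max(k, 1)))[:, :k] if k else np.zeros((n, 0))
    if k:
        q, _ = np.linalg.qr(loadings)
        loadings = q / np.sqrt(np.mean(q ** 2, axis=0, keepdims=True))

    def pct_shape(cov: np.ndarray) -> np.ndarray:
        ranks = np.argsort(np.argsort(cov, kind="stable"), kind="stable")
        return np.sin(2 * np.pi * (ranks + 0.5) / cov.size)

    bg_split = 0.5 + config.background_imbalance * rng.uniform(-1.0, 1.0, n_snp)
    bg_split = np.clip(bg_split, 0.05, 0.95)
    return SharedTruth(
        annotation=annotation,
        snp_index=snp_index,
        allele_freq=allele_freq,
        affinity=affinity,
        latent_loadings=loadings,
        gc_shape=pct_shape(annotation.gc_content),
        fraglen_shape=pct_shape(annotation.fragment_length.astype(float)),
        bg_split=bg_split,
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def draw_genotypes(shared: SharedTruth, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg genotype draw: number of B alleles per SNP."""
    return rng.binomial(2, shared.allele_freq).astype(np.int8)


def child_genotypes(father: np.ndarray, mother: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Mendelian child genotypes: one transmitted allele from each parent."""
    from_f = (rng.random(father.size) < father / 2.0).astype(np.int8)
    from_m = (rng.random(mother.size) < mother / 2.0).astype(np.int8)
    return from_f + from_m


# ---------------------------------------------------------------------------
# Intensity synthesis
# ---------------------------------------------------------------------------

def _homologue_counts(config: GeneratorConfig, shared: SharedTruth, sex: str,
                      cnvs: tuple[CnvSpec, ...]) -> tuple[np.ndarray, np.ndarray]:
    ann = shared.annotation
    hap1 = np.ones(ann.n_probes)
    hap2 = np.ones(ann.n_probes)
    if sex.upper().startswith("M"):
        hap2[ann.chromosomes == "X"] = 0.0
    for cnv in cnvs:
        region = ((ann.chromosomes == cnv.chromosome)
                  & (ann.positions >= cnv.start) & (ann.positions <= cnv.end))
        cf = cnv.cell_fraction
        hap1[region] = cf * cnv.h_a + (1 - cf) * hap1[region]
        hap2[region] = cf * cnv.h_b + (1 - cf) * hap2[region]
    return hap1, hap2


def synthesize_sample(config: GeneratorConfig, shared: SharedTruth,
                      rng: np.random.Generator, sample_id: str, *,
                      genotypes: np.ndarray | None = None, sex: str = "F",
                      cnvs: tuple[CnvSpec, ...] = (),
                      scores: np.ndarray | None = None,
                      brightness: float | None = None,
                      gc_coef: float | None = None,
                      fraglen_coef: float | None = None,
                      noise_scale: float | None = None) -> tuple[IntensitySet, SampleTruth]:
    """Draw one sample's allele intensities from the generative model."""
    ann = shared.annotation
    n = ann.n_probes
    sidx = shared.snp_index
    if genotypes is None:
        genotypes = draw_genotypes(shared, rng)
    phase = (rng.random(sidx.size) < 0.5).astype(np.int8)
    k = config.n_latent_components
    if scores is None:
        scores = rng.normal(0.0, config.latent_score_sd, k) if k else np.zeros(0)
    scores = np.asarray(scores, dtype=float)
    if brightness is None:
        brightness = float(rng.normal(0.0, config.brightness_sd))
    if gc_coef is None:
        gc_coef = float(rng.normal(1.0, 0.3))
    if fraglen_coef is None:
        fraglen_coef = float(rng.normal(1.0, 0.3))
    if noise_scale is None:
        noise_scale = float(rng.uniform(0.85, 1.25))

    hap1, hap2 = _homologue_counts(config, shared, sex, cnvs)
    abundance = hap1 + hap2

    # allele copy numbers at SNP probes
    n_b = np.zeros(sidx.size)
    het = genotypes == 1
    n_b[genotypes == 2] = abundance[sidx][genotypes == 2]
    n_b[het] = np.where(phase[het] == 0, hap1[sidx][het], hap2[sidx][het])
    n_a = abundance[sidx] - n_b

    # cross-hybridization sets the asymptotic cluster centers
    c_aa, _, c_bb = config.baf_cluster_centers
    g_b = c_aa / (1.0 - c_aa)        # B-channel signal from A alleles
    g_a = (1.0 - c_bb) / c_bb        # A-channel signal from B alleles
    conc_a = n_a + g_a * n_b
    conc_b = n_b + g_b * n_a
    theta_g = np.arctan2(conc_b, np.maximum(conc_a, 1e-9))
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_rawbaf = np.where(conc_a + conc_b > 0, conc_b / (conc_a + conc_b), 0.5)

    # saturating hybridization of the total concentration
    h, kk = config.saturation_hill, config.saturation_k
    beta = config.saturation_background
    conc = abundance * shared.affinity
    frac = conc ** h / (conc ** h + kk ** h)
    magnitude = config.saturation_imax * (frac + beta)
    signal_weight = frac / (frac + beta)

    # sample-specific systematic variation, in log2 units
    bias = np.full(n, brightness)
    bias += gc_coef * config.gc_bias_amplitude * shared.gc_shape
    bias += fraglen_coef * config.fraglen_bias_amplitude * shared.fraglen_shape
    if k:
        bias += shared.latent_loadings @ scores
    bias[sidx] += config.genotype_lr_slope * (exp_rawbaf - 0.5)
    bias += rng.normal(0.0, config.noise_sd * noise_scale, n)
    magnitude = magnitude * 2.0 ** bias

    # split SNP magnitude on the quarter circle; background pulls each SNP
    # toward its probe-specific background composition (near 0.5)
    theta_bg = np.arctan2(shared.bg_split, 1.0 - shared.bg_split)
    theta = signal_weight[sidx] * theta_g + (1 - signal_weight[sidx]) * theta_bg
    theta = theta + rng.normal(0.0, 2.0 * config.baf_cluster_spread, sidx.size)
    theta = np.clip(theta, 1e-3, np.pi / 2 - 1e-3)
    a = magnitude.copy()
    b = np.full(n, np.nan)
    a[sidx] = magnitude[sidx] * np.cos(theta)
    b[sidx] = magnitude[sidx] * np.sin(theta)

    iset = IntensitySet(sample_id=sample_id, a=a, b=b)
    truth = SampleTruth(
        sample_id=sample_id, sex=sex, genotypes=genotypes, phase=phase,
        brightness=brightness, scores=scores, gc_coef=gc_coef,
        fraglen_coef=fraglen_coef, noise_scale=noise_scale, cnvs=tuple(cnvs),
        abundance=abundance,
    )
    return iset, truth


# ---------------------------------------------------------------------------
# Panel / query / trio generation
# ---------------------------------------------------------------------------

def generate_panel(config: GeneratorConfig) -> PanelResult:
    """Generate a CNV-free reference panel, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    shared = make_shared(config, rng)
    samples: list[IntensitySet] = []
    sexes: list[str] = []
    truth = GroundTruth(shared=shared)
    k = config.n_latent_components
    for i in range(config.n_reference_samples):
        sex = ("F" if i % 2 == 0 else "M") if config.include_x else "F"
        panel_scores = rng.normal(0.0, config.panel_latent_score_sd, k) if k else np.zeros(0)
        iset, st = synthesize_sample(config, shared, rng, f"ref{i:03d}", sex=sex,
                                     scores=panel_scores)
        samples.append(iset)
        sexes.append(sex)
        truth.samples.append(st)
    return PanelResult(annotation=shared.annotation, samples=samples,
                       sexes=sexes, truth=truth)


def generate_sample(config: GeneratorConfig, shared: SharedTruth, seed: int,
                    sample_id: str = "query", cnvs: tuple[CnvSpec, ...] | None = None,
                    **kw) -> tuple[IntensitySet, SampleTruth]:
    """Generate one query sample from an existing shared structure."""
    rng = np.random.default_rng(seed)
    if cnvs is None:
        cnvs = config.cnvs
    return synthesize_sample(config, shared, rng, sample_id, cnvs=cnvs, **kw)


@dataclass
class TrioResult:
    shared: SharedTruth
    father: IntensitySet
    mother: IntensitySet
    child: IntensitySet
    truths: dict[str, SampleTruth]
    child_cnvs: tuple[CnvSpec, ...]
    inherited: list[bool]          # per child CNV: carried by a parent


def generate_trio(config: GeneratorConfig, shared: SharedTruth | None = None,
                  seed: int | None = None, child_cnvs: tuple[CnvSpec, ...] | None = None,
                  denovo_rate: float = 0.0) -> TrioResult:
    """Generate a father/mother/child trio with Mendelian child genotypes.

    Each child CNV is de novo with probability ``denovo_rate``; otherwise it
    is also placed in a randomly chosen transmitting parent.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if shared is None:
        shared = make_shared(config, rng)
    if child_cnvs is None:
        child_cnvs = config.cnvs
    inherited = [bool(rng.random() >= denovo_rate) for _ in child_cnvs]
    parent_of = [int(rng.integers(2)) for _ in child_cnvs]
    f_cnvs = tuple(c for c, inh, p in zip(child_cnvs, inherited, parent_of) if inh and p == 0)
    m_cnvs = tuple(c for c, inh, p in zip(child_cnvs, inherited, parent_of) if inh and p == 1)
    gf = draw_genotypes(shared, rng)
    gm = draw_genotypes(shared, rng)
    gc = child_genotypes(gf, gm, rng)
    father, tf = synthesize_sample(config, shared, rng, "father", genotypes=gf, cnvs=f_cnvs)
    mother, tm = synthesize_sample(config, shared, rng, "mother", genotypes=gm, cnvs=m_cnvs)
    child, tc = synthesize_sample(config, shared, rng, "child", genotypes=gc, cnvs=tuple(child_cnvs))
    return TrioResult(shared=shared, father=father, mother=mother, child=child,
                      truths={"father": tf, "mother": tm, "child": tc},
                      child_cnvs=tuple(child_cnvs), inherited=inherited)


def mix_intensities(primary: IntensitySet, contaminant: IntensitySet,
                    alpha: float, sample_id: str | None = None) -> IntensitySet:
    """Linear DNA mixture: fraction ``alpha`` of the contaminant's intensities."""
    sid = sample_id or f"{primary.sample_id}+{alpha:.2f}x{contaminant.sample_id}"
    return IntensitySet(
        sample_id=sid,
        a=(1 - alpha) * primary.a + alpha * contaminant.a,
        b=(1 - alpha) * primary.b + alpha * contaminant.b,
    )


# ---------------------------------------------------------------------------
# Desk-scale shortcuts used by the statistics modules
# ---------------------------------------------------------------------------

def simulate_segment_baf(h_a: float, h_b: float, n_snps: int = 2000,
                         noise_sd: float = 0.03, het_fraction: float = 0.31,
                         rng: np.random.Generator | int = 0) -> np.ndarray:
    """BAF values of one segment with homologue copy numbers (h_a, h_b).

    Heterozygous SNPs sit at h/(h_a+h_b) for the homologue carrying the B
    allele; homozygous SNPs at 0 or 1; Gaussian noise on top.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    total = h_a + h_b
    if total <= 0:
        raise ConfigurationError("h_a + h_b must be positive")
    het = rng.random(n_snps) < het_fraction
    baf = np.where(rng.random(n_snps) < 0.5, 0.0, 1.0)
    side = rng.random(n_snps) < 0.5
    baf[het] = np.where(side[het], h_a / total, h_b / total)
    return baf + rng.normal(0.0, noise_sd, n_snps)


def generate_trio_segment_tables(rng: np.random.Generator | int = 0,
                                 n_alterations: int = 10,
                                 denovo_rate: float = 0.3,
                                 n_chromosomes: int = 22,
                                 chromosome_length: int = 100_000_000
                                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
    """Segment-level trio: child alteration segments, two parent tables, and
    the number of inherited (parent-matched) alterations.

    Inherited alterations appear with identical coordinates and a
    same-direction median in one random parent; de novo ones appear only in
    the child.  Used for validating the trio prediction-accuracy statistic at
    scale without synthesizing intensities.
    """
    from .probe_data_io import SEGMENT_COLUMNS

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows_c, rows_p = [], ([], [])
    n_inherited = 0
    for i in range(n_alterations):
        chrom = str(int(rng.integers(1, n_chromosomes + 1)))
        length = int(rng.integers(500_000, 5_000_000))
        start = int(rng.integers(1, chromosome_length - length))
        gain = bool(rng.random() < 0.5)
        med = float(rng.uniform(0.3, 0.6)) if gain else float(rng.uniform(-0.8, -0.4))
        seg = {
            "sample_id": "child", "chromosome": chrom, "start": start,
            "end": start + length - 1, "n_probes": max(10, length // 2000),
            "median_logratio": med, "allelic_imbalance": float("nan"),
            "genes": "", "cytoband": "",
        }
        rows_c.append(seg)
        if rng.random() >= denovo_rate:
            n_inherited += 1
            p = int(rng.integers(2))
            pseg = dict(seg, sample_id=f"parent{p + 1}",
                        median_logratio=med + float(rng.normal(0, 0.02)))
            rows_p[p].append(pseg)
    child = pd.DataFrame(rows_c, columns=SEGMENT_COLUMNS)
    p1 = pd.DataFrame(rows_p[0], columns=SEGMENT_COLUMNS)
    p2 = pd.DataFrame(rows_p[1], columns=SEGMENT_COLUMNS)
    return child, p1, p2, n_inherited


def recovered_generator_scores(truth: GroundTruth, mds_model,
                               annotation: ProbeAnnotation,
                               fitted_scores: np.ndarray) -> np.ndarray:
    """Express a sample's fitted MDS scores in the generator's component basis.

    Fitted components are only identified up to rotation within the latent
    subspace, so a per-component comparison projects the total fitted
    contribution (sum_k score_k * loading_k) onto each generator loading
    vector.  Scores are additionally only identified up to an additive
    constant per component (the reference functions absorb the panel-mean
    contribution), so recovered and true scores must both be centered across
    a query cohort before an absolute comparison.
    """
    w = truth.shared.latent_loadings
    n = w.shape[0]
    loadings = mds_model.loadings_for(annotation)
    contribution = loadings @ np.asarray(fitted_scores, dtype=float)
    gram = w.T @ w / n
    return np.linalg.solve(gram, w.T @ contribution / n)


def single_bias_config(config: GeneratorConfig, mechanism: str) -> GeneratorConfig:
    """A copy of ``config`` with exactly one bias mechanism enabled.

    ``mechanism`` is one of ``none``, ``gc``, ``fraglen``, ``latent``,
    ``genotype``.  Used for the knob-by-knob recovery checks.
    """
    off = dict(gc_bias_amplitude=0.0, fraglen_bias_amplitude=0.0,
               n_latent_components=0, genotype_lr_slope=0.0)
    keep = {
        "none": {},
        "gc": {"gc_bias_amplitude": config.gc_bias_amplitude},
        "fraglen": {"fraglen_bias_amplitude": config.fraglen_bias_amplitude},
        "latent": {"n_latent_components": config.n_latent_components},
        "genotype": {"genotype_lr_slope": config.genotype_lr_slope},
    }
    if mechanism not in keep:
        raise ConfigurationError(f"unknown bias mechanism {mechanism!r}")
    return replace(config, **{**off, **keep[mechanism]})
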
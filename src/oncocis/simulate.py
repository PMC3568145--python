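"""Synthetic copy-number / expression data generator for benchmarking.

The generator emulates the simulation design used to compare copy-number and
expression integration methods: 10,000 ordered genes, of which 90 sit in
contiguous copy-number variant regions of varying size and amplitude, and 54
of those are dosage-coupled in expression (the true positives).  CNV regions
are clustered into a handful of same-sign "zones" separated by short runs of
neutral genes — mimicking chromosome arms carrying several focal events —
which is what makes downstream segmentation state substantially more altered
genes than the 90 truly aberrant ones.

Tumor intensities are region dosage plus Gaussian probe noise.  Expression is
a per-gene baseline plus, for coupled genes only, a dosage-dependence term
(linear, stepwise or sigmoid) plus Gaussian noise; normal samples and
uncoupled genes carry baseline and noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import NORMAL, TUMOR

LINEAR = "LINEAR"
STEPWISE = "STEPWISE"
SIGMOID = "SIGMOID"
MODELS = (LINEAR, STEPWISE, SIGMOID)


@dataclass
class SimulationSetting:
    """Generative parameters; defaults reproduce the benchmark conditions."""

    n_genes: int = 10_000
    n_tumors: int = 100
    n_normals: int = 10
    model: str = LINEAR
    n_cnv_genes: int = 90
    n_coupled: int = 54
    seed: int = 0
    # region / zone layout
    amplitudes: tuple[float, ...] = (0.5, 1.0, 2.0)   # |log2 ratio| per region
    amplitude_weights: tuple[float, ...] = (0.25, 0.375, 0.375)
    region_size_range: tuple[int, int] = (4, 24)      # genes per region
    recurrence_range: tuple[float, float] = (0.15, 0.6)
    n_zones: int = 6
    zone_gap_range: tuple[int, int] = (5, 40)         # neutral genes between regions
    # noise / coupling
    noise_sd: float = 0.25         # per-probe intensity noise
    dosage_smooth_sigma: float = 3.0  # shoulder width of intensity peaks, in genes
    wave_sd: float = 0.25          # sd of the per-sample wave coefficient
    wave_length: int = 150         # correlation length of the wave, in genes
    wave_threshold: float = 1.65   # soft-threshold carving the wave into sparse peaks
    expr_noise_sd: float = 0.5
    beta: float = 0.75             # expression shift per unit of dosage
    sigmoid_k: float = 1.0
    base_mean: float = 7.0
    base_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.n_coupled <= self.n_cnv_genes <= self.n_genes:
            raise ValueError("need n_coupled <= n_cnv_genes <= n_genes")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")


@dataclass
class GroundTruth:
    """Which genes truly carry CNVs, and which are expression-coupled."""

    cnv_genes: frozenset
    coupled_genes: frozenset

    def __post_init__(self) -> None:
        if not self.coupled_genes <= self.cnv_genes:
            raise ValueError("coupled genes must be a subset of CNV genes")


@dataclass
class SimulatedDataset:
    intensities: pd.DataFrame    # genes x tumors, log2 ratios
    expression: pd.DataFrame     # genes x (tumors + normals)
    annotation: pd.Series
    truth: GroundTruth
    setting: SimulationSetting
    regions: list = field(default_factory=list)


def gene_ids(n: int) -> pd.Index:
    return pd.Index([f"g{i:05d}" for i in range(n)], name="gene")


def place_aberrations(
    setting: SimulationSetting, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict], np.ndarray]:
    """Lay out CNV regions and per-tumor dosage.

    Returns (dosage matrix genes x tumors, region descriptors, CNV gene index).
    Regions are grouped into ``n_zones`` same-sign clusters placed in disjoint
    stretches of the gene order; each region gets an amplitude from
    ``amplitudes`` (sign from its zone) and an independent carrier subset of
    tumors of size recurrence x n_tumors.
    """
    G, T = setting.n_genes, setting.n_tumors
    dosage = np.zeros((G, T), dtype=float)
    if setting.n_cnv_genes == 0:
        return dosage, [], np.empty(0, dtype=int)

    lo, hi = setting.region_size_range
    sizes: list[int] = []
    total = 0
    while total < setting.n_cnv_genes:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, setting.n_cnv_genes - total)
        sizes.append(s)
        total += s

    n_zones = min(setting.n_zones, len(sizes))
    zone_of = rng.integers(0, n_zones, size=len(sizes))
    # guarantee no empty zone so the layout spreads across the genome
    for z in range(n_zones):
        if not np.any(zone_of == z):
            zone_of[int(rng.integers(0, len(sizes)))] = z
    zone_sign = rng.choice([-1.0, 1.0], size=n_zones)

    glo, ghi = setting.zone_gap_range
    regions: list[dict] = []
    chunk = G // n_zones
    cursor = 0  # keeps regions in order and inside the genome on small inputs
    for z in range(n_zones):
        idx = np.flatnonzero(zone_of == z)
        if idx.size == 0:
            continue
        gaps = rng.integers(glo, ghi + 1, size=idx.size - 1) if idx.size > 1 else []
        span = int(sum(sizes[i] for i in idx) + sum(gaps))
        cstart = z * chunk
        margin = max(chunk - span - 1, 1)
        pos = max(cstart + int(rng.integers(0, margin)), cursor)
        for r, ri in enumerate(idx):
            size = sizes[ri]
            pos = max(min(pos, G - size), cursor)
            weights = np.asarray(setting.amplitude_weights, dtype=float)
            amp = zone_sign[z] * float(
                rng.choice(np.asarray(setting.amplitudes), p=weights / weights.sum())
            )
            f = float(rng.uniform(*setting.recurrence_range))
            n_carriers = max(1, int(round(f * T)))
            carriers = rng.choice(T, size=min(n_carriers, T), replace=False)
            dosage[pos : pos + size][:, carriers] += amp
            regions.append(
                {
                    "start": pos,
                    "end": pos + size,
                    "amplitude": amp,
                    "recurrence": f,
                    "carriers": np.sort(carriers),
                    "zone": z,
                }
            )
            cursor = pos + size
            if r < idx.size - 1:
                pos += size + int(gaps[r])
    cnv_idx = np.unique(np.concatenate([np.arange(r["start"], r["end"]) for r in regions]))
    return dosage, regions, cnv_idx


def emit_intensities(
    dosage: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Observed log-ratio intensities: dosage plus Gaussian probe noise."""
    if noise_sd == 0:
        return dosage.copy()
    return dosage + rng.normal(0.0, noise_sd, size=dosage.shape)


def smooth_peaks(dosage: np.ndarray, sigma: float) -> np.ndarray:
    """Turn boxcar dosage regions into peaks with gradual shoulders.

    Array intensities do not jump sharply at region boundaries; probes near an
    amplified or deleted stretch partially reflect it.  Convolving the dosage
    along the gene order with a Gaussian kernel (total signal preserved)
    yields the peak-shaped intensity profiles whose transitions the segmenter
    then smooths into regions substantially wider than the truth.
    """
    if sigma <= 0:
        return dosage
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(dosage, sigma=sigma, axis=0, mode="constant")


def emit_baseline_waves(
    n_genes: int,
    n_samples: int,
    wave_sd: float,
    wave_length: int,
    rng: np.random.Generator,
    wave_threshold: float = 1.5,
) -> np.ndarray:
    """Position-correlated baseline artifacts ("genomic waves").

    Array copy-number data carries smooth, position-specific baseline
    structure shared across samples with sample-specific strength and sign.
    The segmenter turns the wave peaks into gain/loss segments in the samples
    whose coefficient is large, which — together with the smoothed shoulders
    of true regions — inflates the number of called genes well beyond the
    truly aberrant ones while leaving expression untouched.

    One smooth profile is drawn per dataset (Gaussian-smoothed white noise,
    unit variance, correlation length ``wave_length``), soft-thresholded at
    ``wave_threshold`` so only its excursion peaks survive, and scaled per
    sample by an independent N(0, wave_sd) coefficient.
    """
    if wave_sd <= 0 or n_genes < 2:
        return np.zeros((n_genes, n_samples))
    from scipy.ndimage import gaussian_filter1d

    shape = gaussian_filter1d(rng.standard_normal(n_genes), sigma=wave_length, mode="reflect")
    sd = shape.std()
    if sd == 0:
        return np.zeros((n_genes, n_samples))
    shape = shape / sd
    peaks = np.sign(shape) * np.maximum(np.abs(shape) - wave_threshold, 0.0)
    coef = rng.normal(0.0, wave_sd, size=n_samples)
    return peaks[:, None] * coef[None, :]


def dependence(
    model: str, d: np.ndarray | float, beta: float = 1.0, k: float = 2.0
) -> np.ndarray | float:
    """Expected expression shift as a function of dosage d.

    LINEAR: beta*d.  STEPWISE: beta*sign(d)*floor(|d|) — expression responds
    in whole steps {0, +-beta, +-2*beta} and sub-unit dosage changes are
    silent.  SIGMOID: 2*beta*(logistic(k*d) - 1/2), saturating at +-beta for
    large |d|.
    """
    d = np.asarray(d, dtype=float)
    if model == LINEAR:
        out = beta * d
    elif model == STEPWISE:
        out = beta * np.sign(d) * np.floor(np.abs(d))
    elif model == SIGMOID:
        with np.errstate(over="ignore"):
            out = 2.0 * beta * (1.0 / (1.0 + np.exp(-k * d)) - 0.5)
    else:
        raise ValueError(f"unknown model {model!r}")
    return out if out.ndim else float(out)


def emit_expression(
    dosage: np.ndarray,
    coupled_idx: np.ndarray,
    setting: SimulationSetting,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expression for tumors then normals (genes x (n_tumors + n_normals))."""
    G, T = dosage.shape
    N = setting.n_normals
    base = rng.normal(setting.base_mean, setting.base_sd, size=G)
    expr = np.tile(base[:, None], (1, T + N))
    if coupled_idx.size:
        expr[coupled_idx, :T] += dependence(
            setting.model, dosage[coupled_idx], setting.beta, setting.sigmoid_k
        )
    if setting.expr_noise_sd > 0:
        expr += rng.normal(0.0, setting.expr_noise_sd, size=expr.shape)
    return expr


def simulate(setting: SimulationSetting | None = None, **overrides) -> SimulatedDataset:
    """Generate one fully labelled dataset, reproducible from ``setting.seed``."""
    if setting is None:
        setting = SimulationSetting(**overrides)
    elif overrides:
        setting = replace(setting, **overrides)
    rng = np.random.default_rng(setting.seed)

    dosage, regions, cnv_idx = place_aberrations(setting, rng)
    if cnv_idx.size:
        coupled_idx = np.sort(
            rng.choice(cnv_idx, size=min(setting.n_coupled, cnv_idx.size), replace=False)
        )
    else:
        coupled_idx = np.empty(0, dtype=int)

    signal = smooth_peaks(dosage, setting.dosage_smooth_sigma)
    intensities = emit_intensities(signal, setting.noise_sd, rng)
    intensities += emit_baseline_waves(
        setting.n_genes,
        setting.n_tumors,
        setting.wave_sd,
        setting.wave_length,
        rng,
        setting.wave_threshold,
    )
    expression = emit_expression(dosage, coupled_idx, setting, rng)

    genes = gene_ids(setting.n_genes)
    tumors = [f"t{i:03d}" for i in range(setting.n_tumors)]
    normals = [f"n{i:02d}" for i in range(setting.n_normals)]
    annotation = pd.Series(
        {**{s: TUMOR for s in tumors}, **{s: NORMAL for s in normals}}, name="class"
    )
    truth = GroundTruth(
        cnv_genes=frozenset(genes[cnv_idx]),
        coupled_genes=frozenset(genes[coupled_idx]),
    )
    return SimulatedDataset(
        intensities=pd.DataFrame(intensities, index=genes, columns=tumors),
        expression=pd.DataFrame(expression, index=genes, columns=tumors + normals),
        annotation=annotation,
        truth=truth,
        setting=setting,
        regions=regions,
    )


def truth_table(ds: SimulatedDataset) -> pd.DataFrame:
    """Per-gene truth labels as a writable table (gene, is_cnv, is_coupled)."""
    genes = ds.expression.index
    return pd.DataFrame(
        {
            "is_cnv": [int(g in ds.truth.cnv_genes) for g in genes],
            "is_coupled": [int(g in ds.truth.coupled_genes) for g in genes],
        },
        index=genes,
    )
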
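"""Expression-impact scoring of copy-number altered genes.

For each gene carrying multi-copy amplifications (code +2) or homozygous
deletions (code -2) in at least ``min_altered`` tumors, every altered tumor
gets an expression impact score

    EIS_ij = (exp_ij - M_R) / (IQR_A + IQR_R)

where M_R is the reference-group median of the gene's expression, and IQR_A /
IQR_R are the interquartile ranges of the altered group and the reference
group.  Two references are used: the normal samples (EIS_NORMAL) and the
diploid tumors, i.e. tumors with code 0 for that gene (EIS_TUMOR).  The
per-gene observed score is the median EIS over its altered tumors, and is
standardised against a resampled null: medians of n draws (with replacement)
from the pool of all EIS values of the same direction and reference, where n
is the gene's altered-sample count.  The two standard scores are combined
with equal weights by Stouffer's method,

    Z_COMB = (Z_NORMAL + Z_TUMOR) / sqrt(2),

falling back to Z_COMB = Z_TUMOR when no normal samples exist.  One-sided
normal p-values (upper tail for amplifications, lower tail for deletions) are
corrected across the genes of the alteration set, and genes are ranked by
Z_COMB (decreasing for amplifications, increasing for deletions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NORMAL, RESULT_COLUMNS, TUMOR, AlterationDataset

logger = logging.getLogger(__name__)

AMP = "AMP"
DEL = "DEL"

#: copy-number code treated as an event, per direction
EVENT_CODE = {AMP: 2, DEL: -2}


@dataclass
class RunConfig:
    """Tunable parameters of one amplification or deletion analysis."""

    n_sampling: int = 10_000      # resampling replicates per null model
    min_altered: int = 2          # minimum altered tumors for a gene to be scored
    alpha: float = 0.05           # corrected-p threshold for calling positives
    seed: int = 0
    epsilon_scale: float = 0.01   # denominator guard, relative to global expression IQR
    correction: str = "bh"        # "bh" | "bonferroni"
    z_cap: float = 50.0           # sentinel |Z| when a null model has zero spread
    min_reference: int = 2        # minimum reference-group size

    def __post_init__(self) -> None:
        if self.n_sampling <= 0 or self.min_altered < 1:
            raise ValueError("n_sampling and min_altered must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("bh", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class ReferenceStats:
    """Location/spread summary entering the EIS denominator and numerator."""

    median_ref: float
    iqr_ref: float
    iqr_alt: float


@dataclass
class BackgroundModel:
    """Summary of a resampled null distribution of median EIS values."""

    mean: float
    sd: float
    n_reps: int


def _iqr(values: np.ndarray) -> float:
    """Interquartile range with linear interpolation (NaN-tolerant)."""
    v = values[~np.isnan(values)]
    if v.size == 0:
        return np.nan
    q75, q25 = np.percentile(v, [75.0, 25.0])
    return float(q75 - q25)


def compute_sample_eis(exp: float, ref: ReferenceStats, epsilon: float) -> float:
    """EIS of one altered sample against one reference group."""
    denom = max(ref.iqr_alt + ref.iqr_ref, epsilon)
    return (exp - ref.median_ref) / denom


def observed_gene_eis(sample_scores) -> float:
    """Observed per-gene EIS: median of the per-sample scores."""
    scores = np.asarray(sample_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no per-sample EIS values: gene should be skipped")
    return float(np.median(scores))


def build_background(
    pool: np.ndarray, n: int, n_reps: int, rng: np.random.Generator
) -> BackgroundModel:
    """Null model for a gene altered in n tumors.

    Draws ``n_reps`` n-tuples uniformly with replacement from the pooled EIS
    values of the same direction and reference and records the median of each.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty EIS pool: no altered samples in the dataset")
    if n < 1:
        raise ValueError("background sample size n must be >= 1")
    idx = rng.integers(0, pool.size, size=(n_reps, n))
    medians = np.median(pool[idx], axis=1)
    return BackgroundModel(
        mean=float(medians.mean()), sd=float(medians.std(ddof=0)), n_reps=n_reps
    )


def z_score(observed: float, bg: BackgroundModel, cap: float = 50.0) -> float:
    """Standard score of the observed EIS against its null model.

    A degenerate null (sd = 0) yields 0 when the observation matches its mean
    and a signed sentinel of magnitude ``cap`` otherwise.
    """
    if bg.sd > 0.0:
        return (observed - bg.mean) / bg.sd
    if observed == bg.mean:
        return 0.0
    return cap if observed > bg.mean else -cap


def combine_stouffer(z_normal: float | None, z_tumor: float) -> float:
    """Equal-weight Stouffer combination; Z_TUMOR alone if no normals."""
    if z_normal is None or (isinstance(z_normal, float) and np.isnan(z_normal)):
        return z_tumor
    return (z_normal + z_tumor) / np.sqrt(2.0)


def significance(
    z_comb: np.ndarray, direction: str, alpha: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided p-values, multiplicity-corrected p, and positive calls.

    Amplifications are tested in the upper tail (overexpression), deletions in
    the lower tail (underexpression).
    """
    z = np.asarray(z_comb, dtype=float)
    if z.size == 0:
        return z, z, z.astype(bool)
    p = stats.norm.sf(z) if direction == AMP else stats.norm.cdf(z)
    mt_method = "fdr_bh" if method == "bh" else "bonferroni"
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method=mt_method)
    return p, p_adj, p_adj <= alpha


def select_event_samples(
    dataset: AlterationDataset, gene: str, direction: str
) -> tuple[list[str], list[str], list[str]]:
    """Partition samples for one gene: (altered tumors, diploid tumors, normals).

    Altered tumors carry code +2 (AMP) or -2 (DEL); the diploid reference is
    tumors with code 0.  Single-copy events and opposite-sign events belong to
    neither group.  Normals are all NORMAL samples regardless of copy number.
    """
    codes = dataset.cna.loc[gene]
    event = EVENT_CODE[direction]
    altered = [s for s in codes.index if codes[s] == event]
    diploid = [s for s in codes.index if codes[s] == 0]
    return altered, diploid, dataset.normal_samples


def _gene_eis(
    expr_row: np.ndarray,
    altered_idx: np.ndarray,
    ref_values: np.ndarray,
    epsilon: float,
) -> np.ndarray | None:
    """Per-sample EIS of one gene against one reference group, or None."""
    alt = expr_row[altered_idx]
    alt = alt[~np.isnan(alt)]
    ref = ref_values[~np.isnan(ref_values)]
    if alt.size == 0 or ref.size == 0:
        return None
    stats_ref = ReferenceStats(
        median_ref=float(np.median(ref)), iqr_ref=_iqr(ref), iqr_alt=_iqr(alt)
    )
    denom = max(stats_ref.iqr_alt + stats_ref.iqr_ref, epsilon)
    return (alt - stats_ref.median_ref) / denom


@dataclass
class _GeneWork:
    gene: str
    n_altered: int
    eis_tumor_scores: np.ndarray
    eis_normal_scores: np.ndarray | None


def analyze(
    dataset: AlterationDataset, direction: str, config: RunConfig | None = None
) -> pd.DataFrame:
    """Run the full per-direction pipeline and return the ranked gene table.

    Output columns: gene, n_altered, eis_normal, eis_tumor, z_normal, z_tumor,
    z_comb, p_value, corrected_p; rows ranked by z_comb (AMP descending, DEL
    ascending, ties broken by gene id).  Genes with fewer than
    ``config.min_altered`` scored tumors, or without a usable diploid tumor
    reference, are absent from the output.
    """
    if direction not in (AMP, DEL):
        raise ValueError(f"direction must be AMP or DEL, got {direction!r}")
    cfg = config or RunConfig()

    tumors = dataset.tumor_samples
    normals = dataset.normal_samples
    have_normals = len(normals) > 0

    expr = dataset.expression
    expr_t = expr[tumors].to_numpy(dtype=float)
    expr_n = expr[normals].to_numpy(dtype=float) if have_normals else None
    codes = dataset.cna[tumors].to_numpy()

    global_iqr = _iqr(expr_t.ravel())
    epsilon = cfg.epsilon_scale * (global_iqr if global_iqr > 0 else 1.0)

    event = EVENT_CODE[direction]
    altered_mask = codes == event
    diploid_mask = codes == 0

    work: list[_GeneWork] = []
    genes = list(dataset.genes)
    for gi, gene in enumerate(genes):
        alt_idx = np.flatnonzero(altered_mask[gi])
        if alt_idx.size < cfg.min_altered:
            continue
        row = expr_t[gi]
        # drop altered samples with missing expression from the event count
        n_altered = int(np.sum(~np.isnan(row[alt_idx])))
        if n_altered < cfg.min_altered:
            continue
        dip_idx = np.flatnonzero(diploid_mask[gi])
        dip_vals = row[dip_idx]
        dip_vals = dip_vals[~np.isnan(dip_vals)]
        if dip_vals.size < cfg.min_reference:
            logger.warning(
                "gene %s skipped: only %d diploid tumor(s) as reference",
                gene,
                dip_vals.size,
            )
            continue
        eis_t = _gene_eis(row, alt_idx, dip_vals, epsilon)
        if eis_t is None:
            continue
        eis_n = None
        if have_normals:
            # altered values from the tumor row, reference = the gene's normals
            eis_n = _gene_eis(row, alt_idx, expr_n[gi], epsilon)
        work.append(_GeneWork(gene, n_altered, eis_t, eis_n))

    if not work:
        logger.warning("no gene qualified for the %s analysis", direction)
        return pd.DataFrame(columns=RESULT_COLUMNS)

    pool_tumor = np.concatenate([w.eis_tumor_scores for w in work])
    pool_normal = (
        np.concatenate([w.eis_normal_scores for w in work if w.eis_normal_scores is not None])
        if have_normals
        else None
    )

    # Null models depend only on (pool, n): share one resampled model across
    # genes with the same altered-sample count.
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0 if direction == AMP else 1])
    )
    bg_tumor: dict[int, BackgroundModel] = {}
    bg_normal: dict[int, BackgroundModel] = {}
    for n in sorted({w.n_altered for w in work}):
        bg_tumor[n] = build_background(pool_tumor, n, cfg.n_sampling, rng)
        if have_normals and pool_normal is not None and pool_normal.size:
            bg_normal[n] = build_background(pool_normal, n, cfg.n_sampling, rng)

    rows = []
    for w in work:
        obs_t = observed_gene_eis(w.eis_tumor_scores)
        z_t = z_score(obs_t, bg_tumor[w.n_altered], cfg.z_cap)
        if have_normals and w.eis_normal_scores is not None and w.n_altered in bg_normal:
            obs_n = observed_gene_eis(w.eis_normal_scores)
            z_n = z_score(obs_n, bg_normal[w.n_altered], cfg.z_cap)
        else:
            obs_n, z_n = np.nan, None
        z_c = combine_stouffer(z_n, z_t)
        rows.append(
            {
                "gene": w.gene,
                "n_altered": w.n_altered,
                "eis_normal": obs_n,
                "eis_tumor": obs_t,
                "z_normal": np.nan if z_n is None else z_n,
                "z_tumor": z_t,
                "z_comb": z_c,
            }
        )

    res = pd.DataFrame(rows)
    p, p_adj, _ = significance(res["z_comb"].to_numpy(), direction, cfg.alpha, cfg.correction)
    res["p_value"] = p
    res["corrected_p"] = p_adj
    ascending = direction == DEL
    res = res.sort_values(
        ["z_comb", "gene"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    res.index = pd.RangeIndex(1, len(res) + 1, name="rank")
    return res


def positive_genes(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes called positive at the corrected-p threshold."""
    if results.empty:
        return set()
    return set(results.loc[results["corrected_p"] <= alpha, "gene"])
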
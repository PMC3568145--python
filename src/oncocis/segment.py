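"""Circular binary segmentation of probe-ordered copy-number log ratios.

Each sample's profile is recursively partitioned: the best circular arc
(i..j] is the one maximising the two-sample pooled-variance t statistic
between the arc and its complement; a split is kept when that statistic is
significant against a null of rearranged values, and the recursion continues
inside the resulting pieces.  Final segment means are thresholded at
``gain_cut`` / ``loss_cut`` (+0.2 / -0.2) to produce discrete gene-level
gain/loss codes (+2 / -2) compatible with the EIS analysis.

Implementation notes
--------------------
With centered cumulative sums D (D[0] = D[P] = 0), the between-group sum of
squares of an arc of length k starting after i is

    SS_b(i, j) = (D[j] - D[i])^2 * P / (k (P - k)),

and the pooled t statistic satisfies T^2 = (P-2) SS_b / (SS_tot - SS_b),
which is strictly increasing in SS_b.  Maximising T over all arcs therefore
reduces to maximising v = d^2 / (k (P - k)), which a pruned exact scan
(bounded by the range of D) computes in far less than O(P^2) time on typical
profiles.  Significance uses within-segment permutations for short segments
and, for long segments, a Monte-Carlo null-threshold table computed once per
length bucket from i.i.d. Gaussian data (the studentised statistic is scale
free), the approach long used by production CBS implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

#: sentinel statistic for a split that leaves (numerically) zero within-variance
T_CAP = 1e12


@dataclass
class SegmentationConfig:
    """Parameters of the segmentation and of the discrete gain/loss calls."""

    alpha_split: float = 0.01     # significance level to accept a split
    n_permutations: int = 1000
    min_width: int = 2            # minimum arc (and complement) width
    gain_cut: float = 0.2
    loss_cut: float = -0.2
    seed: int = 0
    exact_max_size: int = 128     # permutation test below, null table above

    def __post_init__(self) -> None:
        if not self.loss_cut < 0.0 < self.gain_cut:
            raise ValueError("cuts must satisfy loss_cut < 0 < gain_cut")
        if self.min_width < 1 or self.n_permutations < 1:
            raise ValueError("min_width and n_permutations must be positive")


@njit(cache=False)
def _scan_best_arc(D: np.ndarray, minw: int):  # pragma: no cover - numba
    """Max of v = d^2 / (k(P-k)) over arcs with min width on arc and complement.

    Returns (best_v, i, j) with the arc being positions i..j-1 (0-based).
    The scan visits arc lengths k = minw..P//2 together with their complements
    and stops once range(D)^2 / (k(P-k)) can no longer beat the current best.
    """
    P = D.shape[0] - 1
    best = -1.0
    bi = 0
    bj = 0
    dmax = D[0]
    dmin = D[0]
    for t in range(1, P + 1):
        if D[t] > dmax:
            dmax = D[t]
        if D[t] < dmin:
            dmin = D[t]
    r2 = (dmax - dmin) * (dmax - dmin)
    half = P // 2
    for k in range(minw, half + 1):
        denom = float(k) * float(P - k)
        if best > 0.0 and r2 / denom <= best:
            break
        for i in range(0, P - k + 1):
            d = D[i + k] - D[i]
            v = d * d / denom
            if v > best:
                best = v
                bi = i
                bj = i + k
        kk = P - k
        if kk != k and kk >= minw:
            for i in range(0, P - kk + 1):
                d = D[i + kk] - D[i]
                v = d * d / denom
                if v > best:
                    best = v
                    bi = i
                    bj = i + kk
    return best, bi, bj


@njit(cache=False)
def _scan_exceeds(D: np.ndarray, minw: int, v_obs: float) -> bool:  # pragma: no cover
    """True if any admissible arc of the profile reaches v >= v_obs."""
    P = D.shape[0] - 1
    dmax = D[0]
    dmin = D[0]
    for t in range(1, P + 1):
        if D[t] > dmax:
            dmax = D[t]
        if D[t] < dmin:
            dmin = D[t]
    r2 = (dmax - dmin) * (dmax - dmin)
    half = P // 2
    for k in range(minw, half + 1):
        denom = float(k) * float(P - k)
        if r2 / denom < v_obs:
            break
        for i in range(0, P - k + 1):
            d = D[i + k] - D[i]
            if d * d / denom >= v_obs:
                return True
        kk = P - k
        if kk != k and kk >= minw:
            for i in range(0, P - kk + 1):
                d = D[i + kk] - D[i]
                if d * d / denom >= v_obs:
                    return True
    return False


def _centered_cumsum(x: np.ndarray) -> np.ndarray:
    D = np.empty(x.size + 1, dtype=np.float64)
    D[0] = 0.0
    np.cumsum(x - x.mean(), out=D[1:])
    return D


def _t_from_v(v: float, ss_tot: float, P: int) -> float:
    """Convert the scan value v to the pooled t statistic."""
    if v <= 0.0 or ss_tot <= 0.0 or P < 3:
        return 0.0
    ss_b = v * P
    within = ss_tot - ss_b
    if within <= 1e-12 * ss_tot:
        return T_CAP
    return float(np.sqrt((P - 2) * ss_b / within))


def cbs_statistic(x: np.ndarray, i: int, j: int) -> float:
    """Pooled-variance t statistic of arc x[i:j] against its complement.

    Indices are 0-based with 0 <= i < j <= len(x); the complement wraps around
    the index circle.  A constant profile (zero pooled variance, equal means)
    scores 0; a perfect noiseless split scores the ``T_CAP`` sentinel.
    """
    x = np.asarray(x, dtype=float)
    P = x.size
    if not 0 <= i < j <= P or (j - i) == P:
        raise ValueError("need 0 <= i < j <= P with a nonempty complement")
    arc = x[i:j]
    comp = np.concatenate([x[:i], x[j:]])
    m1, m2 = arc.mean(), comp.mean()
    ss = float(((arc - m1) ** 2).sum() + ((comp - m2) ** 2).sum())
    if P < 3 or ss <= 1e-12 * max(float(((x - x.mean()) ** 2).sum()), 1e-300):
        return 0.0 if m1 == m2 else T_CAP
    pooled = ss / (P - 2)
    return float(abs(m1 - m2) / np.sqrt(pooled * (1.0 / arc.size + 1.0 / comp.size)))


# --- Monte-Carlo null thresholds for long segments ------------------------

_NULL_THRESHOLDS: dict[tuple, float] = {}


def _length_bucket(P: int) -> int:
    """Half-log2 length bucket (within ~19% of P).

    The null threshold grows only like sqrt(2 log P), so a ~19% length error
    moves it by well under 2%; bucketing keeps the number of Monte-Carlo
    table builds small.
    """
    return int(round(2.0 ** (round(np.log2(P) * 2.0) / 2.0)))


def _null_threshold(P: int, n_perm: int, alpha: float, minw: int) -> float:
    """(1 - alpha) quantile of the max arc statistic on i.i.d. Gaussian data.

    Deterministic for a given (length bucket, n_perm, alpha, min_width): the
    simulation seed is a fixed function of the key, so the table acts like a
    critical-value table and does not consume the caller's random stream.
    """
    bucket = _length_bucket(P)
    key = (bucket, n_perm, round(alpha, 9), minw)
    if key in _NULL_THRESHOLDS:
        return _NULL_THRESHOLDS[key]
    rng = np.random.default_rng(
        np.random.SeedSequence([812763490, bucket, n_perm, int(alpha * 1e9), minw])
    )
    maxima = np.empty(n_perm)
    for r in range(n_perm):
        x = rng.standard_normal(bucket)
        D = _centered_cumsum(x)
        v, _, _ = _scan_best_arc(D, minw)
        ss_tot = float(((x - x.mean()) ** 2).sum())
        maxima[r] = _t_from_v(v, ss_tot, bucket)
    thr = float(np.quantile(maxima, 1.0 - alpha))
    _NULL_THRESHOLDS[key] = thr
    return thr


# --- recursive segmentation ------------------------------------------------


def _split_significant(
    x: np.ndarray,
    v_obs: float,
    t_obs: float,
    cfg: SegmentationConfig,
    rng: np.random.Generator,
) -> bool:
    P = x.size
    if P > cfg.exact_max_size:
        return t_obs > _null_threshold(P, cfg.n_permutations, cfg.alpha_split, cfg.min_width)
    allowed = int(np.floor(cfg.alpha_split * cfg.n_permutations))
    count = 0
    for _ in range(cfg.n_permutations):
        xp = rng.permutation(x)
        if _scan_exceeds(_centered_cumsum(xp), cfg.min_width, v_obs):
            count += 1
            if count > allowed:
                return False
    return True


def segment_profile(
    values: np.ndarray,
    cfg: SegmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Segment one probe-ordered log-ratio profile.

    Returns a DataFrame with 1-based inclusive ``start``/``end`` columns and
    the arithmetic ``mean`` of each segment; segments abut and cover 1..P.
    """
    cfg = cfg or SegmentationConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x = np.ascontiguousarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty profile")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")

    segments: list[tuple[int, int, float]] = []
    stack: list[tuple[int, int]] = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        P = seg.size
        if P < max(2 * cfg.min_width, 3):
            segments.append((lo, hi, float(seg.mean())))
            continue
        ss_tot = float(((seg - seg.mean()) ** 2).sum())
        if ss_tot <= 0.0:
            segments.append((lo, hi, float(seg.mean())))
            continue
        D = _centered_cumsum(seg)
        v, i, j = _scan_best_arc(D, cfg.min_width)
        t_obs = _t_from_v(v, ss_tot, P)
        if v > 0.0 and _split_significant(seg, v, t_obs, cfg, rng):
            # push pieces right-to-left so they are processed left-to-right
            pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
            for a, b in reversed(pieces):
                if b > a:
                    stack.append((a, b))
        else:
            segments.append((lo, hi, float(seg.mean())))

    segments.sort()
    return pd.DataFrame(
        {
            "start": [s[0] + 1 for s in segments],
            "end": [s[1] for s in segments],
            "mean": [s[2] for s in segments],
        }
    )


def segment_dataset(
    intensities: pd.DataFrame, cfg: SegmentationConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Segment every sample column of a gene x sample intensity matrix.

    Each sample gets an independent, reproducible random stream derived from
    ``cfg.seed`` and its column position.
    """
    cfg = cfg or SegmentationConfig()
    out: dict[str, pd.DataFrame] = {}
    for si, sample in enumerate(intensities.columns):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, si]))
        out[sample] = segment_profile(intensities[sample].to_numpy(), cfg, rng)
    return out


def call_genes(
    segments: dict[str, pd.DataFrame],
    genes: pd.Index,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Discrete per-gene gain/loss calls from fitted segment means.

    Every gene inherits the mean of its segment; status is +2 when the mean
    reaches ``gain_cut``, -2 when it falls below ``loss_cut``, else 0.
    """
    cfg = cfg or SegmentationConfig()
    n_genes = len(genes)
    calls = np.zeros((n_genes, len(segments)), dtype=np.int8)
    for si, (sample, segs) in enumerate(segments.items()):
        means = np.empty(n_genes)
        for start, end, mean in segs[["start", "end", "mean"]].itertuples(index=False):
            means[start - 1 : end] = mean
        calls[means >= cfg.gain_cut, si] = 2
        calls[means <= cfg.loss_cut, si] = -2
    return pd.DataFrame(calls, index=genes, columns=list(segments.keys()))


def segments_table(segments: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample segment frames into one (sample, start, end, mean) table."""
    frames = []
    for sample, segs in segments.items():
        f = segs.copy()
        f.insert(0, "sample", sample)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
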
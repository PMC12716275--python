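"""Open-ended dynamic time warping of nights and barycenter archetypes.

Two nights of sleep rarely unfold at the same rate or last equally long.
Open-ended DTW (OE-DTW) aligns the *whole* of the shorter night to a
prefix of the longer one: the warping path starts at the common fixed
point (sleep onset), moves through the local-cost matrix with steps
{(1,0),(0,1),(1,1)}, and terminates at whichever column of the longer
night minimises the accumulated cost once the shorter night's last bin is
consumed. The dissimilarity D is the accumulated cost along the optimal
path divided by the number of path cells, so that D -> 0 for identical
nights and D = 0 exactly when one night is a prefix of the other.

OE-DTW barycenter averaging (OE-DBA) iteratively re-estimates an
"archetypal night" that minimises the summed D to a set of nights, and
hierarchical clustering of per-subject archetypes groups individuals with
shared sleep dynamics.

The dynamic program is this package's own implementation (numba-compiled);
no external DTW library is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.stats import ttest_ind

from .core import BandPowerSeries, Hypnogram, QCError, SLEEP_STAGES, STAGES
from .cycles import segment_cycles
from .spectral import zscore_bands

__all__ = [
    "NightFeatures",
    "WarpResult",
    "Archetype",
    "WithinAcrossResult",
    "ClusterResult",
    "build_night_features",
    "oe_dtw",
    "pairwise_dissimilarity",
    "compare_within_across",
    "oe_dba",
    "stage_conditioned_dissimilarity",
    "cluster_archetypes",
    "shared_archetype",
]


@dataclass
class NightFeatures:
    """One night as a 5xL matrix of z-scored band powers.

    ``matrix`` rows are (delta, theta, alpha, sigma, beta); bins run from
    sleep onset (bin 0) to the final awakening. ``stages`` carries the
    scored stage of each bin for stage-conditioned analyses.
    """

    matrix: np.ndarray
    bin_s: float
    night_id: str
    subject_id: str
    sleep_onset_bin: int = 0
    night_index: int = 0
    stages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 5:
            raise ValueError("matrix must be 5 x L")
        if self.matrix.shape[1] < 10:
            raise ValueError("need at least 10 feature bins")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])


@dataclass(frozen=True)
class WarpResult:
    """Alignment of two nights: path, normalised dissimilarity, coverage."""

    path: np.ndarray  # (P, 2) index pairs into (a, b)
    dissimilarity: float
    matched_len: int  # bins of the longer night consumed


@dataclass
class Archetype:
    """Barycenter-averaged archetypal night."""

    matrix: np.ndarray
    bin_s: float
    member_ids: list[str]
    objective_trace: list[float]
    subject_id: str = ""


# ---------------------------------------------------------------------------
# dynamic program


@njit(cache=True)
def _accumulate(cost: np.ndarray) -> np.ndarray:
    m, n = cost.shape
    acc = np.empty((m, n))
    acc[0, 0] = cost[0, 0]
    for j in range(1, n):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, m):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, n):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost[i, j] + best
    return acc


@njit(cache=True)
def _backtrack(acc: np.ndarray, end_j: int) -> np.ndarray:
    m = acc.shape[0]
    # path length bounded by m + end_j
    buf = np.empty((m + end_j + 1, 2), dtype=np.int64)
    i, j = m - 1, end_j
    k = 0
    buf[k, 0], buf[k, 1] = i, j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            d = acc[i - 1, j - 1]
            u = acc[i - 1, j]
            l = acc[i, j - 1]
            if d <= u and d <= l:
                i -= 1
                j -= 1
            elif u <= l:
                i -= 1
            else:
                j -= 1
        k += 1
        buf[k, 0], buf[k, 1] = i, j
    return buf[: k + 1][::-1].copy()


def _oe_dtw_directed(short: np.ndarray, long_: np.ndarray) -> tuple[float, np.ndarray, int]:
    """OE-DTW with ``short`` fully consumed; returns (D, path, matched)."""
    cost = cdist(short.T, long_.T)
    acc = _accumulate(cost)
    end_j = int(np.argmin(acc[-1, :]))
    path = _backtrack(acc, end_j)
    total = float(acc[-1, end_j])
    return total / path.shape[0], path, end_j + 1


def _as_matrix(x) -> np.ndarray:
    return x.matrix if isinstance(x, NightFeatures) else np.ascontiguousarray(x, dtype=float)


def oe_dtw(a, b) -> WarpResult:
    """Open-ended DTW dissimilarity between two nights.

    ``a`` and ``b`` are :class:`NightFeatures` (or bare 5xL arrays) at the
    same resolution. The shorter sequence determines the open-ended
    termination; the returned path is in ``(index into a, index into b)``
    order regardless of which is shorter. For equal lengths both
    orientations are evaluated and the smaller D taken, making the
    operation exactly symmetric.
    """
    if isinstance(a, NightFeatures) and isinstance(b, NightFeatures):
        if not np.isclose(a.bin_s, b.bin_s):
            raise ValueError(f"resolution mismatch: {a.bin_s} s vs {b.bin_s} s")
    ma, mb = _as_matrix(a), _as_matrix(b)
    if ma.shape[0] != mb.shape[0]:
        raise ValueError("nights must share the same band ordering (5 rows)")
    la, lb = ma.shape[1], mb.shape[1]
    if la < lb:
        d, path, matched = _oe_dtw_directed(ma, mb)
    elif lb < la:
        d, path, matched = _oe_dtw_directed(mb, ma)
        path = path[:, ::-1]
    else:
        d1, p1, m1 = _oe_dtw_directed(ma, mb)
        d2, p2, m2 = _oe_dtw_directed(mb, ma)
        if d1 <= d2:
            d, path, matched = d1, p1, m1
        else:
            d, path, matched = d2, p2[:, ::-1], m2
    return WarpResult(path=path, dissimilarity=float(d), matched_len=int(matched))


# ---------------------------------------------------------------------------
# feature construction and QC


def build_night_features(
    series: BandPowerSeries,
    hypnogram: Hypnogram,
    resolution_s: float = 60.0,
    night_id: str = "night",
    subject_id: str = "s01",
    night_index: int = 0,
    max_invalid_frac: float = 0.2,
) -> NightFeatures:
    """Crop, downsample, z-score and QC one night.

    Quality control mirrors the study's inclusion rules: nights shorter
    than 1.5 NREM-REM cycles are rejected (``QCError('min-cycles')``), as
    are nights with more than ``max_invalid_frac`` invalid bins between
    sleep onset and final awakening (``QCError('disconnection')``).
    Residual invalid bins are linearly interpolated per band so that the
    warping input is gap-free.
    """
    cycles = segment_cycles(hypnogram)
    score = sum(1.0 if c.rem_start_epoch is not None else 0.5 for c in cycles)
    if score < 1.5:
        raise QCError("min-cycles", f"night has {score:.1f} cycles; need >= 1.5")

    sleep = np.isin(hypnogram.labels, list(SLEEP_STAGES))
    idx = np.flatnonzero(sleep)
    onset_s = idx[0] * hypnogram.epoch_s
    end_s = (idx[-1] + 1) * hypnogram.epoch_s
    centers = series.times()
    keep = (centers >= onset_s) & (centers < end_s)
    if keep.sum() < 10:
        raise QCError("too-short", "fewer than 10 bins between onset and final awakening")
    vals = series.values[:, keep]
    valid = series.valid[keep]
    if (~valid).mean() > max_invalid_frac:
        raise QCError(
            "disconnection",
            f"{(~valid).mean():.0%} invalid bins inside the sleep period "
            f"(limit {max_invalid_frac:.0%})",
        )

    factor = max(1, int(round(resolution_s / series.bin_s)))
    L = vals.shape[1] // factor
    if L < 10:
        raise QCError("too-short", "fewer than 10 bins at the requested resolution")
    ds = np.empty((5, L))
    ds_valid = np.empty(L, dtype=bool)
    for k in range(L):
        sl = slice(k * factor, (k + 1) * factor)
        v = valid[sl]
        ds_valid[k] = v.any()
        ds[:, k] = vals[:, sl][:, v].mean(axis=1) if v.any() else np.nan
    # interpolate interior gaps per band
    if not ds_valid.all():
        good = np.flatnonzero(ds_valid)
        for r in range(5):
            ds[r] = np.interp(np.arange(L), good, ds[r, good])
    ds_series = BandPowerSeries(ds, bin_s=factor * series.bin_s)
    z = zscore_bands(ds_series, scope="night").values
    stage_centers = onset_s + (np.arange(L) + 0.5) * factor * series.bin_s
    return NightFeatures(
        matrix=z,
        bin_s=factor * series.bin_s,
        night_id=night_id,
        subject_id=subject_id,
        night_index=night_index,
        stages=hypnogram.stage_at(stage_centers),
    )


# ---------------------------------------------------------------------------
# cohort-level dissimilarity


def pairwise_dissimilarity(
    nights: list[NightFeatures],
    exclude_adjacent: bool = True,
    return_paths: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, dict]:
    """D for all unordered non-adjacent pairs of nights.

    Adjacent means consecutive calendar nights (``night_index`` differing
    by 1) of the same subject; those cells are left NaN and flagged in the
    tidy table. Returns ``(matrix, tidy)`` and optionally a dict of
    warping paths keyed by night-id pairs.
    """
    if len(nights) < 2:
        raise ValueError("need at least 2 nights")
    ids = [n.night_id for n in nights]
    if len(set(ids)) != len(ids):
        raise ValueError("night_ids must be unique")
    mat = np.full((len(nights), len(nights)), np.nan)
    np.fill_diagonal(mat, 0.0)
    rows = []
    paths: dict[tuple[str, str], np.ndarray] = {}
    for i in range(len(nights)):
        for j in range(i + 1, len(nights)):
            a, b = nights[i], nights[j]
            adjacent = (
                exclude_adjacent
                and a.subject_id == b.subject_id
                and abs(a.night_index - b.night_index) == 1
            )
            d = np.nan
            if not adjacent:
                res = oe_dtw(a, b)
                d = res.dissimilarity
                mat[i, j] = mat[j, i] = d
                if return_paths:
                    paths[(a.night_id, b.night_id)] = res.path
            rows.append(
                {
                    "night_a": a.night_id,
                    "night_b": b.night_id,
                    "subject_a": a.subject_id,
                    "subject_b": b.subject_id,
                    "within_subject": a.subject_id == b.subject_id,
                    "excluded_adjacent": adjacent,
                    "D": d,
                }
            )
    matrix = pd.DataFrame(mat, index=ids, columns=ids)
    tidy = pd.DataFrame(rows)
    if return_paths:
        return matrix, tidy, paths
    return matrix, tidy


@dataclass(frozen=True)
class WithinAcrossResult:
    """Two-sample t-test of within- vs across-subject dissimilarity."""

    t: float
    p: float
    mean_within: float
    sd_within: float
    mean_across: float
    sd_across: float
    n_within: int
    n_across: int


def compare_within_across(tidy: pd.DataFrame) -> WithinAcrossResult:
    """Student's t-test of within- vs across-subject mean dissimilarity.

    To avoid pseudo-replication the unit of analysis is the per-subject
    mean (within group) and the per-subject-pair mean (across group).
    """
    tab = tidy[~tidy["excluded_adjacent"] & tidy["D"].notna()]
    within = (
        tab[tab["within_subject"]].groupby("subject_a")["D"].mean().to_numpy()
    )
    across_tab = tab[~tab["within_subject"]].copy()
    if len(across_tab):
        key = across_tab.apply(
            lambda r: tuple(sorted((r["subject_a"], r["subject_b"]))), axis=1
        )
        across = across_tab.groupby(key)["D"].mean().to_numpy()
    else:
        across = np.empty(0)
    if within.size < 2 or across.size < 2:
        raise ValueError("each group needs at least 2 units for a t-test")
    t, p = ttest_ind(within, across)
    return WithinAcrossResult(
        t=float(t),
        p=float(p),
        mean_within=float(within.mean()),
        sd_within=float(within.std(ddof=1)),
        mean_across=float(across.mean()),
        sd_across=float(across.std(ddof=1)),
        n_within=int(within.size),
        n_across=int(across.size),
    )


# ---------------------------------------------------------------------------
# barycenter averaging


def _dba_objective(avg: np.ndarray, members: list[np.ndarray]) -> float:
    return sum(oe_dtw(avg, m).dissimilarity for m in members)


def oe_dba(
    nights: list[NightFeatures],
    init: str | np.ndarray = "medoid",
    max_iter: int = 10,
    tol: float = 1e-3,
    subject_id: str = "",
) -> Archetype:
    """OE-DTW barycenter averaging ("archetypal night").

    Initialised at the medoid (the member with minimal summed D to the
    others) unless an explicit 5xL array is given. Each iteration aligns
    every member to the current average with OE-DTW and re-estimates each
    average bin as the arithmetic mean of all member vectors mapped to it
    (classic DBA update; bins left unmatched by shorter members keep their
    previous value). Iteration stops at ``max_iter``, when the relative
    objective change falls below ``tol``, or — since the heuristic carries
    no guarantee under length normalisation — at the first non-improving
    update, which keeps the recorded objective trace non-increasing.
    """
    if not nights:
        raise ValueError("need at least one night")
    members = [n.matrix for n in nights]
    member_ids = [n.night_id for n in nights]
    if isinstance(init, np.ndarray):
        avg = np.array(init, dtype=float)
    elif init == "medoid":
        if len(members) == 1:
            avg = members[0].copy()
        else:
            sums = [
                sum(oe_dtw(members[i], members[j]).dissimilarity for j in range(len(members)) if j != i)
                for i in range(len(members))
            ]
            avg = members[int(np.argmin(sums))].copy()
    else:
        raise ValueError("init must be 'medoid' or a 5xL array")

    trace = [_dba_objective(avg, members)]
    for _ in range(max_iter):
        sums = np.zeros_like(avg)
        counts = np.zeros(avg.shape[1])
        for m in members:
            path = oe_dtw(avg, m).path
            for i, j in path:
                sums[:, i] += m[:, j]
                counts[i] += 1
        new = avg.copy()
        hit = counts > 0
        new[:, hit] = sums[:, hit] / counts[hit]
        obj = _dba_objective(new, members)
        if obj > trace[-1]:
            break  # non-improving update: keep previous average
        avg = new
        improved = trace[-1] - obj
        trace.append(obj)
        if trace[-2] > 0 and improved / trace[-2] < tol:
            break
    return Archetype(
        matrix=avg,
        bin_s=nights[0].bin_s,
        member_ids=member_ids,
        objective_trace=trace,
        subject_id=subject_id or nights[0].subject_id,
    )


def shared_archetype(nights: list[NightFeatures], **kwargs) -> Archetype:
    """Archetype across subjects within a cluster (OE-DBA over all their
    nights)."""
    arch = oe_dba(nights, **kwargs)
    arch.subject_id = "+".join(sorted({n.subject_id for n in nights}))
    return arch


# ---------------------------------------------------------------------------
# stage-conditioned dissimilarity and clustering


def stage_conditioned_dissimilarity(
    nights: list[NightFeatures],
    pairs: list[tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean local alignment cost bucketed by the scored stage pair.

    For each warped pair of nights, the Euclidean cost of every path cell
    is accumulated into the (stage_a, stage_b) bucket; bucket means are
    symmetrised. Returns ``(mean_matrix, count_matrix)`` as 5x5 DataFrames
    over stages (W, N1, N2, N3, REM). Nights must carry per-bin stages.
    """
    for n in nights:
        if n.stages is None:
            raise ValueError("nights must carry per-bin stage labels")
    if pairs is None:
        pairs = [(i, j) for i in range(len(nights)) for j in range(i + 1, len(nights))]
    k = len(STAGES)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    sums = np.zeros((k, k))
    counts = np.zeros((k, k))
    for i, j in pairs:
        a, b = nights[i], nights[j]
        res = oe_dtw(a, b)
        cost = np.linalg.norm(a.matrix[:, res.path[:, 0]] - b.matrix[:, res.path[:, 1]], axis=0)
        sa = np.asarray([stage_idx[s] for s in a.stages[res.path[:, 0]]])
        sb = np.asarray([stage_idx[s] for s in b.stages[res.path[:, 1]]])
        np.add.at(sums, (sa, sb), cost)
        np.add.at(counts, (sa, sb), 1)
    sums_s = sums + sums.T
    counts_s = counts + counts.T
    with np.errstate(invalid="ignore"):
        means = np.where(counts_s > 0, sums_s / np.maximum(counts_s, 1), np.nan)
    idx = list(STAGES)
    return (
        pd.DataFrame(means, index=idx, columns=idx),
        pd.DataFrame(counts, index=idx, columns=idx),
    )


@dataclass
class ClusterResult:
    """Hierarchical clustering of per-subject archetypes."""

    distance: pd.DataFrame
    linkage: np.ndarray
    labels: dict[str, int] = field(default_factory=dict)


def cluster_archetypes(
    archetypes: list[Archetype],
    k: int = 2,
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering on pairwise archetype OE-DTW dissimilarity.

    The dendrogram is cut into ``k`` flat clusters; ``labels`` maps each
    archetype's subject_id to its cluster index (1-based, relabelled so
    cluster sizes are descending).
    """
    if len(archetypes) < 2:
        raise ValueError("need at least 2 archetypes")
    n = len(archetypes)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = oe_dtw(archetypes[i].matrix, archetypes[j].matrix).dissimilarity
    Z = linkage(squareform(dm, checks=False), method=method)
    flat = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters by descending size for stable reporting
    order = pd.Series(flat).value_counts().index.tolist()
    relabel = {old: new + 1 for new, old in enumerate(order)}
    ids = [a.subject_id for a in archetypes]
    return ClusterResult(
        distance=pd.DataFrame(dm, index=ids, columns=ids),
        linkage=Z,
        labels={sid: relabel[c] for sid, c in zip(ids, flat)},
    )
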
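"""Spatiotemporal cluster-based permutation test for paired ERP contrasts.

Subject-average condition data (subjects x channels x times) are
compared with paired t-statistics at every spatiotemporal location;
locations with |t| above a threshold are grouped into positive and
negative clusters over spatial (sensor adjacency) and temporal
(consecutive samples) neighbours, and each cluster is scored by the sum
of its t-values (its "mass").  The null distribution of the largest
positive and smallest negative mass is built by sign-flipping the
paired differences within random subject subsets (all 2^n flips are
enumerated when n <= 12), which controls the family-wise error of the
whole channels-x-times search space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .layout import ChannelLayout, build_adjacency

#: Stand-in t for zero-variance locations (excluded from cluster masses).
T_SENTINEL = 1e6

EXACT_MAX_SUBJECTS = 12


@dataclass
class TMap:
    values: np.ndarray          # (n_channels, n_times)
    df: int
    ch_names: list[str]
    times: np.ndarray
    degenerate: np.ndarray = None  # bool mask of zero-variance locations

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.values, dtype=bool)


@dataclass
class Cluster:
    members: list[tuple[int, int]]   # (channel index, time index)
    polarity: str                    # positive | negative
    mass: float
    p_value: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PermutationNull:
    max_mass: np.ndarray
    min_mass: np.ndarray
    n_permutations: int
    seed: int | None
    exact: bool = False


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tmap: TMap
    null: PermutationNull
    alpha: float
    threshold: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None
                and c.p_value <= self.alpha]

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "threshold": self.threshold,
            "n_permutations": self.null.n_permutations,
            "clusters": [{
                "polarity": c.polarity, "mass": c.mass, "p_value": c.p_value,
                "members": [[int(i), int(j)] for i, j in c.members],
            } for c in self.clusters],
        }, indent=1)


def paired_tmap(a: np.ndarray, b: np.ndarray,
                ch_names: list[str] | None = None,
                times: np.ndarray | None = None) -> TMap:
    """One-sample t of a-b across subjects at each (channel, time).

    Zero-variance locations get a +/- sentinel value (or 0 when the mean
    is also 0) and are marked degenerate.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("condition tensors must have the same shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degen = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degen] = np.sign(mean[degen]) * T_SENTINEL
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(a.shape[1])]
    if times is None:
        times = np.arange(a.shape[2], dtype=float)
    return TMap(t, n - 1, list(ch_names), np.asarray(times), degen)


def _adjacent_pairs(adjacency: np.ndarray) -> np.ndarray:
    i, j = np.nonzero(np.triu(adjacency, 1))
    return np.column_stack([i, j])


def _component_masses(t: np.ndarray, mask: np.ndarray,
                      pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masses and labels of connected components of ``mask``.

    Connectivity: (c,t)~(c,t+-1) and (c,t)~(c',t) for adjacent channels.
    Sentinel-valued cells contribute zero to the mass.  Returns
    (masses per component, label image with -1 outside the mask).
    """
    n_ch, n_t = mask.shape
    idx = np.arange(n_ch * n_t).reshape(n_ch, n_t)
    rows, cols = [], []
    tm = mask[:, :-1] & mask[:, 1:]
    rows.append(idx[:, :-1][tm]); cols.append(idx[:, 1:][tm])
    for i, j in pairs:
        cm = mask[i] & mask[j]
        rows.append(idx[i][cm]); cols.append(idx[j][cm])
    r = np.concatenate(rows) if rows else np.array([], int)
    c = np.concatenate(cols) if cols else np.array([], int)
    graph = sparse.coo_matrix(
        (np.ones(len(r)), (r, c)), shape=(n_ch * n_t, n_ch * n_t))
    _, labels = connected_components(graph, directed=False)
    labels = labels.reshape(n_ch, n_t)

    flat_mask = mask.ravel()
    masked_labels = labels.ravel()[flat_mask]
    uniq, renum = np.unique(masked_labels, return_inverse=True)
    weights = t.ravel()[flat_mask].copy()
    weights[np.abs(weights) >= T_SENTINEL] = 0.0
    masses = np.bincount(renum, weights=weights, minlength=len(uniq))
    label_img = np.full(mask.shape, -1, dtype=int)
    label_img.ravel()[flat_mask] = renum
    return masses, label_img


def find_clusters(tmap: TMap | np.ndarray, threshold: float = 2.0,
                  adjacency: np.ndarray | None = None) -> list[Cluster]:
    """Positive and negative supra-threshold clusters with summed-t masses."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = tmap.values if isinstance(tmap, TMap) else np.asarray(tmap, float)
    if adjacency is None:
        adjacency = np.zeros((t.shape[0], t.shape[0]), bool)
    pairs = _adjacent_pairs(adjacency)
    clusters: list[Cluster] = []
    for polarity, mask in (("positive", t > threshold),
                           ("negative", t < -threshold)):
        if not mask.any():
            continue
        masses, labels = _component_masses(t, mask, pairs)
        for k, mass in enumerate(masses):
            members = [(int(i), int(j)) for i, j in zip(*np.nonzero(labels == k))]
            clusters.append(Cluster(members, polarity, float(mass)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _adjacency_lists(adjacency: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(row) for row in adjacency]


def _bfs_extreme(t: np.ndarray, mask: np.ndarray,
                 adj_lists: list[np.ndarray], positive: bool) -> float:
    """Extreme component mass by breadth-first search over supra cells.

    Fast path for permutation nulls, where supra-threshold sets are
    typically tiny; avoids building a full sparse graph per permutation.
    """
    cellset = {(int(c), int(ti)) for c, ti in zip(*np.nonzero(mask))}
    seen: set[tuple[int, int]] = set()
    best = 0.0
    for cell in list(cellset):
        if cell in seen:
            continue
        stack = [cell]
        seen.add(cell)
        mass = 0.0
        while stack:
            c, ti = stack.pop()
            v = t[c, ti]
            if abs(v) < T_SENTINEL:
                mass += v
            for nb in ((c, ti - 1), (c, ti + 1)):
                if nb in cellset and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
            for cc in adj_lists[c]:
                nb = (int(cc), ti)
                if nb in cellset and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        best = max(best, mass) if positive else min(best, mass)
    return best


def _extreme_masses(t: np.ndarray, threshold: float, pairs: np.ndarray,
                    adj_lists: list[np.ndarray] | None = None
                    ) -> tuple[float, float]:
    """(largest positive mass, smallest negative mass), zeros when none."""
    hi = 0.0
    mask = t > threshold
    if mask.any():
        if adj_lists is not None and mask.sum() <= 500:
            hi = _bfs_extreme(t, mask, adj_lists, positive=True)
        else:
            masses, _ = _component_masses(t, mask, pairs)
            if len(masses):
                hi = float(masses.max())
    lo = 0.0
    mask = t < -threshold
    if mask.any():
        if adj_lists is not None and mask.sum() <= 500:
            lo = _bfs_extreme(t, mask, adj_lists, positive=False)
        else:
            masses, _ = _component_masses(t, mask, pairs)
            if len(masses):
                lo = float(masses.min())
    return hi, lo


def _sign_matrix(n: int, n_permutations: int,
                 seed: int | None) -> tuple[np.ndarray, bool]:
    if n <= EXACT_MAX_SUBJECTS:
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :] & 1
        return 2.0 * bits - 1.0, True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_permutations, n)), False


def _flip_tmaps(d2: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for sign-flipped paired differences, vectorized over flips.

    ``d2`` is (n_subjects, n_locations); sign flips only move the mean,
    the sum of squares is invariant.
    """
    n = d2.shape[0]
    ss = (d2 ** 2).sum(axis=0)
    mean = signs @ d2 / n
    var = np.maximum(ss / n - mean ** 2, 0.0) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = np.sign(mean[~np.isfinite(t)]) * T_SENTINEL
    return t


def permutation_null(a: np.ndarray, b: np.ndarray, threshold: float = 2.0,
                     adjacency: np.ndarray | None = None,
                     n_permutations: int = 2000,
                     seed: int | None = None) -> PermutationNull:
    """Null distribution of extreme cluster masses under sign flipping.

    Each permutation flips the condition assignment within a random
    subject subset (equivalently the sign of that subject's difference),
    recomputes the t-map and clusters, and records the largest positive
    and smallest negative cluster mass (zero when a polarity has no
    clusters).  All 2^n flips are enumerated when n <= 12.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.shape[0]
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    if adjacency is None:
        adjacency = np.zeros((a.shape[1], a.shape[1]), bool)
    pairs = _adjacent_pairs(adjacency)
    adj_lists = _adjacency_lists(adjacency)
    d = (a - b).reshape(n, -1)
    shape = a.shape[1:]
    signs, exact = _sign_matrix(n, n_permutations, seed)

    hi = np.zeros(len(signs))
    lo = np.zeros(len(signs))
    chunk = max(1, int(5e6 // max(d.shape[1], 1)))
    for s0 in range(0, len(signs), chunk):
        t_block = _flip_tmaps(d, signs[s0:s0 + chunk])
        supra = np.abs(t_block) > threshold
        for k in np.flatnonzero(supra.any(axis=1)):
            h, l = _extreme_masses(t_block[k].reshape(shape), threshold,
                                   pairs, adj_lists)
            hi[s0 + k], lo[s0 + k] = h, l
    return PermutationNull(hi, lo, len(signs), seed, exact)


def cluster_test(a: np.ndarray, b: np.ndarray,
                 layout: ChannelLayout | np.ndarray | None = None,
                 alpha: float = 0.05, threshold: float = 2.0,
                 n_permutations: int = 2000, seed: int | None = None,
                 ch_names: list[str] | None = None,
                 times: np.ndarray | None = None) -> ClusterResult:
    """Full paired cluster permutation test.

    ``layout`` may be a ChannelLayout (adjacency from angular distance)
    or a precomputed boolean adjacency matrix.  Each cluster's |mass| is
    compared against the permutation distribution of the most extreme
    cluster mass of either polarity (the two-sided max-statistic
    reference), so the family-wise error is controlled at ``alpha``
    across the whole search space and both polarities.  P-values use
    the add-one estimate p = (1 + #{null at least as extreme}) /
    (1 + P), guaranteeing validity; clusters with p <= alpha are
    flagged significant.
    """
    if isinstance(layout, ChannelLayout):
        adjacency = build_adjacency(layout)
        ch_names = ch_names or list(layout.ch_names)
    else:
        adjacency = layout
    tmap = paired_tmap(a, b, ch_names=ch_names, times=times)
    clusters = find_clusters(tmap, threshold, adjacency)
    null = permutation_null(a, b, threshold, adjacency, n_permutations, seed)
    P = null.n_permutations
    extreme = np.maximum(null.max_mass, -null.min_mass)
    for c in clusters:
        more = int((extreme >= abs(c.mass)).sum())
        c.p_value = (1 + more) / (1 + P)
    return ClusterResult(clusters, tmap, null, alpha, threshold)
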
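"""Spatiotemporal cluster-based permutation testing of TRF waveforms.

Family-wise error control for channel x time comparisons: a t-test (paired
or Welch) runs at every point; points whose |t| exceeds the two-sided
cluster-forming threshold are grouped into clusters connected through
temporal contiguity and spatial electrode adjacency (default: electrodes
within 4 cm); each cluster's mass (sum of t) is compared against a Monte
Carlo null distribution of maximum cluster masses obtained by sign-flipping
condition differences (paired) or shuffling group labels (independent).
Positive and negative clusters are formed separately from the signed t map.
Corrected p = (1 + #{null >= observed}) / (n_permutations + 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterResult",
    "build_adjacency",
    "cluster_perm_test",
    "result_to_json",
    "summary_table",
]


@dataclass
class AdjacencyGraph:
    """Undirected electrode neighborhood graph (no self-edges)."""

    ch_names: list[str]
    pairs: list[tuple[int, int]]
    radius: float

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)


def build_adjacency(
    ch_names: list[str], positions: np.ndarray, radius: float = 0.04
) -> AdjacencyGraph:
    """Neighbors are channel pairs within ``radius`` meters (center-to-center)."""
    positions = np.asarray(positions, dtype=float)
    if len(ch_names) < 2:
        raise ValueError("at least 2 channels required")
    if positions.shape != (len(ch_names), 3) or not np.all(np.isfinite(positions)):
        bad = (
            [n for n, p in zip(ch_names, positions) if not np.all(np.isfinite(p))]
            if positions.shape == (len(ch_names), 3)
            else list(ch_names)
        )
        raise ValueError(f"missing or invalid positions for channels: {bad}")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    pairs = [
        (i, j)
        for i in range(len(ch_names))
        for j in range(i + 1, len(ch_names))
        if d[i, j] <= radius
    ]
    return AdjacencyGraph(ch_names=list(ch_names), pairs=pairs, radius=radius)


@dataclass
class Cluster:
    """One spatiotemporal cluster: members, mass statistic, corrected p."""

    members: list[tuple[int, int]]  # (channel index, time index)
    mass: float
    p: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cluster_alpha: float
    n_permutations: int
    t_obs: np.ndarray = field(repr=False)
    threshold: float | np.ndarray = field(repr=False, default=0.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _label_components(
    mask: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Connected components of supra-threshold (channel, time) points.

    Connectivity: same channel at adjacent times, or neighboring channels at
    the same time.  Returns (flat node indices, component label per node,
    n_components).
    """
    n_ch, n_t = mask.shape
    flat = mask.ravel()
    nodes = np.flatnonzero(flat)
    if nodes.size == 0:
        return nodes, np.empty(0, dtype=int), 0
    index_of = np.full(n_ch * n_t, -1, dtype=np.int64)
    index_of[nodes] = np.arange(nodes.size)
    rows, cols = [], []
    tm = mask[:, :-1] & mask[:, 1:]
    if tm.any():
        c_idx, t_idx = np.nonzero(tm)
        rows.append(c_idx * n_t + t_idx)
        cols.append(c_idx * n_t + t_idx + 1)
    for a, b in pairs:
        sm = mask[a] & mask[b]
        if sm.any():
            t_idx = np.flatnonzero(sm)
            rows.append(a * n_t + t_idx)
            cols.append(b * n_t + t_idx)
    if rows:
        r = index_of[np.concatenate(rows)]
        c = index_of[np.concatenate(cols)]
        graph = sparse.coo_matrix(
            (np.ones(len(r)), (r, c)), shape=(nodes.size, nodes.size)
        )
        n_comp, labels = connected_components(graph, directed=False)
    else:
        n_comp, labels = nodes.size, np.arange(nodes.size)
    return nodes, labels, n_comp


def _clusters_from_tmap(
    tmap: np.ndarray, threshold: np.ndarray | float, pairs: list[tuple[int, int]]
) -> list[tuple[np.ndarray, float, int]]:
    """Signed clusters: (flat member indices, mass, sign)."""
    out = []
    for sign in (1, -1):
        mask = (sign * tmap) > threshold
        nodes, labels, n_comp = _label_components(mask, pairs)
        if n_comp == 0:
            continue
        masses = np.bincount(labels, weights=tmap.ravel()[nodes], minlength=n_comp)
        for k in range(n_comp):
            out.append((nodes[labels == k], float(masses[k]), sign))
    return out


def _max_mass(tmap, threshold, pairs) -> float:
    clusters = _clusters_from_tmap(tmap, threshold, pairs)
    if not clusters:
        return 0.0
    return max(abs(m) for _, m, _ in clusters)


def _paired_tmaps(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t maps for sign-flipped subject differences.

    ``diffs``: (n_subjects, n_points); ``signs``: (n_perm, n_subjects) of ±1.
    Squares are sign-invariant, so only the mean changes per permutation.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n
    ssq = (diffs**2).sum(axis=0) / n
    var = (ssq - mean**2) * n / (n - 1)
    var = np.clip(var, 1e-300, None)
    return mean / np.sqrt(var / n)


def _welch_tmaps(
    X: np.ndarray, members: np.ndarray, n1: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and df maps for group memberships.

    ``X``: (n_subjects, n_points); ``members``: (n_perm, n_subjects) boolean
    masks selecting group 1 (each row has exactly n1 True).
    """
    n = X.shape[0]
    n2 = n - n1
    M = members.astype(float)
    s1 = M @ X
    q1 = M @ (X**2)
    s = X.sum(axis=0)
    q = (X**2).sum(axis=0)
    m1 = s1 / n1
    m2 = (s - s1) / n2
    v1 = np.clip((q1 - n1 * m1**2) / (n1 - 1), 1e-300, None)
    v2 = np.clip(((q - q1) - n2 * m2**2) / (n2 - 1), 1e-300, None)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def cluster_perm_test(
    A: np.ndarray,
    B: np.ndarray,
    design: str,
    adjacency: AdjacencyGraph,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> ClusterResult:
    """Compare two sets of per-subject (channels x times) waveforms.

    ``design="paired"`` requires the same subjects in the same order in A and
    B and permutes by sign-flipping within-subject differences;
    ``design="independent"`` compares disjoint groups with Welch t-tests and
    permutes group labels.  Identical seeds reproduce identical p-values.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 3 or B.ndim != 3 or A.shape[1:] != B.shape[1:]:
        raise ValueError("A and B must be (subjects, channels, times) with equal maps")
    if A.shape[1] != adjacency.n_channels:
        raise ValueError("adjacency graph does not match channel count")
    if A.shape[2] < 2:
        raise ValueError("at least 2 time samples required")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_ch, n_t = A.shape[1:]
    pairs = adjacency.pairs

    if design == "paired":
        if A.shape[0] != B.shape[0]:
            raise ValueError("paired design requires matched subjects")
        diffs = (A - B).reshape(A.shape[0], -1)
        n = diffs.shape[0]
        threshold = float(t_dist.ppf(1 - cluster_alpha / 2, df=n - 1))
        t_obs = _paired_tmaps(diffs, np.ones((1, n)))[0].reshape(n_ch, n_t)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        null_t = _paired_tmaps(diffs, signs)
        null_max = np.array(
            [
                _max_mass(null_t[p].reshape(n_ch, n_t), threshold, pairs)
                for p in range(n_permutations)
            ]
        )
        thr_arr: float | np.ndarray = threshold
    elif design == "independent":
        n1, n2 = A.shape[0], B.shape[0]
        X = np.concatenate([A, B], axis=0).reshape(n1 + n2, -1)
        obs_members = np.zeros((1, n1 + n2), dtype=bool)
        obs_members[0, :n1] = True
        t_map, df_map = _welch_tmaps(X, obs_members, n1)
        t_obs = t_map[0].reshape(n_ch, n_t)
        thr_arr = t_dist.ppf(1 - cluster_alpha / 2, df=df_map[0]).reshape(n_ch, n_t)
        perm_members = np.zeros((n_permutations, n1 + n2), dtype=bool)
        for p in range(n_permutations):
            perm_members[p, rng.permutation(n1 + n2)[:n1]] = True
        null_t, null_df = _welch_tmaps(X, perm_members, n1)
        null_max = np.empty(n_permutations)
        for p in range(n_permutations):
            thr_p = t_dist.ppf(1 - cluster_alpha / 2, df=null_df[p]).reshape(n_ch, n_t)
            null_max[p] = _max_mass(null_t[p].reshape(n_ch, n_t), thr_p, pairs)
        threshold = thr_arr
    else:
        raise ValueError("design must be 'paired' or 'independent'")

    clusters = []
    for nodes, mass, sign in _clusters_from_tmap(t_obs, thr_arr, pairs):
        p_val = (1 + int((null_max >= abs(mass)).sum())) / (n_permutations + 1)
        members = [(int(k // n_t), int(k % n_t)) for k in nodes]
        clusters.append(Cluster(members=members, mass=mass, p=p_val, sign=sign))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters=clusters,
        cluster_alpha=cluster_alpha,
        n_permutations=n_permutations,
        t_obs=t_obs,
        threshold=threshold,
    )


def result_to_json(
    result: ClusterResult,
    ch_names: list[str],
    times_ms: np.ndarray,
    path: str | Path | None = None,
) -> dict:
    """Serialize clusters with channel labels and times in milliseconds."""
    payload = {
        "cluster_alpha": result.cluster_alpha,
        "n_permutations": result.n_permutations,
        "clusters": [
            {
                "mass": c.mass,
                "p": c.p,
                "sign": c.sign,
                "members": [
                    {"channel": ch_names[ci], "time_ms": float(times_ms[ti])}
                    for ci, ti in c.members
                ],
            }
            for c in result.clusters
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def summary_table(
    result: ClusterResult, ch_names: list[str], times_ms: np.ndarray
) -> pd.DataFrame:
    """Tidy per-cluster summary: span, channel count, mass, corrected p."""
    rows = []
    for k, c in enumerate(result.clusters):
        ts = [times_ms[ti] for _, ti in c.members]
        chs = {ch_names[ci] for ci, _ in c.members}
        rows.append(
            {
                "cluster": k,
                "sign": c.sign,
                "t_start_ms": min(ts),
                "t_end_ms": max(ts),
                "n_channels": len(chs),
                "mass": c.mass,
                "p": c.p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", "sign", "t_start_ms", "t_end_ms", "n_channels", "mass", "p"],
    )
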
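"""Permutation and cluster-permutation tests for ERP condition contrasts.

All tests share the same scheme: the observed statistic is computed from
the condition labels, the labels are randomly re-partitioned many times
(keeping the group sizes), and the p-value is the add-one proportion of
permutations at least as extreme as the observation,

    p = (1 + #{perm >= obs}) / (1 + n_perm),

so the smallest attainable p is 1/(n_perm + 1) (0.001 at 1,000
permutations) and p = 0 never occurs.

The cluster-based variants threshold the *raw mean difference* waveform
(temporal) or the window-averaged per-channel mean difference (spatial),
form clusters of adjacent supra-threshold samples/channels of the same
sign, score each cluster by the summed mean difference, and compare
against the permutation distribution of the maximum cluster score.  The
cluster-forming threshold changes sensitivity but not the false-alarm
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import EpochSet, ERPWave, ValidationError


class UndefinedSimilarityError(ValidationError):
    """Cosine similarity of a zero-norm waveform is undefined."""


def bonferroni_alpha(base_alpha: float, n_comparisons: int) -> float:
    """Bonferroni-corrected significance level base/n."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return base_alpha / n_comparisons


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_matrix(x, channel: str | None = None) -> np.ndarray:
    """Coerce an EpochSet (one channel picked) or array to (epochs, samples)."""
    if isinstance(x, EpochSet):
        if channel is not None:
            return x.get_channel(channel)
        if x.n_channels == 1:
            return x.data[:, 0, :]
        raise ValidationError(
            "multi-channel EpochSet: a channel must be selected"
        )
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _perm_mean_diffs(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean differences (subset_a - subset_b) for random partitions.

    Returns (n_perm, features).  Only the smaller subset is summed per
    permutation; the other mean follows from the pooled total.
    """
    n = pooled.shape[0]
    n_b = n - n_a
    total = pooled.sum(axis=0)
    k = min(n_a, n_b)
    out = np.empty((n_perm, pooled.shape[1]))
    for i in range(n_perm):
        idx = rng.permutation(n)[:k]
        s_k = pooled[idx].sum(axis=0)
        if k == n_a:
            out[i] = s_k / n_a - (total - s_k) / n_b
        else:
            out[i] = (total - s_k) / n_a - s_k / n_b
    return out


# ---------------------------------------------------------------------------
# plain permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    a,
    b,
    n_perm: int = 1000,
    sided: str = "two",
    channel: str | None = None,
    seed: int | np.random.Generator | None = None,
):
    """Label-permutation test of the difference of condition means.

    ``a`` and ``b`` are (epochs, features) arrays or single-channel
    EpochSets (pick a channel with ``channel``).  The statistic is
    ``mean(a) - mean(b)`` per feature; extremeness is two-sided
    (``|perm| >= |obs|``) or one-sided (``perm >= obs``).  Returns a
    scalar p for one feature, else an array of per-feature p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    A = _as_matrix(a, channel)
    B = _as_matrix(b, channel)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError("both condition sets must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = A.mean(axis=0) - B.mean(axis=0)
    pooled = np.concatenate([A, B], axis=0)
    diffs = _perm_mean_diffs(pooled, A.shape[0], n_perm, rng)
    if sided == "two":
        exceed = (np.abs(diffs) >= np.abs(obs)[None, :]).sum(axis=0)
    else:
        exceed = (diffs >= obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(p[0]) if p.size == 1 else p


# ---------------------------------------------------------------------------
# cluster machinery
# ---------------------------------------------------------------------------

@dataclass
class ClusterTestResult:
    """Clusters, their summed-difference scores and permutation p-values.

    ``clusters`` holds half-open sample-index intervals ``(start, stop)``
    for temporal tests, or tuples of channel labels for spatial tests.
    """

    clusters: list
    cluster_stats: np.ndarray
    p_values: np.ndarray
    threshold: float
    n_permutations: int
    sided: str
    mode: str                      # "temporal" | "spatial"
    alpha: float = 0.05
    times_ms: np.ndarray | None = None
    null_max: np.ndarray | None = None

    def __post_init__(self):
        self.cluster_stats = np.asarray(self.cluster_stats, float)
        self.p_values = np.asarray(self.p_values, float)
        assert len(self.clusters) == self.p_values.size

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def extents_ms(self) -> list[tuple[float, float]]:
        """Temporal cluster extents [start, end] in ms (inclusive ends)."""
        if self.mode != "temporal" or self.times_ms is None:
            raise ValidationError("extents_ms applies to temporal results")
        return [
            (float(self.times_ms[s]), float(self.times_ms[e - 1]))
            for s, e in self.clusters
        ]

    def significant(self, alpha: float | None = None) -> np.ndarray:
        alpha = self.alpha if alpha is None else alpha
        return self.p_values <= alpha

    def any_significant(self, alpha: float | None = None) -> bool:
        return bool(self.significant(alpha).any()) if self.n_clusters else False

    def to_frame(self) -> pd.DataFrame:
        if self.mode == "temporal":
            ext = self.extents_ms()
            desc = [f"{s:.0f}..{e:.0f} ms" for s, e in ext]
        else:
            desc = [",".join(c) for c in self.clusters]
        return pd.DataFrame(
            {
                "cluster": desc,
                "stat": self.cluster_stats,
                "p_value": self.p_values,
            }
        )

    def summary(self) -> str:
        head = (
            f"{self.mode} cluster permutation test "
            f"({self.sided}-sided, threshold {self.threshold:g}, "
            f"{self.n_permutations} permutations)"
        )
        if self.n_clusters == 0:
            return head + "\nno supra-threshold clusters"
        return head + "\n" + self.to_frame().to_string(index=False)


def _find_clusters_1d(
    d: np.ndarray, threshold: float, sided: str
) -> list[tuple[int, int, float]]:
    """Same-sign runs of supra-threshold samples: (start, stop, sum)."""
    out = []
    masks = [d > threshold]
    if sided == "two":
        masks.append(d < -threshold)
    for mask in masks:
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((int(s), int(e), float(d[s:e].sum())))
    out.sort(key=lambda c: c[0])
    return out


def temporal_cluster_test(
    a,
    b,
    channel: str | None = None,
    threshold: float = 1.0,
    n_perm: int = 1000,
    sided: str = "two",
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    times_ms: np.ndarray | None = None,
) -> ClusterTestResult:
    """Cluster permutation test of a single-channel condition contrast.

    Clusters are maximal runs of temporally adjacent samples whose mean
    difference exceeds ``threshold`` (absolutely, for two-sided testing;
    runs keep one sign).  Each cluster is scored by the summed difference;
    the null distribution is the maximum (absolute) cluster score over
    label permutations, with permutations lacking any supra-threshold
    cluster contributing 0.
    """
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    A = _as_matrix(a, channel)
    B = _as_matrix(b, channel)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError("both condition sets must be nonempty")
    if times_ms is None and isinstance(a, EpochSet):
        times_ms = a.times_ms
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d_obs = A.mean(axis=0) - B.mean(axis=0)
    clusters = _find_clusters_1d(d_obs, threshold, sided)

    pooled = np.concatenate([A, B], axis=0)
    diffs = _perm_mean_diffs(pooled, A.shape[0], n_perm, rng)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _find_clusters_1d(diffs[i], threshold, sided)
        if cl:
            null_max[i] = max(abs(c[2]) for c in cl) if sided == "two" else max(
                c[2] for c in cl
            )

    stats_ = np.array([c[2] for c in clusters])
    ref = np.abs(stats_) if sided == "two" else stats_
    p = np.array(
        [(1.0 + (null_max >= r).sum()) / (1.0 + n_perm) for r in ref]
    )
    return ClusterTestResult(
        clusters=[(s, e) for s, e, _ in clusters],
        cluster_stats=stats_,
        p_values=p,
        threshold=threshold,
        n_permutations=n_perm,
        sided=sided,
        mode="temporal",
        alpha=alpha,
        times_ms=None if times_ms is None else np.asarray(times_ms, float),
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# spatial (channel-adjacency) cluster test
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyGraph:
    """Channel neighbourhood graph (symmetric, no self-edges)."""

    labels: list[str]
    edges: set[frozenset]

    def __post_init__(self):
        for e in self.edges:
            if len(e) != 2:
                raise ValidationError("adjacency edges must join two channels")
            for c in e:
                if c not in self.labels:
                    raise ValidationError(f"edge references unknown channel {c!r}")

    @classmethod
    def from_montage(
        cls,
        montage2d: Mapping[str, tuple[float, float]],
        labels: Sequence[str] | None = None,
        factor: float = 1.5,
    ) -> "AdjacencyGraph":
        """Channels within ``factor`` x the median nearest-neighbour distance."""
        labels = list(labels) if labels is not None else list(montage2d)
        pos = np.array([montage2d[c] for c in labels], float)
        n = len(labels)
        if n < 2:
            return cls(labels, set())
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        cutoff = factor * float(np.median(d.min(axis=1)))
        edges = {
            frozenset((labels[i], labels[j]))
            for i in range(n)
            for j in range(i + 1, n)
            if d[i, j] <= cutoff
        }
        return cls(labels, edges)

    def neighbors(self, label: str) -> set[str]:
        return {next(iter(e - {label})) for e in self.edges if label in e}

    def subgraph_components(self, members: Sequence[str]) -> list[list[str]]:
        """Connected components of the induced subgraph over ``members``."""
        members = list(members)
        index = {c: i for i, c in enumerate(members)}
        rows, cols = [], []
        for e in self.edges:
            u, v = tuple(e)
            if u in index and v in index:
                rows += [index[u], index[v]]
                cols += [index[v], index[u]]
        m = len(members)
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
        n_comp, assign = connected_components(graph, directed=False)
        comps: list[list[str]] = [[] for _ in range(n_comp)]
        for c, k in zip(members, assign):
            comps[k].append(c)
        return comps


def _find_clusters_spatial(
    stat: np.ndarray,
    labels: Sequence[str],
    adjacency: AdjacencyGraph,
    threshold: float,
    sided: str,
) -> list[tuple[tuple[str, ...], float]]:
    out = []
    masks = [stat > threshold]
    if sided == "two":
        masks.append(stat < -threshold)
    lab = np.asarray(labels, object)
    for mask in masks:
        if not mask.any():
            continue
        members = list(lab[mask])
        for comp in adjacency.subgraph_components(members):
            idx = [list(labels).index(c) for c in comp]
            out.append((tuple(comp), float(stat[idx].sum())))
    out.sort(key=lambda c: -abs(c[1]))
    return out


def spatial_cluster_test(
    a: EpochSet,
    b: EpochSet,
    window: tuple[float, float],
    adjacency: AdjacencyGraph | None = None,
    threshold: float = 1.0,
    n_perm: int = 1000,
    sided: str = "two",
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> ClusterTestResult:
    """Cluster permutation test over channels in a time window.

    The per-channel statistic is the condition mean difference averaged
    over ``window`` (ms).  Spatial clusters are connected components of
    same-sign supra-threshold channels in the adjacency graph; everything
    else follows the temporal machinery.
    """
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    if a.channel_labels != b.channel_labels:
        raise ValidationError("channel sets differ")
    labels = list(a.channel_labels)
    if adjacency is None:
        adjacency = AdjacencyGraph.from_montage(a.montage2d, labels)
    missing = [c for c in labels if c not in adjacency.labels]
    if missing:
        raise ValidationError(f"channels missing from adjacency: {missing}")
    lo, hi = window
    mask = (a.times_ms >= lo) & (a.times_ms <= hi)
    if not mask.any():
        raise ValidationError(f"empty window {window}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # per-epoch, per-channel window means -> (epochs, channels)
    Ma = a.data[:, :, mask].mean(axis=2)
    Mb = b.data[:, :, mask].mean(axis=2)
    if Ma.shape[0] == 0 or Mb.shape[0] == 0:
        raise ValidationError("both condition sets must be nonempty")
    stat_obs = Ma.mean(axis=0) - Mb.mean(axis=0)
    clusters = _find_clusters_spatial(stat_obs, labels, adjacency, threshold, sided)

    pooled = np.concatenate([Ma, Mb], axis=0)
    diffs = _perm_mean_diffs(pooled, Ma.shape[0], n_perm, rng)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _find_clusters_spatial(diffs[i], labels, adjacency, threshold, sided)
        if cl:
            null_max[i] = max(abs(c[1]) for c in cl) if sided == "two" else max(
                c[1] for c in cl
            )

    stats_ = np.array([c[1] for c in clusters])
    ref = np.abs(stats_) if sided == "two" else stats_
    p = np.array(
        [(1.0 + (null_max >= r).sum()) / (1.0 + n_perm) for r in ref]
    )
    return ClusterTestResult(
        clusters=[c[0] for c in clusters],
        cluster_stats=stats_,
        p_values=p,
        threshold=threshold,
        n_permutations=n_perm,
        sided=sided,
        mode="spatial",
        alpha=alpha,
        null_max=null_max,
    )


# ---------------------------------------------------------------------------
# cosine similarity between scalp and ear difference waveforms
# ---------------------------------------------------------------------------

def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError(
            "cosine similarity undefined for a zero-norm waveform"
        )
    return float(u @ v / (nu * nv))


def cosine_similarity_test(
    ear_target,
    ear_nontarget,
    scalp_diff: ERPWave | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Similarity of the ear difference ERP to a scalp difference wave.

    The score is the cosine between the ear target-minus-non-target
    average (from spatially filtered single-channel ear epochs) and the
    scalp difference waveform.  The null is built by shuffling the ear
    epochs' target/non-target labels, recomputing the ear difference ERP
    and rescoring; p is the add-one proportion of permuted scores >= the
    observed score.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    T = _as_matrix(ear_target)
    N = _as_matrix(ear_nontarget)
    if T.shape[0] == 0 or N.shape[0] == 0:
        raise ValidationError("both condition sets must be nonempty")
    if isinstance(scalp_diff, ERPWave):
        if scalp_diff.data.shape[0] != 1:
            raise ValidationError("scalp_diff must be a single-channel wave")
        v = scalp_diff.data[0]
    else:
        v = np.asarray(scalp_diff, float).ravel()
    if v.size != T.shape[1]:
        raise ValidationError("time axes of ear and scalp waveforms differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs = _cosine(T.mean(axis=0) - N.mean(axis=0), v)
    pooled = np.concatenate([T, N], axis=0)
    diffs = _perm_mean_diffs(pooled, T.shape[0], n_perm, rng)
    norms = np.linalg.norm(diffs, axis=1)
    norms[norms == 0] = np.inf  # zero-diff permutation scores 0
    scores = diffs @ v / (norms * np.linalg.norm(v))
    p = (1.0 + (scores >= obs).sum()) / (1.0 + n_perm)
    return obs, float(p)
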
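"""Nonparametric cluster-based permutation inference.

Per-bin t statistics are thresholded at a two-tailed t-distribution quantile
(cluster-forming alpha), contiguous suprathreshold bins of equal sign are
clustered, cluster mass is the summed t, and family-wise error is controlled
by comparing each mass against the permutation distribution of the maximum
cluster mass (sign-flipping subject deviations for one-sample tests,
equivalent to within-subject condition swapping for paired tests).
Defaults follow common practice for sleep-EEG group analyses: 2000
permutations, two-tailed, cluster-forming p < 0.05, cluster p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist


@dataclass
class ClusterTestConfig:
    n_permutations: int = 2000
    alpha_cluster_forming: float = 0.05
    alpha_cluster: float = 0.05
    seed: int | None = 0
    time_window: tuple[float, float] | None = None   # restrict bins by time, needs `times`

    def __post_init__(self) -> None:
        if not 0 < self.alpha_cluster_forming < 1 or not 0 < self.alpha_cluster < 1:
            raise ValueError("alphas must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class ClusterResult:
    bins: np.ndarray          # 1-D: bin indices; TFR: (k, 3) array of (ch, freq, time)
    mass: float
    p: float
    sign: int                 # +1 or -1

    @property
    def significant(self) -> bool:
        return self.p < 0.05


_TINY_SD_T = 1e12   # stand-in t for zero-variance bins (sign carried by the mean)


def _t_one_sample(X: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0, robust to zero variance."""
    n = X.shape[0]
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    zero = sd == 0
    t[zero] = np.sign(m[zero]) * _TINY_SD_T
    return t


def _t_signflip_batch(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for a batch of sign-flip permutations.

    ``X`` is (n_subjects, n_bins) and ``signs`` (n_perm, n_subjects); uses the
    identity that flipping signs leaves per-bin sums of squares unchanged.
    """
    n = X.shape[0]
    m = signs @ X / n                               # (n_perm, n_bins)
    sumsq = (X**2).sum(axis=0)[None, :]
    var = (sumsq - n * m**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    zero = var == 0
    t[zero] = np.sign(m[zero]) * _TINY_SD_T
    return t


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index ranges of True runs in a boolean vector."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def _clusters_1d(t: np.ndarray, crit: float, allowed: np.ndarray | None):
    """Same-sign contiguous suprathreshold clusters of a 1-D t vector."""
    out = []
    for sign in (+1, -1):
        mask = (sign * t) > crit
        if allowed is not None:
            mask &= allowed
        for a, b in _runs(mask):
            out.append((np.arange(a, b), float(t[a:b].sum()), sign))
    return out


def _max_mass_1d(t: np.ndarray, crit: float, allowed: np.ndarray | None) -> float:
    clusters = _clusters_1d(t, crit, allowed)
    return max((abs(m) for _, m, _ in clusters), default=0.0)


def cluster_test_timecourse(data: np.ndarray, null_value: float = 0.0,
                            config: ClusterTestConfig | None = None,
                            times: np.ndarray | None = None) -> list[ClusterResult]:
    """Group-level cluster permutation test on per-subject time courses.

    ``data`` is (n_subjects, n_bins); per bin a one-sample t against
    ``null_value`` is formed, thresholded two-tailed, clustered over
    contiguous bins, and cluster masses are referred to the sign-flip
    permutation distribution of the maximum |mass|.
    """
    config = config or ClusterTestConfig()
    X = np.asarray(data, dtype=float) - null_value
    if X.ndim != 2:
        raise ValueError("data must be (n_subjects, n_bins)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("cluster test needs at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains NaN or infinite values")

    allowed = None
    if config.time_window is not None:
        if times is None:
            raise ValueError("time_window restriction requires the `times` vector")
        allowed = (times >= config.time_window[0]) & (times <= config.time_window[1])

    crit = stats.t.ppf(1 - config.alpha_cluster_forming / 2, df=n - 1)
    t_obs = _t_one_sample(X)
    observed = _clusters_1d(t_obs, crit, allowed)
    if not observed:
        return []

    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    null_max = np.empty(config.n_permutations)
    for chunk in range(0, config.n_permutations, 200):
        t_perm = _t_signflip_batch(X, signs[chunk:chunk + 200])
        for j, row in enumerate(t_perm):
            null_max[chunk + j] = _max_mass_1d(row, crit, allowed)

    results = []
    for bins, mass, sign in observed:
        p = (1 + np.sum(null_max >= abs(mass))) / (config.n_permutations + 1)
        results.append(ClusterResult(bins=bins, mass=mass, p=float(p), sign=sign))
    return sorted(results, key=lambda c: c.p)


# ---------------------------------------------------------------------------
# channel x frequency x time clusters
# ---------------------------------------------------------------------------

def channel_adjacency(positions: np.ndarray, threshold: float = 0.075) -> np.ndarray:
    """Symmetric boolean adjacency from electrode coordinates (metres).

    Channels within ``threshold`` of each other are neighbours; channels
    without any neighbour are left isolated (they can still form clusters on
    their own in frequency/time).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need coordinates for at least 2 channels")
    if not np.all(np.isfinite(pos)):
        raise ValueError("missing (non-finite) channel coordinates")
    d = squareform(pdist(pos))
    adj = d <= threshold
    np.fill_diagonal(adj, False)
    return adj


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _clusters_3d(t: np.ndarray, crit: float, adjacency: np.ndarray,
                 allowed_t: np.ndarray | None):
    """Same-sign clusters over (channel, freq, time): 4-neighbourhood in the
    freq-time plane plus cross-channel links through the adjacency graph."""
    n_ch, n_f, n_t = t.shape
    out = []
    for sign in (+1, -1):
        mask = (sign * t) > crit
        if allowed_t is not None:
            mask &= allowed_t[None, None, :]
        voxels = np.argwhere(mask)
        if voxels.size == 0:
            continue
        index = {tuple(v): k for k, v in enumerate(voxels)}
        uf = _UnionFind(len(voxels))
        neighbours_of = [np.flatnonzero(adjacency[c]) for c in range(n_ch)]
        for k, (c, f, tt) in enumerate(voxels):
            for cand in ((c, f + 1, tt), (c, f, tt + 1)):
                j = index.get(cand)
                if j is not None:
                    uf.union(k, j)
            for c2 in neighbours_of[c]:
                j = index.get((c2, f, tt))
                if j is not None:
                    uf.union(k, j)
        groups: dict[int, list[int]] = {}
        for k in range(len(voxels)):
            groups.setdefault(uf.find(k), []).append(k)
        for members in groups.values():
            vox = voxels[members]
            mass = float(t[vox[:, 0], vox[:, 1], vox[:, 2]].sum())
            out.append((vox, mass, sign))
    return out


def cluster_test_tfr(cond_a: np.ndarray, cond_b: np.ndarray, adjacency: np.ndarray,
                     config: ClusterTestConfig | None = None,
                     times: np.ndarray | None = None) -> list[ClusterResult]:
    """Paired cluster permutation test on per-subject TFRs.

    ``cond_a``/``cond_b`` are (n_subjects, n_channels, n_freqs, n_times);
    per-bin paired t on A - B, clusters contiguous in frequency and time and
    adjacent in channel space, permutation by within-subject condition
    swapping (sign flips of the difference).  ``config.time_window``
    restricts cluster-forming bins (e.g. to the post-cue interval).
    """
    config = config or ClusterTestConfig()
    A = np.asarray(cond_a, dtype=float)
    B = np.asarray(cond_b, dtype=float)
    if A.shape != B.shape or A.ndim != 4:
        raise ValueError("conditions must share shape (n_subjects, n_ch, n_freq, n_time)")
    n, n_ch = A.shape[0], A.shape[1]
    if n < 2:
        raise ValueError("cluster test needs at least 2 subjects")
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency must cover all channels")

    allowed_t = None
    if config.time_window is not None:
        if times is None:
            raise ValueError("time_window restriction requires the `times` vector")
        allowed_t = (times >= config.time_window[0]) & (times <= config.time_window[1])

    D = (A - B).reshape(n, -1)
    shape3 = A.shape[1:]
    crit = stats.t.ppf(1 - config.alpha_cluster_forming / 2, df=n - 1)
    t_obs = _t_one_sample(D).reshape(shape3)
    observed = _clusters_3d(t_obs, crit, adjacency, allowed_t)
    if not observed:
        return []

    rng = np.random.default_rng(config.seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    null_max = np.empty(config.n_permutations)
    for chunk in range(0, config.n_permutations, 50):
        t_perm = _t_signflip_batch(D, signs[chunk:chunk + 50])
        for j, row in enumerate(t_perm):
            clusters = _clusters_3d(row.reshape(shape3), crit, adjacency, allowed_t)
            null_max[chunk + j] = max((abs(m) for _, m, _ in clusters), default=0.0)

    results = []
    for vox, mass, sign in observed:
        p = (1 + np.sum(null_max >= abs(mass))) / (config.n_permutations + 1)
        results.append(ClusterResult(bins=vox, mass=mass, p=float(p), sign=sign))
    return sorted(results, key=lambda c: c.p)


#: Summary bands for cluster topographies: theta and the broad spindle band.
THETA_BAND = (5.0, 8.0)
SPINDLE_BAND = (10.0, 20.0)
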
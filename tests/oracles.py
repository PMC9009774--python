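"""Independent brute-force oracles used only by the test suite."""

import numpy as np
from scipy.spatial.distance import cdist


def dbscan_oracle(X: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Direct density-reachability DBSCAN: BFS from each unvisited core point.

    A point is core when its closed eps-ball (including itself) holds at
    least ``min_samples`` points; clusters are the density-reachable sets,
    everything else is noise (-1).
    """
    n = len(X)
    D = cdist(X, X)
    core = (D <= eps).sum(axis=1) >= min_samples
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        frontier = [i]
        while frontier:
            j = frontier.pop()
            if not core[j]:
                continue
            for k in np.nonzero(D[j] <= eps)[0]:
                if labels[k] == -1:
                    labels[k] = cid
                    frontier.append(int(k))
        cid += 1
    return labels


def dbscan_equivalent(labels_a: np.ndarray, labels_b: np.ndarray,
                      X: np.ndarray, eps: float, min_samples: int) -> bool:
    """Equality of two DBSCAN labelings up to relabeling.

    Noise sets must coincide and core points must induce the same partition;
    a border point (non-core, non-noise) may legitimately be claimed by any
    cluster owning a core point within eps of it, so those are checked
    against that reachability condition rather than for exact label match.
    """
    D = cdist(X, X)
    core = (D <= eps).sum(axis=1) >= min_samples
    noise_a, noise_b = labels_a == -1, labels_b == -1
    if not np.array_equal(noise_a, noise_b):
        return False
    # core partition must match under a label bijection
    mapping: dict[int, int] = {}
    used = set()
    for i in np.nonzero(core)[0]:
        la, lb = labels_a[i], labels_b[i]
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in used:
                return False
            mapping[la] = lb
            used.add(lb)
    # border points: both labels must own a core point within eps
    for i in np.nonzero(~core & ~noise_a)[0]:
        for labels in (labels_a, labels_b):
            owners = np.nonzero(core & (labels == labels[i]))[0]
            if not owners.size or D[i, owners].min() > eps:
                return False
    return True


def otsu_oracle_threshold(values: np.ndarray) -> float:
    """Exhaustive Otsu: maximize between-class variance over all cuts
    between consecutive distinct values; the threshold is the midpoint of
    the best cut."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    distinct = np.unique(v)
    best, best_thr = -np.inf, distinct[0]
    n = len(v)
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = (lo + hi) / 2.0
        left = v[v <= t]
        right = v[v > t]
        w0, w1 = len(left) / n, len(right) / n
        var_between = w0 * w1 * (left.mean() - right.mean()) ** 2
        if var_between > best:
            best, best_thr = var_between, t
    return best_thr


def bilateral_oracle(frame: np.ndarray, sigma_space: float, sigma_range: float) -> np.ndarray:
    """Per-pixel direct summation of bilateral weights (reflect padding)."""
    import math

    f = np.asarray(frame, dtype=np.float64)
    radius = max(1, int(math.ceil(3.0 * sigma_space)))
    padded = np.pad(f, radius, mode="reflect")
    h, w = f.shape
    out = np.zeros_like(f)
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    val = padded[i + radius + di, j + radius + dj]
                    wgt = math.exp(-(di * di + dj * dj) / (2 * sigma_space**2)) * math.exp(
                        -((val - f[i, j]) ** 2) / (2 * sigma_range**2)
                    )
                    num += wgt * val
                    den += wgt
            out[i, j] = num / den
    return out
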
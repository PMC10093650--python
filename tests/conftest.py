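import numpy as np
import pytest

from dryvision import DryingLaw, SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20231372)


@pytest.fixture
def small_scene():
    """Compact scene for fast rendering tests."""
    return SceneSpec(height=160, width=160, disks=((80.0, 80.0, 45.0),),
                     dust_count=10)


@pytest.fixture
def fast_law():
    """Law reaching the stopping ratio in a few minutes (short grids)."""
    return DryingLaw(page_k=0.8, page_n=1.2)


def svd_min_norm_lstsq(H, y):
    """Minimum-norm least-squares solution built explicitly from the SVD,
    with the standard max(M,N)·eps relative singular-value cutoff."""
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    cutoff = s.max() * max(H.shape) * np.finfo(float).eps if s.size else 0.0
    s_inv = np.where(s > cutoff, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return Vt.T @ (s_inv * (U.T @ y))


def random_histogram(rng, n_pixels=500):
    """Random 256-bin histogram with mass spread over a random support."""
    h = np.zeros(256, dtype=np.int64)
    n_levels = int(rng.integers(2, 40))
    levels = rng.choice(256, size=n_levels, replace=False)
    counts = rng.multinomial(n_pixels, np.ones(n_levels) / n_levels)
    h[levels] = counts
    return h


def brute_force_threshold(h):
    """Direct per-k evaluation of the metric cost; independent of the
    broadcast implementation. Returns (k, cost) at the smallest minimizer."""
    h = np.asarray(h, dtype=float)
    levels = np.arange(256, dtype=float)
    costs = {}
    for k in range(255):
        lo, hi = h[:k + 1], h[k + 1:]
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        mu1 = (lo * levels[:k + 1]).sum() / lo.sum()
        mu2 = (hi * levels[k + 1:]).sum() / hi.sum()
        costs[k] = (lo * np.abs(levels[:k + 1] - mu1)).sum() + \
                   (hi * np.abs(levels[k + 1:] - mu2)).sum()
    cmin = min(costs.values())
    tol = 1e-9 * max(cmin, 1.0)  # flat stretches over empty bins tie to fp noise
    k = min(k for k, c in costs.items() if c <= cmin + tol)
    return k, costs[k]


def flood_fill_label(mask):
    """Label 8-connected components by explicit flood fill (stack-based)."""
    mask = np.asarray(mask)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not labels[si, sj]:
                nxt += 1
                stack = [(si, sj)]
                labels[si, sj] = nxt
                while stack:
                    i, j = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] \
                                    and not labels[ni, nj]:
                                labels[ni, nj] = nxt
                                stack.append((ni, nj))
    return labels, nxt


def border_flood_fill_holes(mask):
    """Hole filling by complement of a 4-connected flood fill from the border."""
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    stack = [(i, j) for i in range(h) for j in (0, w - 1) if not mask[i, j]]
    stack += [(i, j) for i in (0, h - 1) for j in range(w) if not mask[i, j]]
    for i, j in stack:
        outside[i, j] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj] and not outside[ni, nj]:
                outside[ni, nj] = True
                stack.append((ni, nj))
    return (~outside).astype(np.uint8)
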
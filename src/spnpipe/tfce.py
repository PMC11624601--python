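"""Threshold-free cluster enhancement (TFCE) on vertex x time data and its
permutation tests.

TFCE replaces a cluster-forming threshold by integrating, over all
thresholds h, each supra-threshold spatiotemporal component's extent e(h)
raised to E times h raised to H:

    TFCE(p) = integral_{h0}^{h_p} e(h)^E h^H dh

approximated by a Riemann sum at thresholds h0 + k*dh (defaults E = 0.5,
H = 2, h0 = 0, dh = 0.4), with a final partial step up to the map maximum.
Spatiotemporal connectivity joins spatial neighbors at the same time sample
and the same vertex at adjacent samples; hemispheres are enhanced
disjointly.  Two-sided maps are enhanced separately per sign and recombined
with their signs.

Family-wise corrected p-values come from the permutation distribution of
the maximum |TFCE| over the whole map (both hemispheres jointly); a
pointwise null is available behind ``correction="pointwise"``.  The
one-sample test permutes by flipping the sign of whole-subject difference
maps, the two-sample test by shuffling group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse import csgraph

from .cohort import SourceSpace

__all__ = [
    "TfceParams",
    "TfceResult",
    "tfce_enhance",
    "connected_components",
    "one_sample_tfce_test",
    "two_sample_tfce_test",
]


@dataclass
class TfceParams:
    """TFCE exponents, threshold grid, and permutation settings."""

    e: float = 0.5
    h: float = 2.0
    h0: float = 0.0
    dh: float = 0.4
    n_perm: int = 5000
    two_sided: bool = True
    alpha: float = 0.05
    correction: str = "max"       # "max" (FWER) or "pointwise"

    def __post_init__(self):
        if self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if self.correction not in ("max", "pointwise"):
            raise ValueError("correction must be 'max' or 'pointwise'")


@dataclass
class TfceResult:
    """Statistic map, enhanced map, corrected p-values and clusters."""

    stat_map: np.ndarray       # (n_vert, n_time)
    tfce_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    cluster_labels: np.ndarray  # int, -1 = background
    alpha: float
    params: TfceParams
    n_perm_used: int
    exhaustive: bool = False

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max()) + 1 if self.sig_mask.any() else 0


# ---------------------------------------------------------------------------
# enhancement kernel: union-find over descending thresholds
# ---------------------------------------------------------------------------

@njit(cache=False)
def _uf_find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


@njit(cache=False)
def _enhance_one_sided(vals, indptr, indices, n_vert, n_time, E, H, h0, dh):
    """TFCE of a non-negative (n_vert*n_time,) map on the vertex-adjacency
    CSR x time lattice.  Nodes are added in descending value order and merged
    with already-present neighbors; at each threshold every present node
    accrues dh * h^H * size^E of its current component."""
    n = n_vert * n_time
    out = np.zeros(n)
    vmax = 0.0
    for i in range(n):
        if vals[i] > vmax:
            vmax = vals[i]
    if vmax <= h0 + 1e-12:
        return out

    n_full = int(np.floor((vmax - h0) / dh + 1e-9))
    partial = vmax - (h0 + n_full * dh)
    n_thr = n_full + (1 if partial > 1e-12 else 0)
    hs = np.empty(n_thr)
    ws = np.empty(n_thr)
    k = 0
    if partial > 1e-12:          # descending: partial step at the map max first
        hs[0] = vmax
        ws[0] = partial
        k = 1
    for j in range(n_full, 0, -1):
        hs[k] = h0 + j * dh
        ws[k] = dh
        k += 1

    order = np.argsort(-vals)
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    added = np.empty(n, dtype=np.int64)
    n_added = 0
    ptr = 0

    for ti in range(n_thr):
        h = hs[ti]
        thr = h - 1e-12
        while ptr < n and vals[order[ptr]] >= thr:
            node = order[ptr]
            parent[node] = node
            size[node] = 1
            v = node // n_time
            t = node % n_time
            # temporal neighbors
            for nb in (node - 1, node + 1):
                if nb >= 0 and nb < n and nb // n_time == v and parent[nb] >= 0:
                    ra = _uf_find(parent, node)
                    rb = _uf_find(parent, nb)
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            # spatial neighbors at the same time
            for j in range(indptr[v], indptr[v + 1]):
                nb = indices[j] * n_time + t
                if parent[nb] >= 0:
                    ra = _uf_find(parent, node)
                    rb = _uf_find(parent, nb)
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            added[n_added] = node
            n_added += 1
            ptr += 1
        coef = ws[ti] * h ** H
        for i in range(n_added):
            node = added[i]
            r = _uf_find(parent, node)
            out[node] += coef * size[r] ** E
    return out


def _hemi_blocks(space: SourceSpace) -> list[tuple[np.ndarray, sparse.csr_matrix]]:
    """(vertex index array, within-hemisphere adjacency CSR) per hemisphere."""
    adj = space.adjacency()
    blocks = []
    for hemi in ("L", "R"):
        idx = np.flatnonzero(space.hemi_mask(hemi))
        if len(idx):
            blocks.append((idx, adj[idx][:, idx].tocsr()))
    return blocks


def tfce_enhance(
    stat_map: np.ndarray,
    adjacency: sparse.spmatrix,
    params: TfceParams | None = None,
) -> np.ndarray:
    """Enhance a (n_vert, n_time) statistic map over the given vertex
    adjacency.  Two-sided enhancement (per sign, recombined signed) when
    ``params.two_sided``; vertices with no edges are isolated points."""
    params = params or TfceParams()
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("statistic map contains non-finite values")
    n_vert, n_time = stat_map.shape
    adj = sparse.csr_matrix(adjacency)
    if adj.shape != (n_vert, n_vert):
        raise ValueError("adjacency shape does not match the statistic map")
    flat = stat_map.ravel()
    pos = _enhance_one_sided(
        np.clip(flat, 0, None), adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64), n_vert, n_time,
        params.e, params.h, params.h0, params.dh,
    )
    if params.two_sided:
        neg = _enhance_one_sided(
            np.clip(-flat, 0, None), adj.indptr.astype(np.int64),
            adj.indices.astype(np.int64), n_vert, n_time,
            params.e, params.h, params.h0, params.dh,
        )
        out = pos - neg
    else:
        out = pos
    return out.reshape(n_vert, n_time)


def connected_components(
    mask: np.ndarray, adjacency: sparse.spmatrix
) -> np.ndarray:
    """Label spatiotemporal components of a boolean (n_vert, n_time) mask.

    Edges: spatial neighbor at the same time, same vertex at adjacent times.
    Returns int labels 0..k-1, background -1.
    """
    mask = np.asarray(mask, dtype=bool)
    n_vert, n_time = mask.shape
    labels = np.full(mask.shape, -1, dtype=int)
    idx = np.flatnonzero(mask.ravel())
    if len(idx) == 0:
        return labels
    adj = sparse.csr_matrix(adjacency)
    spatial = sparse.kron(adj, sparse.eye(n_time, format="csr"), format="csr")
    tt = sparse.diags([np.ones(n_time - 1)], [1], format="csr")
    temporal = sparse.kron(sparse.eye(n_vert, format="csr"), tt + tt.T, format="csr")
    g = (spatial + temporal)[idx][:, idx]
    _, lab = csgraph.connected_components(g, directed=False)
    # relabel by first appearance for determinism
    order = {}
    out = np.empty(len(lab), dtype=int)
    for i, l in enumerate(lab):
        if l not in order:
            order[l] = len(order)
        out[i] = order[l]
    labels.ravel()[idx] = out
    return labels


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _one_sample_t(mean: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    var = (ssq - n * mean**2) / (n - 1)
    var = np.clip(var, 1e-300, None)
    return mean / np.sqrt(var / n)


def _enhance_hemis(stat_map, blocks, n_time, params):
    out = np.zeros_like(stat_map)
    for idx, adj in blocks:
        out[idx] = tfce_enhance(stat_map[idx], adj, params)
    return out


def _collect_p(
    tfce_obs: np.ndarray,
    perm_stats,                      # iterator of (n_chunk, n_vert, n_time)
    blocks,
    params: TfceParams,
    n_perm_total: int,
    exhaustive: bool,
) -> np.ndarray:
    """Corrected p-map from permuted statistic maps."""
    n_time = tfce_obs.shape[1]
    obs_abs = np.abs(tfce_obs)
    count = np.zeros_like(obs_abs)
    n_seen = 0
    for chunk in perm_stats:
        for pm in chunk:
            tf = np.abs(_enhance_hemis(pm, blocks, n_time, params))
            if params.correction == "max":
                count += tf.max() >= obs_abs
            else:
                count += tf >= obs_abs
            n_seen += 1
    if exhaustive:
        return count / n_seen          # identity permutation is enumerated
    return (1.0 + count) / (n_seen + 1.0)


def _finalize(stat_map, tfce_map, p_map, space, params) -> TfceResult:
    sig = p_map < params.alpha
    labels = np.full(stat_map.shape, -1, dtype=int)
    offset = 0
    for idx, adj in _hemi_blocks(space):
        lab = connected_components(sig[idx], adj)
        lab[lab >= 0] += offset
        if lab.max() >= 0:
            offset = lab.max() + 1
        labels[idx] = lab
    return TfceResult(
        stat_map=stat_map,
        tfce_map=tfce_map,
        p_map=p_map,
        sig_mask=sig,
        cluster_labels=labels,
        alpha=params.alpha,
        params=params,
        n_perm_used=params.n_perm,
    )


def one_sample_tfce_test(
    diffs: np.ndarray,
    space: SourceSpace,
    params: TfceParams | None = None,
    rng: np.random.Generator | None = None,
    chunk: int = 64,
) -> TfceResult:
    """One-sample permutation test on within-subject difference maps.

    ``diffs`` is (n_subjects, n_vertices, n_times); the statistic is the
    one-sample t across subjects and the null is built by random sign flips
    of whole-subject maps (exhaustive enumeration when 2^n does not exceed
    ``n_perm``).
    """
    params = params or TfceParams()
    rng = rng or np.random.default_rng()
    diffs = np.asarray(diffs, dtype=float)
    n_subj, n_vert, n_time = diffs.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    blocks = _hemi_blocks(space)

    X = diffs.reshape(n_subj, -1)
    ssq = (X**2).sum(axis=0)
    t_obs = _one_sample_t(X.mean(axis=0), ssq, n_subj).reshape(n_vert, n_time)
    tfce_obs = _enhance_hemis(t_obs, blocks, n_time, params)

    exhaustive = 2**n_subj <= params.n_perm
    if exhaustive:
        n_eff = 2**n_subj
        bits = ((np.arange(n_eff)[:, None] >> np.arange(n_subj)) & 1)
        flips_all = 1.0 - 2.0 * bits
    else:
        n_eff = params.n_perm
        flips_all = rng.choice([-1.0, 1.0], size=(n_eff, n_subj))

    def perm_iter():
        for lo in range(0, n_eff, chunk):
            F = flips_all[lo : lo + chunk]
            mean = (F @ X) / n_subj
            t = _one_sample_t(mean, ssq, n_subj)
            yield t.reshape(-1, n_vert, n_time)

    p_map = _collect_p(tfce_obs, perm_iter(), blocks, params, n_eff, exhaustive)
    res = _finalize(t_obs, tfce_obs, p_map, space, params)
    res.n_perm_used = n_eff
    res.exhaustive = exhaustive
    return res


def two_sample_tfce_test(
    diffs_a: np.ndarray,
    diffs_b: np.ndarray,
    space: SourceSpace,
    params: TfceParams | None = None,
    rng: np.random.Generator | None = None,
    chunk: int = 64,
) -> TfceResult:
    """Two-sample permutation test on per-subject differential responses.

    Statistic: two-sided pooled-variance two-sample t (group A minus B);
    null: random reassignment of group labels.
    """
    params = params or TfceParams()
    rng = rng or np.random.default_rng()
    diffs_a = np.asarray(diffs_a, dtype=float)
    diffs_b = np.asarray(diffs_b, dtype=float)
    n1, n_vert, n_time = diffs_a.shape
    n2 = diffs_b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 subjects")
    blocks = _hemi_blocks(space)

    X = np.concatenate([diffs_a, diffs_b]).reshape(n1 + n2, -1)
    X2 = X**2
    tot_s = X.sum(axis=0)
    tot_q = X2.sum(axis=0)

    def tmap(ga: np.ndarray) -> np.ndarray:
        """two-sample t for boolean group-A indicator rows (m, n1+n2)."""
        s1 = ga @ X
        q1 = ga @ X2
        s2 = tot_s - s1
        q2 = tot_q - q1
        m1, m2 = s1 / n1, s2 / n2
        varp = (q1 - n1 * m1**2 + q2 - n2 * m2**2) / (n1 + n2 - 2)
        varp = np.clip(varp, 1e-300, None)
        return (m1 - m2) / np.sqrt(varp * (1.0 / n1 + 1.0 / n2))

    ident = np.zeros((1, n1 + n2))
    ident[0, :n1] = 1.0
    t_obs = tmap(ident)[0].reshape(n_vert, n_time)
    tfce_obs = _enhance_hemis(t_obs, blocks, n_time, params)

    from math import comb

    exhaustive = comb(n1 + n2, n1) <= params.n_perm
    if exhaustive:
        from itertools import combinations

        assigns = list(combinations(range(n1 + n2), n1))
        n_eff = len(assigns)

        def perm_iter():
            for lo in range(0, n_eff, chunk):
                batch = assigns[lo : lo + chunk]
                G = np.zeros((len(batch), n1 + n2))
                for r, sel in enumerate(batch):
                    G[r, list(sel)] = 1.0
                yield tmap(G).reshape(len(batch), n_vert, n_time)

    else:
        n_eff = params.n_perm

        def perm_iter():
            for lo in range(0, n_eff, chunk):
                m = min(chunk, n_eff - lo)
                G = np.zeros((m, n1 + n2))
                for r in range(m):
                    G[r, rng.permutation(n1 + n2)[:n1]] = 1.0
                yield tmap(G).reshape(m, n_vert, n_time)

    p_map = _collect_p(tfce_obs, perm_iter(), blocks, params, n_eff, exhaustive)
    res = _finalize(t_obs, tfce_obs, p_map, space, params)
    res.n_perm_used = n_eff
    res.exhaustive = exhaustive
    return res
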
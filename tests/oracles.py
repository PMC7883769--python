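"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as plain loops over definitions, deliberately
sharing no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np


def glcm_pairs_bruteforce(volume, mask, levels, offsets, symmetric=True):
    """Co-occurrence counts by an explicit double loop over voxel pairs."""
    vals = volume[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        q = np.zeros(volume.shape, dtype=int)
    else:
        q = np.clip(np.floor((volume - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    counts = np.zeros((levels, levels))
    shape = volume.shape
    for idx in itertools.product(*[range(n) for n in shape]):
        if not mask[idx]:
            continue
        for off in offsets:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= n for j, n in zip(jdx, shape)):
                continue
            if mask[jdx]:
                counts[q[idx], q[jdx]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def glcm_features_bruteforce(p):
    """Literal-sum GLCM formulas with explicit loops (1-based levels)."""
    L = p.shape[0]
    out = {}
    mux = sum((a + 1) * p[a, b] for a in range(L) for b in range(L))
    muy = sum((b + 1) * p[a, b] for a in range(L) for b in range(L))
    sigx = sum((a + 1 - mux) ** 2 * p[a, b] for a in range(L) for b in range(L)) ** 0.5
    sigy = sum((b + 1 - muy) ** 2 * p[a, b] for a in range(L) for b in range(L)) ** 0.5

    def S(fn):
        return sum(fn(a + 1, b + 1) * p[a, b] for a in range(L) for b in range(L))

    out["glcm_contrast"] = S(lambda i, j: (i - j) ** 2)
    out["glcm_dissimilarity"] = S(lambda i, j: abs(i - j))
    out["glcm_idm"] = S(lambda i, j: 1.0 / (1 + (i - j) ** 2))
    out["glcm_id"] = S(lambda i, j: 1.0 / (1 + abs(i - j)))
    out["glcm_idmn"] = S(lambda i, j: 1.0 / (1 + (i - j) ** 2 / L**2))
    out["glcm_idn"] = S(lambda i, j: 1.0 / (1 + abs(i - j) / L))
    out["glcm_joint_energy"] = float((p**2).sum())
    corr_num = S(lambda i, j: i * j) - mux * muy
    out["glcm_correlation"] = corr_num / (sigx * sigy) if sigx * sigy else 0.0
    out["glcm_autocorrelation"] = S(lambda i, j: i * j)
    out["glcm_cluster_shade"] = S(lambda i, j: (i + j - mux - muy) ** 3)
    out["glcm_cluster_prominence"] = S(lambda i, j: (i + j - mux - muy) ** 4)
    out["glcm_cluster_tendency"] = S(lambda i, j: (i + j - mux - muy) ** 2)
    out["glcm_joint_entropy"] = -sum(
        p[a, b] * np.log2(p[a, b]) for a in range(L) for b in range(L) if p[a, b] > 0
    )
    out["glcm_joint_average"] = mux
    out["glcm_joint_variance"] = S(lambda i, j: (i - mux) ** 2)

    psum = {k: 0.0 for k in range(2, 2 * L + 1)}
    pdiff = {k: 0.0 for k in range(L)}
    for a in range(L):
        for b in range(L):
            psum[a + b + 2] += p[a, b]
            pdiff[abs(a - b)] += p[a, b]
    sa = sum(k * v for k, v in psum.items())
    da = sum(k * v for k, v in pdiff.items())
    out["glcm_sum_average"] = sa
    out["glcm_sum_entropy"] = -sum(v * np.log2(v) for v in psum.values() if v > 0)
    out["glcm_sum_variance"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    out["glcm_difference_average"] = da
    out["glcm_difference_entropy"] = -sum(v * np.log2(v) for v in pdiff.values() if v > 0)
    out["glcm_difference_variance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    hy = -sum(v * np.log2(v) for v in py if v > 0)
    hxy = out["glcm_joint_entropy"]
    hxy1 = -sum(
        p[a, b] * np.log2(px[a] * py[b])
        for a in range(L) for b in range(L)
        if p[a, b] > 0 and px[a] * py[b] > 0
    )
    hxy2 = -sum(
        px[a] * py[b] * np.log2(px[a] * py[b])
        for a in range(L) for b in range(L)
        if px[a] * py[b] > 0
    )
    out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) else 0.0
    out["glcm_imc2"] = float(np.sqrt(max(1 - np.exp(-2 * (hxy2 - hxy)), 0.0)))
    out["glcm_max_probability"] = float(p.max())
    return out


def glrlm_bruteforce(q, mask, levels, directions):
    """Run-length counts by explicit line scanning per direction."""
    shape = q.shape
    max_len = max(shape)
    out = np.zeros((levels, max_len))
    for d in directions:
        for idx in itertools.product(*[range(n) for n in shape]):
            if not mask[idx]:
                continue
            prev = tuple(i - o for i, o in zip(idx, d))
            inside = all(0 <= j < n for j, n in zip(prev, shape))
            if inside and mask[prev] and q[prev] == q[idx]:
                continue  # not a run start for this direction
            # walk the run forward
            length = 0
            cur = idx
            while (
                all(0 <= j < n for j, n in zip(cur, shape))
                and mask[cur]
                and q[cur] == q[idx]
            ):
                length += 1
                cur = tuple(i + o for i, o in zip(cur, d))
            out[q[idx], length - 1] += 1
    return out


def glszm_bruteforce(q, mask, levels):
    """Zone counts by breadth-first flood fill with 26-connectivity."""
    shape = q.shape
    visited = np.zeros(shape, dtype=bool)
    neigh = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    zones = []
    for idx in itertools.product(*[range(n) for n in shape]):
        if not mask[idx] or visited[idx]:
            continue
        g = q[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in neigh:
                nxt = tuple(i + o for i, o in zip(cur, off))
                if any(j < 0 or j >= n for j, n in zip(nxt, shape)):
                    continue
                if mask[nxt] and not visited[nxt] and q[nxt] == g:
                    visited[nxt] = True
                    stack.append(nxt)
        zones.append((g, size))
    max_size = max(s for _, s in zones) if zones else 1
    out = np.zeros((levels, max_size))
    for g, s in zones:
        out[g, s - 1] += 1
    return out


def gldm_bruteforce(q, mask, levels, alpha=0):
    """Dependence counts by explicit neighbour loops."""
    shape = q.shape
    neigh = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    rows = []
    for idx in itertools.product(*[range(n) for n in shape]):
        if not mask[idx]:
            continue
        dep = 0
        for off in neigh:
            nxt = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= n for j, n in zip(nxt, shape)):
                continue
            if mask[nxt] and abs(int(q[nxt]) - int(q[idx])) <= alpha:
                dep += 1
        rows.append((q[idx], dep))
    max_dep = max(d for _, d in rows) if rows else 0
    out = np.zeros((levels, max_dep + 1))
    for g, d in rows:
        out[g, d] += 1
    return out


def convolve_bruteforce(volume, kernel):
    """Direct convolution with reflect ('mirror') padding via shifted adds."""
    assert all(k % 2 == 1 for k in kernel.shape)
    rads = [k // 2 for k in kernel.shape]
    padded = np.pad(volume, [(r, r) for r in rads], mode="reflect")
    out = np.zeros_like(volume, dtype=float)
    for dz in range(kernel.shape[0]):
        for dy in range(kernel.shape[1]):
            for dx in range(kernel.shape[2]):
                w = kernel[dz, dy, dx]
                if w == 0:
                    continue
                # correlation == convolution for the symmetric kernels used
                out += w * padded[
                    dz : dz + volume.shape[0],
                    dy : dy + volume.shape[1],
                    dx : dx + volume.shape[2],
                ]
    return out


def auc_pair_counting(scores, labels):
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def otsu_bruteforce(values):
    """Exhaustive between-class-variance maximization over midpoints."""
    values = np.sort(np.asarray(values, dtype=float))
    candidates = (values[1:] + values[:-1]) / 2.0
    best_thr, best_score = None, -np.inf
    for thr in np.unique(candidates):
        lo = values[values <= thr]
        hi = values[values > thr]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if score > best_score:
            best_score, best_thr = score, thr
    return best_thr
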
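"""Independent brute-force oracles, deliberately written apart from the
production code: plain Python loops and textbook formulas only."""

from __future__ import annotations

import itertools

import numpy as np


def glrlm_brute(levels: np.ndarray, mask: np.ndarray, direction) -> dict:
    """Run-length counts {(level, run_length): count} by naive walking."""
    lv = np.where(mask, levels, 0)
    shape = lv.shape
    d = tuple(direction)
    counts: dict = {}

    def inside(p):
        return all(0 <= p[a] < shape[a] for a in range(3))

    for idx in itertools.product(*[range(s) for s in shape]):
        if lv[idx] == 0:
            continue
        prev = tuple(idx[a] - d[a] for a in range(3))
        if inside(prev) and lv[prev] == lv[idx]:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(cur[a] + d[a] for a in range(3))
            if inside(nxt) and lv[nxt] == lv[idx]:
                length += 1
                cur = nxt
            else:
                break
        key = (int(lv[idx]), length)
        counts[key] = counts.get(key, 0) + 1
    return counts


def ngtdm_brute(levels: np.ndarray, mask: np.ndarray, distance) -> tuple[dict, dict, int]:
    """(p_i, s_i, n_valid) by per-voxel loops over the box neighborhood."""
    lv = np.where(mask, levels, 0)
    shape = lv.shape
    dx, dy, dz = distance
    n_i: dict = {}
    s_i: dict = {}
    n_valid = 0
    for idx in itertools.product(*[range(s) for s in shape]):
        if lv[idx] == 0:
            continue
        neighbors = []
        for ox in range(-dx, dx + 1):
            for oy in range(-dy, dy + 1):
                for oz in range(-dz, dz + 1):
                    if (ox, oy, oz) == (0, 0, 0):
                        continue
                    p = (idx[0] + ox, idx[1] + oy, idx[2] + oz)
                    if all(0 <= p[a] < shape[a] for a in range(3)) and lv[p] > 0:
                        neighbors.append(lv[p])
        if not neighbors:
            continue
        n_valid += 1
        level = int(lv[idx])
        n_i[level] = n_i.get(level, 0) + 1
        s_i[level] = s_i.get(level, 0.0) + abs(level - float(np.mean(neighbors)))
    p_i = {k: v / n_valid for k, v in n_i.items()}
    return p_i, s_i, n_valid


def ad_statistic_brute(samples: list[np.ndarray]) -> float:
    """Normalized k-sample Anderson-Darling statistic (midrank variant),
    computed from the published rank formulas."""
    k = len(samples)
    all_values = np.concatenate(samples)
    N = len(all_values)
    z_sorted = np.sort(all_values)
    z_star = np.unique(z_sorted)

    a2 = 0.0
    for sample in samples:
        ni = len(sample)
        inner = 0.0
        for j, z in enumerate(z_star):
            lj = np.sum(z_sorted == z)
            bj = np.sum(z_sorted < z) + lj / 2.0
            mij = np.sum(sample < z) + np.sum(sample == z) / 2.0
            denom = bj * (N - bj) - N * lj / 4.0
            if denom > 0:
                inner += (lj / N) * (N * mij - ni * bj) ** 2 / denom
        a2 += inner / ni
    a2 *= (N - 1) / N

    # variance of A2akN under H0 (textbook polynomial in N, k)
    H = sum(1.0 / len(s) for s in samples)
    h = sum(1.0 / i for i in range(1, N))
    g = 0.0
    for i in range(1, N - 1):
        for j in range(i + 1, N):
            g += 1.0 / ((N - i) * j)
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return (a2 - (k - 1)) / np.sqrt(var)


def c_index_brute(risk, time, event) -> float:
    """Harrell's C by exhaustive pair enumeration."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = 0.0
    den = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def cox_loglik_brute(beta: float, x, time, event) -> float:
    """Cox partial log-likelihood, single covariate, no ties (Breslow=Efron)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def cox_beta_grid(x, time, event, lo=-5.0, hi=5.0) -> float:
    """Grid-search maximizer of the brute partial likelihood, refined to 1e-6."""
    for _ in range(8):
        grid = np.linspace(lo, hi, 101)
        vals = [cox_loglik_brute(b, x, time, event) for b in grid]
        best = grid[int(np.argmax(vals))]
        step = (hi - lo) / 100.0
        lo, hi = best - step, best + step
    return float(best)


def cluster_index_brute(x, labels) -> float:
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    overall = x.mean(axis=0)
    total = sum(float(np.sum((row - overall) ** 2)) for row in x)
    within = 0.0
    for lab in set(labels.tolist()):
        rows = x[labels == lab]
        centre = rows.mean(axis=0)
        within += sum(float(np.sum((row - centre) ** 2)) for row in rows)
    return within / total
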
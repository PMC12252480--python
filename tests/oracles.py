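"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops over samples, independent of
the vectorised/scipy-based production code paths, so that agreement between
the two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def local_maxima(x) -> list[int]:
    """Indices of strict local maxima (both neighbours smaller)."""
    return [i for i in range(1, len(x) - 1)
            if x[i] > x[i - 1] and x[i] > x[i + 1]]


def select_by_distance(indices, heights, distance) -> list[int]:
    """Highest-priority-first distance pruning (mirrors peak selection by
    minimal spacing: smaller peaks closer than ``distance`` samples to an
    already kept one are removed)."""
    if not indices:
        return []
    distance = math.ceil(distance)
    order = sorted(range(len(indices)), key=lambda k: heights[k], reverse=True)
    kept: list[int] = []
    for k in order:
        if all(abs(indices[k] - indices[j]) >= distance for j in kept):
            kept.append(k)
    return sorted(indices[k] for k in kept)


def brute_s1_peaks(x, fs, t0, a_frac=0.1, b_frac=0.5, refractory_s=0.425):
    """Step-by-step S1 detection: threshold runs -> centres -> amplitude
    gate -> greedy refractory rule."""
    x = list(x)
    sq = [v * v for v in x]
    m = max(sq)
    assert m > 0
    mask = [v >= a_frac * m for v in sq]
    centers = []
    i = 0
    n = len(x)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            centers.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    if not centers:
        return []
    vals = [x[c] for c in centers]
    b_th = b_frac * sum(vals) / len(vals)
    centers = [c for c, v in zip(centers, vals) if v >= b_th]
    kept = []
    for c in centers:
        t = t0 + c / fs
        if not kept or t - kept[-1] >= refractory_s:
            kept.append(t)
    return kept


def brute_s2_peaks(x, fs, t0, s1_t, min_delay=0.125, max_delay=0.5,
                   min_height_frac=0.1):
    """Per-beat S2 search: gated local maxima of the squared signal within
    the systolic window, averaged."""
    sq = [v * v for v in x]
    out = []
    idx = [min(max(int(round((t - t0) * fs)), 0), len(x) - 1) for t in s1_t]
    for j, start in enumerate(idx):
        stop = idx[j + 1] if j + 1 < len(idx) else len(x) - 1
        if stop - start < 3:
            out.append(float("nan"))
            continue
        seg = sq[start:stop + 1]
        gate = min_height_frac * max(seg) if min_height_frac else -1.0
        cands = [i for i in local_maxima(seg) if seg[i] >= gate]
        delays = [i / fs for i in cands
                  if min_delay < i / fs < max_delay]
        if delays:
            out.append(s1_t[j] + sum(delays) / len(delays))
        else:
            out.append(float("nan"))
    return out


def brute_s1_onsets(x, fs, t0, s1_t, height_frac=0.2, min_dist_s=0.2,
                    tol_s=0.05):
    """Trough detection on the inverted signal, backward slope walk,
    validation against known S1 times, earliest onset per beat."""
    inv = [-v for v in x]
    out = [float("nan")] * len(s1_t)
    m = max(inv)
    if m <= 0:
        return out
    cands = [i for i in local_maxima(inv) if inv[i] >= height_frac * m]
    locs = select_by_distance(cands, [inv[i] for i in cands],
                              round(min_dist_s * fs))
    half_sample = 0.5 / fs
    for loc in locs:
        idx = loc
        while idx > 0 and x[idx] < x[idx - 1]:
            idx -= 1
        t_on = t0 + idx / fs
        if not len(s1_t):
            continue
        j = min(range(len(s1_t)), key=lambda k: abs(s1_t[k] - t_on))
        if abs(s1_t[j] - t_on) > tol_s or t_on > s1_t[j] + half_sample:
            continue
        if math.isnan(out[j]) or t_on < out[j]:
            out[j] = t_on
    return out


def brute_r_peaks(x, fs, t0, r_frac=0.5):
    th = r_frac * max(x)
    return [t0 + i / fs for i in local_maxima(x) if x[i] >= th]


def brute_q_peaks(x, fs, t0, r_t, qs_frac=0.2, half_window_s=0.250):
    inv = [-v for v in x]
    th = qs_frac * max(inv)
    half = round(half_window_s * fs)
    out = []
    for r in r_t:
        r_idx = min(max(int(round((r - t0) * fs)), 0), len(x) - 1)
        lo = max(r_idx - half, 0)
        if r_idx - lo < 3:
            out.append(float("nan"))
            continue
        seg = inv[lo:r_idx + 1]
        cands = [i for i in local_maxima(seg) if seg[i] >= th]
        out.append(t0 + (lo + cands[-1]) / fs if cands else float("nan"))
    return out


def brute_s_waves(x, fs, t0, r_t, qs_frac=0.2, half_window_s=0.250,
                  cap_s=0.05, range_frac=0.9):
    inv = [-v for v in x]
    th = qs_frac * max(inv)
    half = round(half_window_s * fs)
    out = []
    for r in r_t:
        r_idx = min(max(int(round((r - t0) * fs)), 0), len(x) - 1)
        hi = min(r_idx + half, len(x) - 1)
        if hi - r_idx < 3:
            out.append(float("nan"))
            continue
        span = (hi - r_idx) / fs
        dist = max(1, round(min(cap_s, range_frac * span) * fs))
        seg = inv[r_idx:hi + 1]
        cands = [i for i in local_maxima(seg) if seg[i] >= th]
        kept = select_by_distance(cands, [seg[i] for i in cands], dist)
        out.append(t0 + (r_idx + kept[0]) / fs if kept else float("nan"))
    return out


def bland_altman_loop(a, b):
    """Naive Bland-Altman: mean difference and 1.96-SD limits."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    sd = math.sqrt(var)
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def error_metrics_loop(a, b):
    """Naive absolute/relative error metrics with b as reference."""
    abs_err = [abs(x - y) for x, y in zip(a, b)]
    rel = [abs(x - y) / abs(y) for x, y in zip(a, b) if y != 0]
    return (sum(abs_err) / len(abs_err), max(abs_err),
            sum(rel) / len(rel), max(rel))
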
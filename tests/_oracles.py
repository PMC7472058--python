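"""Independent brute-force reference implementations used only by tests.

Everything here is written straight from the mathematical definitions
(explicit loops, direct DFT, hand percentile formula) and deliberately does
not share code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def vm_of(samples) -> list[float]:
    return [math.sqrt(x * x + y * y + z * z) for x, y, z in samples]


def percentile_linear(values, q) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    s = sorted(values)
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    frac = h - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def pop_sd(values) -> float:
    mu = sum(values) / len(values)
    return math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))


def pearson(a, b) -> float:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    sa = math.sqrt(sum((x - ma) ** 2 for x in a) / n)
    sb = math.sqrt(sum((x - mb) ** 2 for x in b) / n)
    if sa == 0 or sb == 0:
        return 0.0
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    return cov / (sa * sb)


def dominant_frequency_dft(vm, rate, band=(0.25, 5.0), min_nfft=1024):
    """Direct DFT evaluated bin by bin; first strict maximum wins."""
    n = len(vm)
    mu = sum(vm) / n
    x = np.asarray(vm, dtype=float) - mu
    nfft = max(min_nfft, n)
    freqs = [k * rate / nfft for k in range(nfft // 2 + 1)]
    best_f, best_m = None, -1.0
    j = np.arange(n)
    for k, f in enumerate(freqs):
        if f < band[0] or f > band[1]:
            continue
        c = np.exp(-2j * np.pi * k * j / nfft)
        mag = abs((x * c).sum()) * 2.0 / n
        if mag > best_m + 0.0:
            best_m = mag
            best_f = f
    return best_f, best_m


def base_features_bruteforce(samples, rate) -> dict:
    vm = vm_of(samples)
    n = len(vm)
    mean = sum(vm) / n
    sd = pop_sd(vm)
    p10 = percentile_linear(vm, 10)
    p25 = percentile_linear(vm, 25)
    p50 = percentile_linear(vm, 50)
    p75 = percentile_linear(vm, 75)
    p95 = percentile_linear(vm, 95)
    crossings = 0
    for a, b in zip(vm[:-1], vm[1:]):
        if (a - p50) * (b - p50) < 0:
            crossings += 1
    dom_hz, dom_mag = dominant_frequency_dft(vm, rate)
    xs = [s[0] for s in samples]
    ys = [s[1] for s in samples]
    zs = [s[2] for s in samples]
    return {
        "vm_mean": mean,
        "vm_sd": sd,
        "vm_min": min(vm),
        "vm_max": max(vm),
        "vm_iqr": p75 - p25,
        "vm_p10": p10,
        "vm_p25": p25,
        "vm_p50": p50,
        "vm_p75": p75,
        "vm_p95": p95,
        "vm_cv": sd / mean if mean != 0 else 0.0,
        "vm_sum": sum(vm),
        "vm_power": sum(v * v for v in vm) / n,
        "vm_p2p": max(vm) - min(vm),
        "vm_median_crossings": float(crossings),
        "corr_xy": pearson(xs, ys),
        "corr_xz": pearson(xs, zs),
        "corr_yz": pearson(ys, zs),
        "dom_freq_hz": dom_hz,
        "dom_freq_mag": dom_mag,
    }


def temporal_features_bruteforce(windows_vm, index) -> dict:
    """windows_vm: list of per-window VM value lists."""
    k = len(windows_vm)

    def clamp(j):
        return min(max(j, 0), k - 1)

    sds = [pop_sd(v) for v in windows_vm]
    means = [sum(v) / len(v) for v in windows_vm]
    five = [means[clamp(index + off)] for off in (-2, -1, 0, 1, 2)]
    return {
        "sd_lag1": sds[clamp(index - 1)],
        "sd_lag2": sds[clamp(index - 2)],
        "sd_lead1": sds[clamp(index + 1)],
        "sd_lead2": sds[clamp(index + 2)],
        "sd_5win": pop_sd(five),
    }


def f_scores_bruteforce(cm):
    """cm: 5x5 list-of-lists, rows predicted, cols observed."""
    k = len(cm)
    out = []
    for c in range(k):
        tp = cm[c][c]
        row = sum(cm[c])
        col = sum(cm[r][c] for r in range(k))
        p = tp / row if row > 0 else 0.0
        r = tp / col if col > 0 else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        out.append({"precision": p, "recall": r, "f": f, "support": col})
    tot = sum(o["support"] for o in out)
    weighted = sum(o["support"] * o["f"] for o in out) / tot
    return out, weighted


def kappa_bruteforce(a, b):
    n = len(a)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    codes = set(a) | set(b)
    p_e = sum((sum(1 for x in a if x == c) / n) * (sum(1 for y in b if y == c) / n) for c in codes)
    return (p_o - p_e) / (1 - p_e)


def majority_label_bruteforce(codes, exclude=("OUT_OF_VIEW", "UNLABELED")):
    """Window label by hand enumeration over a list of per-sample codes."""
    m = len(codes)
    real = [c for c in codes if c != "UNLABELED"]
    distinct = set(real)
    mixed = len(distinct) > 1
    best, best_count = None, 0
    for c in distinct:
        cnt = sum(1 for x in codes if x == c)
        if cnt > best_count:
            best, best_count = c, cnt
    if best is None or best_count * 2 <= m or best in exclude:
        return "EXCLUDED", mixed
    return best, mixed
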
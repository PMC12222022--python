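"""Independent reference implementations used only by the tests.

These deliberately avoid the library's code paths: transient detection is an
exhaustive prominence-by-definition scan, the similarity fit is the
closed-form Procrustes/Umeyama solution written out by hand, and the rule
decoder is a plain re-application of the table.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# brute-force transient detection
# ---------------------------------------------------------------------------

def local_maxima(x: np.ndarray) -> list[int]:
    """Strict interior local maxima (continuous-valued traces: no plateaus)."""
    return [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]


def prominence_by_definition(x: np.ndarray, p: int) -> float:
    """Peak prominence from its definition: on each side, find the minimum
    between the peak and the nearest strictly higher sample (or the signal
    edge); the prominence is the peak height above the higher of the two
    minima."""
    xp = x[p]
    left_min = xp
    j = p - 1
    while j >= 0 and x[j] <= xp:
        left_min = min(left_min, x[j])
        j -= 1
    right_min = xp
    j = p + 1
    while j < len(x) and x[j] <= xp:
        right_min = min(right_min, x[j])
        j += 1
    return xp - max(left_min, right_min)


def preceding_minimum_index(x: np.ndarray, p: int) -> int:
    i = p
    while i > 0 and x[i - 1] < x[i]:
        i -= 1
    return i


def detect_by_definition(
    x: np.ndarray,
    fs: float,
    min_prominence: float,
    min_abs_peak: float,
    min_interpeak: float,
) -> list[tuple[int, float, float]]:
    """Exhaustive detection: (peak index, prominence, amplitude) triples.

    Same stated rules as the library (thresholds inclusive; spacing in
    samples, rounding half-up; spacing ties resolved by keeping the larger
    prominence, then the earlier peak), coded independently.
    """
    cands = [
        (p, prominence_by_definition(x, p))
        for p in local_maxima(x)
    ]
    cands = [
        (p, pr) for p, pr in cands if pr >= min_prominence and x[p] >= min_abs_peak
    ]
    spacing = int(np.floor(min_interpeak * fs + 0.5))
    kept: list[tuple[int, float]] = []
    for p, pr in sorted(cands, key=lambda c: (-c[1], c[0])):
        if all(abs(p - q) >= spacing for q, _ in kept):
            kept.append((p, pr))
    kept.sort()
    return [
        (p, pr, x[p] - x[preceding_minimum_index(x, p)]) for p, pr in kept
    ]


# ---------------------------------------------------------------------------
# closed-form similarity (Procrustes / Umeyama)
# ---------------------------------------------------------------------------

def similarity_closed_form(src: np.ndarray, dst: np.ndarray):
    """Least-squares scaled rotation + translation, written out by hand.

    Returns (scale, rotation_deg, translation) minimizing
    sum ||s R src_i + t - dst_i||^2.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(0), dst.mean(0)
    a, b = src - mu_s, dst - mu_d
    cov = b.T @ a / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    D = np.diag([1.0, d])
    rot = u @ D @ vt
    var_s = (a**2).sum() / len(src)
    scale = np.trace(np.diag(s) @ D) / var_s
    t = mu_d - scale * rot @ mu_s
    angle = np.degrees(np.arctan2(rot[1, 0], rot[0, 0]))
    return float(scale), float(angle), (float(t[0]), float(t[1]))


# ---------------------------------------------------------------------------
# independent rule decoding
# ---------------------------------------------------------------------------

def decode_by_reapplication(calls: dict[str, str], table) -> str:
    """Straightforward re-application of a rule table, independent of the
    library's decode loop (no untested-gene logic: calls must be complete)."""
    for rule in table.rules:
        ok = all(calls[g] in levels for g, levels in rule.require.items())
        if ok and not any(calls[g] in levels for g, levels in rule.forbid.items()):
            return rule.label
    return "unclassified"


# ---------------------------------------------------------------------------
# exact interval CIs for stochastic checks
# ---------------------------------------------------------------------------

def binomial_ci(n: int, p: float, conf: float = 0.99) -> tuple[float, float]:
    """Central probability interval for Binomial(n, p) counts."""
    lo = sps.binom.ppf((1 - conf) / 2, n, p)
    hi = sps.binom.ppf(1 - (1 - conf) / 2, n, p)
    return float(lo), float(hi)


def poisson_ci(mu: float, conf: float = 0.99) -> tuple[float, float]:
    lo = sps.poisson.ppf((1 - conf) / 2, mu)
    hi = sps.poisson.ppf(1 - (1 - conf) / 2, mu)
    return float(lo), float(hi)
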
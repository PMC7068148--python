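"""Time-domain epoch features: Hjorth parameters, approximate entropy, RMS.

Hjorth parameters use first differences (no sampling-rate scaling; the
downstream rank statistics are invariant to the constant factor):

    activity   = var(x)
    mobility   = sqrt(var(dx) / var(x))
    complexity = mobility(dx) / mobility(x)

Approximate entropy follows the classic Pincus construction with
self-matches included: ApEn(m, r) = phi_m - phi_{m+1}, where phi_m is the
average over templates of log(fraction of templates within Chebyshev
distance r).  Defaults m=2, r = 0.2 x SD(epoch) are the field-standard
choices for 4-s EEG epochs.  The kernel sorts templates by their first
coordinate so only first-coordinate-compatible pairs are compared, which
makes the exact O(N^2) count fast enough for cohort-scale batch runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["hjorth", "approx_entropy", "rms", "time_features", "TIME_FEATURES"]

TIME_FEATURES = (
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "approximate_entropy",
    "rms_value",
)


class ZeroVarianceError(ValueError):
    """Constant input has no defined Hjorth parameters."""


class InsufficientLengthError(ValueError):
    """Epoch too short for the requested statistic."""


def hjorth(epoch: np.ndarray) -> tuple[float, float, float]:
    """(activity, mobility, complexity) of one epoch."""
    x = np.asarray(epoch, dtype=float)
    if x.size < 3:
        raise InsufficientLengthError("Hjorth parameters need >= 3 samples")
    var_x = x.var()
    if var_x == 0:
        raise ZeroVarianceError("constant epoch")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = dx.var()
    var_ddx = ddx.var()
    mobility = np.sqrt(var_dx / var_x)
    mobility_dx = np.sqrt(var_ddx / var_dx) if var_dx > 0 else 0.0
    complexity = mobility_dx / mobility if mobility > 0 else 0.0
    return float(var_x), float(mobility), float(complexity)


@njit(cache=True)
def _apen_phis_m2(x: np.ndarray, r: float) -> tuple[float, float]:
    """Specialised m=2 variant of :func:`_apen_phis` (the battery default;
    identical counts, no inner coordinate loop)."""
    n = x.shape[0]
    nm = n - 1
    nm1 = n - 2
    cm = np.ones(nm)
    cm1 = np.ones(nm1)
    order = np.argsort(x[:nm])
    xs = x[:nm][order]
    for a in range(nm):
        i = order[a]
        xi = xs[a]
        for b in range(a + 1, nm):
            if xs[b] - xi > r:
                break
            j = order[b]
            if abs(x[i + 1] - x[j + 1]) <= r:
                cm[i] += 1.0
                cm[j] += 1.0
                if i < nm1 and j < nm1 and abs(x[i + 2] - x[j + 2]) <= r:
                    cm1[i] += 1.0
                    cm1[j] += 1.0
    phi_m = np.mean(np.log(cm / nm))
    phi_m1 = np.mean(np.log(cm1 / nm1))
    return phi_m, phi_m1


@njit(cache=True)
def _apen_phis(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """phi_m and phi_{m+1} by exact template counting (self-matches in).

    Templates are visited in order of their first coordinate; a pair whose
    first coordinates differ by more than r can never match, so the inner
    scan breaks early.  Counts are exactly those of the naive double loop.
    """
    n = x.shape[0]
    nm = n - m + 1  # templates of length m
    nm1 = n - m  # templates of length m + 1
    cm = np.ones(nm)
    cm1 = np.ones(nm1)
    order = np.argsort(x[:nm])
    xs = x[:nm][order]  # sorted first coordinates, contiguous for the scan
    for a in range(nm):
        i = order[a]
        xi = xs[a]
        for b in range(a + 1, nm):
            if xs[b] - xi > r:
                break
            j = order[b]
            ok = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                cm[i] += 1.0
                cm[j] += 1.0
                if i < nm1 and j < nm1 and abs(x[i + m] - x[j + m]) <= r:
                    cm1[i] += 1.0
                    cm1[j] += 1.0
    phi_m = np.mean(np.log(cm / nm))
    phi_m1 = np.mean(np.log(cm1 / nm1))
    return phi_m, phi_m1


def approx_entropy(epoch: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """ApEn(m, r) in nats with tolerance r = r_factor x SD(epoch)."""
    x = np.ascontiguousarray(epoch, dtype=float)
    if x.size < 50:
        raise InsufficientLengthError("ApEn needs >= 50 samples")
    r = r_factor * x.std()
    if r <= 0:
        raise ZeroVarianceError("ApEn tolerance r must be positive")
    if m == 2:
        phi_m, phi_m1 = _apen_phis_m2(x, r)
    else:
        phi_m, phi_m1 = _apen_phis(x, m, r)
    return float(phi_m - phi_m1)


def rms(epoch: np.ndarray) -> float:
    """Root mean square of the epoch."""
    x = np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise InsufficientLengthError("empty epoch")
    return float(np.sqrt(np.mean(x * x)))


def time_features(epoch: np.ndarray, m: int = 2, r_factor: float = 0.2) -> dict:
    """All five time-domain features of one epoch, by name."""
    activity, mobility, complexity = hjorth(epoch)
    return {
        "hjorth_activity": activity,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "approximate_entropy": approx_entropy(epoch, m=m, r_factor=r_factor),
        "rms_value": rms(epoch),
    }
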
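"""Exposure metrics and prediction-acceptance statistics.

Implements the quantities the validation workflow is judged on: linear
trapezoidal AUC (optionally extrapolated to infinity from the terminal
log-linear slope), geometric-mean exposure ratios, the Guest
variability-adjusted acceptance interval for predicted vs observed DDI
ratios, fold-error classification, visual-predictive-check percentile
bands, age-group normalization against a reference group, and parameter
sensitivity sweeps on re-simulated scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKMetrics",
    "GuestInterval",
    "auc_trapezoid",
    "compute_pk_metrics",
    "geometric_mean_ratio",
    "guest_limits",
    "fold_error",
    "fold_classification",
    "vpc_bands",
    "normalize_to_reference",
]


@dataclass
class PKMetrics:
    auc_0_t: float  # ng*h/mL
    auc_0_inf: float | None
    cmax: float  # ng/mL
    tmax: float  # h
    ctrough: dict[float, float] | None = None  # time -> ng/mL


@dataclass
class GuestInterval:
    """Variability-adjusted acceptance interval around an observed ratio.

    For R >= 1 the limit is L = (delta + 2(R-1)) / R and the interval is
    [R/L, R*L]; ratios below one use the reciprocal symmetry.  The
    default delta of 1.25 encodes 20 % assay/trial variability and makes
    the interval collapse to the bioequivalence band (0.80, 1.25) at
    R = 1 while approaching plain 2-fold limits for large ratios.
    """

    observed_ratio: float
    delta: float
    lower: float
    upper: float

    def contains(self, predicted_ratio: float) -> bool:
        return self.lower <= predicted_ratio <= self.upper


def auc_trapezoid(
    times, concs, extrapolate: bool = False, min_terminal_points: int = 3
) -> float:
    """Linear trapezoidal AUC (ng*h/mL); optional extrapolation to infinity.

    Extrapolation fits a log-linear regression to the last
    ``min_terminal_points`` or more positive concentrations and adds
    C_last / k_z, gated on an adjusted R^2 of at least 0.9.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or t.size < 2:
        raise ValueError("need matching 1-D arrays with at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    auc = float(np.trapezoid(c, t))
    if not extrapolate:
        return auc
    pos = c > 0
    t_pos, c_pos = t[pos], c[pos]
    if t_pos.size < min_terminal_points:
        raise ValueError("too few positive points for terminal extrapolation")
    # grow the terminal window while the log-linear fit stays acceptable
    best = None
    for npts in range(min_terminal_points, min(t_pos.size, 12) + 1):
        tt, lc = t_pos[-npts:], np.log(c_pos[-npts:])
        slope, intercept = np.polyfit(tt, lc, 1)
        pred = slope * tt + intercept
        ss_res = float(np.sum((lc - pred) ** 2))
        ss_tot = float(np.sum((lc - lc.mean()) ** 2))
        if ss_tot <= 0:
            continue
        r2 = 1 - ss_res / ss_tot
        adj = 1 - (1 - r2) * (npts - 1) / (npts - 2)
        if slope < 0 and adj >= 0.9:
            best = (slope, adj, npts)
    if best is None:
        raise ValueError("no acceptable terminal log-linear fit (adj R^2 < 0.9)")
    kz = -best[0]
    return auc + float(c_pos[-1]) / kz


def compute_pk_metrics(
    times, concs, trough_times=(), extrapolate: bool = False
) -> PKMetrics:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    auc_t = auc_trapezoid(t, c, extrapolate=False)
    auc_inf = auc_trapezoid(t, c, extrapolate=True) if extrapolate else None
    imax = int(np.argmax(c))
    troughs = {float(tt): float(np.interp(tt, t, c)) for tt in trough_times}
    return PKMetrics(
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        cmax=float(c[imax]),
        tmax=float(t[imax]),
        ctrough=troughs or None,
    )


def geometric_mean_ratio(paired) -> float:
    """exp(mean(log(with/without))) over subject-matched metric pairs.

    ``paired`` is an iterable of (with_perpetrator, without_perpetrator)
    values; all must be positive.
    """
    arr = np.asarray(list(paired), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty sequence of (with, without) pairs")
    if np.any(arr <= 0):
        raise ValueError("metrics must be strictly positive")
    return float(np.exp(np.mean(np.log(arr[:, 0] / arr[:, 1]))))


def guest_limits(observed_ratio: float, delta: float = 1.25) -> GuestInterval:
    """Acceptance limits for a predicted DDI ratio given the observed one."""
    if observed_ratio <= 0:
        raise ValueError("observed ratio must be > 0")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    r = observed_ratio if observed_ratio >= 1 else 1.0 / observed_ratio
    limit = (delta + 2.0 * (r - 1.0)) / r
    lo, hi = r / limit, r * limit
    if observed_ratio < 1:
        lo, hi = 1.0 / hi, 1.0 / lo
    return GuestInterval(observed_ratio=observed_ratio, delta=delta, lower=lo, upper=hi)


def fold_error(predicted: float, observed: float) -> float:
    """Symmetric fold error max(p/o, o/p), always >= 1."""
    if predicted <= 0 or observed <= 0:
        raise ValueError("predicted and observed must be > 0")
    return max(predicted / observed, observed / predicted)


def fold_classification(pairs, thresholds=(1.25, 1.5, 2.0)) -> dict[float, float]:
    """Fraction of (predicted, observed) pairs within each fold threshold."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no comparisons supplied")
    errs = [fold_error(p, o) for p, o in pairs]
    return {th: sum(e <= th for e in errs) / len(errs) for th in thresholds}


def vpc_bands(profiles: np.ndarray, lower_pct: float = 5.0, upper_pct: float = 95.0):
    """Per-time mean and percentile bands over simulated profiles.

    ``profiles`` is an (n_profiles, n_times) array on a shared time grid
    with at least 20 profiles.  Percentiles use linear interpolation
    between order statistics.  Returns (mean, lower, upper) arrays.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2:
        raise ValueError("profiles must be a 2-D array on a shared grid")
    if arr.shape[0] < 20:
        raise ValueError("need at least 20 profiles for percentile bands")
    mean = arr.mean(axis=0)
    lower = np.percentile(arr, lower_pct, axis=0, method="linear")
    upper = np.percentile(arr, upper_pct, axis=0, method="linear")
    return mean, lower, upper


def vpc_coverage(band_times, lower, upper, obs_times, obs_concs) -> tuple[float, list[bool]]:
    """Fraction of observed points inside the band, plus per-point flags."""
    lo = np.interp(obs_times, band_times, lower)
    hi = np.interp(obs_times, band_times, upper)
    inside = [(l <= c <= h) for l, h, c in zip(lo, hi, obs_concs)]
    return (sum(inside) / len(inside) if inside else float("nan")), inside


def normalize_to_reference(
    ratios_by_age_group: dict[str, float], reference: str = "20-59"
) -> dict[str, dict]:
    """Divide each age group's DDI ratio by the reference group's.

    Returns, per group, the normalized ratio and whether it sits inside
    the 1.25-fold bioequivalence interval (1/1.25, 1.25).
    """
    if reference not in ratios_by_age_group:
        raise ValueError(f"reference group {reference!r} missing")
    ref = ratios_by_age_group[reference]
    if ref <= 0:
        raise ValueError("reference ratio must be positive")
    out = {}
    for group, r in ratios_by_age_group.items():
        norm = r / ref
        out[group] = {
            "normalized_ratio": norm,
            "within_1_25_fold": bool(1.0 / 1.25 <= norm <= 1.25),
        }
    return out
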
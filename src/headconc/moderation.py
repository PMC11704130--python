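"""Simple slopes, Holm correction, Johnson-Neyman region, effect grids.

All computations operate on the fixed-effect vector ``beta = (b0, b1, b2,
b3)`` and its 4x4 Wald covariance.  The conditional slope of standardized
headline concreteness at moderator value ``m`` (test concreteness mean) is

    omega(m) = b1 + b3 * m,   var(omega) = v11 + m^2 v33 + 2 m v13.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .glmm import predict_ctr

DEFAULT_CRITICAL = 1.959963984540054


@dataclass(frozen=True)
class SimpleSlope:
    moderator_value: float
    slope: float
    se: float
    z: float
    p: float
    p_holm: float | None = None

    def to_dict(self) -> dict:
        d = {
            "moderator_value": self.moderator_value,
            "slope": self.slope,
            "se": self.se,
            "z": self.z,
            "p": self.p,
        }
        if self.p_holm is not None:
            d["p_holm"] = self.p_holm
        return d


@dataclass(frozen=True)
class JNRegion:
    lower_bound: float | None
    upper_bound: float | None
    critical_value: float
    significant_outside: bool
    fraction_below: float | None = None
    fraction_above: float | None = None

    def to_dict(self) -> dict:
        return {
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "critical_value": self.critical_value,
            "significant_outside": self.significant_outside,
            "fraction_below": self.fraction_below,
            "fraction_above": self.fraction_above,
        }


def _slope_var(vcov: np.ndarray, m: float) -> float:
    return float(vcov[1, 1] + m * m * vcov[3, 3] + 2.0 * m * vcov[1, 3])


def _check_vcov(vcov: np.ndarray) -> np.ndarray:
    vcov = np.asarray(vcov, dtype=float)
    if vcov.shape != (4, 4):
        raise ValueError("vcov must be 4x4 (b0, b1, b2, b3)")
    sub = vcov[np.ix_([1, 3], [1, 3])]
    eig = np.linalg.eigvalsh((sub + sub.T) / 2.0)
    if eig.min() < -1e-10:
        raise ValueError("vcov is not positive semi-definite in (b1, b3)")
    return vcov


def simple_slope(beta: np.ndarray, vcov: np.ndarray, m: float) -> SimpleSlope:
    """Conditional slope of headline concreteness at moderator value ``m``.

    Delta-method SE, normal z, two-sided p.
    """
    beta = np.asarray(beta, dtype=float)
    vcov = _check_vcov(vcov)
    omega = float(beta[1] + beta[3] * m)
    var = _slope_var(vcov, m)
    if var <= 0:
        raise ValueError("non-positive slope variance")
    se = float(np.sqrt(var))
    z = omega / se
    p = float(2.0 * norm.sf(abs(z)))
    return SimpleSlope(float(m), omega, se, z, p)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    order = np.argsort(p, kind="stable")
    multipliers = k - np.arange(k)
    adj_sorted = np.maximum.accumulate(p[order] * multipliers)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(k)
    out[order] = adj_sorted
    return out


def johnson_neyman(
    beta: np.ndarray,
    vcov: np.ndarray,
    critical_value: float = DEFAULT_CRITICAL,
    moderator_values: np.ndarray | None = None,
) -> JNRegion:
    """Moderator-value bounds where the conditional slope is significant.

    Solves ``omega(m)^2 = crit^2 * var(omega(m))`` — a quadratic in ``m`` —
    and classifies where |z| >= crit.  ``significant_outside=True`` means the
    slope is significant for m below ``lower_bound`` and above
    ``upper_bound`` (the typical crossover pattern); ``False`` means it is
    significant only between the bounds.  With both bounds ``None`` the slope
    is either significant everywhere or nowhere; inspect
    ``significant_outside`` (True -> everywhere).

    When ``moderator_values`` (observed per-test moderator values) is given,
    the fractions of tests below/above the bounds are reported.
    """
    beta = np.asarray(beta, dtype=float)
    vcov = _check_vcov(vcov)
    if beta[3] == 0:
        raise ValueError("interaction coefficient is zero; no JN bounds")
    c2 = critical_value * critical_value
    # (b1 + b3 m)^2 - c2 (v11 + 2 m v13 + m^2 v33) = 0
    qa = beta[3] ** 2 - c2 * vcov[3, 3]
    qb = 2.0 * beta[1] * beta[3] - 2.0 * c2 * vcov[1, 3]
    qc = beta[1] ** 2 - c2 * vcov[1, 1]

    lower = upper = None
    disc = qb * qb - 4.0 * qa * qc
    if abs(qa) < 1e-300:
        if abs(qb) > 0:
            root = -qc / qb
            lower = upper = float(root)
    elif disc >= 0:
        r1 = (-qb - np.sqrt(disc)) / (2.0 * qa)
        r2 = (-qb + np.sqrt(disc)) / (2.0 * qa)
        lower, upper = float(min(r1, r2)), float(max(r1, r2))

    if lower is None:
        # no real roots: |z| never crosses crit
        mid_sig = bool(abs(simple_slope(beta, vcov, 0.0).z) >= critical_value)
        return JNRegion(None, None, float(critical_value), mid_sig)

    midpoint = 0.5 * (lower + upper)
    if lower == upper:
        inside_sig = False
    else:
        inside_sig = bool(abs(simple_slope(beta, vcov, midpoint).z) >= critical_value)
    region = JNRegion(lower, upper, float(critical_value), not inside_sig)

    if moderator_values is not None:
        mv = np.asarray(moderator_values, dtype=float)
        region = JNRegion(
            lower,
            upper,
            float(critical_value),
            not inside_sig,
            fraction_below=float(np.mean(mv < lower)),
            fraction_above=float(np.mean(mv > upper)),
        )
    return region


def conditional_effects_grid(
    beta: np.ndarray,
    m_values,
    hc_range: tuple[float, float] = (-1.0, 1.0),
    n_points: int = 41,
):
    """Predicted CTR curves over a standardized-concreteness grid.

    Returns a DataFrame with columns ``moderator_value, hc, ctr`` for each
    moderator value; ``hc`` spans ``hc_range`` (default -1..+1 standardized
    units, i.e. 2 SD below to 2 SD above the test mean).
    """
    import pandas as pd

    hc = np.linspace(hc_range[0], hc_range[1], n_points)
    frames = []
    for m in np.atleast_1d(np.asarray(m_values, dtype=float)):
        frames.append(
            pd.DataFrame(
                {"moderator_value": m, "hc": hc, "ctr": predict_ctr(beta, hc, m)}
            )
        )
    return pd.concat(frames, ignore_index=True)
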
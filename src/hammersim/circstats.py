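"""Circular descriptive statistics and the T-linear circular association.

Only the statistics the analysis pipeline needs: the circular mean with the
resultant-length-based SD/SE, and the Fisher-Lee T-linear coefficient for
association between two angular variables,

    rho_T = sum_{i<j} sin(t_i - t_j) sin(p_i - p_j)
            / sqrt( sum_{i<j} sin^2(t_i - t_j) * sum_{i<j} sin^2(p_i - p_j) )

with a one-sided permutation test for significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .angles import wrap_deg

__all__ = ["CircSummary", "AssocResult", "circ_mean_sd", "circ_tlinear_assoc"]

_RESULTANT_EPS = 1e-9


@dataclass(frozen=True)
class CircSummary:
    mean_angle: float  # deg in (-180, 180]
    resultant_length: float  # in [0, 1]
    circular_sd: float  # deg, sqrt(-2 ln R)
    circular_se: float  # deg, circular_sd / sqrt(n)
    n: int
    undefined_mean: bool = False


@dataclass(frozen=True)
class AssocResult:
    rho: float
    p_value: float
    n_perm: int
    seed: Optional[int]


def circ_mean_sd(angles_deg: Sequence[float]) -> CircSummary:
    """Circular mean, resultant length and SD/SE of angles in degrees."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circ_mean_sd requires at least one angle")
    z = np.exp(1j * a).mean()
    r = min(float(np.abs(z)), 1.0)
    undefined = r < _RESULTANT_EPS
    mean = float(wrap_deg(np.rad2deg(np.angle(z)))) if not undefined else float("nan")
    # guard log of tiny/one: R in [eps, 1]
    sd_rad = np.sqrt(-2.0 * np.log(max(r, _RESULTANT_EPS))) if not undefined else float("inf")
    sd = float(np.rad2deg(sd_rad))
    return CircSummary(
        mean_angle=mean,
        resultant_length=r,
        circular_sd=sd,
        circular_se=sd / np.sqrt(a.size),
        n=int(a.size),
        undefined_mean=undefined,
    )


def _tlinear_terms(theta_rad: np.ndarray):
    s, c = np.sin(theta_rad), np.cos(theta_rad)
    # sum_{i<j} sin^2(ti - tj) via |sum exp(2i t)|^2
    n = theta_rad.size
    ss2 = 0.25 * (n**2 - np.abs(np.exp(2j * theta_rad).sum()) ** 2)
    return s, c, ss2


def _rho_from_sums(st, ct, sp, cp):
    # sum over ordered pairs: sum_{i,j} sin(ti-tj) sin(pi-pj)
    #   = 2 [ (s.u)(c.v) - (s.v)(c.u) ]
    # halved to match the i<j sums used in the denominator
    return (st @ sp) * (ct @ cp) - (st @ cp) * (ct @ sp)


def circ_tlinear_assoc(
    theta_deg: Sequence[float],
    phi_deg: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> AssocResult:
    """Fisher-Lee T-linear association between two angle samples (degrees).

    Significance is a one-sided permutation p-value (large positive rho)
    obtained by shuffling ``phi``; ``p = (1 + #{rho_perm >= rho}) / (n_perm + 1)``.
    """
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    p = np.deg2rad(np.asarray(phi_deg, dtype=float))
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("theta and phi must be 1-d and of equal length")
    if t.size < 3:
        raise ValueError("need at least 3 angle pairs")
    st, ct, sst = _tlinear_terms(t)
    sp, cp, ssp = _tlinear_terms(p)
    tol = 1e-12 * t.size**2
    if sst < tol or ssp < tol or not np.isfinite(sst * ssp):
        raise ValueError("degenerate sample: all angles equal in one variable")
    denom = np.sqrt(sst * ssp)
    rho = float(_rho_from_sums(st, ct, sp, cp) / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        k = rng.permutation(t.size)
        r = _rho_from_sums(st, ct, sp[k], cp[k]) / denom
        if r >= rho:
            count += 1
    p_value = (1.0 + count) / (n_perm + 1.0)
    return AssocResult(rho=rho, p_value=float(p_value), n_perm=int(n_perm), seed=seed)
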
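"""From g2(tau, Q) to the hydrodynamic radius.

Three stages, mirroring standard XPCS practice for Brownian suspensions:

1. per Q, fit the single exponential Delta g2 = beta exp(-2 tau / tau0)
   (beta fixed to the static-reference contrast, or free for
   diagnostics);
2. fit the decay rates Gamma = 1/tau0 against Q^2 through the origin —
   for simple diffusion Gamma = D Q^2, so the slope is the diffusivity;
3. convert D to the hydrodynamic radius with Stokes-Einstein,
   R_H = kT / (6 pi eta D), using the sample's temperature and
   viscosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .simulate import BOLTZMANN

__all__ = [
    "Environment",
    "G2FitEntry",
    "G2Fit",
    "DiffusionFit",
    "RadiusEstimate",
    "fit_single_exponential",
    "fit_g2_result",
    "fit_tau_vs_q",
    "stokes_einstein_radius",
]

TAU0_BOUNDS = (1e-7, 1e3)  # seconds; hitting a bound flags the entry


@dataclass(frozen=True)
class Environment:
    """Sample environment for the Stokes-Einstein conversion."""

    temperature: float            # K
    viscosity: float              # Pa s
    label: str = ""
    boltzmann: float = BOLTZMANN  # J/K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")


@dataclass
class G2FitEntry:
    """Exponential fit at one Q: tau0 (s) with its standard error,
    the beta used or fitted, reduced chi-square, and convergence flag."""

    q: float
    tau0: float
    sigma_tau0: float
    beta: float
    sigma_beta: float
    red_chisq: float
    converged: bool


@dataclass
class G2Fit:
    entries: list[G2FitEntry] = field(default_factory=list)

    @property
    def converged_entries(self) -> list[G2FitEntry]:
        return [e for e in self.entries if e.converged]


@dataclass
class DiffusionFit:
    """Diffusivity from the Gamma-vs-Q^2 fit and the derived R_H."""

    d: float                      # m^2/s
    sigma_d: float
    q_max_used: float             # nm^-1
    q_used: np.ndarray            # nm^-1
    residuals: np.ndarray         # (Gamma - D Q^2) / sigma_Gamma per point
    r_h: float | None = None      # nm
    sigma_r_h: float | None = None
    environment: Environment | None = None


class RadiusEstimate(NamedTuple):
    r_h: float        # nm
    sigma_r_h: float  # nm


def _exp_model(tau, tau0, beta):
    return beta * np.exp(-2.0 * tau / tau0)


def fit_single_exponential(
    delays: np.ndarray,
    g2: np.ndarray,
    sigma_g2: np.ndarray | None,
    beta: float | None = 0.14,
    q: float = np.nan,
) -> G2FitEntry:
    """Weighted fit of Delta g2 = beta exp(-2 tau / tau0) at one Q.

    ``beta=None`` frees the contrast; otherwise it is held fixed.  Zero
    or missing sigmas are replaced by the median of the positive ones
    (unit weights if none).  Non-convergence or tau0 pinned at its
    bounds yields ``converged=False``; downstream fits skip such
    entries.
    """
    delays = np.asarray(delays, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    dg2 = g2 - 1.0
    ok = np.isfinite(delays) & np.isfinite(dg2) & (delays > 0)
    if sigma_g2 is not None:
        sigma = np.asarray(sigma_g2, dtype=float).copy()
        ok &= np.isfinite(sigma)
    else:
        sigma = np.ones_like(dg2)
    delays, dg2, sigma = delays[ok], dg2[ok], sigma[ok]
    if delays.size < 6:
        return G2FitEntry(q, np.nan, np.nan, beta if beta else np.nan,
                          np.nan, np.nan, converged=False)
    pos = sigma > 0
    sigma = np.where(pos, sigma, np.median(sigma[pos]) if pos.any() else 1.0)

    # initial tau0 from the first crossing of beta/e (robust enough for
    # monotone decays); fall back to the geometric mid-lag
    beta0 = beta if beta is not None else max(dg2.max(), 0.01)
    below = np.flatnonzero(dg2 < beta0 / np.e)
    tau0_init = delays[below[0]] * 2.0 if below.size else float(
        np.sqrt(delays[0] * delays[-1])
    )
    tau0_init = float(np.clip(tau0_init, *TAU0_BOUNDS))

    try:
        if beta is None:
            popt, pcov = curve_fit(
                _exp_model, delays, dg2, p0=[tau0_init, beta0], sigma=sigma,
                absolute_sigma=True,
                bounds=([TAU0_BOUNDS[0], 0.0], [TAU0_BOUNDS[1], 2.0]),
                maxfev=20000,
            )
            tau0, beta_fit = popt
            sigma_tau0, sigma_beta = np.sqrt(np.diag(pcov))
        else:
            popt, pcov = curve_fit(
                lambda t, tau0: _exp_model(t, tau0, beta),
                delays, dg2, p0=[tau0_init], sigma=sigma, absolute_sigma=True,
                bounds=([TAU0_BOUNDS[0]], [TAU0_BOUNDS[1]]), maxfev=20000,
            )
            tau0 = popt[0]
            sigma_tau0 = float(np.sqrt(pcov[0, 0]))
            beta_fit, sigma_beta = beta, 0.0
    except (RuntimeError, ValueError):
        return G2FitEntry(q, np.nan, np.nan, beta if beta else np.nan,
                          np.nan, np.nan, converged=False)

    resid = (dg2 - _exp_model(delays, tau0, beta_fit)) / sigma
    n_par = 1 if beta is not None else 2
    red_chisq = float(resid @ resid / max(delays.size - n_par, 1))
    at_bound = (
        tau0 <= TAU0_BOUNDS[0] * (1 + 1e-9) or tau0 >= TAU0_BOUNDS[1] * (1 - 1e-9)
    )
    # a flat signal is "fit" arbitrarily well by any tiny tau0; the huge
    # relative error exposes the unidentifiability
    degenerate = not np.isfinite(sigma_tau0) or sigma_tau0 > 10 * tau0
    return G2FitEntry(
        q=q, tau0=float(tau0), sigma_tau0=float(sigma_tau0),
        beta=float(beta_fit), sigma_beta=float(sigma_beta),
        red_chisq=red_chisq,
        converged=bool(not at_bound and not degenerate and np.isfinite(tau0)),
    )


def fit_g2_result(result, beta: float | None = 0.14) -> G2Fit:
    """Exponential fits for every coarse Q in a :class:`G2Result`."""
    fits = G2Fit()
    for i in range(result.n_q):
        fits.entries.append(
            fit_single_exponential(
                result.delays, result.g2[i], result.sigma_g2[i],
                beta=beta, q=float(result.q[i]),
            )
        )
    return fits


def fit_tau_vs_q(g2fits: G2Fit, q_max: float = 0.1) -> DiffusionFit:
    """Weighted linear fit of Gamma = 1/tau0 against Q^2 through the
    origin; the slope is the diffusivity D in m^2/s.

    Only converged entries with Q <= q_max (nm^-1; default 0.1, above
    which simple Stokes-Einstein scaling is no longer guaranteed) enter
    the fit.  tau0 errors propagate to Gamma via sigma_Gamma =
    sigma_tau0 / tau0^2; points without a usable error get the median
    weight.
    """
    use = [e for e in g2fits.converged_entries
           if np.isfinite(e.q) and e.q <= q_max and e.tau0 > 0]
    if len(use) < 3:
        raise ValueError(
            f"need >= 3 converged Q points below q_max = {q_max}, got {len(use)}"
        )
    q_nm = np.array([e.q for e in use])
    q_si = q_nm * 1e9                      # nm^-1 -> m^-1
    gamma = np.array([1.0 / e.tau0 for e in use])
    sigma_gamma = np.array([
        e.sigma_tau0 / e.tau0**2 if e.sigma_tau0 > 0 and np.isfinite(e.sigma_tau0)
        else np.nan
        for e in use
    ])
    if np.isnan(sigma_gamma).all():
        sigma_gamma = np.ones_like(gamma)
    else:
        med = np.nanmedian(sigma_gamma)
        sigma_gamma = np.where(np.isfinite(sigma_gamma), sigma_gamma, med)

    w = 1.0 / sigma_gamma**2
    x = q_si**2
    d = float((w * gamma * x).sum() / (w * x * x).sum())
    sigma_d = float(np.sqrt(1.0 / (w * x * x).sum()))
    resid = (gamma - d * x) / sigma_gamma
    return DiffusionFit(
        d=d, sigma_d=sigma_d, q_max_used=q_max, q_used=q_nm, residuals=resid,
    )


def stokes_einstein_radius(fit: DiffusionFit, env: Environment) -> RadiusEstimate:
    """R_H = kT / (6 pi eta D) in nm, with sigma_R_H/R_H = sigma_D/D.

    Stores the radius and environment back on the DiffusionFit and
    returns the (R_H, sigma) pair.
    """
    if not fit.d > 0:
        raise ValueError("diffusivity must be positive")
    r_h = env.boltzmann * env.temperature / (6.0 * np.pi * env.viscosity * fit.d) * 1e9
    sigma_r_h = r_h * fit.sigma_d / fit.d
    fit.r_h = float(r_h)
    fit.sigma_r_h = float(sigma_r_h)
    fit.environment = env
    return RadiusEstimate(float(r_h), float(sigma_r_h))
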
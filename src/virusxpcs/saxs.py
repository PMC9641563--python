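"""SAXS reduction: time averaging, azimuthal averaging, and the
Gaussian-polydisperse sphere form-factor fit yielding the geometric
radius R0.

The form-factor model is the standard one for a dilute suspension of
homogeneous spheres whose radii follow a Gaussian number distribution
N(R; R0, sigma_R): the scattered intensity is the V(R)^2-weighted
average of the squared sphere amplitude,

    P(q) = < V(R)^2 A(qR)^2 >_N / < V(R)^2 >_N,
    A(x) = 3 [sin x - x cos x] / x^3,

normalized so P(0) = 1.  Because measured curves span several decades,
the fit minimizes weighted residuals of log I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import least_squares

__all__ = [
    "SaxsCurve",
    "FormFactorFit",
    "FitError",
    "time_average",
    "azimuthal_average",
    "sphere_amplitude",
    "polydisperse_intensity",
    "fit_form_factor",
]


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge; carries the
    last iterate in ``last_params``."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class SaxsCurve:
    """1D azimuthally averaged scattering intensity.

    ``intensity`` is in mean counts per pixel per frame (arbitrary
    units); ``sigma_intensity`` is the standard error per bin;
    ``n_pixels`` the number of contributing pixels per bin.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma_intensity: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma_intensity = np.asarray(self.sigma_intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=np.int64)
        if self.q.size and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma_intensity < 0):
            raise ValueError("sigma_intensity must be non-negative")

    def to_text(self, path) -> None:
        """Write the 4-column plain-text form (q, I, sigma, n)."""
        np.savetxt(
            path,
            np.column_stack([self.q, self.intensity, self.sigma_intensity, self.n_pixels]),
            header="q_nm^-1 intensity sigma n_pixels",
        )

    @classmethod
    def from_text(cls, path) -> "SaxsCurve":
        arr = np.loadtxt(path, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3].astype(np.int64))


@dataclass
class FormFactorFit:
    """Result of the polydisperse-sphere fit: geometric radius R0 (nm),
    distribution width sigma_R (nm), scale, background, their covariance,
    and the reduced chi-square over the fitted q range."""

    r0: float
    sigma_r: float
    scale: float
    background: float
    covariance: np.ndarray
    red_chisq: float
    q_range: tuple[float, float]
    residuals: np.ndarray
    q_used: np.ndarray

    @property
    def r0_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


def time_average(events) -> np.ndarray:
    """Per-pixel mean counts per frame from a sparse event stream.

    Returns a flat (n_pixels,) array: sum of counts per pixel divided by
    n_frames.  An empty stream gives all zeros.
    """
    sums = np.bincount(
        events.pixel_index.astype(np.int64),
        weights=events.count.astype(np.float64),
        minlength=events.n_pixels,
    )
    return sums / events.n_frames


def azimuthal_average(mean_image: np.ndarray, qmap) -> SaxsCurve:
    """Group a per-pixel mean intensity into the SAXS Q partitions.

    Per partition: intensity = mean over unmasked member pixels; sigma =
    population std of member pixels / sqrt(n); empty partitions are
    dropped.
    """
    img = np.asarray(mean_image, dtype=float).ravel()
    if img.size != qmap.n_pixels:
        raise ValueError("image size does not match qmap")
    labels = qmap.saxs_labels
    good = qmap.mask & (labels >= 0)
    if not good.any():
        warnings.warn("no unmasked pixels; empty SAXS curve", stacklevel=2)
        empty = np.empty(0)
        return SaxsCurve(empty, empty, empty, np.empty(0, dtype=np.int64))
    lab = labels[good]
    vals = img[good]
    n_part = int(lab.max()) + 1
    counts = np.bincount(lab, minlength=n_part)
    sums = np.bincount(lab, weights=vals, minlength=n_part)
    sq_sums = np.bincount(lab, weights=vals**2, minlength=n_part)
    nonempty = counts > 0
    n = counts[nonempty]
    mean = sums[nonempty] / n
    var = np.maximum(sq_sums[nonempty] / n - mean**2, 0.0)
    sigma = np.sqrt(var / n)
    q_rep = qmap.q_saxs[: n_part][nonempty]
    order = np.argsort(q_rep)
    return SaxsCurve(q_rep[order], mean[order], sigma[order], n[order])


def sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized scattering amplitude of a homogeneous sphere,
    A(x) = 3 [sin x - x cos x] / x^3 with A(0) = 1.

    For x < 1e-2 the Taylor series 1 - x^2/10 + x^4/280 is used; the
    direct formula loses significance there to cancellation (its rounding
    error grows as eps/x^2), while the series truncation error is below
    1e-16 at the branch point.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x = qR must be non-negative")
    out = np.empty_like(x)
    small = x < 1e-2
    xs2 = x[small] ** 2
    out[small] = 1.0 - xs2 / 10.0 + xs2**2 / 280.0
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return out


# quadrature grid for the Gaussian size average: R0 +/- 4 sigma, 129 points
_N_QUAD = 129
_SIGMA_SPAN = 4.0


def polydisperse_intensity(q: np.ndarray, r0: float, sigma_r: float) -> np.ndarray:
    """Form factor P(q) of spheres with a Gaussian radius distribution.

    Number-weighted Gaussian N(R; R0, sigma_R) with V(R)^2 intensity
    weighting, integrated on a fixed 129-point grid over R0 +/- 4 sigma
    (truncated at R > 0) and normalized so P(0) = 1.  sigma_R = 0 reduces
    exactly to the monodisperse sphere.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if not r0 > 0:
        raise ValueError("r0 must be positive")
    if sigma_r < 0:
        raise ValueError("sigma_r must be non-negative")
    if sigma_r == 0:
        return sphere_amplitude(q * r0) ** 2
    if sigma_r > r0 / 2:
        warnings.warn(
            "sigma_r > r0/2: the truncated Gaussian average may be biased",
            stacklevel=2,
        )
    r_lo = max(r0 - _SIGMA_SPAN * sigma_r, 1e-12)
    r_hi = r0 + _SIGMA_SPAN * sigma_r
    r = np.linspace(r_lo, r_hi, _N_QUAD)
    gauss = np.exp(-0.5 * ((r - r0) / sigma_r) ** 2)
    w = gauss * r**6  # V(R)^2 ~ R^6; constant factors cancel on normalization
    amp_sq = sphere_amplitude(np.outer(q, r)) ** 2
    num = simpson(w * amp_sq, x=r, axis=1)
    den = simpson(w, x=r)
    return num / den


def fit_form_factor(
    curve: SaxsCurve,
    init: tuple[float, float, float, float] = (10.0, 2.0, 1.0, 0.0),
    q_range: tuple[float, float] | None = None,
) -> FormFactorFit:
    """Weighted least squares of the polydisperse sphere model on log I.

    Residuals are (log I_model - log I_data) / w with weights propagated
    from sigma_intensity (w = sigma/I); bins with sigma = 0 (noise-free
    curves) get unit weights.  ``q_range`` restricts the fit, e.g. to cut
    the low-q upturn of aggregated samples.
    """
    if q_range is None:
        sel = np.ones(curve.q.size, dtype=bool)
    else:
        sel = (curve.q >= q_range[0]) & (curve.q <= q_range[1])
    q = curve.q[sel]
    intensity = curve.intensity[sel]
    sigma = curve.sigma_intensity[sel]
    positive = intensity > 0
    q, intensity, sigma = q[positive], intensity[positive], sigma[positive]
    if q.size < 8:
        raise ValueError(f"need >= 8 bins in the fitted q range, got {q.size}")

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(sigma > 0, sigma / intensity, 0.0)
    if np.all(w == 0):
        w = np.ones_like(q)
    else:
        w = np.where(w > 0, w, np.median(w[w > 0]))
    log_i = np.log(intensity)

    def residual(p):
        r0, sigma_r, scale, background = p
        model = scale * polydisperse_intensity(q, r0, sigma_r) + background
        model = np.maximum(model, 1e-300)
        return (np.log(model) - log_i) / w

    lower = [1e-3, 0.0, 1e-300, -np.inf]
    upper = [np.inf, np.inf, np.inf, np.inf]
    result = least_squares(
        residual, x0=np.asarray(init, dtype=float), bounds=(lower, upper),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not result.success:
        raise FitError(f"form-factor fit did not converge: {result.message}",
                       last_params=result.x)

    n_free = q.size - 4
    chisq = float(result.cost * 2.0)
    red_chisq = chisq / max(n_free, 1)
    # covariance from the Jacobian at the solution
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * (red_chisq if np.all(sigma == 0) else 1.0)
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
    return FormFactorFit(
        r0=float(result.x[0]),
        sigma_r=float(result.x[1]),
        scale=float(result.x[2]),
        background=float(result.x[3]),
        covariance=cov,
        red_chisq=red_chisq,
        q_range=(float(q.min()), float(q.max())),
        residuals=-result.fun * w,  # unweighted log(data) - log(model) per bin
        q_used=q,
    )
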
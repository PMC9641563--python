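"""Synthetic Brownian-speckle photon streams.

Generates sparse detector-frame time series with the exact statistical
structure the analysis chain assumes for a dilute Brownian suspension:

* per pixel, the complex scattered field is a sum of ``n_modes``
  independent coherent modes, each an Ornstein–Uhlenbeck process with
  relaxation rate Gamma = D Q^2, so the pre-detection intensity obeys
  g2(tau) = 1 + (1/n_modes) exp(-2 D Q^2 tau);
* partial beam coherence enters as the incoherent mode sum — contrast
  beta is realized as exactly 1/n_modes;
* photon detection is a per-pixel, per-frame Poisson draw whose mean is
  set by the configured count rate, optionally shaped in Q by the
  polydisperse sphere form factor.

Pixels are statistically independent: the analysis only uses per-pixel
time correlations and pixel averages, so inter-pixel speckle correlation
would not change any measured quantity while making the simulation far
more expensive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .saxs import polydisperse_intensity

__all__ = [
    "BOLTZMANN",
    "SimulationConfig",
    "PhotonEvents",
    "diffusivity_from_radius",
    "hydrodynamic_radius_from_diffusivity",
    "brownian_speckle_sequence",
    "static_speckle_sequence",
    "saxs_curve",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23


def diffusivity_from_radius(r_h_nm: float, temperature: float, viscosity: float) -> float:
    """Stokes–Einstein diffusivity D = kT / (6 pi eta R_H) in m^2/s.

    ``r_h_nm`` in nm, ``temperature`` in K, ``viscosity`` in Pa s.
    """
    if not (r_h_nm > 0 and temperature > 0 and viscosity > 0):
        raise ValueError("R_H, temperature and viscosity must all be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * viscosity * r_h_nm * 1e-9)


def hydrodynamic_radius_from_diffusivity(
    d: float, temperature: float, viscosity: float
) -> float:
    """Inverse of :func:`diffusivity_from_radius`; returns R_H in nm."""
    if not (d > 0 and temperature > 0 and viscosity > 0):
        raise ValueError("D, temperature and viscosity must all be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * viscosity * d) * 1e9


@dataclass
class SimulationConfig:
    """Conditions for a synthetic speckle sequence.

    Defaults reproduce the measurement conditions of the dilute virus
    study this generator emulates: sample A environment (T = 279 K,
    eta = 1.520e-3 Pa s), true hydrodynamic radius 18.7 nm, beamline
    contrast ~0.14 (7 coherent modes), 52 kHz frame rate, 100 000-frame
    sequences, and a mean count rate of 7e-5 photons/pixel/frame.
    """

    true_r_h: float = 18.7           # nm
    temperature: float = 279.0       # K
    viscosity: float = 1.520e-3      # Pa s
    contrast_beta: float = 0.14
    n_modes: int | None = None       # default round(1/contrast_beta)
    frame_rate: float = 52_000.0     # Hz
    n_frames: int = 100_000
    mean_count_rate: float = 7e-5    # photons / pixel / frame at reference Q
    ring_spec: list[tuple[float, int]] = field(
        default_factory=lambda: [(0.031, 100)]
    )
    form_factor: tuple[float, float] | str = "flat"  # (R0 nm, sigma_R nm) or "flat"
    reference_q: float | None = None  # default: lowest ring Q
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.contrast_beta <= 1:
            raise ValueError("contrast_beta must be in (0, 1]")
        if self.n_modes is None:
            self.n_modes = max(1, round(1.0 / self.contrast_beta))
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        realized = 1.0 / self.n_modes
        if abs(realized - self.contrast_beta) > 0.05:
            warnings.warn(
                f"realized contrast 1/{self.n_modes} = {realized:.3f} differs from "
                f"requested beta = {self.contrast_beta:.3f} by more than 0.05",
                stacklevel=2,
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (self.frame_rate > 0 and self.mean_count_rate > 0):
            raise ValueError("frame_rate and mean_count_rate must be positive")
        if not self.ring_spec:
            raise ValueError("ring_spec must not be empty")
        if any(q <= 0 or n < 1 for q, n in self.ring_spec):
            raise ValueError("ring_spec entries must have Q > 0 and n_pixels >= 1")
        if not (self.true_r_h > 0 and self.temperature > 0 and self.viscosity > 0):
            raise ValueError("true_r_h, temperature, viscosity must be positive")

    @property
    def realized_beta(self) -> float:
        """Contrast actually realized by the mode sum, 1/n_modes."""
        return 1.0 / self.n_modes

    @property
    def diffusivity(self) -> float:
        """Ground-truth D in m^2/s implied by (R_H, T, eta)."""
        return diffusivity_from_radius(self.true_r_h, self.temperature, self.viscosity)


@dataclass
class PhotonEvents:
    """Sparse photon events: (frame_index, pixel_index, count) triples.

    Events are sorted by (frame_index, pixel_index); densifying and
    re-sparsifying is lossless.  ``q_per_pixel`` carries the ring table
    for simulated data (NaN where unknown).
    """

    frame_index: np.ndarray
    pixel_index: np.ndarray
    count: np.ndarray
    n_frames: int
    n_pixels: int
    frame_rate: float
    q_per_pixel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.uint32)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.uint32)
        self.count = np.asarray(self.count, dtype=np.uint16)
        if not (self.frame_index.shape == self.pixel_index.shape == self.count.shape):
            raise ValueError("event arrays must have identical shapes")
        if self.frame_index.size:
            if int(self.frame_index.max()) >= self.n_frames:
                raise ValueError("frame_index out of bounds")
            if int(self.pixel_index.max()) >= self.n_pixels:
                raise ValueError("pixel_index out of bounds")
            if int(self.count.min()) < 1:
                raise ValueError("event counts must be >= 1")
        if self.q_per_pixel is not None:
            self.q_per_pixel = np.asarray(self.q_per_pixel, dtype=float)
            if self.q_per_pixel.size != self.n_pixels:
                raise ValueError("q_per_pixel must have one entry per pixel")

    @property
    def n_events(self) -> int:
        return self.frame_index.size

    @property
    def duration(self) -> float:
        """Sequence duration in seconds, n_frames / frame_rate."""
        return self.n_frames / self.frame_rate

    def to_dense(self, pixels: slice | np.ndarray | None = None) -> np.ndarray:
        """Dense (n_pixels, n_frames) float64 count array (optionally a
        pixel subset)."""
        if pixels is None:
            dense = np.zeros((self.n_pixels, self.n_frames))
            dense[self.pixel_index, self.frame_index] = self.count
            return dense
        pix = np.arange(self.n_pixels)[pixels]
        lookup = np.full(self.n_pixels, -1, dtype=np.int64)
        lookup[pix] = np.arange(pix.size)
        sel = lookup[self.pixel_index] >= 0
        dense = np.zeros((pix.size, self.n_frames))
        dense[lookup[self.pixel_index[sel]], self.frame_index[sel]] = self.count[sel]
        return dense

    @classmethod
    def from_dense(
        cls,
        dense: np.ndarray,
        frame_rate: float,
        q_per_pixel: np.ndarray | None = None,
    ) -> "PhotonEvents":
        """Sparsify a dense (n_pixels, n_frames) integer count array."""
        dense = np.asarray(dense)
        pix, frm = np.nonzero(dense)
        order = np.lexsort((pix, frm))
        return cls(
            frame_index=frm[order],
            pixel_index=pix[order],
            count=dense[pix[order], frm[order]],
            n_frames=dense.shape[1],
            n_pixels=dense.shape[0],
            frame_rate=frame_rate,
            q_per_pixel=q_per_pixel,
        )


def _ou_intensity(
    rng: np.random.Generator,
    n_pixels: int,
    n_frames: int,
    n_modes: int,
    gamma_dt: float,
) -> np.ndarray:
    """Mode-summed speckle intensity with unit mean, shape (n_pixels, n_frames).

    Each mode is a stationary complex Ornstein–Uhlenbeck process advanced
    one frame at a time by the exact discrete update
    E(t+1) = a E(t) + sqrt(1 - a^2) xi,  a = exp(-gamma_dt),
    which is an AR(1) recursion applied with a C-level IIR filter.
    """
    a = float(np.exp(-gamma_dt))
    intensity = np.zeros((n_pixels, n_frames))
    for _ in range(n_modes):
        e0 = (
            rng.standard_normal(n_pixels) + 1j * rng.standard_normal(n_pixels)
        ) * np.sqrt(0.5)
        if a == 1.0 or gamma_dt == 0.0:
            # frozen field: no temporal evolution
            field_t = np.broadcast_to(e0[:, None], (n_pixels, n_frames))
            intensity += np.abs(field_t) ** 2
            continue
        noise = (
            rng.standard_normal((n_pixels, n_frames))
            + 1j * rng.standard_normal((n_pixels, n_frames))
        ) * np.sqrt(0.5)
        sig = np.sqrt(1.0 - a * a)
        # y[t] = a y[t-1] + sig x[t], with y[-1] = e0 (stationary start)
        zi = (a * e0)[:, None]
        field_t, _ = lfilter([sig], [1.0, -a], noise, axis=1, zi=zi)
        intensity += np.abs(field_t) ** 2
    return intensity / n_modes


def _form_factor_weight(config: SimulationConfig, q: float, q_ref: float) -> float:
    if config.form_factor == "flat":
        return 1.0
    r0, sigma_r = config.form_factor  # type: ignore[misc]
    return float(
        polydisperse_intensity(np.array([q]), r0, sigma_r)[0]
        / polydisperse_intensity(np.array([q_ref]), r0, sigma_r)[0]
    )


def brownian_speckle_sequence(
    config: SimulationConfig, static: bool = False
) -> PhotonEvents:
    """Simulate a sparse photon stream from Brownian speckle dynamics.

    For each ring at momentum transfer Q the field relaxes at
    Gamma = D Q^2 with D from the configured (R_H, T, eta); photon counts
    are Poisson draws around the speckle intensity scaled to the
    configured mean count rate (shaped by the form factor if one is set).
    All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    d = config.diffusivity
    dt = 1.0 / config.frame_rate
    q_ref = config.reference_q
    if q_ref is None:
        q_ref = min(q for q, _ in config.ring_spec)

    frames_all: list[np.ndarray] = []
    pixels_all: list[np.ndarray] = []
    counts_all: list[np.ndarray] = []
    pixel_offset = 0
    q_per_pixel: list[np.ndarray] = []

    for q_nm, n_pix in config.ring_spec:
        gamma = 0.0 if static else d * (q_nm * 1e9) ** 2
        gamma_dt = gamma * dt
        if gamma_dt > 50:
            warnings.warn(
                f"Gamma*dt = {gamma_dt:.1f} at Q = {q_nm} nm^-1: dynamics far "
                "faster than the frame rate; g2 will look fully decorrelated",
                stacklevel=2,
            )
        intensity = _ou_intensity(rng, n_pix, config.n_frames, config.n_modes, gamma_dt)
        mean_rate = config.mean_count_rate * _form_factor_weight(config, q_nm, q_ref)
        counts = rng.poisson(intensity * mean_rate)
        pix, frm = np.nonzero(counts)
        frames_all.append(frm)
        pixels_all.append(pix + pixel_offset)
        counts_all.append(counts[pix, frm])
        q_per_pixel.append(np.full(n_pix, q_nm))
        pixel_offset += n_pix

    frm = np.concatenate(frames_all)
    pix = np.concatenate(pixels_all)
    cnt = np.concatenate(counts_all)
    order = np.lexsort((pix, frm))
    return PhotonEvents(
        frame_index=frm[order],
        pixel_index=pix[order],
        count=cnt[order],
        n_frames=config.n_frames,
        n_pixels=pixel_offset,
        frame_rate=config.frame_rate,
        q_per_pixel=np.concatenate(q_per_pixel),
    )


def static_speckle_sequence(config: SimulationConfig) -> PhotonEvents:
    """Frozen-field speckle (Gamma = 0): the static reference used to
    measure the beamline contrast beta."""
    return brownian_speckle_sequence(config, static=True)


def saxs_curve(
    r0: float,
    sigma_r: float,
    q_grid: np.ndarray,
    scale: float = 1.0,
    background: float = 0.0,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
):
    """Noise-free (or multiplicatively noisy) synthetic 1D SAXS curve.

    I(q) = scale * P(q; R0, sigma_R) + background with P the Gaussian-
    polydisperse sphere form factor, normalized to P(0) = 1.  Returns a
    :class:`~virusxpcs.saxs.SaxsCurve`.
    """
    from .saxs import SaxsCurve

    q_grid = np.asarray(q_grid, dtype=float)
    intensity = scale * polydisperse_intensity(q_grid, r0, sigma_r) + background
    sigma = np.zeros_like(intensity)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_sd_rel * rng.standard_normal(q_grid.size))
        sigma = np.abs(intensity) * noise_sd_rel
    return SaxsCurve(
        q=q_grid,
        intensity=intensity,
        sigma_intensity=sigma,
        n_pixels=np.ones(q_grid.size, dtype=np.int64),
    )
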
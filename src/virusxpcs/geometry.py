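"""Detector geometry and momentum-transfer (Q) maps.

Maps every detector pixel to a momentum transfer Q and assigns the three
partition schemes used downstream:

* *fine* partitions — narrow contiguous Q bins (default width 1e-3 nm^-1,
  roughly two pixels at small-angle geometry) inside which the intensity is
  nearly constant, so that binning the correlator sums does not inflate the
  g2 baseline;
* *coarse* partitions — groups of consecutive fine partitions (default 10,
  so ~1e-2 nm^-1 wide) at which g2(tau, Q) is finally reported;
* *saxs* partitions — logarithmically spaced Q bins (default 270) for the
  1D azimuthally averaged intensity.

A ring-style map (:func:`qmap_from_rings`) covers simulated data where
pixels are listed per Q ring instead of sitting on a 2D grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HC_KEV_ANGSTROM",
    "DetectorGeometry",
    "QMap",
    "wavelength_from_energy",
    "build_qmap",
    "make_partitions",
    "qmap_from_rings",
]

#: hc in keV·Å; divides photon energy to give the wavelength.
HC_KEV_ANGSTROM = 12.3984


def wavelength_from_energy(photon_energy_kev: float) -> float:
    """X-ray wavelength in Å for a photon energy in keV (lambda = hc/E)."""
    if not photon_energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {photon_energy_kev}")
    return HC_KEV_ANGSTROM / photon_energy_kev


@dataclass(frozen=True)
class DetectorGeometry:
    """Small-angle scattering geometry of an area detector.

    Parameters
    ----------
    pixel_pitch:
        Pixel size in µm.
    distance:
        Sample–detector distance in m.
    photon_energy:
        Photon energy in keV; the wavelength is derived from it.
    beam_center:
        Direct-beam position as (row, col) in fractional 0-based pixel
        coordinates.
    frame_rate:
        Detector frame rate in Hz.
    shape:
        Detector array shape (n_rows, n_cols).
    """

    pixel_pitch: float
    distance: float
    photon_energy: float
    beam_center: tuple[float, float]
    frame_rate: float
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if not self.distance > 0:
            raise ValueError("distance must be positive")
        if not self.photon_energy > 0:
            raise ValueError("photon_energy must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        n_rows, n_cols = self.shape
        if n_rows < 1 or n_cols < 1:
            raise ValueError("shape must have positive extents")
        # beam center may sit off-detector (small-angle setups often park it
        # behind a beamstop near an edge) but not absurdly far away
        limit_r, limit_c = 10.0 * n_rows, 10.0 * n_cols
        br, bc = self.beam_center
        if abs(br) > limit_r or abs(bc) > limit_c:
            raise ValueError(
                f"beam center {self.beam_center} is outside 10x the detector extent"
            )

    @property
    def wavelength(self) -> float:
        """Wavelength in Å."""
        return wavelength_from_energy(self.photon_energy)


@dataclass
class QMap:
    """Per-pixel momentum transfer, mask, and partition labels.

    All per-pixel arrays are flat (C-order raveled detector).  A label of
    ``-1`` means the pixel is masked or not assigned to any partition.
    ``q_fine``/``q_coarse``/``q_saxs`` hold the representative Q per
    partition: the pixel-count-weighted mean Q of the member pixels, the
    same weighting used when intensities are averaged.
    """

    q: np.ndarray
    mask: np.ndarray
    shape: tuple[int, int]
    fine_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    coarse_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    saxs_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    q_fine: np.ndarray = field(default=None)  # type: ignore[assignment]
    q_coarse: np.ndarray = field(default=None)  # type: ignore[assignment]
    q_saxs: np.ndarray = field(default=None)  # type: ignore[assignment]
    fine_width: float | None = None
    rebin_factor: int | None = None
    saxs_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.q.shape != self.mask.shape:
            raise ValueError("q and mask must have the same number of pixels")
        n = self.q.size
        if self.fine_labels is None:
            self.fine_labels = np.full(n, -1, dtype=np.int64)
        if self.coarse_labels is None:
            self.coarse_labels = np.full(n, -1, dtype=np.int64)
        if self.saxs_labels is None:
            self.saxs_labels = np.full(n, -1, dtype=np.int64)
        if self.q_fine is None:
            self.q_fine = np.empty(0)
        if self.q_coarse is None:
            self.q_coarse = np.empty(0)
        if self.q_saxs is None:
            self.q_saxs = np.empty(0)

    @property
    def n_pixels(self) -> int:
        return self.q.size

    @property
    def n_fine(self) -> int:
        return self.q_fine.size

    @property
    def n_coarse(self) -> int:
        return self.q_coarse.size


def build_qmap(geometry: DetectorGeometry, mask: np.ndarray) -> QMap:
    """Compute per-pixel Q (nm^-1) from the geometry; partitions stay empty.

    Uses the exact formula q = (4 pi / lambda) sin(atan(r/L) / 2) rather
    than the small-angle approximation 2 pi r / (L lambda); at typical
    small-angle geometries the two agree to ~1e-6 relative.
    """
    mask = np.asarray(mask)
    if mask.shape != geometry.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match geometry shape {geometry.shape}"
        )
    n_rows, n_cols = geometry.shape
    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    pitch_m = geometry.pixel_pitch * 1e-6
    dr = (rows - geometry.beam_center[0]) * pitch_m
    dc = (cols - geometry.beam_center[1]) * pitch_m
    r = np.hypot(dr, dc)
    two_theta = np.arctan2(r, geometry.distance)
    wavelength_nm = geometry.wavelength * 0.1
    q = (4.0 * np.pi / wavelength_nm) * np.sin(0.5 * two_theta)
    return QMap(q=q, mask=mask.astype(bool), shape=geometry.shape)


def _representative_q(q: np.ndarray, labels: np.ndarray, n_part: int) -> np.ndarray:
    """Pixel-count-weighted mean Q per partition (NaN for empty partitions)."""
    counts = np.bincount(labels[labels >= 0], minlength=n_part).astype(float)
    sums = np.bincount(labels[labels >= 0], weights=q[labels >= 0], minlength=n_part)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def make_partitions(
    qmap: QMap,
    fine_width: float = 1e-3,
    rebin_factor: int = 10,
    n_saxs: int = 270,
) -> QMap:
    """Assign fine, coarse, and SAXS partition labels to a QMap.

    Fine partitions are contiguous Q bins of width ``fine_width`` starting
    at the minimum unmasked Q (a partial trailing bin is kept).  Coarse
    partitions group ``rebin_factor`` consecutive fine partitions
    (``coarse = fine // rebin_factor``).  SAXS partitions are ``n_saxs``
    log-spaced bins spanning the unmasked Q range.
    """
    if not fine_width > 0:
        raise ValueError("fine_width must be positive")
    if rebin_factor < 1:
        raise ValueError("rebin_factor must be >= 1")
    if n_saxs < 1:
        raise ValueError("n_saxs must be >= 1")

    usable = qmap.mask & np.isfinite(qmap.q)
    q_use = qmap.q[usable]
    if np.unique(q_use).size < 2:
        raise ValueError("need at least 2 distinct unmasked Q values to partition")

    q_min, q_max = float(q_use.min()), float(q_use.max())

    fine = np.full(qmap.n_pixels, -1, dtype=np.int64)
    fine[usable] = np.floor((qmap.q[usable] - q_min) / fine_width).astype(np.int64)
    n_fine = int(fine.max()) + 1

    coarse = np.where(fine >= 0, fine // rebin_factor, -1)
    n_coarse = int(coarse.max()) + 1

    # log-spaced SAXS bins; Q = 0 pixels (the beam center) cannot go on a
    # log grid and are left unlabeled
    pos = usable & (qmap.q > 0)
    q_lo = float(qmap.q[pos].min()) if pos.any() else q_min
    edges = np.geomspace(q_lo, q_max, n_saxs + 1) if pos.any() else np.array([q_min, q_max])
    saxs = np.full(qmap.n_pixels, -1, dtype=np.int64)
    if pos.any():
        idx = np.searchsorted(edges, qmap.q[pos], side="right") - 1
        saxs[pos] = np.clip(idx, 0, n_saxs - 1)
    n_saxs_eff = int(saxs.max()) + 1 if pos.any() else 0

    return replace(
        qmap,
        fine_labels=fine,
        coarse_labels=coarse,
        saxs_labels=saxs,
        q_fine=_representative_q(qmap.q, fine, n_fine),
        q_coarse=_representative_q(qmap.q, coarse, n_coarse),
        q_saxs=_representative_q(qmap.q, saxs, n_saxs_eff),
        fine_width=fine_width,
        rebin_factor=rebin_factor,
        saxs_edges=edges if pos.any() else None,
    )


def qmap_from_rings(ring_spec: list[tuple[float, int]]) -> QMap:
    """QMap for ring-listed pixels: each Q ring is its own fine partition.

    ``ring_spec`` is a list of (Q in nm^-1, n_pixels).  Pixels are laid out
    contiguously ring by ring; fine and coarse labels both equal the ring
    index (rings are already the reporting granularity), so this map plugs
    into the correlator exactly like a detector-derived one.
    """
    if not ring_spec:
        raise ValueError("ring_spec must not be empty")
    qs, counts = zip(*ring_spec)
    if any(c < 1 for c in counts):
        raise ValueError("every ring needs at least one pixel")
    if any(q <= 0 for q in qs):
        raise ValueError("ring Q values must be positive")
    order = np.argsort(qs, kind="stable")
    if not np.array_equal(order, np.arange(len(qs))):
        warnings.warn("ring_spec not sorted by Q; sorting", stacklevel=2)
        ring_spec = [ring_spec[i] for i in order]
        qs, counts = zip(*ring_spec)
    q = np.repeat(np.asarray(qs, dtype=float), counts)
    labels = np.repeat(np.arange(len(qs), dtype=np.int64), counts)
    return QMap(
        q=q,
        mask=np.ones(q.size, dtype=bool),
        shape=(1, q.size),
        fine_labels=labels,
        coarse_labels=labels.copy(),
        saxs_labels=labels.copy(),
        q_fine=np.asarray(qs, dtype=float),
        q_coarse=np.asarray(qs, dtype=float),
        q_saxs=np.asarray(qs, dtype=float),
        rebin_factor=1,
    )
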
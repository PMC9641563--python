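"""Multi-tau intensity autocorrelation with symmetric normalization.

Computes g2(tau, Q) from sparse photon frames the way sparse-photon XPCS
requires:

* delay channels on a multi-tau grid — level 0 correlates the raw frame
  stream at lags 1..c; every further level first block-averages frames
  by 2 and correlates the coarser stream, giving logarithmic lag
  coverage at linear cost;
* symmetric normalization — the "future" and "past" window means IF(tau)
  = <I(t)> over [0, T-tau] and IP(tau) = <I(t+tau)> over [tau, T] remove
  slow intensity drift to first order;
* pixel binning BEFORE division — within each narrow (fine) Q partition
  the pixel-averaged sums are combined as <G2> / (<IF><IP>).  At count
  rates of ~1e-4 photons/pixel/frame the per-pixel ratio G2/(IF*IP) is
  dominated by the shot noise of the denominators; averaging the sums
  first removes that bias and keeps the contrast beta measurable even
  with no temporal decorrelation;
* the reported error bar is the population standard deviation of the
  per-pixel g2 within the coarse Q partition.

Pixels whose correlation plateau is abnormally high (a photon-counting
detector artifact whose impact grows as count rates fall) are flagged by
a robust median + 5 scaled-MAD rule on the small-lag plateau and
excluded from normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "LagChannel",
    "MultiTauLags",
    "CorrAccumulator",
    "G2Result",
    "build_lags",
    "correlate_multitau",
    "average_accumulators",
    "flag_bad_pixels",
    "normalize",
]


class LagChannel(NamedTuple):
    level: int
    channel: int          # lag in (block) frames at this level
    lag_frames: int       # lag in native frames = channel * 2**level
    lag_seconds: float


@dataclass
class MultiTauLags:
    """Multi-tau delay grid: ``levels`` levels of ``channels_per_level``
    channels; level ``l`` correlates frames pre-averaged in blocks of
    ``2**l``."""

    levels: int
    channels_per_level: int
    frame_rate: float
    delays: list[LagChannel]

    @property
    def lag_frames(self) -> np.ndarray:
        return np.array([d.lag_frames for d in self.delays], dtype=np.int64)

    @property
    def lag_seconds(self) -> np.ndarray:
        return np.array([d.lag_seconds for d in self.delays])

    @property
    def n_lags(self) -> int:
        return len(self.delays)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MultiTauLags)
            and self.channels_per_level == other.channels_per_level
            and self.frame_rate == other.frame_rate
            and self.delays == other.delays
        )


def build_lags(
    n_frames: int,
    frame_rate: float,
    levels: int | None = None,
    channels_per_level: int = 8,
    max_lag_fraction: float = 0.25,
) -> MultiTauLags:
    """Build the exponentially recursive multi-tau lag grid.

    Level 0 holds lags 1..c in native frames; level l >= 1 holds lags
    (c/2, c] * 2**l.  Lags beyond ``max_lag_fraction * n_frames``
    (default 1/4, a statistical-reliability floor) are dropped.  If
    ``levels`` is None, levels are added until none of their lags fit.
    """
    c = channels_per_level
    if c < 2 or c % 2:
        raise ValueError("channels_per_level must be an even integer >= 2")
    if n_frames <= c:
        raise ValueError(f"n_frames = {n_frames} must exceed channels_per_level = {c}")
    max_lag = int(n_frames * max_lag_fraction)
    delays: list[LagChannel] = []
    for k in range(1, c + 1):
        if k <= max_lag:
            delays.append(LagChannel(0, k, k, k / frame_rate))
    level = 1
    while levels is None or level < levels:
        width = 2**level
        added = False
        for k in range(c // 2 + 1, c + 1):
            lag = k * width
            if lag <= max_lag:
                delays.append(LagChannel(level, k, lag, lag / frame_rate))
                added = True
        if not added:
            break
        level += 1
    n_levels = (max(d.level for d in delays) + 1) if delays else 0
    return MultiTauLags(
        levels=n_levels,
        channels_per_level=c,
        frame_rate=frame_rate,
        delays=delays,
    )


@dataclass
class CorrAccumulator:
    """Unnormalized per-pixel correlator sums.

    ``g2_sums`` (G2), ``if_sums`` (IF) and ``ip_sums`` (IP) have shape
    (n_pixels, n_lags) and hold *time-averaged* quantities, so merging
    repeats is a weighted mean with per-lag pair-count weights.
    """

    lags: MultiTauLags
    fine_labels: np.ndarray        # (n_pixels,) partition label, -1 = unused
    pixel_q: np.ndarray            # (n_pixels,)
    g2_sums: np.ndarray            # (n_pixels, n_lags)
    if_sums: np.ndarray
    ip_sums: np.ndarray
    weights: np.ndarray            # (n_lags,) time-pair counts x n_repeats
    n_repeats: int = 1
    flags: np.ndarray | None = None  # True = bad pixel, set by flag_bad_pixels

    @property
    def n_pixels(self) -> int:
        return self.fine_labels.size

    def same_structure(self, other: "CorrAccumulator") -> bool:
        return (
            self.lags == other.lags
            and np.array_equal(self.fine_labels, other.fine_labels)
        )


def _level_streams(dense: np.ndarray, levels: int):
    """Yield (level, block-averaged stream); level l averaged in
    non-overlapping blocks of 2**l (intensity-preserving means)."""
    stream = dense
    for level in range(levels):
        yield level, stream
        t = stream.shape[1] // 2
        if t < 1:
            return
        stream = 0.5 * (stream[:, : 2 * t : 2] + stream[:, 1 : 2 * t : 2])


def correlate_multitau(
    events,
    qmap,
    lags: MultiTauLags,
    pixel_chunk: int = 512,
) -> CorrAccumulator:
    """Exact per-pixel G2/IF/IP at every multi-tau lag.

    At level l the products run over the 2**l-block-averaged stream with
    symmetric windows: G2(tau) averages I(t) I(t+tau) for t in [0, T-tau),
    IF averages I(t) over the same window and IP averages I(t+tau).
    Lags that do not fit in the (block) stream are dropped with a warning.
    """
    if events.n_pixels != qmap.n_pixels:
        raise ValueError("events and qmap disagree on the number of pixels")
    n_lags = lags.n_lags
    n_pix = events.n_pixels
    g2 = np.zeros((n_pix, n_lags))
    if_s = np.zeros((n_pix, n_lags))
    ip_s = np.zeros((n_pix, n_lags))
    weights = np.zeros(n_lags)

    by_level: dict[int, list[tuple[int, int]]] = {}
    for j, d in enumerate(lags.delays):
        by_level.setdefault(d.level, []).append((j, d.channel))

    n_levels = max(by_level) + 1
    dropped: list[int] = []

    for start in range(0, n_pix, pixel_chunk):
        stop = min(start + pixel_chunk, n_pix)
        dense = events.to_dense(slice(start, stop))
        first_chunk = start == 0
        for level, stream in _level_streams(dense, n_levels):
            t_level = stream.shape[1]
            for j, k in by_level.get(level, []):
                n_pairs = t_level - k
                if n_pairs < 1:
                    if first_chunk:
                        dropped.append(lags.delays[j].lag_frames)
                    continue
                head = stream[:, :n_pairs]
                tail = stream[:, k : k + n_pairs]
                g2[start:stop, j] = np.einsum("pt,pt->p", head, tail) / n_pairs
                if_s[start:stop, j] = head.mean(axis=1)
                ip_s[start:stop, j] = tail.mean(axis=1)
                if first_chunk:
                    weights[j] = n_pairs
    if dropped:
        warnings.warn(f"dropped lags exceeding the stream length: {sorted(dropped)}",
                      stacklevel=2)

    keep = weights > 0
    if not keep.all():
        kept = [d for d, k in zip(lags.delays, keep) if k]
        lags = MultiTauLags(lags.levels, lags.channels_per_level, lags.frame_rate, kept)
        g2, if_s, ip_s, weights = g2[:, keep], if_s[:, keep], ip_s[:, keep], weights[keep]

    return CorrAccumulator(
        lags=lags,
        fine_labels=qmap.fine_labels.copy(),
        pixel_q=qmap.q.copy(),
        g2_sums=g2,
        if_sums=if_s,
        ip_sums=ip_s,
        weights=weights,
        n_repeats=1,
    )


def average_accumulators(accs: list[CorrAccumulator]) -> CorrAccumulator:
    """Merge repeated measurements by weight-proportional averaging of
    G2, IF and IP (the sums are averaged first; g2 and its error are
    computed only afterwards)."""
    if not accs:
        raise ValueError("no accumulators to average")
    first = accs[0]
    for acc in accs[1:]:
        if not first.same_structure(acc):
            raise ValueError("accumulators have mismatched lag or partition structure")
    w = np.stack([a.weights for a in accs])          # (n_acc, n_lags)
    w_tot = w.sum(axis=0)
    frac = w / w_tot                                  # (n_acc, n_lags)
    g2 = sum(a.g2_sums * f for a, f in zip(accs, frac))
    if_s = sum(a.if_sums * f for a, f in zip(accs, frac))
    ip_s = sum(a.ip_sums * f for a, f in zip(accs, frac))
    return CorrAccumulator(
        lags=first.lags,
        fine_labels=first.fine_labels.copy(),
        pixel_q=first.pixel_q.copy(),
        g2_sums=g2,
        if_sums=if_s,
        ip_sums=ip_s,
        weights=w_tot,
        n_repeats=sum(a.n_repeats for a in accs),
    )


def flag_bad_pixels(
    acc: CorrAccumulator,
    n_plateau_lags: int = 5,
    n_sigma: float = 5.0,
    min_pixels: int = 10,
) -> np.ndarray:
    """Flag pixels with an abnormally high correlation plateau.

    Per pixel the plateau statistic is the median over the
    ``n_plateau_lags`` smallest lags of G2/(IF*IP).  Within each fine
    partition a pixel is flagged when its statistic exceeds
    median + n_sigma * 1.4826 * MAD.  Partitions with fewer than
    ``min_pixels`` members are skipped with a warning.  The flags are
    stored on the accumulator and returned.
    """
    n_take = min(n_plateau_lags, acc.lags.n_lags)
    order = np.argsort(acc.lags.lag_frames)[:n_take]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = acc.g2_sums[:, order] / (acc.if_sums[:, order] * acc.ip_sums[:, order])
    s = np.nanmedian(np.where(np.isfinite(ratio), ratio, np.nan), axis=1)

    flags = np.zeros(acc.n_pixels, dtype=bool)
    labels = acc.fine_labels
    skipped = 0
    for lab in np.unique(labels[labels >= 0]):
        members = np.flatnonzero(labels == lab)
        stats = s[members]
        ok = np.isfinite(stats)
        if ok.sum() < min_pixels:
            skipped += 1
            continue
        med = np.median(stats[ok])
        mad = np.median(np.abs(stats[ok] - med))
        # epsilon keeps identical-pixel partitions (MAD = 0) unflagged
        thresh = med + n_sigma * 1.4826 * mad + 1e-12 * max(1.0, abs(med))
        flags[members[ok]] = stats[ok] > thresh
    if skipped:
        warnings.warn(
            f"bad-pixel flagging skipped in {skipped} partitions with < "
            f"{min_pixels} pixels", stacklevel=2,
        )
    acc.flags = flags
    return flags


@dataclass
class G2Result:
    """Normalized g2(tau, Q) per coarse partition with errors.

    ``g2`` has shape (n_coarse, n_lags); ``sigma_g2`` is the population
    standard deviation of the per-pixel g2 within each coarse partition
    (a deliberately conservative error; divide by sqrt(n_pixels) for a
    standard error of the mean).  Per-fine-partition g2 is retained for
    diagnostics.
    """

    q: np.ndarray
    delays: np.ndarray
    g2: np.ndarray
    sigma_g2: np.ndarray
    n_pixels: np.ndarray
    q_fine: np.ndarray
    g2_fine: np.ndarray
    beta_used: float | None = None
    frame_rate: float = field(default=0.0)

    @property
    def n_q(self) -> int:
        return self.q.size


def normalize(acc: CorrAccumulator, qmap) -> G2Result:
    """Turn accumulator sums into g2(tau, Q) with binned normalization.

    Within each fine partition g2_fine = <G2>_pixels / (<IF>_px <IP>_px);
    coarse g2 is the pixel-count-weighted mean of its member fine g2
    values; sigma is the population std of per-pixel g2 over the coarse
    partition.  Cells whose window means vanish are reported as NaN
    (missing), never as infinities.  Pixels flagged bad are excluded.
    """
    usable = (acc.fine_labels >= 0) & qmap.mask
    if acc.flags is not None:
        usable &= ~acc.flags

    fine = acc.fine_labels
    n_fine = int(fine[usable].max()) + 1 if usable.any() else 0
    n_lags = acc.lags.n_lags

    fine_of_pixel = np.where(usable, fine, -1)
    counts = np.bincount(fine_of_pixel[fine_of_pixel >= 0], minlength=n_fine).astype(float)

    def part_mean(arr: np.ndarray) -> np.ndarray:
        out = np.zeros((n_fine, n_lags))
        sel = fine_of_pixel >= 0
        for j in range(n_lags):
            out[:, j] = np.bincount(
                fine_of_pixel[sel], weights=arr[sel, j], minlength=n_fine
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            return out / counts[:, None]

    g2_mean = part_mean(acc.g2_sums)
    if_mean = part_mean(acc.if_sums)
    ip_mean = part_mean(acc.ip_sums)
    denom = if_mean * ip_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        g2_fine = np.where(denom > 0, g2_mean / denom, np.nan)

    # map fine partitions to coarse partitions via any member pixel
    coarse_of_fine = np.full(n_fine, -1, dtype=np.int64)
    sel = fine_of_pixel >= 0
    coarse_of_fine[fine_of_pixel[sel]] = qmap.coarse_labels[sel]
    present = np.flatnonzero(counts > 0)
    coarse_ids = np.unique(coarse_of_fine[present])
    n_coarse = coarse_ids.size

    g2_coarse = np.full((n_coarse, n_lags), np.nan)
    sigma = np.full((n_coarse, n_lags), np.nan)
    q_coarse = np.zeros(n_coarse)
    npix_coarse = np.zeros(n_coarse, dtype=np.int64)

    # per-pixel g2 for the error estimate
    with np.errstate(invalid="ignore", divide="ignore"):
        g2_pix = acc.g2_sums / (acc.if_sums * acc.ip_sums)

    for i, cid in enumerate(coarse_ids):
        fines = present[coarse_of_fine[present] == cid]
        w = counts[fines]
        vals = g2_fine[fines]                     # (n_member_fine, n_lags)
        ok = np.isfinite(vals)
        w_eff = np.where(ok, w[:, None], 0.0)
        w_sum = w_eff.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            g2_coarse[i] = np.where(
                w_sum > 0, np.nansum(vals * w_eff, axis=0) / w_sum, np.nan
            )
        members = np.flatnonzero((qmap.coarse_labels == cid) & usable)
        npix_coarse[i] = members.size
        q_coarse[i] = acc.pixel_q[members].mean() if members.size else np.nan
        pix_vals = g2_pix[members]
        finite = np.isfinite(pix_vals)
        n_fin = finite.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_pix = np.where(n_fin > 0,
                                np.nansum(np.where(finite, pix_vals, 0), axis=0)
                                / np.maximum(n_fin, 1), np.nan)
            var_pix = np.where(
                n_fin > 0,
                np.nansum(np.where(finite, (pix_vals - mean_pix) ** 2, 0), axis=0)
                / np.maximum(n_fin, 1),
                np.nan,
            )
        sigma[i] = np.sqrt(var_pix)

    order = np.argsort(q_coarse)
    return G2Result(
        q=q_coarse[order],
        delays=acc.lags.lag_seconds,
        g2=g2_coarse[order],
        sigma_g2=sigma[order],
        n_pixels=npix_coarse[order],
        q_fine=np.array([
            acc.pixel_q[(fine_of_pixel == f)].mean() if (fine_of_pixel == f).any()
            else np.nan
            for f in range(n_fine)
        ]),
        g2_fine=g2_fine,
        frame_rate=acc.lags.frame_rate,
    )
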
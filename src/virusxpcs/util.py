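"""Small worked-number helpers shared by the CLI and reports."""

from __future__ import annotations

__all__ = ["sequence_duration", "smallest_lag", "dilution_concentration"]


def sequence_duration(n_frames: int, frame_rate: float) -> float:
    """Duration in seconds of a continuous frame sequence
    (e.g. 100 000 frames at 52 kHz -> 1.92 s)."""
    if n_frames < 1 or frame_rate <= 0:
        raise ValueError("need n_frames >= 1 and frame_rate > 0")
    return n_frames / frame_rate


def smallest_lag(frame_rate: float) -> float:
    """Smallest correlator delay in seconds: one frame period."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return 1.0 / frame_rate


def dilution_concentration(
    stock: float, parts_stock: float, parts_diluent: float
) -> float:
    """Concentration after mixing stock with diluent, e.g. a 7:1 mix of
    10.96 mg/ml stock with water -> 9.59 mg/ml."""
    if stock < 0 or parts_stock <= 0 or parts_diluent < 0:
        raise ValueError("invalid mixing ratio")
    return stock * parts_stock / (parts_stock + parts_diluent)
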
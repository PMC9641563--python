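import numpy as np
import pytest

from virusxpcs.simulate import PhotonEvents


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dense(rng):
    """Random integer 4-pixel x 16-frame count array."""
    return rng.integers(0, 5, size=(4, 16)).astype(float)


def events_from_dense(dense, frame_rate=52_000.0, q_per_pixel=None):
    return PhotonEvents.from_dense(np.asarray(dense), frame_rate, q_per_pixel)


def split_events_in_halves(events):
    """Two PhotonEvents covering the first and second halves of the
    frame sequence (frame indices re-zeroed in the second half)."""
    half = events.n_frames // 2
    first = events.frame_index < half
    parts = []
    for sel, offset in [(first, 0), (~first, half)]:
        parts.append(
            PhotonEvents(
                frame_index=events.frame_index[sel] - offset,
                pixel_index=events.pixel_index[sel],
                count=events.count[sel],
                n_frames=half,
                n_pixels=events.n_pixels,
                frame_rate=events.frame_rate,
                q_per_pixel=events.q_per_pixel,
            )
        )
    return parts
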
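import numpy as np
import pytest

from cracquant import SegmentationParams, TirfSimParams


@pytest.fixture
def seg_defaults() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture
def small_clean_spot_params() -> TirfSimParams:
    """One noise-free spot of amplitude 100 on a zero background.

    The seed places the spot >= 10 px from every border so a +/-5 sigma
    window around it lies fully inside the image.
    """
    return TirfSimParams(
        image_height_px=64,
        image_width_px=64,
        n_spots=1,
        spot_sigma_px=2.0,
        yfp_amplitude_range=(100.0, 100.0),
        true_ratio=0.5,
        background_base=0.0,
        background_gradient=(0.0, 0.0),
        photon_gain=0.0,
        read_noise_sd=0.0,
        seed=6,
    )


def brute_force_otsu(values: np.ndarray, n_bins: int = 256):
    """Independent exhaustive maximizer of the between-class variance.

    Values are snapped to their histogram bin centers (the discretization
    the thresholding operates on); then every candidate bin-edge cut point
    is tried, computing class weights and means directly from the snapped
    values (no cumulative-sum shortcuts) and taking the first (lowest)
    maximizer. Returns None when no cut separates two classes.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    v = np.asarray(values, dtype=float).ravel()
    idx = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    v = 0.5 * (edges[idx] + edges[idx + 1])
    best_t, best_s = None, 0.0
    for t in edges[1:-1]:
        lo = v[v <= t]
        hi = v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / v.size
        w1 = hi.size / v.size
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-15:
            best_s = s
            best_t = t
    return best_t
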
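"""Synthetic TIRF puncta images and Fura-2 SOCE traces with known ground truth.

The generator emulates the two experimental readouts the pipeline quantifies:

* dual-channel (CFP/YFP) TIRF fields of store-depleted cells, modelled as
  isotropic 2-D Gaussian spots on a smoothly varying background with
  Poisson shot noise and additive Gaussian read noise, and
* single-cell Fura-2 340/380 ratio traces following the standard SOCE
  protocol: baseline, thapsigargin-evoked store release in Ca2+-free
  buffer, then a sigmoidal influx rise after Ca2+ re-addition.

Every generator is bit-reproducible given its parameters and seed, and
returns the ground truth (spot table or kinetic parameters) needed for
parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EventOrderError, SpotPlacementError
from .types import CFP, YFP, FieldOfView, FuraTrace, Image2D

__all__ = [
    "TirfSimParams",
    "TraceSimParams",
    "GroundTruth",
    "simulate_tirf_fov",
    "simulate_group_fixtures",
    "simulate_fura_trace",
    "simulate_cell_field",
]


@dataclass(frozen=True)
class TirfSimParams:
    """Parameters of one simulated dual-channel TIRF field of view.

    Defaults describe a bright, EM-CCD-like acquisition: spot peak
    amplitudes of 600-800 a.u. over a background of 2400 a.u. that doubles
    linearly across the field (uneven TIRF illumination), shot noise at a
    quarter-ADU-per-photon gain plus 15 a.u. read noise. The weakest spot
    then sits ~16 noise-sd above the brightest background.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_spots: int = 50
    spot_sigma_px: float = 2.0
    yfp_amplitude_range: tuple[float, float] = (600.0, 800.0)
    true_ratio: float = 1.0
    background_base: float = 2400.0
    background_gradient: tuple[float, float] = (0.0, 2400.0 / 511.0)
    background_blob: Optional[tuple[tuple[float, float], float, float]] = None
    min_separation_px: float = 12.0
    photon_gain: float = 0.25
    read_noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ValueError("image dimensions must be >= 1 px")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.spot_sigma_px <= 0:
            raise ValueError("spot_sigma_px must be > 0")
        lo, hi = self.yfp_amplitude_range
        if lo > hi or lo < 0:
            raise ValueError("yfp_amplitude_range must satisfy 0 <= low <= high")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be >= 0")
        if self.photon_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.true_ratio < 0:
            raise ValueError("true_ratio must be >= 0")


@dataclass(frozen=True)
class TraceSimParams:
    """Parameters of one simulated Fura-2 SOCE trace.

    Timing defaults follow the standard imaging protocol: one ratio sample
    every 2 s, thapsigargin at 60 s in Ca2+-free buffer, Ca2+ re-addition
    at 360 s. ``delta_r`` and ``logistic_k`` set the influx sigmoid whose
    analytic maximal slope is ``delta_r * logistic_k / 4``.
    """

    r0: float = 0.4
    release_amp: float = 0.5
    release_tau_rise: float = 8.0
    release_tau_decay: float = 40.0
    delta_r: float = 1.2
    logistic_k: float = 0.2
    t_tg: float = 60.0
    t_ca: float = 360.0
    t_end: float = 600.0
    dt: float = 2.0
    noise_sd: float = 0.02
    f380_baseline: float = 1000.0
    sigmoid_onset_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_tg < self.t_ca < self.t_end):
            raise EventOrderError(
                f"event times must satisfy 0 < t_tg < t_ca < t_end, got "
                f"t_tg={self.t_tg}, t_ca={self.t_ca}, t_end={self.t_end}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.release_tau_rise <= 0 or self.release_tau_decay <= 0:
            raise ValueError("time constants must be > 0")
        if self.logistic_k <= 0:
            raise ValueError("logistic_k must be > 0")
        if not (0 < self.sigmoid_onset_fraction < 0.5):
            raise ValueError("sigmoid_onset_fraction must be in (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Simulator-side truth for parameter-recovery tests.

    ``spots`` holds one row per simulated spot (spot_id, center_row,
    center_col, yfp_amplitude, cfp_amplitude, sigma_px). For traces,
    ``analytic_max_rate`` is the exact maximal slope of the influx sigmoid,
    ``delta_r * logistic_k / 4``.
    """

    spots: Optional[pd.DataFrame] = None
    tirf_params: Optional[TirfSimParams] = None
    trace_params: Optional[TraceSimParams] = None
    analytic_max_rate: Optional[float] = None


def _background_field(params: TirfSimParams) -> np.ndarray:
    h, w = params.image_height_px, params.image_width_px
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    gy, gx = params.background_gradient
    bg = params.background_base + gy * rows + gx * cols
    if params.background_blob is not None:
        (cr, cc), sigma, amp = params.background_blob
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        bg = bg + amp * np.exp(-d2 / (2.0 * sigma**2))
    return np.broadcast_to(bg, (h, w)).copy()


def _place_spots(params: TirfSimParams, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement of integer spot centers with min separation."""
    h, w = params.image_height_px, params.image_width_px
    centers: list[tuple[int, int]] = []
    max_attempts = 20000 + 2000 * params.n_spots
    attempts = 0
    min_sep2 = params.min_separation_px**2
    while len(centers) < params.n_spots:
        if attempts >= max_attempts:
            raise SpotPlacementError(
                f"could not place {params.n_spots} spots with "
                f"min_separation_px={params.min_separation_px} in a "
                f"{h}x{w} image after {max_attempts} attempts"
            )
        attempts += 1
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep2 for r0, c0 in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=int).reshape(params.n_spots, 2)


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of isotropic Gaussians evaluated at pixel centers.

    Each spot is rendered on a +/-6 sigma window, beyond which the profile
    is below 2e-8 of the peak.
    """
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(6.0 * sigma))
    h, w = shape
    for (r, c), amp in zip(centers, amplitudes):
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        rr = np.arange(r0, r1, dtype=float)[:, None]
        cc = np.arange(c0, c1, dtype=float)[None, :]
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        img[r0:r1, c0:c1] += amp * np.exp(-d2 / (2.0 * sigma**2))
    return img


def _apply_noise(signal: np.ndarray, params: TirfSimParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise (via gain) followed by Gaussian read noise.

    With gain g > 0 the pixel value v is replaced by g * Poisson(v / g),
    which has mean v and variance g*v, approximating an EM-CCD photon
    budget; read noise is additive Gaussian. Values are clipped at zero so
    intensities stay physical.
    """
    out = signal
    if params.photon_gain > 0:
        out = params.photon_gain * rng.poisson(out / params.photon_gain).astype(float)
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_tirf_fov(
    params: TirfSimParams,
    cell_id: str = "cell_0",
    condition: str = "control",
) -> tuple[FieldOfView, GroundTruth]:
    """Simulate one pixel-registered CFP/YFP image pair with ground truth.

    The noiseless YFP signal is ``background + sum_i A_i G_sigma(r - r_i)``;
    the CFP signal uses per-spot amplitude ``true_ratio * A_i`` over the
    same background field. Noise is applied to each channel independently.
    """
    rng = np.random.default_rng(params.seed)
    centers = _place_spots(params, rng)
    lo, hi = params.yfp_amplitude_range
    yfp_amp = rng.uniform(lo, hi, size=params.n_spots)
    cfp_amp = params.true_ratio * yfp_amp

    shape = (params.image_height_px, params.image_width_px)
    bg = _background_field(params)
    yfp = bg + _render_spots(shape, centers, yfp_amp, params.spot_sigma_px)
    cfp = bg + _render_spots(shape, centers, cfp_amp, params.spot_sigma_px)
    yfp = _apply_noise(yfp, params, rng)
    cfp = _apply_noise(cfp, params, rng)

    fov = FieldOfView(
        cell_id=cell_id,
        condition=condition,
        images={
            YFP: Image2D(yfp, bit_depth=16, channel=YFP),
            CFP: Image2D(cfp, bit_depth=16, channel=CFP),
        },
    )
    spots = pd.DataFrame(
        {
            "spot_id": np.arange(params.n_spots),
            "center_row": centers[:, 0] if params.n_spots else np.array([], dtype=int),
            "center_col": centers[:, 1] if params.n_spots else np.array([], dtype=int),
            "yfp_amplitude": yfp_amp,
            "cfp_amplitude": cfp_amp,
            "sigma_px": np.full(params.n_spots, params.spot_sigma_px),
        }
    )
    return fov, GroundTruth(spots=spots, tirf_params=params)


def perturbed_params(
    control: TirfSimParams,
    area_scale: float = 1.5,
    ratio_scale: float = 0.7,
) -> TirfSimParams:
    """Control parameters transformed into the perturbed-arm parameters.

    Cluster area scales with sigma^2, so the spot width is multiplied by
    sqrt(area_scale). The CFP:YFP amplitude ratio is multiplied by
    ratio_scale with YFP amplitudes scaled by 1/ratio_scale, which keeps
    per-spot CFP amplitudes identical to the control arm (the stoichiometry
    change is carried entirely by the YFP channel).
    """
    if area_scale <= 0 or ratio_scale <= 0:
        raise ValueError("area_scale and ratio_scale must be > 0")
    lo, hi = control.yfp_amplitude_range
    return replace(
        control,
        spot_sigma_px=control.spot_sigma_px * float(np.sqrt(area_scale)),
        true_ratio=control.true_ratio * ratio_scale,
        yfp_amplitude_range=(lo / ratio_scale, hi / ratio_scale),
    )


def _child_seed(master: int, arm: str, index: int) -> int:
    # zlib.crc32 is stable across processes (unlike hash() on str)
    arm_key = zlib.crc32(arm.encode("utf-8")) % 2**16
    ss = np.random.SeedSequence(entropy=master, spawn_key=(arm_key, index))
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_group_fixtures(
    control: TirfSimParams | None = None,
    n_cells: int = 9,
    area_scale: float = 1.5,
    ratio_scale: float = 0.7,
    seed: int = 0,
    condition_labels: tuple[str, str] = ("control", "perturbed"),
) -> dict[str, list[tuple[FieldOfView, GroundTruth]]]:
    """Simulate a two-arm comparison: control vs perturbed fields of view.

    The perturbed arm is identical to the control arm except for larger
    spots (expected cluster area scaled by ``area_scale``) and a lower
    CFP:YFP amplitude ratio (scaled by ``ratio_scale``, CFP amplitudes
    held fixed). Per-field seeds are derived deterministically from the
    master seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if control is None:
        control = TirfSimParams(n_spots=110)
    arm_params = {
        condition_labels[0]: control,
        condition_labels[1]: perturbed_params(control, area_scale, ratio_scale),
    }
    out: dict[str, list[tuple[FieldOfView, GroundTruth]]] = {}
    for arm, params in arm_params.items():
        fields = []
        for i in range(n_cells):
            p = replace(params, seed=_child_seed(seed, arm, i))
            fields.append(simulate_tirf_fov(p, cell_id=f"{arm}_{i}", condition=arm))
        out[arm] = fields
    return out


def noiseless_ratio(params: TraceSimParams, t: np.ndarray) -> np.ndarray:
    """Piecewise noiseless ratio model r(t).

    Baseline r0; after t_tg a biexponential store-release transient
    normalized to peak ``release_amp``; after t_ca a logistic influx rise
    of amplitude ``delta_r`` shifted so its value at t_ca equals
    ``sigmoid_onset_fraction * delta_r`` (default 1%), avoiding a large
    discontinuity at re-addition.
    """
    t = np.asarray(t, dtype=float)
    r = np.full_like(t, params.r0)

    tr, td = params.release_tau_rise, params.release_tau_decay
    u = t - params.t_tg
    release = np.where(u >= 0, np.exp(-np.maximum(u, 0) / td) - np.exp(-np.maximum(u, 0) / tr), 0.0)
    # peak of e^{-u/td} - e^{-u/tr} at u* = ln(td/tr)*tr*td/(td-tr)
    if td != tr:
        u_star = np.log(td / tr) * tr * td / (td - tr)
        peak = np.exp(-u_star / td) - np.exp(-u_star / tr)
    else:
        u_star = tr
        peak = np.exp(-1.0)  # limit of u/tr * e^{-u/tr} at u = tr
    if peak > 0:
        r = r + params.release_amp * release / peak

    k = params.logistic_k
    offset = np.log(1.0 / params.sigmoid_onset_fraction - 1.0) / k
    v = t - params.t_ca
    sigmoid = np.where(v >= 0, params.delta_r / (1.0 + np.exp(-k * (v - offset))), 0.0)
    return r + sigmoid


def simulate_fura_trace(
    params: TraceSimParams,
    cell_id: str = "cell_0",
    condition: str = "control",
) -> tuple[FuraTrace, GroundTruth]:
    """Simulate one Fura-2 SOCE trace with raw channels and ground truth.

    Gaussian noise of sd ``noise_sd`` is added to the noiseless ratio; raw
    channels are synthesized as F380 = f380_baseline (constant) and
    F340 = ratio * F380, the simplest model consistent with a ratiometric
    readout.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.t_end + params.dt / 2.0, params.dt)
    r = noiseless_ratio(params, t)
    if params.noise_sd > 0:
        r = r + rng.normal(0.0, params.noise_sd, size=t.shape)
    f380 = np.full_like(t, params.f380_baseline)
    f340 = r * f380
    trace = FuraTrace(
        cell_id=cell_id,
        condition=condition,
        time_s=t,
        f340=f340,
        f380=f380,
        ratio=r,
        t_tg=params.t_tg,
        t_ca=params.t_ca,
    )
    truth = GroundTruth(
        trace_params=params,
        analytic_max_rate=params.delta_r * params.logistic_k / 4.0,
    )
    return trace, truth


def simulate_cell_field(
    n_cells: int = 5,
    shape: tuple[int, int] = (256, 256),
    radius_px: float = 20.0,
    marker_level: float = 800.0,
    target_level: float = 300.0,
    background: float = 50.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[FieldOfView, pd.DataFrame]:
    """Simulate disk-shaped cell bodies for the total-fluorescence assay.

    Returns a field with a YFP marker channel (cell boundaries) and an A555
    target channel, plus a truth table of per-cell centers and integrated
    target signal above background.
    """
    from .types import A555

    rng = np.random.default_rng(seed)
    h, w = shape
    marker = np.full(shape, 0.0)
    target = np.full(shape, background)
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    centers = []
    margin = int(radius_px) + 2
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 10000:
            raise SpotPlacementError("could not place non-overlapping cells")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= (2.2 * radius_px) ** 2 for r0, c0 in centers):
            centers.append((r, c))
    records = []
    for i, (r, c) in enumerate(centers):
        disk = (rows - r) ** 2 + (cols - c) ** 2 <= radius_px**2
        marker[disk] = marker_level
        target[disk] = background + target_level
        records.append(
            {
                "cell_index": i,
                "center_row": r,
                "center_col": c,
                "area_px": int(disk.sum()),
                "true_total": float(target_level * disk.sum()),
            }
        )
    if noise_sd > 0:
        marker = np.clip(marker + rng.normal(0, noise_sd, shape), 0, None)
        target = np.clip(target + rng.normal(0, noise_sd, shape), 0, None)
    fov = FieldOfView(
        cell_id="cells_0",
        condition="control",
        images={
            YFP: Image2D(marker, channel=YFP),
            A555: Image2D(target, channel=A555),
        },
    )
    return fov, pd.DataFrame(records)


def params_to_dict(params) -> dict:
    """Flatten a frozen parameter dataclass to a plain dict (for run logs)."""
    return dataclasses.asdict(params)
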
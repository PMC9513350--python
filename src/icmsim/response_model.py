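"""Synthetic cortical response layer: threshold-shifted Hill dose-response
and generation of voltage-sensitive-dye (VSD) ΔF/F image streams.

In the animal experiments the normalized peak ΔF/F amplitude versus charge
per phase followed a modified Hill curve with a threshold charge I_th
(~0.9 nC/phase), a half-maximum charge I_50 (~2.4 nC/phase) and a Hill
coefficient N (~2.5). The exact functional form behind those three numbers
was not published; this module adopts the threshold-shifted Hill function

    R(q) = 0                                   for q ≤ I_th
    R(q) = (q−I_th)^N / ((q−I_th)^N + (I_50−I_th)^N)   for q > I_th

because it is the standard sigmoid with exactly those three parameters and
their stated meanings (R(I_th)=0, R(I_50)=1/2, N sets steepness). That
interpretation is a deliberate modelling choice, not a reconstruction.

The synthetic movie generator emulates the imaging geometry (100×100 pixels
over 6.25×6.25 mm at 1000 fps) and the qualitative response phenomenology:
a focal depolarization rising to its peak ~13 ms post-stimulus (observed
range 11–15 ms), spreading spatially over the first few milliseconds,
followed by a shallow hyperpolarizing undershoot near 100 ms; pulses
arriving within ~20 ms of a preceding pulse are attenuated (the recruited
inhibitory circuit), modelled as a single multiplicative gain. It is a
caricature for closed-loop desk testing, not a cortical circuit model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .current_generator import GeneratorSettings, quantize_amplitude

FIELD_MM = 6.25
N_PIXELS = 100
PIXEL_PITCH_MM = FIELD_MM / N_PIXELS
FRAME_DT_MS = 1.0

DEFAULT_I_TH = 0.9   # nC/phase
DEFAULT_I_50 = 2.4   # nC/phase
DEFAULT_N = 2.5


@dataclass(frozen=True)
class HillParams:
    """Dose-response parameters in nC per phase (i_th, i_50) and steepness n."""

    i_th: float = DEFAULT_I_TH
    i_50: float = DEFAULT_I_50
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if not 0 <= self.i_th < self.i_50:
            raise ValueError("require 0 <= i_th < i_50")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")


def hill_response(q_nC: float | np.ndarray, p: HillParams) -> float | np.ndarray:
    """Normalized response amplitude in [0, 1) for charge q per phase."""
    q = np.asarray(q_nC, dtype=float)
    if np.any(q < 0):
        raise ValueError("charge must be >= 0")
    shifted = np.clip(q - p.i_th, 0.0, None)
    half = (p.i_50 - p.i_th) ** p.n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(shifted > 0, shifted ** p.n / (shifted ** p.n + half), 0.0)
    return float(r) if np.isscalar(q_nC) else r


class HillFitError(RuntimeError):
    """Raised when the dose-response data cannot constrain a Hill fit."""


def fit_hill(
    charges_nC: Sequence[float], responses: Sequence[float]
) -> tuple[HillParams, float]:
    """Nonlinear least-squares fit of the threshold-shifted Hill function.

    Deterministic multi-start: a fixed grid of initial (i_th, i_50, n)
    triples derived from the data range is refined with bounded
    least-squares and the lowest-cost solution returned along with the
    residual 2-norm. Needs at least five points spanning both sides of the
    half-maximum; all-equal responses raise :class:`HillFitError`.
    """
    q = np.asarray(charges_nC, dtype=float)
    r = np.asarray(responses, dtype=float)
    if q.shape != r.shape or q.ndim != 1:
        raise ValueError("charges and responses must be equal-length 1-D sequences")
    if q.size < 5:
        raise ValueError("need at least 5 dose-response points")
    if np.ptp(r) < 1e-9:
        raise HillFitError("responses are degenerate (no spread); Hill parameters unidentifiable")

    qmax = float(q.max())

    def resid(x: np.ndarray) -> np.ndarray:
        i_th, delta, n = x
        return hill_response(q, HillParams(i_th, i_th + delta, n)) - r

    starts = [
        (i_th0, delta0, n0)
        for i_th0 in (0.0, 0.25 * qmax, 0.5 * qmax)
        for delta0 in (0.25 * qmax, 0.5 * qmax)
        for n0 in (1.0, 2.5)
    ]
    lo = np.array([0.0, 1e-6, 1e-3])
    hi = np.array([qmax, 10 * qmax, 50.0])
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise HillFitError("all fit starts failed")
    i_th, delta, n = best.x
    return HillParams(float(i_th), float(i_th + delta), float(n)), float(
        np.linalg.norm(best.fun)
    )


def charges_from_amplitudes(
    amps_uA: Sequence[float],
    phase_ms: float,
    settings: GeneratorSettings | None = None,
) -> np.ndarray:
    """Charge per phase (nC) for an amplitude series, via DAC quantization.

    Charge = quantized amplitude × phase duration (μA × ms = nC), linking
    the dose axis to what the current generator actually delivers.
    """
    if settings is None:
        settings = GeneratorSettings()
    return np.array(
        [quantize_amplitude(a, settings)[1] * phase_ms for a in amps_uA]
    )


def synth_dose_response(
    p: HillParams,
    charges_nC: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_rep: int = 1,
) -> pd.DataFrame:
    """Synthetic dose-response table (columns charge_nC, response_norm)."""
    rng = np.random.default_rng(seed)
    q = np.repeat(np.asarray(charges_nC, dtype=float), n_rep)
    r = hill_response(q, p) + rng.normal(0.0, noise_sd, q.size)
    return pd.DataFrame({"charge_nC": q, "response_norm": r})


@dataclass(frozen=True)
class ResponseKinetics:
    """Spatiotemporal shape parameters of the synthetic ΔF/F response.

    Times in ms, lengths in mm. The temporal kernel peaks exactly at
    ``t_peak_ms`` (gamma-shaped rise/decay with exponent
    ``rise_sharpness``) and carries a Gaussian hyperpolarizing undershoot
    centered at ``undershoot_time_ms``. The spatial footprint is a Gaussian
    whose σ grows from ``spatial_sigma_mm`` toward ``sigma_growth`` times
    that value with time constant ``growth_tau_ms``, emulating the lateral
    propagation over the first milliseconds. Pulses within
    ``inhibition_window_ms`` of the preceding pulse are scaled by
    ``inhibition_gain`` (compounding along a train).
    """

    t_peak_ms: float = 13.0
    undershoot_time_ms: float = 100.0
    undershoot_depth: float = 0.15
    undershoot_sigma_ms: float = 30.0
    rise_sharpness: float = 2.0
    spatial_sigma_mm: float = 0.15
    sigma_growth: float = 2.0
    growth_tau_ms: float = 5.0
    inhibition_window_ms: float = 20.0
    inhibition_gain: float = 0.5
    bipolar_gain: float = 1.2

    def __post_init__(self) -> None:
        if not 0 < self.t_peak_ms < self.undershoot_time_ms:
            raise ValueError("require 0 < t_peak_ms < undershoot_time_ms")
        if not 0 <= self.undershoot_depth <= 1 or not 0 <= self.inhibition_gain <= 1:
            raise ValueError("undershoot_depth and inhibition_gain must be in [0, 1]")
        if min(self.spatial_sigma_mm, self.growth_tau_ms, self.undershoot_sigma_ms,
               self.rise_sharpness, self.inhibition_window_ms) <= 0:
            raise ValueError("kinetic parameters must be positive")
        if self.sigma_growth < 1:
            raise ValueError("sigma_growth is a final multiple of spatial_sigma_mm, >= 1")

    def temporal_kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-peak temporal kernel at post-stimulus times t (0 outside t>=0)."""
        t = np.asarray(t_ms, dtype=float)
        a = self.rise_sharpness
        with np.errstate(invalid="ignore"):
            rise = np.where(
                t > 0, (t / self.t_peak_ms) ** a * np.exp(a * (1 - t / self.t_peak_ms)), 0.0
            )
        under = self.undershoot_depth * np.exp(
            -((t - self.undershoot_time_ms) ** 2) / (2 * self.undershoot_sigma_ms ** 2)
        )
        return np.where(t > 0, rise - under, 0.0)

    def sigma_at(self, t_ms: np.ndarray) -> np.ndarray:
        """Spatial Gaussian σ (mm) at post-stimulus time t."""
        t = np.clip(np.asarray(t_ms, dtype=float), 0.0, None)
        return self.spatial_sigma_mm * (
            1 + (self.sigma_growth - 1) * (1 - np.exp(-t / self.growth_tau_ms))
        )


@dataclass(frozen=True)
class StimSource:
    """One stimulus delivery: electrode position, dose and onset."""

    x_mm: float
    y_mm: float
    charge_nC: float
    onset_ms: float = 0.0
    is_bipolar_pair: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.x_mm <= FIELD_MM and 0 <= self.y_mm <= FIELD_MM):
            raise ValueError(f"electrode ({self.x_mm}, {self.y_mm}) outside the {FIELD_MM} mm field")
        if self.charge_nC < 0 or self.onset_ms < 0:
            raise ValueError("charge and onset must be >= 0")


@dataclass(frozen=True)
class VSDMovie:
    """ΔF/F image stream: (T, 100, 100) frames at 1 ms steps.

    Pixel (row, col) is centered at x = (col+0.5)·pitch, y = (row+0.5)·pitch
    with the origin at the field's top-left corner.
    """

    frames: np.ndarray
    dt_ms: float = FRAME_DT_MS
    pixel_pitch_mm: float = PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[1:] != (N_PIXELS, N_PIXELS):
            raise ValueError(f"frames must be (T, {N_PIXELS}, {N_PIXELS}), got {f.shape}")
        if not np.isfinite(f).all():
            raise ValueError("frames must be finite")
        object.__setattr__(self, "frames", f)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("frames", data=self.frames, compression="gzip")
            ds.attrs["dt_ms"] = self.dt_ms
            ds.attrs["pixel_pitch_mm"] = self.pixel_pitch_mm

    @classmethod
    def load(cls, path: str | Path) -> "VSDMovie":
        with h5py.File(path, "r") as h5:
            ds = h5["frames"]
            return cls(ds[()], float(ds.attrs["dt_ms"]), float(ds.attrs["pixel_pitch_mm"]))


def _effective_gains(sources: Sequence[StimSource], k: ResponseKinetics) -> list[float]:
    # Each pulse inherits the most recent prior pulse's gain × inhibition_gain
    # when it falls inside the inhibition window, so a 20 ms train decays as
    # 1, g, g^2, ... Simultaneous (multi-site) pulses do not inhibit each other.
    order = sorted(range(len(sources)), key=lambda i: sources[i].onset_ms)
    gains = [1.0] * len(sources)
    for pos, i in enumerate(order):
        prior = [
            j for j in order[:pos]
            if 0 < sources[i].onset_ms - sources[j].onset_ms <= k.inhibition_window_ms
        ]
        if prior:
            latest = max(prior, key=lambda j: sources[j].onset_ms)
            gains[i] = gains[latest] * k.inhibition_gain
    return gains


def synth_vsd_movie(
    sources: Sequence[StimSource],
    p: HillParams | None = None,
    k: ResponseKinetics | None = None,
    duration_ms: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_trials: int = 1,
) -> VSDMovie:
    """Generate a synthetic ΔF/F movie for a set of stimulus deliveries.

    Each source contributes ``hill_response(charge) × gain`` (sequential
    inhibition and the bipolar factor) times a spreading spatial Gaussian
    times the temporal kernel; contributions sum. ``n_trials`` emulates
    trial averaging: the additive i.i.d. Gaussian pixel noise has standard
    deviation ``noise_sd / sqrt(n_trials)``. Deterministic given ``seed``.
    """
    p = p or HillParams()
    k = k or ResponseKinetics()
    n_frames = int(round(duration_ms / FRAME_DT_MS)) + 1
    times = np.arange(n_frames) * FRAME_DT_MS

    centers = (np.arange(N_PIXELS) + 0.5) * PIXEL_PITCH_MM
    xx, yy = np.meshgrid(centers, centers)  # xx: columns→x, yy: rows→y

    frames = np.zeros((n_frames, N_PIXELS, N_PIXELS))
    gains = _effective_gains(sources, k)
    for src, gain in zip(sources, gains):
        amp = hill_response(src.charge_nC, p) * gain
        if src.is_bipolar_pair:
            amp *= k.bipolar_gain
        if amp == 0.0:
            continue
        tau = times - src.onset_ms
        kern = k.temporal_kernel(tau)
        sigma = k.sigma_at(tau)
        d2 = (xx - src.x_mm) ** 2 + (yy - src.y_mm) ** 2
        live = np.nonzero(kern != 0)[0]
        for idx in live:
            frames[idx] += amp * kern[idx] * np.exp(-d2 / (2 * sigma[idx] ** 2))

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, noise_sd / math.sqrt(n_trials), frames.shape)
    return VSDMovie(frames=frames)


def roi_bbox(x_mm: float, y_mm: float, radius_mm: float) -> tuple[int, int, int, int]:
    """Pixel bounding box (row0, row1, col0, col1) of a square ROI around a point."""
    r0 = max(0, int((y_mm - radius_mm) / PIXEL_PITCH_MM))
    r1 = min(N_PIXELS, int(math.ceil((y_mm + radius_mm) / PIXEL_PITCH_MM)))
    c0 = max(0, int((x_mm - radius_mm) / PIXEL_PITCH_MM))
    c1 = min(N_PIXELS, int(math.ceil((x_mm + radius_mm) / PIXEL_PITCH_MM)))
    return r0, r1, c0, c1


def peak_amplitude(
    movie: VSDMovie,
    roi: tuple[int, int, int, int],
    t_start_ms: float = 0.0,
) -> tuple[float, float]:
    """Positive peak of the ROI-averaged ΔF/F trace and its time (ms).

    ``roi`` is a pixel bounding box (row0, row1, col0, col1); the search
    starts at ``t_start_ms`` (post-stimulus window).
    """
    r0, r1, c0, c1 = roi
    if r0 >= r1 or c0 >= c1:
        raise ValueError("empty ROI")
    trace = movie.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    times = np.arange(trace.size) * movie.dt_ms
    mask = times >= t_start_ms
    k = int(np.argmax(trace[mask]))
    return float(trace[mask][k]), float(times[mask][k])


def line_profile(
    movie: VSDMovie,
    p0_mm: tuple[float, float],
    p1_mm: tuple[float, float],
    t_window_ms: tuple[float, float],
    n_samples: int = 101,
) -> pd.DataFrame:
    """Spatial ΔF/F profile along a line, averaged over a time window.

    Returns a DataFrame with columns ``distance_mm`` (from p0) and
    ``dff`` (bilinear-sampled, time-averaged signal).
    """
    t0, t1 = t_window_ms
    k0 = int(round(t0 / movie.dt_ms))
    k1 = int(round(t1 / movie.dt_ms)) + 1
    if not 0 <= k0 < k1 <= movie.frames.shape[0]:
        raise ValueError("time window outside the movie")
    mean_frame = movie.frames[k0:k1].mean(axis=0)

    frac = np.linspace(0.0, 1.0, n_samples)
    xs = p0_mm[0] + frac * (p1_mm[0] - p0_mm[0])
    ys = p0_mm[1] + frac * (p1_mm[1] - p0_mm[1])
    rows = ys / movie.pixel_pitch_mm - 0.5
    cols = xs / movie.pixel_pitch_mm - 0.5
    vals = map_coordinates(mean_frame, np.vstack([rows, cols]), order=1, mode="nearest")
    dist = frac * math.hypot(p1_mm[0] - p0_mm[0], p1_mm[1] - p0_mm[1])
    return pd.DataFrame({"distance_mm": dist, "dff": vals})
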
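"""Signal conditioning and feature extraction for palpation recordings.

The pipeline mirrors standard lock-in practice for force-controlled dynamic
indentation: remove the slow drift in the strain channel with a centred
moving average restarted at every actuation block (the block-local average
captures the global trend as well), truncate each block to an integer number
of periods, project force and (negated) strain onto
sin/cos at the block's actuation frequency to obtain mean, amplitude and
phase of the fundamental, and form

* the mean ratio           ``MR = k_f * F_mean / |eps_mean|``   (N/mm),
* the amplitude ratio      ``AR = k_f * F_amp / eps_amp``       (N/mm),
* the phase difference     ``PD = phase(force) - phase(-strain)``,
* the time lag             ``dt = PD / (2 pi f)``,

then invert the Hertz contact slope at the measured operating depth to turn
MR and AR into a quasi-static and a dynamic modulus in kPa.  The moving
average attenuates the fundamental by a known Dirichlet factor, which is
compensated exactly, so noise-free recovery is limited only by round-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .mechanics import (
    SECANT_TO_TANGENT,
    ProbeGeometry,
    phase_to_timelag,
    stiffness_to_modulus,
)
from .simulate import RawRecording

_TWO_PI = 2.0 * math.pi
_PHASE_EPS = 0.01   # rad; tolerance for clamping slightly negative lags to zero
log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "patient_id", "point_id", "zone", "label", "pressure", "frequency_hz",
    "mr_n_per_mm", "ar_n_per_mm", "pd_rad", "dt_s",
    "e_static_kpa", "e_dynamic_kpa", "tan_pd",
]


@dataclass(frozen=True)
class BlockEstimate:
    """Lock-in estimates for one actuation block."""

    frequency: float
    mean_force: float
    force_amplitude: float
    mean_strain: float
    strain_amplitude: float
    phase_difference: float   # rad, wrapped to [0, 2 pi)


def moving_average_attenuation(window: int, frequency: float,
                               sampling_rate: float) -> float:
    """Gain of a centred ``window``-sample moving average at ``frequency``.

    The Dirichlet kernel value ``sin(pi f W / fs) / (W sin(pi f / fs))``;
    subtracting the moving average therefore scales a sinusoid at ``f`` by
    ``1 - gain`` without phase shift (odd, symmetric window).
    """
    x = math.pi * frequency / sampling_rate
    return math.sin(window * x) / (window * math.sin(x))


def detrend_strain(strain: np.ndarray, window: int, scope: str = "global",
                   blocks: list[slice] | None = None,
                   min_window: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a centred moving average; return (detrended, trend).

    ``scope="global"`` filters the whole series; ``scope="per_block"``
    filters each slice in ``blocks`` independently (restarting the average at
    block boundaries, as required when the mean level settles anew in every
    actuation block).  ``min_window``, when given, is the number of samples
    in one actuation period: windows shorter than a period would remove the
    fundamental itself and are rejected.  Interior samples (further than
    ``window // 2`` from an edge) carry the exact sliding mean; callers
    should trim half a window from each end.
    """
    strain = np.asarray(strain, dtype=float)
    if window % 2 != 1 or not 1 < window < strain.size:
        raise ValueError(
            f"window must be an odd integer in (1, n={strain.size}), got {window}"
        )
    if min_window is not None and window < min_window:
        raise ValueError(
            f"window of {window} samples is shorter than one actuation period "
            f"({min_window} samples) and would gut the fundamental"
        )
    trend = np.empty_like(strain)
    if scope == "global":
        uniform_filter1d(strain, size=window, mode="nearest", output=trend)
    elif scope == "per_block":
        if not blocks:
            raise ValueError("per_block scope requires block slices")
        for sl in blocks:
            trend[sl] = uniform_filter1d(strain[sl], size=window, mode="nearest")
    else:
        raise ValueError(f"scope must be 'global' or 'per_block', got {scope!r}")
    return strain - trend, trend


def extract_fundamental(series: np.ndarray, frequency: float,
                        sampling_rate: float) -> tuple[float, float, float]:
    """Lock-in estimate of (mean, amplitude, phase) at one frequency.

    Projects the series onto sin/cos at exactly ``frequency`` over the
    largest prefix holding an integer number of periods, which makes the
    estimate identical to the corresponding FFT bin on noise-free data.  For
    ``x = A sin(2 pi f t + phi) + c`` returns ``(c, A, phi)``.  At least
    three whole periods are required, and the frequency must be resolvable
    on the sampling grid (more than two samples per period).
    """
    series = np.asarray(series, dtype=float)
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    if sampling_rate <= 2.0 * frequency:
        raise ValueError(
            f"frequency {frequency} Hz is not resolvable at a sampling rate "
            f"of {sampling_rate} Hz"
        )
    n_periods = int(math.floor(series.size * frequency / sampling_rate))
    if n_periods < 3:
        raise ValueError(
            f"series covers only {n_periods} whole period(s) of {frequency} Hz; "
            "at least 3 are required"
        )
    n = int(round(n_periods * sampling_rate / frequency))
    x = series[:n]
    t = np.arange(n) / sampling_rate
    arg = _TWO_PI * frequency * t
    a = 2.0 / n * float(np.dot(x, np.sin(arg)))
    b = 2.0 / n * float(np.dot(x, np.cos(arg)))
    return float(x.mean()), math.hypot(a, b), math.atan2(b, a)


def compute_mr(mean_force: float, mean_strain: float, k_f: float) -> float:
    """Mean ratio ``k_f * F_mean / |eps_mean|`` -- quasi-static stiffness.

    The strain channel is negative-going in compressive contact, so its
    magnitude is used and a positive stiffness is returned.
    """
    if k_f <= 0:
        raise ValueError(f"k_f must be positive, got {k_f}")
    if mean_strain == 0:
        raise ValueError("mean strain is zero: probe not in contact")
    return k_f * mean_force / abs(mean_strain)


def compute_ar(force_amplitude: float, strain_amplitude: float, k_f: float) -> float:
    """Amplitude ratio ``k_f * F_amp / eps_amp`` -- dynamic stiffness magnitude."""
    if k_f <= 0:
        raise ValueError(f"k_f must be positive, got {k_f}")
    if strain_amplitude == 0:
        raise ValueError("strain oscillation amplitude is zero: no dynamic response")
    return k_f * force_amplitude / strain_amplitude


def analyze_block(force: np.ndarray, strain: np.ndarray, frequency: float,
                  sampling_rate: float, detrend_periods: int = 3,
                  discard_periods: int = 1) -> BlockEstimate:
    """Condition one actuation block and estimate its fundamental components.

    The first ``discard_periods`` periods are dropped (application
    transient), the strain is detrended with a ``detrend_periods``-period
    centred moving average whose edge samples are trimmed, and both channels
    are truncated to whole periods before lock-in.  The strain amplitude is
    corrected for the known moving-average attenuation.  The mean strain is
    taken from the raw (not detrended) channel, since the trend *is* the
    mean level.
    """
    n_per = sampling_rate / frequency
    start = int(round(discard_periods * n_per))
    window = int(round(detrend_periods * n_per))
    if window % 2 == 0:
        window += 1
    f_seg = np.asarray(force, dtype=float)[start:]
    s_seg = np.asarray(strain, dtype=float)[start:]
    detrended, _ = detrend_strain(s_seg, window,
                                  min_window=int(math.ceil(n_per)))
    half = window // 2
    f_seg = f_seg[half:len(f_seg) - half]
    s_raw = s_seg[half:len(s_seg) - half]
    s_det = detrended[half:len(detrended) - half]

    _, f_amp, f_phase = extract_fundamental(f_seg, frequency, sampling_rate)
    _, s_amp, s_phase = extract_fundamental(-s_det, frequency, sampling_rate)
    gain = 1.0 - moving_average_attenuation(window, frequency, sampling_rate)
    s_amp /= gain

    n_periods = int(math.floor(s_raw.size * frequency / sampling_rate))
    n = int(round(n_periods * sampling_rate / frequency))
    mean_force = float(f_seg[:n].mean())
    mean_strain = float(s_raw[:n].mean())
    pd_rad = (f_phase - s_phase) % _TWO_PI
    # a lag estimate just below zero (wrapping to just below 2 pi) is a
    # near-zero lag perturbed by noise, not an unphysical advance
    if pd_rad > _TWO_PI - _PHASE_EPS:
        pd_rad = 0.0
    return BlockEstimate(frequency=frequency, mean_force=mean_force,
                         force_amplitude=f_amp, mean_strain=mean_strain,
                         strain_amplitude=s_amp, phase_difference=pd_rad)


def extract_features(recording: RawRecording, geom: ProbeGeometry,
                     detrend_periods: int = 3, discard_periods: int = 1
                     ) -> pd.DataFrame:
    """Full conditioning + feature pipeline for one recording.

    Each actuation block is conditioned with a centred moving average whose
    window (a few periods of the block frequency) restarts at every block
    boundary, which removes both the slow global trend and the per-block
    settle transient before lock-in.  The stiffness ratios are then converted
    to moduli by inverting the Hertz tangent slope at the operating depth
    measured from the mean strain (the secant-to-tangent factor 3/2 maps MR
    onto the tangent slope first).

    Blocks violating a precondition (too few periods, loss of contact, phase
    at or beyond the passive quarter-period bound) are excluded with a logged
    reason; the reasons are kept in ``result.attrs["excluded"]``.
    """
    meta = recording.meta
    protocol = meta.protocol
    fs = protocol.sampling_rate_hz
    blocks = protocol.block_slices()

    rows: list[dict] = []
    excluded: list[str] = []
    for f, sl in blocks:
        tag = f"{meta.point_id or 'point'}/{meta.pressure}/{f:g}Hz"
        try:
            est = analyze_block(recording.force[sl], recording.strain[sl], f, fs,
                                detrend_periods=detrend_periods,
                                discard_periods=discard_periods)
            if est.mean_strain >= 0:
                raise ValueError("non-negative mean strain: probe not in contact")
            if est.phase_difference > math.pi:
                raise ValueError(
                    f"phase difference {est.phase_difference:.3f} rad exceeds pi; "
                    "not interpretable as a passive lag"
                )
            depth_mm = abs(est.mean_strain) / geom.k_f
            mr = compute_mr(est.mean_force, est.mean_strain, geom.k_f)
            ar = compute_ar(est.force_amplitude, est.strain_amplitude, geom.k_f)
            e_static = stiffness_to_modulus(SECANT_TO_TANGENT * mr, geom, depth_mm)
            e_dynamic = stiffness_to_modulus(ar, geom, depth_mm)
            dt = phase_to_timelag(est.phase_difference, f)
        except ValueError as err:
            log.warning("excluding block %s: %s", tag, err)
            excluded.append(f"{tag}: {err}")
            continue
        rows.append({
            "patient_id": meta.patient_id, "point_id": meta.point_id,
            "zone": meta.zone, "label": meta.label, "pressure": meta.pressure,
            "frequency_hz": f, "mr_n_per_mm": mr, "ar_n_per_mm": ar,
            "pd_rad": est.phase_difference, "dt_s": dt,
            "e_static_kpa": e_static, "e_dynamic_kpa": e_dynamic,
            "tan_pd": math.tan(est.phase_difference),
        })
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["excluded"] = excluded
    return df


def extract_cohort_features(recordings, geom: ProbeGeometry,
                            detrend_periods: int = 3, discard_periods: int = 1
                            ) -> pd.DataFrame:
    """Feature table for a set of recordings, one row per (point, pressure, f)."""
    frames = []
    excluded: list[str] = []
    for rec in recordings:
        df = extract_features(rec, geom, detrend_periods=detrend_periods,
                              discard_periods=discard_periods)
        excluded.extend(df.attrs["excluded"])
        if not df.empty:
            frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=FEATURE_COLUMNS)
    out.attrs["excluded"] = excluded
    return out
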
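"""Synthetic palpation cohorts: labelled probe points and raw recordings.

The simulator emulates an instrumented digital rectal examination study:
a small cohort of patients, each probed at 12--16 points over a 3 x 4
(base/mid/apex x left-to-right) grid on the palpable posterior surface of the
prostate, at two clinician-applied contact-pressure levels (light and firm),
with a force-controlled sinusoidal actuation protocol recorded at 1000 Hz for
about 20 s per point.  Each point carries a histology-style binary label:
C (cancer somewhere in the tissue column under the indenter) or NC.

Ground-truth tissue parameters are drawn from class-conditional lognormal
distributions whose medians and interquartile ranges are set by a
*calibration profile*.  The default ``"in_vivo"`` profile reproduces the
class-conditional medians/IQRs of in vivo prostate measurements:
quasi-static modulus about 26.8 kPa (C) vs 24.8 kPa (NC) at firm pressure,
effective dynamic modulus at 5 Hz about 5.15 kPa (C) vs 4.61 kPa (NC), and
force-to-displacement time lags at 5 Hz about 0.0175 s (C) vs 0.0186 s (NC).

The apparent dynamic modulus of such hand-held measurements is far *below*
the Kelvin--Voigt magnitude implied by the static modulus and phase lag,
because the operator's hand partially accommodates the imposed vibration.
The profile therefore carries a separate class-conditional distribution for
the *effective* dynamic modulus; the ratio of effective to constitutive
dynamic modulus is the per-point operator-accommodation factor.

With ``spread_matching`` enabled (the default) tissue parameters are assigned
by rank-stratified quantiles of the target distribution rather than i.i.d.
draws, so the cohort's empirical class medians and IQRs match the calibration
targets for every seed; the random state only permutes which point receives
which quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import ndtri

from .mechanics import (
    ProbeGeometry,
    ViscoParams,
    complex_modulus,
    hertz_tangent_stiffness,
    indentation_depth,
)

_TWO_PI = 2.0 * math.pi
_Z75 = ndtri(0.75)  # 0.6745, the 75th-percentile standard-normal quantile

ZONE_ROWS = ("base", "mid", "apex")
ZONE_COLS = (1, 2, 3, 4)
ZONES = tuple(f"{row}{col}" for row in ZONE_ROWS for col in ZONE_COLS)

PRESSURES = ("firm", "light")


# ---------------------------------------------------------------------------
# Calibration profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassStats:
    """Median and interquartile range of a positive-valued quantity."""

    median: float
    iqr: float

    def sigma(self) -> float:
        """Log-scale spread of the lognormal with this median and IQR."""
        return math.asinh(self.iqr / (2.0 * self.median)) / _Z75

    def quantile(self, u: float | np.ndarray) -> float | np.ndarray:
        """Inverse CDF of the matching lognormal at probability ``u``."""
        return self.median * np.exp(self.sigma() * ndtri(u))


@dataclass(frozen=True)
class CalibrationProfile:
    """Class-conditional generative targets for a synthetic cohort.

    ``static`` maps label -> stats of the firm-pressure quasi-static modulus
    (kPa); ``dynamic`` maps pressure -> label -> stats of the effective
    dynamic modulus (kPa) at the reference frequency; ``lag`` maps actuation
    frequency (Hz) -> pressure -> label -> stats of the time lag (s).
    """

    static: Mapping[str, ClassStats]
    dynamic: Mapping[str, Mapping[str, ClassStats]]
    lag: Mapping[float, Mapping[str, Mapping[str, ClassStats]]]


#: Default profile calibrated to in vivo prostate medians/IQRs.  Static
#: moduli are the firm-pressure pooled class values; dynamic moduli and time
#: lags are the 5 Hz class values per pressure level, with 1 Hz lag targets
#: taken from the corresponding low-frequency class values.
IN_VIVO_PROFILE = CalibrationProfile(
    static={"C": ClassStats(26.8, 13.3), "NC": ClassStats(24.8, 11.9)},
    dynamic={
        "firm": {"C": ClassStats(5.15, 4.86), "NC": ClassStats(4.61, 3.08)},
        "light": {"C": ClassStats(3.12, 3.97), "NC": ClassStats(2.81, 3.42)},
    },
    lag={
        5.0: {
            "firm": {"C": ClassStats(0.0175, 0.0078), "NC": ClassStats(0.0186, 0.0397)},
            "light": {"C": ClassStats(0.0178, 0.0048), "NC": ClassStats(0.0173, 0.0062)},
        },
        1.0: {
            "firm": {"C": ClassStats(0.0281, 0.0500), "NC": ClassStats(0.0422, 0.4549)},
            "light": {"C": ClassStats(0.0204, 0.0261), "NC": ClassStats(0.0261, 0.2514)},
        },
    },
)

PROFILES: dict[str, CalibrationProfile] = {"in_vivo": IN_VIVO_PROFILE}


# ---------------------------------------------------------------------------
# Cohort configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActuationProtocol:
    """Force-controlled actuation schedule for one probe point.

    A protocol is an ordered list of actuation frequencies, each held for
    ``block_duration_s`` seconds while force oscillates sinusoidally about
    the pressure-level mean.  The default amplitude is a fixed fraction of
    the mean force; ``force_amplitude_n`` overrides it absolutely.
    """

    frequencies: tuple[float, ...] = (5.0,)
    block_duration_s: float = 20.0
    sampling_rate_hz: float = 1000.0
    mean_force_light_n: float = 0.5
    mean_force_firm_n: float = 1.5
    force_amplitude_n: float | None = None
    force_amplitude_frac: float = 0.08

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError("frequencies must be a non-empty sequence")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError(f"frequencies must all be positive, got {self.frequencies}")
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be positive")
        if self.sampling_rate_hz < 20.0 * max(self.frequencies):
            raise ValueError(
                "sampling_rate_hz must be at least 20x the highest actuation "
                f"frequency ({max(self.frequencies)} Hz) to protect phase "
                "estimation"
            )

    def mean_force(self, pressure: str) -> float:
        if pressure == "light":
            return self.mean_force_light_n
        if pressure == "firm":
            return self.mean_force_firm_n
        raise ValueError(f"pressure must be 'light' or 'firm', got {pressure!r}")

    def force_amplitude(self, pressure: str) -> float:
        if self.force_amplitude_n is not None:
            return self.force_amplitude_n
        return self.force_amplitude_frac * self.mean_force(pressure)

    @property
    def n_samples_per_block(self) -> int:
        return int(round(self.block_duration_s * self.sampling_rate_hz))

    def block_slices(self) -> list[tuple[float, slice]]:
        """(frequency, sample slice) for each actuation block."""
        nb = self.n_samples_per_block
        return [(f, slice(i * nb, (i + 1) * nb)) for i, f in enumerate(self.frequencies)]


@dataclass
class CohortConfig:
    """Generative settings for a synthetic palpation cohort.

    The defaults emulate the reference in vivo study: 12 patients, the first
    4 measured at 1 Hz and the remaining 8 at 5 Hz, 12--16 points each with
    a 60% per-zone cancer probability (about 165 points, roughly 99 C/66 NC),
    light/firm mean contact forces of 0.5/1.5 N, 20 s recordings at 1000 Hz,
    and mild drift plus measurement noise.
    """

    n_patients: int = 12
    n_low_freq_patients: int = 4
    low_frequency_hz: float = 1.0
    high_frequency_hz: float = 5.0
    points_per_patient: tuple[int, int] = (12, 16)
    p_cancer: float = 0.6
    profile: str = "in_vivo"
    # contact pressure encoding: light/firm mean-force setpoints plus a mild
    # strain-hardening slope so firm contact reads a higher apparent modulus
    mean_force_light_n: float = 0.5
    mean_force_firm_n: float = 1.5
    force_amplitude_frac: float = 0.08
    hardening_per_newton: float = 0.0541
    # operator accommodation: when enabled, the strain oscillation follows the
    # profile's effective dynamic modulus instead of the constitutive |E*|
    accommodation: bool = True
    spread_matching: bool = True
    lag_cap_frac: float = 0.95     # cap time lags below this fraction of 1/(4f)
    # acquisition
    sampling_rate_hz: float = 1000.0
    duration_s: float = 20.0
    # noise (SNR in dB relative to the oscillation amplitude; None = off)
    snr_force_db: float | None = 40.0
    snr_strain_db: float | None = 30.0
    # strain drift: per-block exponential settle + slow global linear trend
    settle_frac: float = 0.1
    settle_tau_s: float = 0.3
    global_drift_frac_per_s: float = 5e-4
    seed: int = 0

    def resolve_profile(self) -> CalibrationProfile:
        try:
            return PROFILES[self.profile]
        except KeyError:
            raise ValueError(
                f"unknown calibration profile {self.profile!r}; "
                f"known: {sorted(PROFILES)}"
            ) from None

    def protocol(self, frequency: float) -> ActuationProtocol:
        return ActuationProtocol(
            frequencies=(frequency,),
            block_duration_s=self.duration_s,
            sampling_rate_hz=self.sampling_rate_hz,
            mean_force_light_n=self.mean_force_light_n,
            mean_force_firm_n=self.mean_force_firm_n,
            force_amplitude_frac=self.force_amplitude_frac,
        )


@dataclass(frozen=True)
class PointTruth:
    """Ground-truth measurement parameters at one (point, pressure)."""

    e_static: float   # apparent quasi-static modulus, kPa
    dt: float         # time lag at the point's actuation frequency, s
    e_dyn: float      # effective dynamic modulus at that frequency, kPa
    eta: float        # Kelvin-Voigt viscosity consistent with (e_static, dt), kPa*s

    @property
    def visco(self) -> ViscoParams:
        return ViscoParams(e_static=self.e_static, eta=self.eta)


@dataclass(frozen=True)
class ProbePoint:
    """One probed location with its label and per-pressure ground truth."""

    patient_id: str
    point_id: str
    zone: str
    label: str                        # "C" or "NC"
    frequency: float                  # actuation frequency for this patient, Hz
    truth: Mapping[str, PointTruth]   # keyed by pressure level

    @property
    def tissue(self) -> ViscoParams:
        """Firm-pressure constitutive parameters (reference condition)."""
        return self.truth["firm"].visco


@dataclass(frozen=True)
class Cohort:
    points: tuple[ProbePoint, ...]
    config: CohortConfig

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.points])


@dataclass(frozen=True)
class RecordingMeta:
    patient_id: str
    point_id: str
    zone: str
    label: str
    pressure: str
    protocol: ActuationProtocol


@dataclass(frozen=True)
class BlockTruth:
    """Noise-free per-block observables stored alongside a recording."""

    frequency: float
    mr: float   # secant stiffness F_mean / depth, N/mm
    ar: float   # oscillatory stiffness F_amp / depth amplitude, N/mm
    pd: float   # phase lag of displacement behind force, rad


@dataclass
class RawRecording:
    """Paired force/strain time series for one probe point and pressure."""

    time: np.ndarray
    force: np.ndarray
    strain: np.ndarray
    meta: RecordingMeta
    truth: tuple[BlockTruth, ...] = ()


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _latents(rng: np.random.Generator, m: int, spread_matching: bool) -> np.ndarray:
    """Per-point probability latents for one stratum."""
    if spread_matching:
        return rng.permutation((np.arange(m) + 0.5) / m)
    return rng.uniform(size=m)


def _check_profile_spread(profile: CalibrationProfile) -> None:
    stats: list[ClassStats] = list(profile.static.values())
    for per_pressure in profile.dynamic.values():
        stats.extend(per_pressure.values())
    for per_freq in profile.lag.values():
        for per_pressure in per_freq.values():
            stats.extend(per_pressure.values())
    for s in stats:
        if s.median <= 0:
            raise ValueError(f"calibration medians must be positive, got {s.median}")
        if s.iqr == 0:
            raise ValueError(
                "degenerate calibration distribution: zero IQR requested "
                "while spread matching is enabled"
            )


def generate_cohort(config: CohortConfig,
                    profile: CalibrationProfile | None = None) -> Cohort:
    """Draw a labelled cohort of probe points with ground-truth tissue state.

    Fully deterministic under ``config.seed``.  Labels are assigned per zone
    (a lesion occupies the whole tissue column under a zone, so points that
    revisit a zone share its label).  Tissue parameters are then assigned
    within rank strata: quasi-static modulus per class pooled over the whole
    cohort, time lag and effective dynamic modulus per (class, frequency
    group), each pressure level sharing the point's latent quantile.
    """
    profile = profile if profile is not None else config.resolve_profile()
    if config.spread_matching:
        _check_profile_spread(profile)
    if not 0.0 <= config.p_cancer <= 1.0:
        raise ValueError(f"p_cancer must lie in [0, 1], got {config.p_cancer}")
    lo, hi = config.points_per_patient
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid points_per_patient range {config.points_per_patient}")

    rng = np.random.default_rng(config.seed)

    # --- patients, points, zones, labels -------------------------------
    meta: list[dict] = []
    for i in range(config.n_patients):
        patient_id = f"P{11 + i}"
        freq = (config.low_frequency_hz if i < config.n_low_freq_patients
                else config.high_frequency_hz)
        n_points = int(rng.integers(lo, hi + 1))
        lesioned = rng.random(len(ZONES)) < config.p_cancer
        for j in range(n_points):
            zone = ZONES[j % len(ZONES)]
            meta.append({
                "patient_id": patient_id,
                "point_id": f"{patient_id}_{j + 1:02d}",
                "zone": zone,
                "label": "C" if lesioned[j % len(ZONES)] else "NC",
                "frequency": freq,
            })

    n = len(meta)
    labels = np.array([m["label"] for m in meta])
    freqs = np.array([m["frequency"] for m in meta])

    # --- stratified latent quantiles ------------------------------------
    u_static = np.empty(n)
    u_lag = np.empty(n)
    u_dyn = np.empty(n)
    for label in ("C", "NC"):
        mask = labels == label
        if mask.any():
            u_static[mask] = _latents(rng, int(mask.sum()), config.spread_matching)
        for f in np.unique(freqs):
            sub = mask & (freqs == f)
            if sub.any():
                u_lag[sub] = _latents(rng, int(sub.sum()), config.spread_matching)
                u_dyn[sub] = _latents(rng, int(sub.sum()), config.spread_matching)

    # --- per-point, per-pressure ground truth ---------------------------
    beta = config.hardening_per_newton
    force = {"firm": config.mean_force_firm_n, "light": config.mean_force_light_n}
    points: list[ProbePoint] = []
    for k, m in enumerate(meta):
        label, f = m["label"], m["frequency"]
        try:
            lag_cells = profile.lag[f]
        except KeyError:
            raise ValueError(
                f"calibration profile has no time-lag targets for {f} Hz"
            ) from None
        omega = _TWO_PI * f
        e_firm = float(profile.static[label].quantile(u_static[k]))
        truth: dict[str, PointTruth] = {}
        for pressure in PRESSURES:
            hardening = (1.0 + beta * force[pressure]) / (1.0 + beta * force["firm"])
            e_s = e_firm * hardening
            dt = float(lag_cells[pressure][label].quantile(u_lag[k]))
            dt = min(dt, config.lag_cap_frac / (4.0 * f))
            e_dyn = float(profile.dynamic[pressure][label].quantile(u_dyn[k]))
            eta = e_s * math.tan(omega * dt) / omega
            truth[pressure] = PointTruth(e_static=e_s, dt=dt, e_dyn=e_dyn, eta=eta)
        points.append(ProbePoint(patient_id=m["patient_id"], point_id=m["point_id"],
                                 zone=m["zone"], label=label, frequency=f,
                                 truth=truth))
    return Cohort(points=tuple(points), config=config)


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------

def synthesize_recording(
    visco: ViscoParams,
    geom: ProbeGeometry,
    protocol: ActuationProtocol,
    pressure: str = "firm",
    *,
    accommodation: float = 1.0,
    snr_force_db: float | None = None,
    snr_strain_db: float | None = None,
    settle_frac: float = 0.0,
    settle_tau_s: float = 0.3,
    global_drift_frac_per_s: float = 0.0,
    rng: np.random.Generator | None = None,
    meta: RecordingMeta | None = None,
) -> RawRecording:
    """Synthesize one raw force/strain recording from tissue parameters.

    The commanded force is a per-block sinusoid about the pressure-level mean.
    The strain channel is the negative-going Hertz-linearised displacement
    response: the mean indentation depth solves the Hertz relation at the
    quasi-static modulus, and each block's oscillation is attenuated by the
    dynamic stiffness built from ``accommodation * |E*(f)|`` and delayed by
    the constitutive phase lag.  Optional per-block exponential settle and a
    slow global linear trend model the drift seen in hand-held recordings,
    and white noise is added per channel at the requested SNR.

    The strain oscillation amplitude is saturated at 90% of the mean strain
    so the probe never (spuriously) leaves contact; saturated blocks keep
    their phase.  Per-block noise-free (MR, AR, PD) are stored as
    ``recording.truth`` for round-trip testing.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if accommodation <= 0:
        raise ValueError(f"accommodation must be positive, got {accommodation}")

    fs = protocol.sampling_rate_hz
    f_mean = protocol.mean_force(pressure)
    f_amp = protocol.force_amplitude(pressure)
    n_total = protocol.n_samples_per_block * len(protocol.frequencies)
    t = np.arange(n_total) / fs

    d0 = indentation_depth(visco.e_static, geom, f_mean)   # mm
    eps_mean = -geom.k_f * d0
    mr_true = f_mean / d0                                  # N/mm (secant)

    force = np.full(n_total, f_mean)
    strain = np.full(n_total, eps_mean)
    truths: list[BlockTruth] = []

    for f, sl in protocol.block_slices():
        omega = _TWO_PI * f
        tb = t[sl] - t[sl][0]
        cm = complex_modulus(visco, f)
        delta = cm.phase
        e_dyn_eff = accommodation * cm.magnitude
        k_dyn = hertz_tangent_stiffness(e_dyn_eff, geom, d0)   # N/mm
        eps_amp = geom.k_f * f_amp / k_dyn
        cap = 0.9 * abs(eps_mean)
        if eps_amp > cap:
            eps_amp = cap
        ar_true = geom.k_f * f_amp / eps_amp                   # N/mm after cap

        force[sl] += f_amp * np.sin(omega * tb)
        strain[sl] -= eps_amp * np.sin(omega * tb - delta)
        if settle_frac > 0.0:
            strain[sl] += settle_frac * abs(eps_mean) * np.exp(-tb / settle_tau_s)
        truths.append(BlockTruth(frequency=f, mr=mr_true, ar=ar_true, pd=delta))

    if global_drift_frac_per_s != 0.0:
        strain -= global_drift_frac_per_s * abs(eps_mean) * t

    if snr_force_db is not None:
        force = force + rng.normal(0.0, f_amp * 10 ** (-snr_force_db / 20.0), n_total)
    if snr_strain_db is not None:
        eps_ref = max(tr.ar for tr in truths)
        noise_scale = geom.k_f * f_amp / eps_ref * 10 ** (-snr_strain_db / 20.0)
        strain = strain + rng.normal(0.0, noise_scale, n_total)

    if meta is None:
        meta = RecordingMeta(patient_id="", point_id="", zone="", label="",
                             pressure=pressure, protocol=protocol)
    return RawRecording(time=t, force=force, strain=strain, meta=meta,
                        truth=tuple(truths))


def simulate_recording(point: ProbePoint, pressure: str, config: CohortConfig,
                       geom: ProbeGeometry,
                       rng: np.random.Generator | None = None,
                       protocol: ActuationProtocol | None = None) -> RawRecording:
    """Simulate the raw recording for one cohort point at one pressure level.

    The operator-accommodation factor is the ratio of the point's calibrated
    effective dynamic modulus to its constitutive |E*| at the point's
    actuation frequency (1.0 when accommodation is disabled in the config).
    """
    truth = point.truth[pressure]
    visco = truth.visco
    if protocol is None:
        protocol = config.protocol(point.frequency)
    if config.accommodation:
        alpha = truth.e_dyn / complex_modulus(visco, point.frequency).magnitude
    else:
        alpha = 1.0
    meta = RecordingMeta(patient_id=point.patient_id, point_id=point.point_id,
                         zone=point.zone, label=point.label, pressure=pressure,
                         protocol=protocol)
    return synthesize_recording(
        visco, geom, protocol, pressure,
        accommodation=alpha,
        snr_force_db=config.snr_force_db,
        snr_strain_db=config.snr_strain_db,
        settle_frac=config.settle_frac,
        settle_tau_s=config.settle_tau_s,
        global_drift_frac_per_s=config.global_drift_frac_per_s,
        rng=rng, meta=meta,
    )


def simulate_cohort(cohort: Cohort, geom: ProbeGeometry | None = None
                    ) -> list[RawRecording]:
    """Simulate recordings for every (point, pressure) in a cohort.

    Each recording gets an independent random stream derived from the cohort
    seed, the point index and the pressure level, so the full set is
    reproducible and insensitive to simulation order.
    """
    geom = geom if geom is not None else ProbeGeometry()
    recordings: list[RawRecording] = []
    for idx, point in enumerate(cohort.points):
        for p_idx, pressure in enumerate(PRESSURES):
            rng = np.random.default_rng([cohort.config.seed, idx, p_idx])
            recordings.append(simulate_recording(point, pressure, cohort.config,
                                                 geom, rng=rng))
    return recordings
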
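"""Synthetic mock-circulatory-loop bench experiment.

Emulates an ex vivo rig in which an excised thoracic aorta is mounted in a
Type I or Type III arch configuration, perfused with pulsatile flow from a
ventricle-like pump, and instrumented with proximal/distal flow meters and a
distal (zone-3) pressure sensor.  The generator produces paired flow
records, a pressure record, planar centerline point sets, and the ground
truth (wave speed, transit time, length) needed for recovery tests.

Physics, deliberately minimal:

* Afterload is a three-element Windkessel (characteristic impedance ``Zc``,
  peripheral resistance ``R``, compliance ``C``) driven by a half-sine
  ventricular ejection.  ``R`` and ``C`` are auto-tuned by bisection so the
  zone-3 pressure lands inside the protocol windows (DBP 75-85, SBP 115-125,
  PP 40-50, MAP 90-100 mmHg), mirroring the experimenters' knob-setting.
* The intrinsic wall wave speed follows Moens-Korteweg,
  ``c = sqrt(E h / (2 rho r))``, evaluated at the landing-zone radius.
* Arch angulation (Type III) multiplies ``R`` by ``arch_resistance_factor``
  (raising all pressures) and scales the wave speed with mean pressure as
  ``c = c_MK * (MAP / MAP_baseline) ** arch_stiffening_exponent`` — the
  mechanism is a hypothesis exposed as parameters, not asserted physics.
* A deployed stent-graft stiffens the covered segment only: local wave speed
  over the covered length is ``kappa * c``, so the transit time becomes
  ``(L - L_stent)/c + L_stent/(kappa c)``.
* The distal flow waveform is the proximal waveform circularly delayed by
  the true transit time (evaluated analytically, so fractional-sample delays
  are exact) and damped by a constant factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import TuningError
from .units import MMHG_TO_PA, lpm_to_m3s, m3s_to_lpm

__all__ = [
    "AortaSample",
    "MockLoopConfig",
    "WaveformRecord",
    "PlanarPointSet",
    "GroundTruth",
    "SimulationResult",
    "CohortPopulation",
    "moens_korteweg",
    "synthesize_flow_pair",
    "simulate_sample",
    "generate_point_set",
    "generate_cohort",
]

REFERENCE_PRESSURE_MMHG = 100.0  # pressure at which length_ref_cm is defined
REFERENCE_SEGMENT_CM = 2.5       # physical length of the on-guide scale bar


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AortaSample:
    """One specimen: tapered diameters, length model and wall parameters.

    Diameters are anteroposterior calibers at the four protocol locations
    (1: ascending aorta, 2: proximal landing zone, 3: distal landing zone,
    4: distal descending aorta) and must taper, ``d1 > d2 > d3 > d4``.
    ``length_ref_cm`` is the Type I centerline length at the reference
    pressure (100 mmHg); ``length_slope_cm_per_mmhg`` its pressure
    sensitivity.  Wall modulus/thickness and fluid density feed the
    Moens-Korteweg wave speed.
    """

    sample_id: str
    d1_mm: float
    d2_mm: float
    d3_mm: float
    d4_mm: float
    length_ref_cm: float
    length_slope_cm_per_mmhg: float = 0.01
    wall_modulus_pa: float = 150e3
    wall_thickness_m: float = 2.0e-3
    fluid_density_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        d = (self.d1_mm, self.d2_mm, self.d3_mm, self.d4_mm)
        if not (d[0] > d[1] > d[2] > d[3] > 0):
            raise ValueError(f"diameters must taper d1>d2>d3>d4>0, got {d}")
        if self.length_ref_cm <= 0:
            raise ValueError("length_ref_cm must be positive")
        if self.length_slope_cm_per_mmhg < 0:
            raise ValueError("length_slope_cm_per_mmhg must be >= 0")
        for name in ("wall_modulus_pa", "wall_thickness_m", "fluid_density_kg_m3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def length_at_cm(self, pressure_mmhg: float, extra_cm: float = 0.0) -> float:
        """Centerline length (cm) at a given pressure, plus any arch offset."""
        return (self.length_ref_cm + extra_cm
                + self.length_slope_cm_per_mmhg
                * (pressure_mmhg - REFERENCE_PRESSURE_MMHG))


@dataclass(frozen=True)
class MockLoopConfig:
    """Rig settings for one acquisition.

    Defaults encode the bench protocol: 75 bpm, cardiac output inside
    4.5-5.5 L/min, pressure windows DBP 75-85 / SBP 115-125 / PP 40-50 /
    MAP 90-100 mmHg, >= 25 consecutive cycles, 1 kHz sampling.  The arch
    and stent factors are calibrated so that Type III raises MAP by
    ~8 mmHg and wave speed by ~8.5%, and the stented 112 mm segment raises
    whole-aorta PWV by ~7%.
    """

    heart_rate_bpm: float = 75.0
    cardiac_output_lpm: float = 5.0
    pressure_windows_mmhg: dict = field(default_factory=lambda: {
        "dbp": (75.0, 85.0),
        "sbp": (115.0, 125.0),
        "pp": (40.0, 50.0),
        "map": (90.0, 100.0),
    })
    map_target_mmhg: float = 94.0
    pp_target_mmhg: float = 44.0
    arch_type: Literal["I", "III"] = "I"
    arch_resistance_factor: float = 1.085
    arch_stiffening_exponent: float = 1.0
    arch_length_delta_cm: float = 0.7
    stent: bool = False
    stent_covered_length_mm: float = 112.0
    stent_speed_factor: float = 1.28
    sampling_rate_hz: float = 1000.0
    n_cycles: int = 25
    ejection_fraction: float = 0.35
    zc_fraction: float = 0.05
    distal_damping: float = 0.85
    noise_sd: float = 0.005
    tuning_max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 25:
            raise ValueError("n_cycles must be >= 25 (protocol minimum)")
        if self.sampling_rate_hz < 100:
            raise ValueError("sampling_rate_hz must be >= 100")
        if self.stent_speed_factor < 1:
            raise ValueError("stent_speed_factor must be >= 1")
        if self.arch_resistance_factor < 1:
            raise ValueError("arch_resistance_factor must be >= 1")
        if self.arch_type not in ("I", "III"):
            raise ValueError("arch_type must be 'I' or 'III'")
        if not (0 < self.ejection_fraction < 1):
            raise ValueError("ejection_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for key, (lo, hi) in self.pressure_windows_mmhg.items():
            if not lo < hi:
                raise ValueError(f"pressure window {key!r} is empty: ({lo}, {hi})")


@dataclass(frozen=True)
class WaveformRecord:
    """Uniformly sampled flow (L/min) or pressure (mmHg) time series."""

    site: Literal["proximal", "distal", "zone3"]
    channel: Literal["flow", "pressure"]
    sampling_rate_hz: float
    heart_rate_bpm: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform contains non-finite samples")
        if self.sampling_rate_hz <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("sampling_rate_hz and heart_rate_bpm must be positive")

    @property
    def units(self) -> str:
        return "L/min" if self.channel == "flow" else "mmHg"

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate_hz

    @property
    def n_complete_cycles(self) -> int:
        spc = round(self.sampling_rate_hz * 60.0 / self.heart_rate_bpm)
        return self.values.size // spc


@dataclass(frozen=True)
class PlanarPointSet:
    """Ordered pixel points along the aortic centerline plus a scale bar.

    ``points`` run proximal to distal; ``scale_segment`` is the pair of
    pixel endpoints of the 2.5 cm reference line on the arch guide.
    ``pressure_mmhg`` is the continuous-flow pressure at acquisition
    (80/100/120 mmHg in the calibration protocol).
    """

    points_px: np.ndarray          # (n, 2)
    scale_segment_px: np.ndarray   # (2, 2)
    pressure_mmhg: float
    scale_length_cm: float = REFERENCE_SEGMENT_CM

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_px, dtype=float)
        seg = np.asarray(self.scale_segment_px, dtype=float)
        object.__setattr__(self, "points_px", pts)
        object.__setattr__(self, "scale_segment_px", seg)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 15:
            raise ValueError("point set needs >= 15 ordered (x, y) pixel points")
        if seg.shape != (2, 2):
            raise ValueError("scale_segment_px must be two (x, y) points")
        if self.pressure_mmhg <= 0:
            raise ValueError("pressure_mmhg must be positive")
        if self.scale_length_cm <= 0:
            raise ValueError("scale_length_cm must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Imposed truth of one simulated acquisition, for recovery tests."""

    wave_speed_m_s: float
    transit_time_s: float
    length_at_map_cm: float
    dbp_mmhg: float
    sbp_mmhg: float
    pp_mmhg: float
    map_mmhg: float
    baseline_map_mmhg: float
    resistance_pa_s_m3: float
    compliance_m3_pa: float
    mean_flow_lpm: float


@dataclass(frozen=True)
class SimulationResult:
    proximal_flow: WaveformRecord
    distal_flow: WaveformRecord
    zone3_pressure: WaveformRecord
    truth: GroundTruth


# --------------------------------------------------------------------------
# wave speed
# --------------------------------------------------------------------------

def moens_korteweg(modulus_pa: float, thickness_m: float,
                   radius_m: float, density_kg_m3: float) -> float:
    """Moens-Korteweg wave speed ``c = sqrt(E h / (2 rho r))`` in m/s."""
    for name, v in (("modulus_pa", modulus_pa), ("thickness_m", thickness_m),
                    ("radius_m", radius_m), ("density_kg_m3", density_kg_m3)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return math.sqrt(modulus_pa * thickness_m / (2.0 * density_kg_m3 * radius_m))


def modulus_for_wave_speed(c_m_s: float, thickness_m: float,
                           radius_m: float, density_kg_m3: float) -> float:
    """Invert Moens-Korteweg for the wall modulus giving wave speed ``c``."""
    if c_m_s <= 0:
        raise ValueError("wave speed must be positive")
    return c_m_s**2 * 2.0 * density_kg_m3 * radius_m / thickness_m


# --------------------------------------------------------------------------
# Windkessel afterload
# --------------------------------------------------------------------------

def _snapped_period(heart_rate_bpm: float, fs: float) -> tuple[float, int]:
    """Cycle period snapped onto the sample grid (exact at 75 bpm / 1 kHz)."""
    n = int(round(fs * 60.0 / heart_rate_bpm))
    return n / fs, n


def _ejection_flow(t: np.ndarray, period: float, ej_frac: float,
                   co_m3s: float) -> np.ndarray:
    """Half-sine ventricular ejection with the requested mean flow (m^3/s)."""
    t_ej = ej_frac * period
    q_peak = co_m3s * math.pi * period / (2.0 * t_ej)
    tt = np.mod(t, period)
    return np.where(tt < t_ej, q_peak * np.sin(np.pi * tt / t_ej), 0.0)


def _windkessel_cycle(R: float, C: float, zc_fraction: float, co_m3s: float,
                      period: float, n: int, ej_frac: float,
                      oversample: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Periodic steady-state zone-3 pressure (Pa) and input flow (m^3/s).

    The storage pressure obeys ``Pc' = Q/C - Pc/(R C)``; the periodic
    solution is obtained in closed form with an exponential integrator on an
    oversampled grid, then decimated to the n-sample acquisition grid.
    ``P = Pc + Zc Q`` with ``Zc = zc_fraction * R``.
    """
    tau = R * C
    nf = n * oversample
    t = np.arange(nf + 1) * (period / nf)
    q = _ejection_flow(t, period, ej_frac, co_m3s)
    integrand = np.exp(t / tau) * q / C
    I = cumulative_trapezoid(integrand, t, initial=0.0)
    decay = math.exp(-period / tau)
    pc0 = decay * I[-1] / (1.0 - decay)
    pc = np.exp(-t / tau) * (pc0 + I)
    p = pc + zc_fraction * R * q
    return p[:-1:oversample], q[:-1:oversample]


def _pressure_indices_pa(p: np.ndarray) -> tuple[float, float, float, float]:
    dbp = float(p.min())
    sbp = float(p.max())
    pp = sbp - dbp
    return dbp, sbp, pp, dbp + pp / 3.0


def tune_windkessel(config: MockLoopConfig) -> tuple[float, float]:
    """Bisection-tune (R, C) so baseline zone-3 pressure hits the windows.

    Mirrors the experimenters' knob-setting: resistance is bisected until
    the (DBP + PP/3) mean pressure hits ``map_target_mmhg``, then compliance
    until the pulse pressure hits ``pp_target_mmhg``; three alternating
    passes absorb the weak coupling.  Raises :class:`TuningError` naming the
    first unmet window if the noise-free baseline lands outside any of them.
    """
    co = lpm_to_m3s(config.cardiac_output_lpm)
    period, n = _snapped_period(config.heart_rate_bpm, config.sampling_rate_hz)
    map_t = config.map_target_mmhg * MMHG_TO_PA
    pp_t = config.pp_target_mmhg * MMHG_TO_PA

    def indices(R: float, C: float):
        p, _ = _windkessel_cycle(R, C, config.zc_fraction, co, period, n,
                                 config.ejection_fraction)
        return _pressure_indices_pa(p)

    R0 = map_t / co
    R, C = R0, 1e-8
    for _ in range(3):
        lo, hi = 0.2 * R0, 5.0 * R0
        if not indices(lo, C)[3] < map_t < indices(hi, C)[3]:
            raise TuningError("MAP target not bracketed by resistance bounds")
        for _ in range(config.tuning_max_iter):
            mid = 0.5 * (lo + hi)
            if indices(mid, C)[3] < map_t:
                lo = mid
            else:
                hi = mid
        R = 0.5 * (lo + hi)
        clo, chi = 1e-10, 1e-6
        if not indices(R, chi)[2] < pp_t < indices(R, clo)[2]:
            raise TuningError("PP target not bracketed by compliance bounds")
        for _ in range(config.tuning_max_iter):
            mid = math.sqrt(clo * chi)
            if indices(R, mid)[2] > pp_t:
                clo = mid
            else:
                chi = mid
        C = math.sqrt(clo * chi)

    dbp, sbp, pp, map_f = (v / MMHG_TO_PA for v in indices(R, C))
    achieved = {"dbp": dbp, "sbp": sbp, "pp": pp, "map": map_f}
    for key, (lo, hi) in config.pressure_windows_mmhg.items():
        if not lo <= achieved[key] <= hi:
            raise TuningError(
                f"tuned {key.upper()} = {achieved[key]:.1f} mmHg outside "
                f"window ({lo}, {hi})")
    return R, C


# --------------------------------------------------------------------------
# acquisition synthesis
# --------------------------------------------------------------------------

def _noise_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _add_noise(values: np.ndarray, noise_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    if noise_sd == 0:
        return values
    ptp = float(values.max() - values.min())
    return values + rng.normal(0.0, noise_sd * ptp, values.size)


def synthesize_flow_pair(delay_s: float, *, heart_rate_bpm: float = 75.0,
                         sampling_rate_hz: float = 1000.0, n_cycles: int = 25,
                         cardiac_output_lpm: float = 5.0,
                         ejection_fraction: float = 0.35,
                         distal_damping: float = 0.85,
                         noise_sd: float = 0.0, seed: int = 0,
                         ) -> tuple[WaveformRecord, WaveformRecord]:
    """Proximal/distal flow records with an exactly imposed transit time.

    The distal waveform is the analytic proximal waveform evaluated at
    ``t - delay_s`` (periodic), so fractional-sample delays are represented
    without interpolation error.
    """
    if delay_s < 0:
        raise ValueError("delay_s must be >= 0")
    period, n = _snapped_period(heart_rate_bpm, sampling_rate_hz)
    co = lpm_to_m3s(cardiac_output_lpm)
    t = np.arange(n) / sampling_rate_hz
    prox_cycle = m3s_to_lpm(1.0) * _ejection_flow(t, period, ejection_fraction, co)
    dist_cycle = m3s_to_lpm(1.0) * distal_damping * _ejection_flow(
        t - delay_s, period, ejection_fraction, co)
    prox = np.tile(prox_cycle, n_cycles)
    dist = np.tile(dist_cycle, n_cycles)
    prox = _add_noise(prox, noise_sd, _noise_rng(seed, 1))
    dist = _add_noise(dist, noise_sd, _noise_rng(seed, 2))
    mk = dict(sampling_rate_hz=sampling_rate_hz, heart_rate_bpm=heart_rate_bpm)
    return (WaveformRecord("proximal", "flow", values=prox, **mk),
            WaveformRecord("distal", "flow", values=dist, **mk))


def simulate_sample(sample: AortaSample, config: MockLoopConfig) -> SimulationResult:
    """Simulate one acquisition of one specimen in one rig configuration.

    Steps: tune (R, C) at baseline; apply the Type III resistance factor if
    requested; derive the configuration wave speed from Moens-Korteweg at
    the landing-zone radius, pressure-scaled by the stiffening exponent;
    evaluate the length model at the achieved MAP; impose the resulting
    transit time on the flow pair; add measurement noise.
    """
    R, C = tune_windkessel(config)
    co = lpm_to_m3s(config.cardiac_output_lpm)
    period, n = _snapped_period(config.heart_rate_bpm, config.sampling_rate_hz)

    p_base, _ = _windkessel_cycle(R, C, config.zc_fraction, co, period, n,
                                  config.ejection_fraction)
    map_base = _pressure_indices_pa(p_base)[3] / MMHG_TO_PA

    if config.arch_type == "III":
        R_eff = R * config.arch_resistance_factor
        p_cfg, _ = _windkessel_cycle(R_eff, C, config.zc_fraction, co, period,
                                     n, config.ejection_fraction)
        length_extra = config.arch_length_delta_cm
    else:
        R_eff, p_cfg, length_extra = R, p_base, 0.0

    dbp, sbp, pp, map_cfg = (v / MMHG_TO_PA for v in _pressure_indices_pa(p_cfg))

    c_mk = moens_korteweg(sample.wall_modulus_pa, sample.wall_thickness_m,
                          sample.d2_mm / 2.0 * 1e-3, sample.fluid_density_kg_m3)
    c = c_mk * (map_cfg / map_base) ** config.arch_stiffening_exponent

    length_cm = sample.length_at_cm(map_cfg, extra_cm=length_extra)
    length_m = length_cm / 100.0
    if config.stent:
        l_stent = config.stent_covered_length_mm / 1000.0
        if l_stent >= length_m:
            raise ValueError("stent covered length exceeds centerline length")
        transit = (length_m - l_stent) / c + l_stent / (config.stent_speed_factor * c)
    else:
        transit = length_m / c

    prox, dist = synthesize_flow_pair(
        transit, heart_rate_bpm=config.heart_rate_bpm,
        sampling_rate_hz=config.sampling_rate_hz, n_cycles=config.n_cycles,
        cardiac_output_lpm=config.cardiac_output_lpm,
        ejection_fraction=config.ejection_fraction,
        distal_damping=config.distal_damping,
        noise_sd=config.noise_sd, seed=config.seed)

    p_vals = np.tile(p_cfg / MMHG_TO_PA, config.n_cycles)
    p_vals = _add_noise(p_vals, config.noise_sd, _noise_rng(config.seed, 3))
    zone3 = WaveformRecord("zone3", "pressure", config.sampling_rate_hz,
                           config.heart_rate_bpm, p_vals)

    truth = GroundTruth(
        wave_speed_m_s=c, transit_time_s=transit, length_at_map_cm=length_cm,
        dbp_mmhg=dbp, sbp_mmhg=sbp, pp_mmhg=pp, map_mmhg=map_cfg,
        baseline_map_mmhg=map_base, resistance_pa_s_m3=R_eff,
        compliance_m3_pa=C, mean_flow_lpm=config.cardiac_output_lpm)
    return SimulationResult(prox, dist, zone3, truth)


# --------------------------------------------------------------------------
# planar point sets
# --------------------------------------------------------------------------

def generate_point_set(sample: AortaSample, pressure_mmhg: float, *,
                       px_per_cm: float = 40.0, jitter_px: float = 0.0,
                       seed: int = 0, n_points: int = 20,
                       length_delta_cm: float = 0.0) -> PlanarPointSet:
    """Synthetic stand-in for a manually annotated planar photograph.

    A candy-cane template (semicircular arch plus straight descending limb)
    is sampled at ``n_points`` and rescaled so that the *polyline* through
    the noise-free points has exactly the sample's centerline length at the
    requested pressure; Gaussian pixel jitter then emulates manual point
    placement.  The 2.5 cm scale bar is emitted jitter-free (it is a crisp
    printed line on the guide, not a manual click).
    """
    if pressure_mmhg <= 0:
        raise ValueError("pressure_mmhg must be positive")
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    if n_points < 15:
        raise ValueError("a minimum of 15 points is required")

    target_cm = sample.length_at_cm(pressure_mmhg, extra_cm=length_delta_cm)
    if target_cm <= 0:
        raise ValueError("length model gives non-positive length")

    # template: unit-radius semicircle (arch) + straight limb of length 2
    s = np.linspace(0.0, 1.0, n_points)
    arc_frac = math.pi / (math.pi + 2.0)
    xs, ys = np.empty(n_points), np.empty(n_points)
    on_arch = s <= arc_frac
    theta = np.pi * s[on_arch] / arc_frac
    xs[on_arch] = -np.cos(theta)
    ys[on_arch] = np.sin(theta)
    drop = (s[~on_arch] - arc_frac) / (1.0 - arc_frac) * 2.0
    xs[~on_arch] = 1.0
    ys[~on_arch] = -drop
    pts = np.column_stack([xs, ys])

    chord = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    pts *= target_cm / chord                      # polyline length == target (cm)
    pts_px = pts * px_per_cm
    if jitter_px > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 7)))
        pts_px = pts_px + rng.normal(0.0, jitter_px, pts_px.shape)

    scale_seg = np.array([[0.0, 0.0], [REFERENCE_SEGMENT_CM * px_per_cm, 0.0]])
    return PlanarPointSet(pts_px, scale_seg, pressure_mmhg)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPopulation:
    """Population parameters for cohort sampling.

    Defaults reproduce the bench cohort: diameter means/SDs at the four
    points, Type I centerline length, and a target baseline wave-speed
    distribution from which each specimen's wall modulus is back-solved via
    Moens-Korteweg.  Diameters are drawn as independent truncated normals
    (+-3 SD) with the tapering order enforced by rejection.
    """

    d_means_mm: tuple = (25.4, 22.8, 16.3, 14.6)
    d_sds_mm: tuple = (1.8, 1.6, 1.0, 1.3)
    length_mean_cm: float = 36.2
    length_sd_cm: float = 2.6
    length_slope_mean: float = 0.01   # cm per mmHg
    length_slope_sd: float = 0.003
    wave_speed_mean_m_s: float = 3.53
    wave_speed_sd_m_s: float = 0.40
    wall_thickness_m: float = 2.0e-3
    fluid_density_kg_m3: float = 1000.0
    cardiac_output_mean_lpm: float = 4.74
    cardiac_output_sd_lpm: float = 0.40
    cardiac_output_bounds_lpm: tuple = (4.5, 5.5)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def draw_cardiac_output(population: CohortPopulation,
                        rng: np.random.Generator) -> float:
    """Per-specimen cardiac output, truncated to the protocol window (L/min)."""
    lo, hi = population.cardiac_output_bounds_lpm
    return _trunc_normal(rng, population.cardiac_output_mean_lpm,
                         population.cardiac_output_sd_lpm, lo, hi)


def generate_cohort(n: int, population: CohortPopulation | None = None,
                    seed: int = 0) -> list[AortaSample]:
    """Draw ``n`` specimens from the configured population (reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = population or CohortPopulation()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    cohort = []
    for i in range(n):
        for _ in range(1000):
            d = [_trunc_normal(rng, m, s, max(m - 3 * s, 1e-3), m + 3 * s)
                 for m, s in zip(pop.d_means_mm, pop.d_sds_mm)]
            if d[0] > d[1] > d[2] > d[3] > 0:
                break
        else:  # pragma: no cover - astronomically unlikely with defaults
            raise RuntimeError("could not draw tapering diameters")
        length = _trunc_normal(rng, pop.length_mean_cm, pop.length_sd_cm,
                               max(pop.length_mean_cm - 3 * pop.length_sd_cm, 1.0),
                               pop.length_mean_cm + 3 * pop.length_sd_cm)
        slope = max(0.0, rng.normal(pop.length_slope_mean, pop.length_slope_sd))
        c_target = _trunc_normal(rng, pop.wave_speed_mean_m_s,
                                 pop.wave_speed_sd_m_s,
                                 max(pop.wave_speed_mean_m_s
                                     - 3 * pop.wave_speed_sd_m_s, 0.5),
                                 pop.wave_speed_mean_m_s
                                 + 3 * pop.wave_speed_sd_m_s)
        E = modulus_for_wave_speed(c_target, pop.wall_thickness_m,
                                   d[1] / 2.0 * 1e-3, pop.fluid_density_kg_m3)
        cohort.append(AortaSample(
            sample_id=f"A{i + 1:03d}", d1_mm=d[0], d2_mm=d[1], d3_mm=d[2],
            d4_mm=d[3], length_ref_cm=length, length_slope_cm_per_mmhg=slope,
            wall_modulus_pa=E, wall_thickness_m=pop.wall_thickness_m,
            fluid_density_kg_m3=pop.fluid_density_kg_m3))
    return cohort


def config_for(sample_seed: int, base: MockLoopConfig | None = None,
               **overrides) -> MockLoopConfig:
    """Derive an acquisition config with a substream seed and overrides."""
    base = base or MockLoopConfig()
    return replace(base, seed=int(sample_seed), **overrides)
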
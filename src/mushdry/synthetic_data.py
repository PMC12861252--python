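"""Synthetic fixtures: pseudo-experimental drying records, RH schedules and
CPMG decays.

No public dataset accompanies the drying experiments, so every consumer of
experimental records in this package is exercised against model-generated
pseudo-data: drying curves from the solver plus seeded Gaussian noise, an
on/off (or sinusoidal) relative-humidity oscillation mimicking dryer control,
and multi-exponential CPMG echo trains at the instrument's acquisition
parameters.  All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ExperimentRecord
from .config import ModelConfig, default_config
from .membrane_state import CpmgDecay
from .solver import AmbientSchedule, DryingModel

__all__ = [
    "NoiseSpec",
    "HA_PRESETS",
    "preset_schedule",
    "gen_drying_experiment",
    "gen_rh_schedule",
    "gen_cpmg_decay",
]


@dataclass
class NoiseSpec:
    """Measurement-noise description for pseudo-experimental records."""

    sigma_yw: float = 0.0  # Gaussian std on wet-basis moisture
    sigma_T: float = 0.0  # Gaussian std on temperatures, K
    rh_amplitude: float = 0.0  # on/off RH oscillation amplitude
    rh_period: float = 1800.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_yw < 0 or self.sigma_T < 0 or self.rh_amplitude < 0:
            raise ValueError("noise magnitudes must be non-negative")


# Synthetic hot-air scenarios at the four nominal dryer temperatures.  The RH
# values share one absolute humidity (that of 30 % RH at 35 degC), mirroring
# a dryer drawing the same room air; they are model presets, not measured
# logs.
HA_PRESETS: dict[str, tuple[float, float, float]] = {
    # name: (T_air K, base RH, u_air m/s)
    "HA33": (306.15, 0.33, 0.3),
    "HA35": (308.15, 0.30, 0.3),
    "HA38": (311.15, 0.26, 0.3),
    "HA51": (324.15, 0.14, 0.3),
}


def preset_schedule(name: str, t_end: float) -> AmbientSchedule:
    T_air, rh, u = HA_PRESETS[name]
    return AmbientSchedule.constant(T_air, rh, u, t_end)


def gen_drying_experiment(
    config: ModelConfig | None,
    ambient: AmbientSchedule,
    noise: NoiseSpec,
    sampling_interval: float = 1800.0,
    t_end: float | None = None,
    model: DryingModel | None = None,
) -> tuple[ExperimentRecord, AmbientSchedule]:
    """Run the drying model and sample it like a logged experiment.

    With zero noise the record equals the simulation exactly at the sample
    times; Gaussian noise is seeded and reproducible.
    """
    cfg = config or default_config()
    if model is None:
        model = DryingModel(cfg)
    if t_end is None:
        t_end = float(ambient.t[-1])
    times = np.arange(0.0, t_end + 0.5 * sampling_interval, sampling_interval)
    result = model.simulate(ambient, t_end, t_eval=times)
    rng = np.random.default_rng(noise.seed)
    y_w = result.y_w + rng.normal(0.0, noise.sigma_yw, len(times)) if noise.sigma_yw else result.y_w.copy()
    t_p = result.T_center + rng.normal(0.0, noise.sigma_T, len(times)) if noise.sigma_T else result.T_center.copy()
    y_w = np.clip(y_w, 1e-4, 1.0 - 1e-4)
    record = ExperimentRecord(
        times,
        y_w,
        t_p,
        T_init=cfg.solver.t_init,
        T_air=ambient.nominal_T_air,
        schedule=ambient,
        T_surface=result.T_surface.copy(),
    )
    return record, ambient


def gen_rh_schedule(
    base_rh: float,
    amplitude: float,
    period: float,
    duration: float,
    T_air: float = 308.15,
    u_air: float = 0.3,
    waveform: str = "square",
    samples_per_period: int = 40,
) -> AmbientSchedule:
    """Oscillating RH about a base value (dryer on/off control emulation).

    The mean over an integer number of periods equals the base RH; square
    waves use short symmetric ramps so the schedule stays piecewise-linear.
    """
    if amplitude > base_rh or base_rh + amplitude > 1.0:
        raise ValueError("oscillation must keep RH within [0, 1]")
    if period <= 0 or duration <= 0:
        raise ValueError("period and duration must be positive")
    if waveform == "square":
        eps = 1e-6 * period
        n_per = max(int(np.ceil(duration / period)), 1)
        t_list = [0.0]
        rh_list = [base_rh + amplitude]
        for k in range(n_per):
            t0 = k * period
            t_list += [t0 + period / 2 - eps, t0 + period / 2 + eps,
                       t0 + period - eps, t0 + period + eps]
            rh_list += [base_rh + amplitude, base_rh - amplitude,
                        base_rh - amplitude, base_rh + amplitude]
        t = np.array(t_list)
        rh = np.array(rh_list)
        keep = t <= duration
        t, rh = t[keep], rh[keep]
        if t[-1] < duration:
            t = np.append(t, duration)
            rh = np.append(rh, rh[-1])
    elif waveform == "sine":
        t = np.linspace(0.0, duration, max(int(duration / period * samples_per_period), 8))
        rh = base_rh + amplitude * np.sin(2.0 * np.pi * t / period)
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    return AmbientSchedule(t, np.full_like(t, T_air), rh, np.full_like(t, u_air))


def gen_cpmg_decay(
    populations: list[tuple[float, float]],
    te: float = 0.5,
    nech: int = 12000,
    snr: float = float("inf"),
    seed: int = 0,
) -> CpmgDecay:
    """Multi-exponential CPMG echo train S(t_n) = sum_k A_k exp(-n TE / T2_k).

    ``populations`` lists (T2_ms, amplitude) pairs; additive Gaussian noise
    has standard deviation max(S)/SNR.
    """
    for t2, amp in populations:
        if t2 <= 0:
            raise ValueError("T2 values must be positive")
        if amp < 0:
            raise ValueError("amplitudes must be non-negative")
    t = te * np.arange(1, nech + 1)
    s = np.zeros(nech)
    for t2, amp in populations:
        s += amp * np.exp(-t / t2)
    noise_level = 0.0
    if np.isfinite(snr) and populations:
        noise_level = float(s.max()) / snr if s.max() > 0 else 0.0
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_level, nech)
    return CpmgDecay(te, s, noise_level=noise_level or None)
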
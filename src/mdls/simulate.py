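"""Synthetic multi-angle dynamic light scattering (MDLS) recordings.

The generator emulates the statistical structure of a 12-channel DLS bench:
monodisperse spheres in Brownian motion scatter a 660 nm laser, and each
photodetector at scattering angle ``theta_c`` sees the coherent sum
(a "phasor sum") of the fields scattered by every particle,

    E_c(t) = sum_j  b(r_j(t)) * sqrt(w(theta_c)) * exp(i q_c . r_j(t)),

with ``b`` a Gaussian beam-profile amplitude weight, ``w(theta)`` the
unpolarized Mie angular intensity, and ``q_c`` the scattering wavevector of
magnitude ``4 pi n sin(theta/2) / lambda``.  Particle displacements follow
Stokes-Einstein diffusion (per-axis step std ``sqrt(2 D dt)``), so the
scattered field decorrelates at rate ``Gamma = D q^2`` and the detected
intensity autocorrelation decays as ``exp(-2 Gamma tau)``.

The detector chain applies a per-channel amplifier gain, a dark offset, a
finite acquisition range (full-scale clip), and additive Gaussian noise.

A cheap ``surrogate`` mode replaces the phasor sum with per-channel
Ornstein-Uhlenbeck intensities whose autocorrelation rate matches
``2 D q_c^2`` exactly; it is intended for fast unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import constants, optimize
from scipy.special import erf

from . import mie

#: Particles simulated per (mg/ml) of sample concentration; calibrated so the
#: 0.025 mg/ml operating point puts 50 walkers in the simulation box.
KAPPA_PARTICLES_PER_MG_ML = 2000.0

DEFAULT_ANGLES_DEG = tuple(float(a) for a in range(15, 126, 10))


def diffusion_coefficient(
    diameter_um: float, temperature_k: float = 298.15, viscosity_pa_s: float = 8.9e-4
) -> float:
    """Stokes-Einstein translational diffusion coefficient, in m^2/s.

    ``D = kB T / (3 pi eta d)`` for a sphere of diameter ``d`` in a fluid of
    viscosity ``eta``.
    """
    if diameter_um <= 0 or temperature_k <= 0 or viscosity_pa_s <= 0:
        raise ValueError("diameter, temperature and viscosity must all be positive")
    return constants.k * temperature_k / (3.0 * np.pi * viscosity_pa_s * diameter_um * 1e-6)


def scattering_wavevector(
    angle_deg: float | np.ndarray, wavelength_nm: float, medium_index: float
) -> float | np.ndarray:
    """Magnitude of the scattering wavevector ``q = 4 pi n sin(theta/2)/lambda`` (1/m)."""
    theta = np.radians(angle_deg)
    return 4.0 * np.pi * medium_index * np.sin(theta / 2.0) / (wavelength_nm * 1e-9)


@dataclass(frozen=True)
class ParticleSpec:
    """A monodisperse spherical scatterer and its class label.

    Default classes follow the three-size experiment: 1 um -> 0, 2 um -> 1,
    4 um -> 2.
    """

    diameter_um: float
    refractive_index: complex = 1.59 + 0.0j  # polystyrene
    label: int | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("particle diameter must be positive")
        if complex(self.refractive_index).imag < 0:
            raise ValueError("imaginary part of the refractive index must be >= 0")


#: The three default particle classes (diameter um -> label).
DEFAULT_CLASSES = (
    ParticleSpec(1.0, label=0),
    ParticleSpec(2.0, label=1),
    ParticleSpec(4.0, label=2),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set for one synthetic recording.

    Optical and medium constants default to a 660 nm laser in water at room
    temperature; detector angles default to 12 values in the forward
    hemisphere (15..125 degrees), where the Mie forward lobe concentrates the
    scattered power.
    """

    particle: ParticleSpec = DEFAULT_CLASSES[0]
    concentration_mg_ml: float = 0.025
    temperature_k: float = 298.15
    viscosity_pa_s: float = 8.9e-4
    wavelength_nm: float = 660.0
    medium_index: float = 1.33
    detector_angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    beam_waist_um: float = 12.0
    box_size_um: float = 50.0
    duration_s: float = 10.0
    fs_hz: float = 1000.0
    noise_sigma_v: float = 0.01
    dark_level_v: float = 0.05
    signal_level_v: float = 0.3
    full_scale_v: float = 1.0
    reference_concentration_mg_ml: float = 0.025
    drift_velocity_um_s: float = 0.0
    n_particles: int | None = None  # None -> round(kappa * concentration)
    mode: str = "phasor"  # or "surrogate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        if self.concentration_mg_ml < 0:
            raise ValueError("concentration must be >= 0")
        if self.mode not in ("phasor", "surrogate"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        if self.n_particles is not None and self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if len(self.detector_angles_deg) < 1:
            raise ValueError("at least one detector angle is required")

    # ---- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    @property
    def n_channels(self) -> int:
        return len(self.detector_angles_deg)

    def effective_n_particles(self) -> int:
        if self.n_particles is not None:
            return int(self.n_particles)
        return int(round(KAPPA_PARTICLES_PER_MG_ML * self.concentration_mg_ml))

    def diffusion_m2_s(self) -> float:
        return diffusion_coefficient(
            self.particle.diameter_um, self.temperature_k, self.viscosity_pa_s
        )

    def wavevectors_m(self) -> np.ndarray:
        return scattering_wavevector(
            np.asarray(self.detector_angles_deg), self.wavelength_nm, self.medium_index
        )

    def decay_rates_hz(self) -> np.ndarray:
        """Field decorrelation rate ``Gamma = D q^2`` per channel (1/s)."""
        return self.diffusion_m2_s() * self.wavevectors_m() ** 2

    def mie_weights(self) -> np.ndarray:
        return mie_angular_weights(
            self.particle,
            self.wavelength_nm,
            self.medium_index,
            np.asarray(self.detector_angles_deg),
        )

    def mean_beam_weight_sq(self) -> float:
        """E[b(r)^2] for a particle uniform in the box (Gaussian beam along z)."""
        w0, L = self.beam_waist_um, self.box_size_um
        # integral of exp(-2 u^2 / w0^2) over [-L/2, L/2], squared, / L^2
        one_axis = w0 * math.sqrt(math.pi / 2.0) * erf(L / (math.sqrt(2.0) * w0))
        return (one_axis / L) ** 2

    def channel_gains(self) -> np.ndarray:
        """Per-channel amplifier gains (V per |E|^2 unit).

        Calibrated analytically so each channel's expected scattering signal
        equals ``signal_level_v`` at the reference concentration: real MDLS
        benches trim each photodiode amplifier so all channels use the
        acquisition range, since the Mie angular pattern spans decades.
        """
        n_ref = max(
            1, int(round(KAPPA_PARTICLES_PER_MG_ML * self.reference_concentration_mg_ml))
        )
        expected = n_ref * self.mean_beam_weight_sq() * self.mie_weights()
        return self.signal_level_v / expected


@dataclass
class MultiChannelSignal:
    """A time x channel voltage recording with its sampling rate."""

    samples: np.ndarray  # (T, C)
    fs_hz: float
    channel_angles_deg: tuple[float, ...]
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channel) array")
        if self.samples.shape[1] != len(self.channel_angles_deg):
            raise ValueError("channel count does not match the angle list")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def mie_angular_weights(
    particle: ParticleSpec,
    wavelength_nm: float,
    medium_index: float,
    angles_deg: Sequence[float],
) -> np.ndarray:
    """Unpolarized Mie intensity weights at the detector angles, max-normalized.

    The size parameter is ``x = pi d n_medium / lambda_vacuum`` and the
    relative index ``m = n_particle / n_medium``.  Weights are
    ``(|S1|^2 + |S2|^2)/2`` scaled so the largest requested weight is 1.
    """
    x = np.pi * particle.diameter_um * 1e3 * medium_index / wavelength_nm
    m = complex(particle.refractive_index) / medium_index
    w = mie.unpolarized_intensity(m, x, np.asarray(angles_deg, dtype=float))
    return w / w.max()


# ---------------------------------------------------------------------------
# recording generators


def _brownian_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Wrapped Brownian trajectories, shape (T, n, 3), in um."""
    T, n = config.n_samples, config.effective_n_particles()
    L = config.box_size_um
    dt = 1.0 / config.fs_hz
    D_um2_s = config.diffusion_m2_s() * 1e12
    step_std = math.sqrt(2.0 * D_um2_s * dt)
    pos = np.empty((T, n, 3))
    pos[0] = rng.uniform(-L / 2.0, L / 2.0, size=(n, 3))
    steps = rng.normal(0.0, step_std, size=(T - 1, n, 3))
    np.cumsum(steps, axis=0, out=steps)
    pos[1:] = pos[0] + steps
    if config.drift_velocity_um_s != 0.0:
        t = (np.arange(T) * dt)[:, None]
        pos[..., 0] += config.drift_velocity_um_s * t
    # periodic wrap: a particle leaving the box re-enters with a fresh phase,
    # which mimics scatterers exchanging with the surrounding volume
    np.mod(pos + L / 2.0, L, out=pos)
    pos -= L / 2.0
    return pos


def _phasor_recording(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    T = config.n_samples
    C = config.n_channels
    n = config.effective_n_particles()
    scatter = np.zeros((T, C))
    if n > 0:
        pos = _brownian_positions(config, rng)
        w0 = config.beam_waist_um
        b = np.exp(-(pos[..., 0] ** 2 + pos[..., 1] ** 2) / w0**2)  # (T, n)
        k_um = 2.0 * np.pi * config.medium_index / (config.wavelength_nm * 1e-3)
        gains = config.channel_gains()
        weights = config.mie_weights()
        for c, theta_deg in enumerate(config.detector_angles_deg):
            theta = math.radians(theta_deg)
            # q = k_s - k_i with incidence along +z, scattering in the x-z plane
            qx = k_um * math.sin(theta)
            qz = k_um * (math.cos(theta) - 1.0)
            phase = pos[..., 0] * qx + pos[..., 2] * qz
            E = (b * np.exp(1j * phase)).sum(axis=1)
            scatter[:, c] = gains[c] * weights[c] * np.abs(E) ** 2
    return scatter


def _surrogate_recording(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck intensity per channel with matched decay rate 2*Gamma."""
    T, C = config.n_samples, config.n_channels
    dt = 1.0 / config.fs_hz
    level = config.signal_level_v * (
        config.concentration_mg_ml / config.reference_concentration_mg_ml
        if config.reference_concentration_mg_ml > 0
        else 1.0
    )
    if config.effective_n_particles() == 0:
        return np.zeros((T, C))
    rates = 2.0 * config.decay_rates_hz()
    scatter = np.empty((T, C))
    for c in range(C):
        rho = math.exp(-rates[c] * dt)
        x = np.empty(T)
        x[0] = rng.normal()
        innov = rng.normal(size=T - 1) * math.sqrt(1.0 - rho * rho)
        for t in range(1, T):
            x[t] = rho * x[t - 1] + innov[t - 1]
        scatter[:, c] = level * np.clip(1.0 + 0.5 * x, 0.0, None)
    return scatter


def simulate_recording(config: SimulationConfig) -> MultiChannelSignal:
    """Generate one multichannel recording under ``config``.

    Deterministic given ``config.seed``.  With zero particles and zero noise
    the output is a constant at the dark level (allowed, degenerate).
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "phasor":
        scatter = _phasor_recording(config, rng)
    else:
        scatter = _surrogate_recording(config, rng)
    v = scatter + config.dark_level_v
    # finite acquisition range (DAQ full scale above dark)
    np.clip(v, None, config.full_scale_v + config.dark_level_v, out=v)
    if config.noise_sigma_v > 0:
        v = v + rng.normal(0.0, config.noise_sigma_v, size=v.shape)
    return MultiChannelSignal(
        samples=v,
        fs_hz=config.fs_hz,
        channel_angles_deg=tuple(config.detector_angles_deg),
        label=config.particle.label,
    )


def derive_seed(base_seed: int, class_index: int, repetition: int) -> int:
    """Deterministic per-recording seed below 2**31."""
    return (base_seed * 1_000_003 + 7_919 * class_index + repetition + 1) % (2**31)


def make_labeled_dataset(
    specs: Sequence[ParticleSpec],
    n_recordings_per_class: int,
    base_config: SimulationConfig,
) -> list[MultiChannelSignal]:
    """Balanced labeled recordings: ``n_recordings_per_class`` per particle spec.

    Per-recording seeds are derived deterministically from the base config's
    seed, so the full dataset is reproducible and recordings are distinct.
    """
    if len(specs) == 0:
        raise ValueError("at least one particle spec is required")
    if n_recordings_per_class < 1:
        raise ValueError("n_recordings_per_class must be >= 1")
    signals = []
    for ci, spec in enumerate(specs):
        for rep in range(n_recordings_per_class):
            cfg = replace(
                base_config,
                particle=spec,
                seed=derive_seed(base_config.seed, ci, rep),
            )
            signals.append(simulate_recording(cfg))
    return signals


# ---------------------------------------------------------------------------
# decay-rate estimation (autocorrelation fit)


def autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocovariance of ``x`` for lags 0..max_lag, FFT-based."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(X * np.conj(X), nfft)[: max_lag + 1] / n
    return acov


def estimate_decay_rate(
    series: np.ndarray, fs_hz: float, max_lag: int | None = None
) -> float:
    """Fit ``A exp(-2 Gamma tau) + C`` to the intensity autocovariance.

    Lag zero is excluded (it carries the white detector-noise variance) and
    the fit window extends to roughly four decay times, so a slowly varying
    background (number fluctuations, beam transits) is absorbed by ``C``.
    Returns ``Gamma`` in 1/s.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 50:
        raise ValueError("need a 1-D series of at least 50 samples")
    if max_lag is None:
        max_lag = min(len(series) // 4, 4000)
    acov = autocovariance(series, max_lag)
    g = acov / acov[1]  # normalize at lag 1 to dodge the noise delta at lag 0
    lags = np.arange(max_lag + 1)

    tail = g[max(2, int(0.8 * max_lag)) :].mean()
    # crude e-folding estimate for the fit window
    amp0 = 1.0 - tail
    below = np.nonzero(g[1:] - tail < amp0 / math.e)[0]
    tau_e = int(below[0]) + 1 if len(below) else max_lag // 4
    fit_to = int(min(max_lag, max(10, 4 * tau_e)))

    def model(tau, A, gamma2, C):
        return A * np.exp(-gamma2 * tau) + C

    p0 = (amp0, 1.0 / max(tau_e, 1), tail)
    popt, _ = optimize.curve_fit(
        model,
        lags[1 : fit_to + 1].astype(float),
        g[1 : fit_to + 1],
        p0=p0,
        bounds=([0.0, 1e-8, -1.0], [10.0, 10.0, 1.0]),
        maxfev=20000,
    )
    gamma2_per_sample = popt[1]
    return 0.5 * gamma2_per_sample * fs_hz


def decorrelation_time(series: np.ndarray, fs_hz: float) -> float:
    """``1 / (2 Gamma)`` from the fitted intensity autocorrelation, in seconds."""
    return 1.0 / (2.0 * estimate_decay_rate(series, fs_hz))


def estimate_diffusion(
    signal: MultiChannelSignal,
    wavelength_nm: float = 660.0,
    medium_index: float = 1.33,
    gamma_band_hz: tuple[float, float] = (2.0, 150.0),
) -> float:
    """Diffusion coefficient (m^2/s) pooled over detector channels.

    Each channel's intensity autocorrelation is fitted for its decay rate
    ``Gamma_c``; channels whose *fitted* rate falls outside ``gamma_band_hz``
    are discarded (too slow to average well over the record, or too fast to
    resolve at the sampling rate), and the per-channel estimates
    ``D_c = Gamma_c / q_c^2`` are combined by their median.  Single channels
    scatter by 10-30% on minute-long records; the median over ~10 angles is
    typically within a few percent.
    """
    qs = scattering_wavevector(
        np.asarray(signal.channel_angles_deg), wavelength_nm, medium_index
    )
    estimates = []
    for c in range(signal.n_channels):
        try:
            gamma = estimate_decay_rate(signal.samples[:, c], signal.fs_hz)
        except (RuntimeError, ValueError):
            continue
        if gamma_band_hz[0] <= gamma <= gamma_band_hz[1]:
            estimates.append(gamma / qs[c] ** 2)
    if not estimates:
        raise ValueError("no channel produced a resolvable decay-rate fit")
    return float(np.median(estimates))
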
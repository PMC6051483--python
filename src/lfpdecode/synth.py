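"""Ground-truth generator for spikes, SRSP-mixed LFP, and kinematics.

The generator emulates the statistical structure both pipelines assume:

* submovements at 1-4 events per second toward 8 targets, with lognormal
  peak speeds and minimum-jerk-like (Gaussian) speed pulses;
* unit firing rates = baseline + cosine direction tuning x event-locked
  activation, realized as inhomogeneous Poisson spike trains by thinning;
* LFP = spike trains convolved with rank-3 SRSP kernels (three damped
  sinusoid sources with distinct delays and frequencies, mixed across
  channels with spatial decay and seeded polarity diversity, so the same
  oscillation appears with different phase on different channels)
  + an event-locked rotational LMP component whose plane tilts with
  submovement direction (the population contribution of unrecorded
  neurons; its in-plane radius is sqrt(speed), making areal velocity
  proportional to submovement speed by construction)
  + white and 1/f channel noise and an optional common-mode artifact.

All randomness flows through one seeded generator; outputs are bit-identical
per seed. Presets encode the per-analysis study conditions: `miso_config`
switches every non-spike-driven LFP component off (kernel-recovery runs),
`rotation_config` makes the rotational component dominant (areal-velocity
and direction-decoding runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import KinematicsTrace, LfpRecording, SpikeTrainSet, ValidationError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "default_config",
    "miso_config",
    "rotation_config",
    "default_fixture",
    "FIXTURE_SEED",
]

FIXTURE_SEED = 20160214


@dataclass
class GeneratorConfig:
    """All tunable study conditions of the synthetic world (units in doc)."""

    seed: int
    session: int = 0  # realization index: same anatomy, fresh events/spikes/noise
    n_units: int = 6
    n_channels: int = 8
    duration: float = 120.0  # s
    fs: float = 100.0  # Hz; also the kernel/bin grid rate

    # unit tuning
    baseline_rate: float = 5.0  # Hz
    peak_rate: float = 25.0  # Hz at preferred direction
    activation_sigma: float = 0.10  # s, event-locked rate pulse width
    activation_delay_spread: float = 0.24  # s, per-unit latency range (M1-vs-PMv-like)
    activation_width_spread: float = 0.5  # fractional per-unit width range

    # SRSP sources (damped sinusoids) and mixing
    n_sources: int = 3
    source_delays: tuple = (0.0, 0.06, 0.12)  # s
    source_freqs: tuple = (1.5, 2.5, 3.5)  # Hz
    source_decay: float = 0.12  # s, Gaussian envelope sigma
    source_amps: tuple = (1.0, 0.7, 0.5)
    kernel_span: float = 0.5  # s each side of the spike
    spatial_decay: float = 1.2  # channel-distance units
    local_mixing_frac: float = 0.4  # per-unit vs shared source-profile blend
    kernel_amp: float = 1.0  # LFP units per spike

    # submovement process
    event_rate: float = 2.5  # events/s, within the 1-4 band
    min_gap: float = 0.25  # s
    n_directions: int = 8
    speed_scale: float = 1.0  # task units/s
    speed_sigma: float = 0.4  # lognormal sigma
    pulse_sigma: float = 0.08  # s, kinematic speed pulse width

    # rotational LMP component
    rotation_amp: float = 0.4  # LFP units at speed = speed_scale
    rotation_freq: float = 2.5  # Hz
    rotation_tilt_deg: float = 10.0  # per-direction axis tilt
    rotation_env_sigma: float = 0.18  # s

    # noise
    white_amp: float = 0.3
    pink_amp: float = 0.3
    common_amp: float = 0.0  # common-mode artifact gain

    def validate(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not (0 < self.event_rate < self.fs / 4):
            raise ValidationError(f"event_rate must lie in (0, fs/4)={self.fs / 4}")
        for name in ("baseline_rate", "peak_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if len(self.source_delays) < self.n_sources:
            raise ValidationError("need a delay per source")


@dataclass
class GroundTruth:
    """Everything the analyses try to recover."""

    kernels: np.ndarray  # unit x channel x lag
    lags: np.ndarray
    rates: np.ndarray  # time x unit instantaneous rates (Hz) at fs
    event_times: np.ndarray
    event_speeds: np.ndarray
    event_directions: np.ndarray
    rotation_frame: np.ndarray  # channel x 3 orthonormal frame
    rotation_axes: np.ndarray  # n_directions x channel rotation-axis vectors
    source_waveforms: np.ndarray  # n_sources x lag
    channel_mixing: np.ndarray  # unit x channel x n_sources loadings


def _source_waveforms(cfg: GeneratorConfig, lags: np.ndarray) -> np.ndarray:
    w = np.empty((cfg.n_sources, lags.size))
    for s in range(cfg.n_sources):
        tau = lags - cfg.source_delays[s]
        w[s] = (
            cfg.source_amps[s]
            * np.exp(-0.5 * (tau / cfg.source_decay) ** 2)
            * np.sin(2 * np.pi * cfg.source_freqs[s] * tau)
        )
    return w


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate(config: GeneratorConfig):
    """Run the generator.

    Returns ``(spikes, lfp, kinematics, ground_truth)``, deterministic for a
    given config (seed included).
    """
    cfg = config
    cfg.validate()
    # anatomy (kernels, mixing, rotation frame) is drawn from the seed alone
    # and is identical across sessions; events/spikes/noise are per-session
    rng_anat = np.random.default_rng([cfg.seed, 0xA])
    rng = np.random.default_rng([cfg.seed, 0xB, cfg.session])
    fs, dur = cfg.fs, cfg.duration
    n_t = int(round(dur * fs))
    t = np.arange(n_t) / fs
    dt = 1.0 / fs

    # --- submovement events -------------------------------------------------
    gaps = []
    total = 0.5
    mean_gap = 1.0 / cfg.event_rate
    while total < dur - 0.7:
        g = max(cfg.min_gap, rng.gamma(4.0, mean_gap / 4.0))
        gaps.append(g)
        total += g
    ev_times = 0.5 + np.cumsum([0.0] + gaps[:-1]) if gaps else np.empty(0)
    n_ev = len(ev_times)
    dir_idx = rng.integers(0, cfg.n_directions, size=n_ev)
    dir_angles = -np.pi + (np.arange(cfg.n_directions) + 1) * 2 * np.pi / cfg.n_directions
    ev_dirs = dir_angles[dir_idx]
    ev_speeds = cfg.speed_scale * rng.lognormal(0.0, cfg.speed_sigma, size=n_ev)

    # --- kinematics ---------------------------------------------------------
    vel = np.zeros((n_t, 2))
    for te, sp, th in zip(ev_times, ev_speeds, ev_dirs):
        pulse = sp * np.exp(-0.5 * ((t - te) / cfg.pulse_sigma) ** 2)
        vel[:, 0] += pulse * np.cos(th)
        vel[:, 1] += pulse * np.sin(th)
    kin = KinematicsTrace(times=t.copy(), position=np.cumsum(vel, axis=0) * dt)

    # --- unit rates and spikes ----------------------------------------------
    # per-unit activation latency and width differ (distinct trial-averaged
    # modulation profiles, as across M1/PMv populations)
    pds = -np.pi + (np.arange(cfg.n_units) + 0.5) * 2 * np.pi / cfg.n_units
    if cfg.n_units > 1:
        frac = np.arange(cfg.n_units) / (cfg.n_units - 1)
    else:
        frac = np.array([0.5])
    delays_u = cfg.activation_delay_spread * (frac - 0.5)
    sigmas_u = cfg.activation_sigma * (1 + cfg.activation_width_spread * (frac - 0.5))
    rates = np.full((n_t, cfg.n_units), cfg.baseline_rate)
    for te, sp, th in zip(ev_times, ev_speeds, ev_dirs):
        tuning = 0.5 * (1 + np.cos(th - pds))
        act = np.exp(
            -0.5 * ((t[:, None] - te - delays_u[None, :]) / sigmas_u[None, :]) ** 2
        ) * (sp / cfg.speed_scale)
        rates += act * (cfg.peak_rate * tuning)[None, :]
    rates = np.maximum(rates, 0.0)

    spike_times = []
    for u in range(cfg.n_units):
        lam_max = rates[:, u].max()
        n_hom = rng.poisson(lam_max * dur)
        cand = np.sort(rng.uniform(0, dur, size=n_hom))
        lam = np.interp(cand, t, rates[:, u])
        accept = rng.uniform(0, lam_max, size=n_hom) < lam
        spike_times.append(cand[accept])
    spikes = SpikeTrainSet(
        unit_ids=[f"u{u + 1}" for u in range(cfg.n_units)],
        spike_times=spike_times,
        t_start=0.0,
        t_stop=dur,
    )

    # --- SRSP kernels -------------------------------------------------------
    # Each source has a shared array-wide channel profile (network currents
    # common to the population: the paper-structure reason population
    # components decode well), blended with a per-unit local profile that
    # decays exponentially with distance from the unit's electrode (what
    # makes individual neurons partially identifiable). Every unit's SRSP
    # matrix remains exactly rank n_sources.
    k_half = int(round(cfg.kernel_span * fs))
    lags = np.arange(-k_half, k_half + 1) * dt
    sources = _source_waveforms(cfg, lags)
    pos = np.arange(cfg.n_channels) * 0.5
    unit_pos = np.linspace(pos[0], pos[-1], cfg.n_units + 2)[1:-1]
    centers = np.linspace(pos[0], pos[-1], cfg.n_sources + 2)[1:-1]
    shared = np.empty((cfg.n_channels, cfg.n_sources))
    for s in range(cfg.n_sources):
        gain = 1.0 + 0.3 * rng_anat.standard_normal(cfg.n_channels)
        polarity = rng_anat.choice([-1.0, 1.0], size=cfg.n_channels)
        shared[:, s] = np.exp(-np.abs(pos - centers[s]) / cfg.spatial_decay) * gain * polarity
    mixing = np.empty((cfg.n_units, cfg.n_channels, cfg.n_sources))
    frac = cfg.local_mixing_frac
    for u in range(cfg.n_units):
        w_us = rng_anat.uniform(0.4, 1.0, size=cfg.n_sources)
        for s in range(cfg.n_sources):
            local = (
                np.exp(-np.abs(pos - unit_pos[u]) / cfg.spatial_decay)
                * (1.0 + 0.3 * rng_anat.standard_normal(cfg.n_channels))
                * rng_anat.choice([-1.0, 1.0], size=cfg.n_channels)
            )
            mixing[u, :, s] = w_us[s] * ((1 - frac) * shared[:, s] + frac * local)
    kernels = cfg.kernel_amp * np.einsum("ucs,sl->ucl", mixing, sources)

    # --- LFP ----------------------------------------------------------------
    from scipy.signal import fftconvolve

    lfp_mat = np.zeros((n_t, cfg.n_channels))
    edges = np.arange(n_t + 1) * dt
    for u in range(cfg.n_units):
        counts, _ = np.histogram(spike_times[u], bins=edges)
        if not counts.any():
            continue
        for c in range(cfg.n_channels):
            full = fftconvolve(counts.astype(float), kernels[u, c])
            lfp_mat[:, c] += full[k_half : k_half + n_t]

    # rotational LMP component with direction-tilted axes
    raw = rng_anat.standard_normal((cfg.n_channels, 3))
    Q, _ = np.linalg.qr(raw)
    eps = np.deg2rad(cfg.rotation_tilt_deg)
    axes_frame = np.column_stack(
        [
            np.sin(eps) * np.cos(dir_angles),
            np.sin(eps) * np.sin(dir_angles),
            np.full(cfg.n_directions, np.cos(eps)),
        ]
    )  # n_directions x 3, unit vectors
    rotation_axes = axes_frame @ Q.T  # channel-space normals
    if cfg.rotation_amp > 0:
        # minimal rotation taking e3 to the tilted axis keeps the in-plane
        # phase frame common to all directions (the first two components are
        # consistent across submovements; only the axis tilts)
        e1, e2, e3 = np.eye(3)
        for te, sp, di in zip(ev_times, ev_speeds, dir_idx):
            n_ax = axes_frame[di]
            k_ax = np.cross(e3, n_ax)
            s_n = np.linalg.norm(k_ax)
            c_n = float(e3 @ n_ax)
            if s_n < 1e-12:
                R = np.eye(3)
            else:
                k_ax = k_ax / s_n
                K = np.array(
                    [[0, -k_ax[2], k_ax[1]], [k_ax[2], 0, -k_ax[0]], [-k_ax[1], k_ax[0], 0]]
                )
                R = np.eye(3) + s_n * K + (1 - c_n) * (K @ K)
            u3 = R @ e1
            v3 = R @ e2
            r = cfg.rotation_amp * np.sqrt(sp / cfg.speed_scale)
            env = np.exp(-0.5 * ((t - te) / cfg.rotation_env_sigma) ** 2)
            phase = 2 * np.pi * cfg.rotation_freq * (t - te)
            coords = (r * env)[:, None] * (
                np.cos(phase)[:, None] * u3[None, :] + np.sin(phase)[:, None] * v3[None, :]
            )
            lfp_mat += coords @ Q.T

    if cfg.white_amp > 0:
        lfp_mat += cfg.white_amp * rng.standard_normal((n_t, cfg.n_channels))
    if cfg.pink_amp > 0:
        for c in range(cfg.n_channels):
            lfp_mat[:, c] += cfg.pink_amp * _pink_noise(rng, n_t)
    if cfg.common_amp > 0:
        lfp_mat += cfg.common_amp * _pink_noise(rng, n_t)[:, None]

    lfp = LfpRecording(
        samples=lfp_mat,
        fs=fs,
        channel_ids=[f"ch{c + 1}" for c in range(cfg.n_channels)],
        t_start=0.0,
        area_labels=["M1" if c < cfg.n_channels // 2 else "PMv" for c in range(cfg.n_channels)],
    )
    truth = GroundTruth(
        kernels=kernels,
        lags=lags,
        rates=rates,
        event_times=np.asarray(ev_times),
        event_speeds=ev_speeds,
        event_directions=ev_dirs,
        rotation_frame=Q,
        rotation_axes=rotation_axes,
        source_waveforms=sources,
        channel_mixing=mixing,
    )
    return spikes, lfp, kin, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def default_config(seed: int) -> GeneratorConfig:
    """The bundled-fixture conditions: both pipelines exercised at once."""
    return GeneratorConfig(seed=seed)


def miso_config(seed: int, duration: float = 300.0) -> GeneratorConfig:
    """Spike-driven LFP only: every non-spike component off.

    Any event-correlated background (noise or the rotational component)
    biases the MISO kernels the same way correlated unrecorded neurons do,
    so kernel-recovery runs exclude them.
    """
    return GeneratorConfig(
        seed=seed, duration=duration, rotation_amp=0.0, white_amp=0.0,
        pink_amp=0.0, common_amp=0.0,
    )


def rotation_config(seed: int, duration: float = 120.0) -> GeneratorConfig:
    """Rotation-dominant conditions for areal-velocity analyses.

    Spike-kernel and background amplitudes are kept small enough that the
    direction-tilt component of the rotational LMP (variance of order
    rotation_amp^2 * sin^2(tilt)) is the third principal component of the
    low-passed LFP — the structure in which the rotation axis, and hence
    submovement direction, is readable from the 3-PC areal-velocity vector.
    """
    return GeneratorConfig(
        seed=seed, duration=duration, rotation_amp=1.2, kernel_amp=0.03,
        white_amp=0.05, pink_amp=0.05,
    )


def default_fixture():
    """The committed small dataset (120 s, 6 units, 8 channels, fixed seed)."""
    return generate(default_config(FIXTURE_SEED))
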
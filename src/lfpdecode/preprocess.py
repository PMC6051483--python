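"""Shared signal preprocessing: LMP filtering, binning, derivatives, PCA.

The local motor potential (LMP) is the <5 Hz component of the LFP; it is
extracted with a zero-phase (forward-backward) Butterworth low-pass so that
phase-sensitive downstream quantities (areal velocity in particular) are not
distorted. Derivatives use central differences: local, artifact-robust, and
consistent with a real-time FIR implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import LfpRecording, SpikeTrainSet, ValidationError

__all__ = [
    "BinnedRates",
    "PcaBasis",
    "lowpass_lmp",
    "bandpass",
    "bin_spikes",
    "time_derivative",
    "fit_pca",
    "project",
    "resample_to_bins",
]


@dataclass
class BinnedRates:
    """Time-bin x unit matrix of spike counts or rates.

    ``values`` holds counts when ``is_rate`` is False (then the column sums
    equal the per-unit spike totals) and Hz otherwise.
    """

    values: np.ndarray
    bin_width: float
    t_start: float
    unit_ids: list
    is_rate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (bin x unit)")
        if not self.bin_width > 0:
            raise ValidationError("bin_width must be positive")
        if len(self.unit_ids) != self.values.shape[1]:
            raise ValidationError("unit_ids length must match column count")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Bin-center times in seconds."""
        return self.t_start + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def to_rates(self) -> "BinnedRates":
        if self.is_rate:
            return self
        return BinnedRates(
            values=self.values / self.bin_width,
            bin_width=self.bin_width,
            t_start=self.t_start,
            unit_ids=list(self.unit_ids),
            is_rate=True,
        )


@dataclass
class PcaBasis:
    """Orthonormal channel-space principal components.

    ``components`` is n_components x n_channels with rows orthonormal and
    ordered by descending explained variance; ``mean`` is the per-channel
    mean removed before fitting. Signs follow a deterministic convention:
    the largest-magnitude coefficient of each component is positive.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_fractions: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance_fractions = np.asarray(
            self.explained_variance_fractions, dtype=float
        )
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-10):
            raise ValidationError("components must be orthonormal")
        if self.explained_variance_fractions.sum() > 1 + 1e-10:
            raise ValidationError("variance fractions must sum to <= 1")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def lowpass_lmp(lfp: LfpRecording, cutoff_hz: float = 5.0, order: int = 4) -> LfpRecording:
    """Zero-phase Butterworth low-pass per channel (LMP extraction).

    Forward-backward application squares the magnitude response and cancels
    phase; output length equals input length.
    """
    if not cutoff_hz < lfp.fs / 2:
        raise ValidationError(f"cutoff {cutoff_hz} Hz must be below Nyquist {lfp.fs / 2} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=lfp.fs, output="sos")
    out = signal.sosfiltfilt(sos, lfp.samples, axis=0)
    return lfp.copy_with(out)


def bandpass(
    lfp: LfpRecording, f_lo: float, f_hi: float, order: int = 4
) -> LfpRecording:
    """Zero-phase band-pass (low-pass when ``f_lo`` is 0)."""
    if not (0 <= f_lo < f_hi < lfp.fs / 2):
        raise ValidationError(f"invalid band ({f_lo}, {f_hi}) Hz for fs={lfp.fs} Hz")
    if f_lo == 0:
        sos = signal.butter(order, f_hi, btype="low", fs=lfp.fs, output="sos")
    else:
        sos = signal.butter(order, [f_lo, f_hi], btype="band", fs=lfp.fs, output="sos")
    return lfp.copy_with(signal.sosfiltfilt(sos, lfp.samples, axis=0))


# ---------------------------------------------------------------------------
# binning / resampling
# ---------------------------------------------------------------------------


def bin_spikes(
    spikes: SpikeTrainSet, bin_width: float = 0.01, align_to: float | None = None
) -> BinnedRates:
    """Count spikes in half-open bins [t, t+bin_width) tiling the recording.

    Count conservation is exact: a spike landing exactly on ``t_stop`` is
    assigned to the final bin.
    """
    if not bin_width > 0:
        raise ValidationError("bin_width must be positive")
    t0 = spikes.t_start if align_to is None else align_to
    n_bins = max(1, int(np.ceil((spikes.t_stop - t0) / bin_width - 1e-12)))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    counts = np.empty((n_bins, spikes.n_units))
    for j, t in enumerate(spikes.spike_times):
        counts[:, j], _ = np.histogram(t, bins=edges)
    return BinnedRates(values=counts, bin_width=bin_width, t_start=t0, unit_ids=list(spikes.unit_ids))


def resample_to_bins(lfp: LfpRecording, bin_width: float) -> LfpRecording:
    """Average LFP samples within consecutive bins of ``bin_width`` seconds.

    Requires an integer number of samples per bin (no fractional resampling).
    Returns a recording at fs = 1/bin_width.
    """
    n_per = bin_width * lfp.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValidationError(
            f"bin_width {bin_width} s is not an integer multiple of the sample interval"
        )
    n_per = int(round(n_per))
    if n_per == 1:
        return lfp
    n_bins = lfp.n_samples // n_per
    x = lfp.samples[: n_bins * n_per].reshape(n_bins, n_per, lfp.n_channels).mean(axis=1)
    return LfpRecording(
        samples=x,
        fs=1.0 / bin_width,
        channel_ids=list(lfp.channel_ids),
        t_start=lfp.t_start,
        area_labels=lfp.area_labels,
    )


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------


def time_derivative(lfp: LfpRecording) -> LfpRecording:
    """Per-channel time derivative (units per second).

    Central differences in the interior (O(h^2)), one-sided at the ends.
    """
    if lfp.n_samples < 3:
        raise ValidationError("need at least 3 samples for a derivative")
    out = np.gradient(lfp.samples, 1.0 / lfp.fs, axis=0)
    return lfp.copy_with(out)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def fit_pca(lfp: LfpRecording, n_components: int) -> PcaBasis:
    """PCA of the channel covariance over the full provided span.

    Per-channel means are removed; variances are not normalized, preserving
    the amplitude information that the areal-velocity/speed relationship
    relies on. Components are sign-fixed (largest-magnitude coefficient
    positive) for reproducibility.
    """
    if n_components > lfp.n_channels:
        raise ValidationError("n_components exceeds channel count")
    x = lfp.samples
    var = x.var(axis=0)
    zero = np.where(var <= 1e-30 * max(var.max(), 1.0))[0]
    if zero.size:
        names = [lfp.channel_ids[i] for i in zero]
        raise ValidationError(f"zero-variance channels: {names}")
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD: right singular vectors are the channel-space components
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2 / xc.shape[0]
    comps = vt[:n_components]
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PcaBasis(
        mean=mean,
        components=comps,
        explained_variance_fractions=ev[:n_components] / ev.sum(),
    )


def project(lfp: LfpRecording, basis: PcaBasis) -> LfpRecording:
    """Project onto a PCA basis; channels become ``pc1..pcK`` scores."""
    scores = (lfp.samples - basis.mean) @ basis.components.T
    ids = [f"pc{i + 1}" for i in range(basis.n_components)]
    return lfp.copy_with(scores, channel_ids=ids)
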
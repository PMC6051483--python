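"""Firing-rate estimation from multichannel LFP via SRSP decomposition.

The per-unit SRSP matrix (channel x lag) is low rank: across an electrode
array the kernel of one neuron is well approximated by a mixture of a few
(typically 3) source waveforms. Per unit we therefore

1. decompose the SRSP matrix by SVD into orthonormal lag-space PC waveforms
   and channel loadings,
2. form *source projections* — the least-squares demixing (pseudoinverse of
   the loadings) that recovers each source's time course from the
   multichannel LFP,
3. Wiener-deconvolve each source signal by its PC waveform,
   G(f) = H*(f) / (|H(f)|^2 + nsr),
4. combine the deconvolved sources into one rate estimate by ordinary least
   squares against training rates (the only supervised step), and
5. collapse the whole linear chain into a bank of acausal FIR filters over
   LFP channels, so that at run time rate estimation is pure FIR filtering
   plus an offset — cheap enough for real-time, low-power hardware.

Estimates are linear in the LFP and may go negative; clipping is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import LfpRecording, ValidationError
from .miso import SrspModel
from .preprocess import BinnedRates, bin_spikes, resample_to_bins

__all__ = [
    "SrspBasis",
    "RateDecoder",
    "decompose_srsp",
    "build_rate_decoder",
    "estimate_rates",
    "stability_report",
]


@dataclass
class SrspBasis:
    """Per-unit principal-component decomposition of the SRSP matrices.

    ``waveforms[u]`` is n_sources x n_lags (orthonormal rows, lag space);
    ``loadings[u]`` is n_channels x n_sources (channel mixing weights);
    ``source_projections[u]`` = pinv(loadings[u]), the channel mixtures whose
    dot product with the LFP best recovers each source's time course.
    """

    waveforms: np.ndarray
    loadings: np.ndarray
    source_projections: np.ndarray
    explained_variance_fractions: np.ndarray
    lags: np.ndarray
    bin_width: float
    unit_ids: list
    channel_ids: list

    @property
    def n_sources(self) -> int:
        return self.waveforms.shape[1]


@dataclass
class RateDecoder:
    """Per-unit acausal FIR filter bank mapping LFP to firing rate (Hz).

    ``filters`` is unit x channel x tap; ``filter_lags`` the tap lag grid in
    seconds (length >= the SRSP lag span). The estimate for unit u is

        r_u[t] = offset_u + sum_c (filters[u, c] * (lfp_c - mean_c))[t]
    """

    filters: np.ndarray
    filter_lags: np.ndarray
    offsets: np.ndarray
    channel_means: np.ndarray
    nsr: float
    bin_width: float
    unit_ids: list
    channel_ids: list

    def __post_init__(self):
        if not np.all(np.isfinite(self.filters)):
            raise ValidationError("filter coefficients must be finite")


def decompose_srsp(model: SrspModel, n_sources: int = 3) -> SrspBasis:
    """SVD decomposition of each unit's channel x lag SRSP matrix.

    Raises if any unit's SRSP matrix has numerical rank below ``n_sources``.
    Components are sign-fixed (largest-magnitude waveform sample positive).
    """
    n_units, n_channels, n_lags = model.kernels.shape
    if n_sources > n_channels:
        raise ValidationError("n_sources exceeds channel count")
    waveforms = np.empty((n_units, n_sources, n_lags))
    loadings = np.empty((n_units, n_channels, n_sources))
    projections = np.empty((n_units, n_sources, n_channels))
    evf = np.empty((n_units, n_sources))
    for u in range(n_units):
        M = model.kernels[u]
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        if n_sources > rank:
            raise ValidationError(
                f"unit {model.unit_ids[u]!r}: requested {n_sources} sources but "
                f"SRSP rank is {rank}"
            )
        W = Vt[:n_sources]
        A = U[:, :n_sources] * s[:n_sources]
        for k in range(n_sources):
            j = np.argmax(np.abs(W[k]))
            if W[k, j] < 0:
                W[k] = -W[k]
                A[:, k] = -A[:, k]
        waveforms[u] = W
        loadings[u] = A
        projections[u] = np.linalg.pinv(A)
        evf[u] = s[:n_sources] ** 2 / np.sum(s**2)
    return SrspBasis(
        waveforms=waveforms,
        loadings=loadings,
        source_projections=projections,
        explained_variance_fractions=evf,
        lags=model.lags,
        bin_width=model.bin_width,
        unit_ids=list(model.unit_ids),
        channel_ids=list(model.channel_ids),
    )


def _wiener_inverse(w: np.ndarray, k_pre: int, n_out_pre: int, n_out_post: int, nsr: float):
    """Acausal Wiener inverse kernel of a lag-space waveform.

    ``w`` spans lags -k_pre .. len(w)-1-k_pre; the returned kernel g spans
    -n_out_pre .. n_out_post and satisfies (g * w)(f) ~ |W|^2/(|W|^2+nsr).
    """
    if not np.any(w):
        raise ValidationError("PC waveform is identically zero")
    if nsr < 0:
        raise ValidationError("nsr must be >= 0")
    n_fft = 1 << max(8, int(np.ceil(np.log2(8 * (len(w) + n_out_pre + n_out_post)))))
    buf = np.zeros(n_fft)
    for j, val in enumerate(w):
        buf[(j - k_pre) % n_fft] = val
    W = np.fft.rfft(buf)
    G = np.conj(W) / (np.abs(W) ** 2 + nsr)
    g = np.fft.irfft(G, n_fft)
    out = np.concatenate([g[-n_out_pre:] if n_out_pre else g[:0], g[: n_out_post + 1]])
    # raised-cosine (Tukey) taper against truncation ripple: flat centre,
    # cosine roll-off over the outer quarter of the taps on each side
    return out * signal.windows.tukey(len(out), alpha=0.5)


def _filter_acausal(x: np.ndarray, h: np.ndarray, k_pre: int) -> np.ndarray:
    """y[t] = sum_l h[l] x[t-l] with h spanning lags -k_pre..len(h)-1-k_pre."""
    full = signal.fftconvolve(x, h)
    return full[k_pre : k_pre + len(x)]


def build_rate_decoder(
    basis: SrspBasis,
    lfp_train: LfpRecording,
    rates_train: BinnedRates,
    nsr: float = 0.01,
) -> RateDecoder:
    """Build the per-unit FIR rate decoder from a fitted SRSP basis.

    ``nsr`` is the Wiener noise-to-signal constant added to |H|^2 in the
    deconvolution denominator; it trades inversion sharpness against noise
    amplification (nsr -> inf collapses the estimate to the mean rate).
    """
    if nsr < 0:
        raise ValidationError("nsr must be >= 0")
    lfp_b = resample_to_bins(lfp_train, basis.bin_width)
    n = min(lfp_b.n_samples, rates_train.n_bins)
    x = lfp_b.samples[:n]
    target = rates_train.to_rates().values[:n]
    means = x.mean(axis=0)
    xc = x - means

    n_lags = basis.lags.size
    k_pre_w = int(round(-basis.lags[0] / basis.bin_width))
    # filter lag span: twice the SRSP span, symmetric
    k_half = n_lags - 1
    filter_lags = np.arange(-k_half, k_half + 1) * basis.bin_width
    n_units = len(basis.unit_ids)
    n_ch = len(basis.channel_ids)
    filters = np.zeros((n_units, n_ch, 2 * k_half + 1))
    offsets = np.zeros(n_units)

    trim = slice(k_half, max(k_half + 1, n - k_half))
    for u in range(n_units):
        P = basis.source_projections[u]  # (S, C)
        src = xc @ P.T  # (n, S) source signals
        S = basis.n_sources
        g_bank = []
        deconv = np.empty((n, S))
        for s_i in range(S):
            g = _wiener_inverse(basis.waveforms[u, s_i], k_pre_w, k_half, k_half, nsr)
            g_bank.append(g)
            deconv[:, s_i] = _filter_acausal(src[:, s_i], g, k_half)
        # supervised combination: OLS of training rates on deconvolved sources
        X = np.column_stack([np.ones(n), deconv])[trim]
        beta, *_ = np.linalg.lstsq(X, target[trim, u], rcond=None)
        offsets[u] = beta[0]
        for s_i in range(S):
            filters[u] += beta[1 + s_i] * P[s_i][:, None] * g_bank[s_i][None, :]
    return RateDecoder(
        filters=filters,
        filter_lags=filter_lags,
        offsets=offsets,
        channel_means=means,
        nsr=nsr,
        bin_width=basis.bin_width,
        unit_ids=list(basis.unit_ids),
        channel_ids=list(basis.channel_ids),
    )


def estimate_rates(
    decoder: RateDecoder, lfp: LfpRecording, clip_nonnegative: bool = False
) -> BinnedRates:
    """Estimate per-unit firing rates (Hz) from LFP by pure FIR filtering.

    The output at bin t depends only on LFP within the filter's lag window
    around t (real-time capable with a fixed latency of the acausal extent).
    Estimates are linear in the LFP and may be negative unless
    ``clip_nonnegative`` is set.
    """
    if list(lfp.channel_ids) != list(decoder.channel_ids):
        raise ValidationError("LFP channels do not match the decoder")
    lfp_b = resample_to_bins(lfp, decoder.bin_width)
    xc = lfp_b.samples - decoder.channel_means
    n = xc.shape[0]
    k_pre = int(round(-decoder.filter_lags[0] / decoder.bin_width))
    out = np.tile(decoder.offsets, (n, 1))
    for u in range(len(decoder.unit_ids)):
        acc = np.zeros(n)
        for c in range(len(decoder.channel_ids)):
            acc += _filter_acausal(xc[:, c], decoder.filters[u, c], k_pre)
        out[:, u] += acc
    if clip_nonnegative:
        np.maximum(out, 0.0, out=out)
    return BinnedRates(
        values=out,
        bin_width=decoder.bin_width,
        t_start=lfp_b.t_start,
        unit_ids=list(decoder.unit_ids),
        is_rate=True,
    )


def _smooth_rates(counts: BinnedRates, sigma_s: float = 0.05) -> np.ndarray:
    """Gaussian-smoothed firing rates (Hz) from binned counts."""
    rates = counts.to_rates().values
    sig = sigma_s / counts.bin_width
    half = int(np.ceil(4 * sig))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
    k /= k.sum()
    out = np.empty_like(rates)
    for j in range(rates.shape[1]):
        out[:, j] = signal.fftconvolve(rates[:, j], k)[half : half + rates.shape[0]]
    return out


def stability_report(
    decoder: RateDecoder,
    sessions: list,
    events: list,
    window: tuple = (-0.5, 0.5),
) -> pd.DataFrame:
    """Cross-session decoding stability of a fixed decoder.

    For each session ``(spikes, lfp)`` with alignment times ``events[i]``:
    per-unit Pearson R between estimated and (Gaussian-smoothed) actual
    rates, and the correlation of event-triggered averages of estimated vs
    actual rates. Sessions without events get NaN for the aligned metric.
    """
    import warnings

    rows = []
    for i, (spikes, lfp) in enumerate(sessions):
        est = estimate_rates(decoder, lfp)
        counts = bin_spikes(spikes, decoder.bin_width, align_to=est.t_start)
        n = min(est.n_bins, counts.n_bins)
        actual = _smooth_rates(
            BinnedRates(counts.values[:n], counts.bin_width, counts.t_start, counts.unit_ids)
        )
        est_v = est.values[:n]
        ev = np.asarray(events[i], dtype=float)
        k_lo = int(round(window[0] / decoder.bin_width))
        k_hi = int(round(window[1] / decoder.bin_width))
        for j, uid in enumerate(decoder.unit_ids):
            sd = actual[:, j].std()
            r_inst = (
                float(np.corrcoef(est_v[:, j], actual[:, j])[0, 1]) if sd > 0 else np.nan
            )
            if ev.size == 0:
                warnings.warn(f"session {i}: no alignment events; aligned R is NaN")
                r_aligned = np.nan
            else:
                idx = np.round((ev - est.t_start) / decoder.bin_width).astype(int)
                idx = idx[(idx + k_lo >= 0) & (idx + k_hi < n)]
                if idx.size == 0:
                    r_aligned = np.nan
                else:
                    lag_idx = idx[:, None] + np.arange(k_lo, k_hi + 1)[None, :]
                    avg_est = est_v[lag_idx, j].mean(axis=0)
                    avg_act = actual[lag_idx, j].mean(axis=0)
                    r_aligned = (
                        float(np.corrcoef(avg_est, avg_act)[0, 1])
                        if avg_act.std() > 0 and avg_est.std() > 0
                        else np.nan
                    )
            rows.append(
                {"session": i, "unit_id": uid, "r_instantaneous": r_inst, "r_aligned": r_aligned}
            )
    return pd.DataFrame(rows)
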
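"""Multiple-input single-output (MISO) identification of spike->LFP kernels.

Each low-frequency LFP channel is modelled as a sum of the recorded spike
trains convolved with acausal impulse responses — the spike-related slow
potentials (SRSPs) — plus a DC offset:

    y_c[t] = b_c + sum_u sum_{l=-K_pre}^{K_post} h_{u,c}[l] x_u[t - l]

where x_u are binned spike counts and lag l < 0 is LFP *preceding* the spike
(acausality). The least-squares normal equations are assembled from input
auto- and cross-correlation functions: the Gram matrix is the block-Toeplitz
matrix of full (zero-padded, biased) cross-correlations minus the outer
products of the 2(K_pre+K_post) boundary rows whose lag window leaves the
recorded span. Those boundary bins are thereby excluded from the objective
and the solution matches an explicit lagged-design-matrix least squares to
machine precision. Unlike a spike-triggered average, the joint solve removes
the contribution of correlated *recorded* spike trains from each unit's
kernel; correlated unrecorded neurons cannot be accounted for.

The Gram depends only on the inputs, so one Cholesky factorization serves
all output channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .io import LfpRecording, ValidationError
from .preprocess import BinnedRates, resample_to_bins

__all__ = ["SrspModel", "fit_miso", "predict_lfp", "evaluate_fit"]


class SingularFitError(np.linalg.LinAlgError):
    """Normal matrix is singular; re-fit with a ridge penalty."""


@dataclass
class SrspModel:
    """Fitted per-(unit, channel) acausal impulse responses.

    ``kernels`` is unit x channel x lag (LFP units per spike count); ``lags``
    the lag grid in seconds from -t_pre to +t_post at ``bin_width`` spacing
    (negative lags = LFP preceding the spike). ``vaf`` holds the per-channel
    variance accounted for on the fitted span.
    """

    kernels: np.ndarray
    lags: np.ndarray
    bin_width: float
    offsets: np.ndarray
    ridge: float
    unit_ids: list
    channel_ids: list
    vaf: np.ndarray

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=float)
        if not np.all(np.isfinite(self.kernels)):
            raise ValidationError("kernels contain non-finite values")
        if self.kernels.shape[2] != self.lags.size:
            raise ValidationError("lag grid length must match kernel lag axis")

    @property
    def n_lags_pre(self) -> int:
        return int(round(-self.lags[0] / self.bin_width))

    @property
    def n_lags_post(self) -> int:
        return int(round(self.lags[-1] / self.bin_width))


def _full_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """r[d] = sum_s a[s] * b[s + d] for d in [-max_lag, max_lag]."""
    r = signal.correlate(b, a, mode="full", method="auto")
    # correlate(b, a)[k] = sum_s a[s] b[s + k - (len(a) - 1)]
    mid = len(a) - 1
    return r[mid - max_lag : mid + max_lag + 1]


def _lagged_rows(counts: np.ndarray, t_rows: np.ndarray, k_pre: int, k_post: int) -> np.ndarray:
    """Design-matrix rows x_u[t - l] for the given bin indices, zero-padded."""
    n_bins, n_units = counts.shape
    lags = np.arange(-k_pre, k_post + 1)
    idx = t_rows[:, None] - lags[None, :]  # (rows, L)
    valid = (idx >= 0) & (idx < n_bins)
    idx = np.clip(idx, 0, n_bins - 1)
    rows = counts[idx, :] * valid[:, :, None]  # (rows, L, units)
    # feature order: (unit major, lag minor) to match kernel layout
    return rows.transpose(0, 2, 1).reshape(len(t_rows), n_units * len(lags))


def _assemble_normal_equations(
    counts: np.ndarray, lfp_bins: np.ndarray, k_pre: int, k_post: int
):
    """Correlation-function assembly of the windowed normal equations.

    Returns (G, B, n_valid) with G the (n_features+1) square Gram including a
    trailing DC row/column and B the (n_features+1, n_channels) RHS, both
    exactly equal to the explicit lagged design-matrix products over the
    interior rows t in [k_post, n_bins - k_pre).
    """
    n_bins, n_units = counts.shape
    n_lags = k_pre + k_post + 1
    nf = n_units * n_lags

    # block-Toeplitz part from full biased cross-correlations
    G = np.empty((nf + 1, nf + 1))
    for u in range(n_units):
        for v in range(n_units):
            r = _full_xcorr(counts[:, u], counts[:, v], n_lags - 1)
            # block[i, j] = r[i - j] with i, j lag indices (ascending lag)
            mid = n_lags - 1
            block = linalg.toeplitz(r[mid : 2 * mid + 1], r[mid::-1])
            G[u * n_lags : (u + 1) * n_lags, v * n_lags : (v + 1) * n_lags] = block

    # subtract boundary rows (lag window leaves the span) -> windowed objective
    edge_t = np.concatenate(
        [np.arange(-k_pre, k_post), np.arange(n_bins - k_pre, n_bins + k_post)]
    )
    E = _lagged_rows(counts, edge_t, k_pre, k_post)
    G[:nf, :nf] -= E.T @ E

    # DC column over the interior rows
    n_valid = n_bins - k_pre - k_post
    if n_valid <= 0:
        raise ValidationError("overlapping span shorter than the lag window")
    dc = np.empty(nf)
    cs = np.vstack([np.zeros(n_units), np.cumsum(counts, axis=0)])  # (n_bins+1, units)
    lags = np.arange(-k_pre, k_post + 1)
    for u in range(n_units):
        lo = np.clip(k_post - lags, 0, n_bins)
        hi = np.clip(n_bins - k_pre - lags, 0, n_bins)
        dc[u * n_lags : (u + 1) * n_lags] = cs[hi, u] - cs[lo, u]
    G[:nf, nf] = dc
    G[nf, :nf] = dc
    G[nf, nf] = n_valid

    # RHS: cross-correlation of each input with each LFP channel, windowed
    n_ch = lfp_bins.shape[1]
    B = np.empty((nf + 1, n_ch))
    in_span = edge_t[(edge_t >= 0) & (edge_t < n_bins)]
    E_in = _lagged_rows(counts, in_span, k_pre, k_post)
    for c in range(n_ch):
        y = lfp_bins[:, c]
        g = np.empty(nf)
        m = max(k_pre, k_post)
        for u in range(n_units):
            g[u * n_lags : (u + 1) * n_lags] = _full_xcorr(counts[:, u], y, m)[
                m - k_pre : m + k_post + 1
            ]
        g -= E_in.T @ y[in_span]
        B[:nf, c] = g
        B[nf, c] = y[k_post : n_bins - k_pre].sum()
    return G, B, n_valid


def fit_miso(
    rates: BinnedRates,
    lfp: LfpRecording,
    t_pre: float = 0.5,
    t_post: float = 0.5,
    ridge: float = 0.0,
) -> SrspModel:
    """Fit the MISO spike->LFP model; one joint solve per output channel.

    Parameters
    ----------
    rates
        Binned spike counts on the model's bin grid.
    lfp
        LFP recording; decimated (bin-averaged) to the count bin width.
    t_pre, t_post
        Acausal kernel extent in seconds before/after the spike. The default
        +-0.5 s covers a full 1-4 Hz submovement cycle either side.
    ridge
        Ridge penalty lambda added to the kernel block of the normal matrix
        (the DC term is not penalized). With the default 0, a singular system
        raises :class:`SingularFitError` carrying a suggested lambda.
    """
    if rates.is_rate:
        raise ValidationError("fit_miso expects spike counts, not rates")
    lfp_b = resample_to_bins(lfp, rates.bin_width)
    # align the overlapping span on the common bin grid
    n = min(rates.n_bins, lfp_b.n_samples)
    if abs(rates.t_start - lfp_b.t_start) > 1e-9:
        raise ValidationError("rates and LFP must share t_start on the bin grid")
    counts = rates.values[:n]
    y = lfp_b.samples[:n]

    k_pre = int(round(t_pre / rates.bin_width))
    k_post = int(round(t_post / rates.bin_width))
    n_lags = k_pre + k_post + 1
    if n - k_pre - k_post < 10 * n_lags:
        raise ValidationError(
            f"overlapping span ({n} bins) must be >= 10x the lag window ({n_lags} bins)"
        )

    G, B, _ = _assemble_normal_equations(counts, y, k_pre, k_post)
    nf = G.shape[0] - 1
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    if ridge > 0:
        G = G.copy()
        G[np.arange(nf), np.arange(nf)] += ridge
    try:
        cho = linalg.cho_factor(G)
        coef = linalg.cho_solve(cho, B)
    except np.linalg.LinAlgError:
        if ridge == 0:
            scale = np.trace(G[:nf, :nf]) / nf
            raise SingularFitError(
                "normal matrix is singular; re-fit with a ridge penalty "
                f"(try ridge around {1e-6 * scale:.3g}-{1e-2 * scale:.3g})"
            ) from None
        raise

    n_units = counts.shape[1]
    kernels = coef[:nf].T.reshape(lfp_b.n_channels, n_units, n_lags).transpose(1, 0, 2)
    offsets = coef[nf]
    lags = np.arange(-k_pre, k_post + 1) * rates.bin_width

    model = SrspModel(
        kernels=kernels,
        lags=lags,
        bin_width=rates.bin_width,
        offsets=offsets,
        ridge=ridge,
        unit_ids=list(rates.unit_ids),
        channel_ids=list(lfp_b.channel_ids),
        vaf=np.zeros(lfp_b.n_channels),
    )
    # diagnostics on the fitted (interior) span
    pred = predict_lfp(model, rates)
    sl = slice(k_post, n - k_pre)
    res = y[sl] - pred.samples[:n][sl]
    denom = y[sl].var(axis=0)
    model.vaf = np.where(denom > 0, 1.0 - res.var(axis=0) / np.where(denom > 0, denom, 1.0), -np.inf)
    return model


def predict_lfp(model: SrspModel, rates: BinnedRates) -> LfpRecording:
    """Acausal convolution of each spike train with each kernel, plus offset.

    Bins within one lag window of either end are edge bins: their prediction
    is missing the out-of-span part of the convolution.
    """
    if list(rates.unit_ids) != list(model.unit_ids):
        raise ValidationError("unit_ids do not match the fitted model")
    if rates.is_rate:
        raise ValidationError("predict_lfp expects spike counts, not rates")
    counts = rates.values
    n = counts.shape[0]
    k_pre = model.n_lags_pre
    out = np.tile(model.offsets, (n, 1))
    for u in range(len(model.unit_ids)):
        x = counts[:, u]
        if not x.any():
            continue
        for c in range(len(model.channel_ids)):
            full = signal.fftconvolve(x, model.kernels[u, c])
            out[:, c] += full[k_pre : k_pre + n]
    return LfpRecording(
        samples=out,
        fs=1.0 / model.bin_width,
        channel_ids=list(model.channel_ids),
        t_start=rates.t_start,
    )


def evaluate_fit(model: SrspModel, rates: BinnedRates, lfp: LfpRecording):
    """Per-channel Pearson R and variance accounted for on a held-out span.

    The span should be disjoint from the fitting span for an unbiased
    estimate (the caller owns the split). Edge bins are excluded.
    """
    lfp_b = resample_to_bins(lfp, model.bin_width)
    n = min(rates.n_bins, lfp_b.n_samples)
    pred = predict_lfp(model, rates).samples[:n]
    y = lfp_b.samples[:n]
    sl = slice(model.n_lags_post, n - model.n_lags_pre)
    pred, y = pred[sl], y[sl]
    if np.any(y.var(axis=0) == 0):
        raise ValidationError("zero-variance LFP channel: correlation undefined")
    r = np.array(
        [np.corrcoef(pred[:, c], y[:, c])[0, 1] for c in range(y.shape[1])]
    )
    vaf = 1.0 - (y - pred).var(axis=0) / y.var(axis=0)
    return r, vaf
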
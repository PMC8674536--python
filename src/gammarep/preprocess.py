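"""Raw session arrays -> analysis-ready responses.

dMUA denoising (per-site minimum subtraction over 10 ms bins), Gaussian rate
smoothing, session-baseline normalization, epoching for spectral estimation,
and unipolar / common-average / bipolar site derivations.

Conventions: bins and epochs are half-open ``[start, stop)`` in seconds;
sample ``i`` covers ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "EpochSet",
    "NormalizedResponse",
    "compute_dmua",
    "smooth_rate",
    "baseline_normalize",
    "epoch",
    "derive_sites",
]


@dataclass
class EpochSet:
    """Non-overlapping epochs cut from a fixed trial window.

    ``data`` has shape (trial, epoch, site, sample); epochs are left-aligned
    within ``window`` and each spans ``epoch_len`` seconds.
    """

    data: np.ndarray
    fs: float
    epoch_len: float
    window: tuple
    origin: str = "custom"

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]


@dataclass
class NormalizedResponse:
    """Trial-wise responses divided by the session-average baseline per site."""

    values: np.ndarray
    baseline_stat: np.ndarray
    bad_sites: np.ndarray


def _window_mask(time, window):
    return (time >= window[0]) & (time < window[1])


def compute_dmua(mua: np.ndarray, time: np.ndarray, fs: float,
                 bin_ms: float = 10.0, window=(-1.0, 1.5)):
    """Denoised MUA: 10 ms bin means with the per-site minimum subtracted.

    The MUA envelope is averaged in ``bin_ms`` windows over ``window``
    (default -1..1.5 s peri-stimulus) across all trials; the minimum binned
    value per site over all trials and bins, the best available estimate of
    the site's noise floor, is subtracted. The per-site minimum of the output
    is exactly 0.

    Returns ``(dmua, bin_centers)`` with ``dmua`` shaped (site, trial, bin).
    """
    if mua.ndim != 3:
        raise ValueError("mua must be (site, trial, time)")
    mask = _window_mask(time, window)
    if not mask.any():
        raise ValueError("analysis window outside the recorded time axis")
    seg = mua[:, :, mask]
    if seg.shape[1] == 0:
        raise ValueError("empty trial set")
    bin_len = int(round(bin_ms / 1000.0 * fs))
    n_bins = seg.shape[2] // bin_len
    seg = seg[:, :, : n_bins * bin_len]
    binned = seg.reshape(seg.shape[0], seg.shape[1], n_bins, bin_len).mean(axis=3)
    floor = binned.min(axis=(1, 2), keepdims=True)
    t0 = time[mask][0]
    centers = t0 + (np.arange(n_bins) + 0.5) * bin_len / fs
    return binned - floor, centers


def smooth_rate(dmua: np.ndarray, fs_bins: float, sd_ms: float = 20.0) -> np.ndarray:
    """Gaussian smoothing (SD ``sd_ms``) along the last axis, reflection-padded.

    Latency-sensitive analyses (first-significant-bin tests) must use the
    unsmoothed input; smoothing shifts apparent onsets.
    """
    if sd_ms <= 0:
        raise ValueError("sd_ms must be positive")
    sigma = sd_ms / 1000.0 * fs_bins
    return gaussian_filter1d(dmua, sigma=sigma, axis=-1, mode="reflect")


def baseline_normalize(numerator: np.ndarray, baseline: np.ndarray,
                       trial_axis: int = 1) -> NormalizedResponse:
    """Divide trial-wise responses by the session-average baseline per site.

    ``numerator`` is (site, trial, ...), ``baseline`` (site, trial, ...) with
    matching non-trial axes; the baseline is averaged over *all* trials of the
    session per site (never per trial) before division. Sites with a
    non-positive average baseline are flagged and set to NaN.
    """
    base = baseline.mean(axis=trial_axis, keepdims=True)
    bad = (base <= 0).any(axis=tuple(range(1, base.ndim)))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = numerator / base
    values[bad] = np.nan
    return NormalizedResponse(values=values, baseline_stat=np.squeeze(base, axis=trial_axis),
                              bad_sites=np.asarray(bad))


def epoch(signal: np.ndarray, time: np.ndarray, fs: float,
          window=(0.5, 1.5), epoch_len: float = 0.25,
          origin: str = "custom") -> EpochSet:
    """Cut ``floor(window/epoch_len)`` non-overlapping, left-aligned epochs.

    ``signal`` is (site, trial, time); returns an :class:`EpochSet` with data
    (trial, epoch, site, sample).
    """
    span = window[1] - window[0]
    if epoch_len > span + 1e-12:
        raise ValueError("epoch_len exceeds the analysis window")
    n_samp = int(round(epoch_len * fs))
    n_ep = int(np.floor(span / epoch_len + 1e-9))
    start = int(np.searchsorted(time, window[0] - 1e-9))
    chunks = []
    for k in range(n_ep):
        sl = signal[:, :, start + k * n_samp: start + (k + 1) * n_samp]
        chunks.append(sl)
    data = np.stack(chunks, axis=0)  # epoch, site, trial, sample
    data = data.transpose(2, 0, 1, 3)
    return EpochSet(data=data, fs=fs, epoch_len=epoch_len, window=tuple(window),
                    origin=origin)


def derive_sites(lfp: np.ndarray, mode: str = "unipolar",
                 pairs=None) -> np.ndarray:
    """Re-reference the LFP: unipolar (identity), common_average, or bipolar.

    Bipolar derivations are sample-by-sample differences between the paired
    channels; each unipolar channel may enter at most one pair.
    """
    if mode == "unipolar":
        return lfp
    if mode == "common_average":
        return lfp - lfp.mean(axis=0, keepdims=True)
    if mode == "bipolar":
        if pairs is None:
            raise ValueError("bipolar derivation requires neighbor pairs")
        used: set = set()
        for a, b in pairs:
            if a in used or b in used:
                raise ValueError(f"channel used in two bipolar pairs: {(a, b)}")
            used.update((a, b))
        return np.stack([lfp[a] - lfp[b] for a, b in pairs], axis=0)
    raise ValueError(f"unknown derivation mode: {mode!r}")
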
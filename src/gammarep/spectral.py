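"""LFP power and MUA-LFP pairwise phase consistency (PPC).

Power is estimated per epoch with unit-energy tapers (Hann for 500 ms epochs,
DPSS multitapers for 250 ms epochs with +/-10 Hz smoothing), averaged over
tapers and then over within-trial epochs to give per-trial spectra. The FFT
length equals the epoch length (no zero padding), so the frequency grid is
1/epoch_len: 4 Hz for 250 ms epochs, 2 Hz for 500 ms.

The taper count follows K = 2*T*W (T = 0.25 s, W = 10 Hz -> 5 tapers). The
alternative reading K = 2TW - 1 is available via ``TaperConfig(k_rule=...)``.

PPC over N unit cross-spectra z_j is the average cosine of all pairwise phase
differences, computed from the resultant:

    PPC = (|sum_j z_j|^2 - N) / (N (N - 1))

which equals (2/(N(N-1))) * sum_{j<k} cos(theta_j - theta_k) exactly and is
unbiased by the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .preprocess import EpochSet

__all__ = [
    "TaperConfig",
    "HANN_500MS",
    "DPSS_250MS",
    "DPSS_ONSET",
    "PowerSpectrum",
    "PPCSpectrum",
    "taper_power",
    "cross_spectral_phases",
    "ppc",
    "ppc_brute_force",
    "mua_lfp_ppc",
]


@dataclass(frozen=True)
class TaperConfig:
    """Epoch length, taper family and (for DPSS) half-bandwidth in Hz."""

    epoch_len: float
    taper: str = "dpss"  # "dpss" | "hann"
    half_bandwidth: float = 10.0
    k_rule: str = "2TW"  # "2TW" | "2TW-1"
    name: str = ""

    @property
    def n_tapers(self) -> int:
        if self.taper == "hann":
            return 1
        tw = self.epoch_len * self.half_bandwidth
        k = int(round(2 * tw)) if self.k_rule == "2TW" else int(round(2 * tw)) - 1
        if k < 1:
            raise ValueError("epoch too short for the requested half-bandwidth")
        return k

    def tapers(self, n_samples: int) -> np.ndarray:
        """(taper, sample) array of unit-energy tapers."""
        if self.taper == "hann":
            w = windows.hann(n_samples, sym=False)
            w = w / np.sqrt(np.sum(w ** 2))
            return w[None, :]
        if self.taper == "dpss":
            nw = self.epoch_len * self.half_bandwidth
            tap = windows.dpss(n_samples, NW=nw, Kmax=self.n_tapers)
            return np.atleast_2d(tap)
        raise ValueError(f"unknown taper: {self.taper!r}")


HANN_500MS = TaperConfig(epoch_len=0.5, taper="hann", name="hann_500ms")
DPSS_250MS = TaperConfig(epoch_len=0.25, taper="dpss", half_bandwidth=10.0,
                         name="dpss_250ms_5tapers")
DPSS_ONSET = TaperConfig(epoch_len=0.25, taper="dpss", half_bandwidth=10.0,
                         name="dpss_onset_0to250ms")


@dataclass
class PowerSpectrum:
    """Per-trial power, (trial, site, freq); ``normalized`` flags ratios."""

    power: np.ndarray
    freqs: np.ndarray
    cfg: TaperConfig
    normalized: bool = False


@dataclass
class PPCSpectrum:
    """PPC per site and frequency; NaN where a site had no eligible pairing."""

    ppc: np.ndarray
    freqs: np.ndarray
    n_epochs: int
    pairing: list


def _check_cfg(epochs: EpochSet, cfg: TaperConfig) -> None:
    if abs(epochs.epoch_len - cfg.epoch_len) > 1e-9:
        raise ValueError(
            f"epoch length {epochs.epoch_len} inconsistent with config "
            f"{cfg.epoch_len}")


def _tapered_fft(data: np.ndarray, fs: float, cfg: TaperConfig):
    """rfft of tapered epochs; data (..., sample) -> (..., taper, freq)."""
    n = data.shape[-1]
    tap = cfg.tapers(n)
    x = data[..., None, :] * tap
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return spec, freqs


def taper_power(epochs: EpochSet, cfg: TaperConfig) -> PowerSpectrum:
    """Per-trial power spectra: |tapered FFT|^2 averaged over tapers, then
    over the trial's epochs. Input epochs are (trial, epoch, site, sample)."""
    _check_cfg(epochs, cfg)
    spec, freqs = _tapered_fft(epochs.data, epochs.fs, cfg)
    power = (np.abs(spec) ** 2).mean(axis=-2)  # over tapers
    power = power.mean(axis=1)  # over within-trial epochs -> (trial, site, freq)
    return PowerSpectrum(power=power, freqs=freqs, cfg=cfg)


def cross_spectral_phases(lfp_epochs: np.ndarray, mua_epochs: np.ndarray,
                          fs: float, cfg: TaperConfig) -> np.ndarray:
    """Unit-magnitude cross-spectra per epoch.

    Inputs are (epoch, sample) arrays for one LFP-MUA pair; the per-epoch
    cross-spectrum (summed over tapers) is divided by its magnitude, leaving
    phase-only complex values. Zero-magnitude bins become NaN and are
    excluded from downstream PPC averages.
    """
    if lfp_epochs.shape != mua_epochs.shape:
        raise ValueError("LFP and MUA epochs must have matching shapes")
    sl, _ = _tapered_fft(lfp_epochs, fs, cfg)
    sm, _ = _tapered_fft(mua_epochs, fs, cfg)
    cross = (sl * np.conj(sm)).sum(axis=-2)
    mag = np.abs(cross)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, cross / np.where(mag > 0, mag, 1.0),
                        np.nan + 0j)
    return unit


def ppc(unit_cross_spectra: np.ndarray) -> np.ndarray:
    """Pairwise phase consistency over the first axis of unit phasors.

    Closed form from the mean resultant; identical (to machine precision) to
    the brute-force average over all pairs of cos(theta_j - theta_k).
    NaN entries (zero-magnitude bins) are excluded per frequency.
    """
    z = np.asarray(unit_cross_spectra)
    valid = np.isfinite(z)
    n = valid.sum(axis=0)
    zs = np.where(valid, z, 0)
    s = np.abs(zs.sum(axis=0)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (s - n) / (n * (n - 1.0))
    return np.where(n >= 2, out, np.nan)


def ppc_brute_force(unit_cross_spectra: np.ndarray) -> np.ndarray:
    """Reference implementation: explicit sum over all epoch pairs."""
    z = np.asarray(unit_cross_spectra)
    n = z.shape[0]
    phases = np.angle(z)
    acc = np.zeros(z.shape[1:])
    for j in range(n):
        for k in range(j + 1, n):
            acc += np.cos(phases[j] - phases[k])
    return acc / (n * (n - 1) / 2.0)


def mua_lfp_ppc(lfp_epochs: EpochSet, mua_epochs: EpochSet,
                neighbors: list, cfg: TaperConfig,
                trial_indices=None) -> PPCSpectrum:
    """PPC spectrum per MUA site, averaged over its neighboring LFP sites.

    ``neighbors`` lists undirected (i, j) array-neighbor pairs; same-electrode
    combinations are excluded (spike bleed-in). Epochs are pooled over all
    trials of the group (``trial_indices`` optionally restricts the trials).
    Sites without an eligible neighbor come back as NaN rows.
    """
    _check_cfg(lfp_epochs, cfg)
    _check_cfg(mua_epochs, cfg)
    ld = lfp_epochs.data
    md = mua_epochs.data
    if trial_indices is not None:
        ld = ld[trial_indices]
        md = md[trial_indices]
    n_trials, n_ep, n_sites, n_samp = ld.shape
    adj: dict = {i: set() for i in range(n_sites)}
    for a, b in neighbors:
        if a == b:
            continue  # same-electrode pairs excluded
        adj[a].add(b)
        adj[b].add(a)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / lfp_epochs.fs)
    out = np.full((n_sites, freqs.size), np.nan)
    n_pooled = n_trials * n_ep
    for m_site in range(n_sites):
        lfp_sites = sorted(adj[m_site])
        if not lfp_sites:
            continue
        vals = []
        mseg = md[:, :, m_site, :].reshape(n_pooled, n_samp)
        for l_site in lfp_sites:
            lseg = ld[:, :, l_site, :].reshape(n_pooled, n_samp)
            unit = cross_spectral_phases(lseg, mseg, lfp_epochs.fs, cfg)
            vals.append(ppc(unit))
        out[m_site] = np.nanmean(vals, axis=0)
    return PPCSpectrum(ppc=out, freqs=freqs, n_epochs=n_pooled,
                       pairing=list(neighbors))
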
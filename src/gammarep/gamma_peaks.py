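"""Per-stimulus gamma peaks: detection, permutation validation, grouping.

Gamma peak frequencies vary strongly between stimuli (and somewhat between
sites), so gamma-band scalars are computed in bands centered on individually
detected peaks. Peaks are strict local maxima of the relative power spectrum
between 20 and 190 Hz; the two largest are kept per (site, stimulus). A peak
is validated by a one-sided permutation test of trial-wise band power around
the peak (+/- 8 Hz) against activity +/- 8 Hz around 190 Hz, a reference
chosen to be above any spike-leakage plateau. Sites whose largest peaks agree
within a tolerance (+/- 16 Hz by default) are grouped, and spectra can be
shifted on the frequency grid so each stimulus's peak sits at 0 relative
frequency (integer-bin shifts only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GammaPeak",
    "find_peaks",
    "validate_peak",
    "group_sites",
    "align_spectra",
    "band_mean",
    "group_and_align",
    "MIN_SITES",
    "MIN_TRIALS",
    "MIN_TRIALS_EARLY",
]

# trial-selection thresholds for gamma-based analyses
MIN_SITES = 5
MIN_TRIALS = 8
MIN_TRIALS_EARLY = 4


@dataclass
class GammaPeak:
    stimulus_id: str
    site_id: str
    freq_hz: float
    rank: int
    height: float
    validated: bool = False
    p_perm: float = np.nan


def find_peaks(spectrum: np.ndarray, freqs: np.ndarray, fmin: float = 20.0,
               fmax: float = 190.0, n_peaks: int = 2, stimulus_id: str = "",
               site_id: str = "") -> list[GammaPeak]:
    """Strict local maxima of a spectrum in [fmin, fmax], largest first.

    Ties in height are broken toward the lower frequency. A monotone spectrum
    yields no peaks (an empty list is a valid result).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("find_peaks expects a single spectrum")
    is_max = np.zeros(spectrum.size, dtype=bool)
    is_max[1:-1] = (spectrum[1:-1] > spectrum[:-2]) & (spectrum[1:-1] > spectrum[2:])
    in_band = (freqs >= fmin) & (freqs <= fmax)
    idx = np.flatnonzero(is_max & in_band)
    # sort by descending height, lower frequency wins ties
    order = sorted(idx, key=lambda i: (-spectrum[i], freqs[i]))
    return [
        GammaPeak(stimulus_id=stimulus_id, site_id=site_id,
                  freq_hz=float(freqs[i]), rank=r + 1,
                  height=float(spectrum[i]))
        for r, i in enumerate(order[:n_peaks])
    ]


def band_mean(spectrum: np.ndarray, freqs: np.ndarray, center: float,
              half_band: float = 8.0) -> np.ndarray:
    """Mean over the bins fully inside center +/- half_band (inclusive),
    along the last axis."""
    mask = (freqs >= center - half_band - 1e-9) & (freqs <= center + half_band + 1e-9)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return np.asarray(spectrum)[..., mask].mean(axis=-1)


def validate_peak(trial_power: np.ndarray, freqs: np.ndarray, peak_hz: float,
                  ref_hz: float = 190.0, half_band: float = 8.0,
                  n_perm: int = 1000, alpha: float = 0.05,
                  rng: np.random.Generator | None = None):
    """One-sided permutation test of peak-band power against the reference band.

    Trials are pooled across sessions; ``trial_power`` is (trial, freq). The
    observed statistic is the mean over trials of (peak-band mean - reference-
    band mean); each permutation re-assigns the two band labels independently
    per trial. Returns ``(validated, p)`` with validated iff p < alpha.
    """
    if abs(peak_hz - ref_hz) < 2 * half_band:
        raise ValueError("peak band overlaps the reference band")
    rng = np.random.default_rng() if rng is None else rng
    a = band_mean(trial_power, freqs, peak_hz, half_band)
    b = band_mean(trial_power, freqs, ref_hz, half_band)
    d = a - b
    obs = d.mean()
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null = (signs * d).mean(axis=1)
    p = max(int(np.sum(null >= obs)), 1) / n_perm
    return p < alpha, p


def group_sites(peak_freqs: dict, tol_hz: float = 16.0) -> list[list]:
    """Group sites whose largest peaks agree within +/- tol_hz.

    ``peak_freqs`` maps site -> peak frequency; grouping is by connected
    components of the |f_i - f_j| <= tol graph.
    """
    sites = list(peak_freqs)
    parent = {s: s for s in sites}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if abs(peak_freqs[a] - peak_freqs[b]) <= tol_hz + 1e-9:
                parent[find(a)] = find(b)
    groups: dict = {}
    for s in sites:
        groups.setdefault(find(s), []).append(s)
    return sorted(groups.values(), key=lambda g: min(peak_freqs[s] for s in g))


def align_spectra(spectra: np.ndarray, freqs: np.ndarray,
                  peak_hz: np.ndarray):
    """Shift each spectrum so its peak sits at relative frequency 0.

    Shifts are integer numbers of grid bins (the grid is regular); out-of-
    range bins become NaN. Returns ``(aligned, rel_freqs)`` where ``aligned``
    matches the input shape and ``rel_freqs`` is the frequency axis relative
    to the peak.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    df = freqs[1] - freqs[0]
    nf = freqs.size
    aligned = np.full_like(spectra, np.nan)
    for i, pk in enumerate(np.atleast_1d(peak_hz)):
        shift = int(round((pk - freqs[0]) / df))
        # place bin `shift` (the peak) at index nf//2
        offset = nf // 2 - shift
        src_lo = max(0, -offset)
        src_hi = min(nf, nf - offset)
        aligned[i, src_lo + offset: src_hi + offset] = spectra[i, src_lo:src_hi]
    rel = (np.arange(nf) - nf // 2) * df
    return aligned, rel


def group_and_align(peaks: dict, spectra: np.ndarray, freqs: np.ndarray,
                    tol_hz: float = 16.0):
    """Convenience wrapper: group sites by their largest validated peak and
    align the per-site spectra to the peaks.

    ``peaks`` maps site -> peak frequency (largest validated peak); ``spectra``
    is (site, freq) in the same site order as ``sorted(peaks)``. Returns
    ``(groups, aligned, rel_freqs)``.
    """
    sites = sorted(peaks)
    groups = group_sites(peaks, tol_hz=tol_hz)
    pk = np.array([peaks[s] for s in sites])
    aligned, rel = align_spectra(spectra, freqs, pk)
    return groups, aligned, rel
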
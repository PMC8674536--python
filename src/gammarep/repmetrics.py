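"""Repetition-effect metrics.

Quantifies how a response (dMUA rate, gamma-band power, PPC) changes across
stimulus repetitions: z-scored trajectories, ordinary-least-squares slopes
over the early (repetitions 1-4) and late (5 onward) segments, the
repetition-related change ratio

    RRC = r_last / (0.5 * (r_last + r_first))

evaluated at the *fitted* endpoints (1 = no change, > 1 = increase; more
robust than r_last/r_first when both responses are near zero), and the
cross-validated intercept-slope (drive-dependence) Spearman correlation with
a median-split floor-effect control.

x-axis conventions: interleaved natural-image sequences are fit against the
raw repetition number; block designs against log10(trial-in-block), with the
first four trials excluded from log fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RepetitionFit",
    "zscore_trajectory",
    "fit_slopes",
    "rrc",
    "crossval_drive_dependence",
    "median_split_control",
    "EARLY_REPS",
]

#: the early segment is repetitions 1-4 exactly
EARLY_REPS = (1, 4)


@dataclass
class RepetitionFit:
    """OLS fit of response vs (transformed) repetition number."""

    slope: float
    intercept: float
    r_first: float
    r_last: float
    segment: str
    x_transform: str
    x_first: float
    x_last: float
    n_points: int
    stimulus_id: str = ""
    site_id: str = ""
    session_id: str = ""


def zscore_trajectory(responses: np.ndarray):
    """z-score a repetition trajectory (population SD; missing stay missing).

    Returns ``(z, degenerate)``; a zero-variance trajectory yields all zeros
    with ``degenerate=True``. The z-score is invariant to any affine rescaling
    of the input, which removes between-stimulus offset and gain differences.
    """
    y = np.asarray(responses, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite repetitions")
    mu = y[finite].mean()
    sd = y[finite].std()  # population (N) SD
    z = np.full_like(y, np.nan)
    if sd == 0:
        z[finite] = 0.0
        return z, True
    z[finite] = (y[finite] - mu) / sd
    return z, False


def _segment_mask(reps: np.ndarray, segment: str) -> np.ndarray:
    if segment == "early":
        return (reps >= EARLY_REPS[0]) & (reps <= EARLY_REPS[1])
    if segment == "late":
        return reps > EARLY_REPS[1]
    if segment == "all":
        return np.ones_like(reps, dtype=bool)
    raise ValueError(f"unknown segment: {segment!r}")


def fit_slopes(responses: np.ndarray, reps: np.ndarray | None = None,
               segment: str = "all", x_transform: str = "repetition",
               **labels) -> RepetitionFit | None:
    """OLS fit of responses against the (transformed) repetition axis.

    ``reps`` defaults to 1..n. For ``x_transform='log10_trial_in_block'`` the
    regressor is log10 of the repetition/trial number and the early trials
    (1-4) are excluded unless ``segment='early'`` is requested explicitly.
    Fitted endpoint responses ``r_first``/``r_last`` are evaluated from the
    fit at the segment endpoints (not from raw trials). Returns None when the
    segment holds fewer than 2 finite points.
    """
    y = np.asarray(responses, dtype=float)
    reps = np.arange(1, y.size + 1, dtype=float) if reps is None else \
        np.asarray(reps, dtype=float)
    mask = _segment_mask(reps, segment) & np.isfinite(y)
    if x_transform == "log10_trial_in_block" and segment in ("late", "all"):
        mask &= reps > EARLY_REPS[1]
    if mask.sum() < 2:
        return None
    x = reps[mask]
    if x_transform == "log10_trial_in_block":
        x = np.log10(x)
    elif x_transform != "repetition":
        raise ValueError(f"unknown x_transform: {x_transform!r}")
    yy = y[mask]
    slope, intercept = np.polyfit(x, yy, 1)
    x_first, x_last = x.min(), x.max()
    return RepetitionFit(slope=float(slope), intercept=float(intercept),
                         r_first=float(intercept + slope * x_first),
                         r_last=float(intercept + slope * x_last),
                         segment=segment, x_transform=x_transform,
                         x_first=float(x_first), x_last=float(x_last),
                         n_points=int(mask.sum()), **labels)


def rrc(fit: RepetitionFit, eps: float = 1e-6) -> float:
    """Repetition-related change: r_last / (0.5 * (r_last + r_first)).

    Equals 1 iff the fitted slope is zero; > 1 for increases. Returns NaN
    (degenerate, to be excluded and counted by the caller) when
    |r_first + r_last| < eps, where the ratio is unstable.
    """
    denom = 0.5 * (fit.r_last + fit.r_first)
    if abs(2 * denom) < eps:
        return np.nan
    return fit.r_last / denom


def _interleaved_fits(y: np.ndarray, reps: np.ndarray, segment: str):
    """Two independent OLS fits on interleaved repetition subsets.

    Half 1 takes every second repetition starting with the first of the
    segment, half 2 every second starting with the second; this decouples the
    intercept estimate of one half from the slope estimate of the other
    (removing the trivial mean-vs-slope coupling).
    """
    mask = _segment_mask(reps, segment) & np.isfinite(y)
    idx = np.flatnonzero(mask)
    if idx.size < 4:
        return None
    out = []
    for start in (0, 1):
        sel = idx[start::2]
        if sel.size < 2:
            return None
        slope, intercept = np.polyfit(reps[sel], y[sel], 1)
        out.append((slope, intercept))
    return out


def crossval_drive_dependence(responses: np.ndarray, segment: str = "all"):
    """Cross-validated intercept-slope Spearman correlation.

    ``responses`` is (session, stimulus, site, repetition) with NaN for
    missing entries. Per session and stimulus-site combination, two OLS fits
    are computed on interleaved repetition halves; the median slope and
    intercept across sessions are taken per combination, and the slope of one
    half is rank-correlated with the independently estimated intercept of the
    other half (both directions, averaged) across combinations.

    Returns ``(rho, slopes, intercepts)`` where ``slopes``/``intercepts`` are
    (combination, half) arrays for downstream controls.
    """
    n_sess, n_stim, n_site, n_rep = responses.shape
    reps = np.arange(1, n_rep + 1, dtype=float)
    slopes = np.full((n_stim * n_site, 2), np.nan)
    intercepts = np.full((n_stim * n_site, 2), np.nan)
    for s in range(n_stim):
        for c in range(n_site):
            per_sess = []
            for k in range(n_sess):
                fits = _interleaved_fits(responses[k, s, c], reps, segment)
                if fits is not None:
                    per_sess.append([f for pair in fits for f in pair])
            if per_sess:
                med = np.median(np.asarray(per_sess), axis=0)
                slopes[s * n_site + c] = med[0], med[2]
                intercepts[s * n_site + c] = med[1], med[3]
    ok = np.isfinite(slopes).all(axis=1) & np.isfinite(intercepts).all(axis=1)
    if ok.sum() < 3:
        raise ValueError("need >= 3 stimulus-site combinations")
    r1 = sps.spearmanr(slopes[ok, 0], intercepts[ok, 1]).statistic
    r2 = sps.spearmanr(slopes[ok, 1], intercepts[ok, 0]).statistic
    return 0.5 * (r1 + r2), slopes[ok], intercepts[ok]


def median_split_control(intercepts: np.ndarray, slopes: np.ndarray,
                         n_perm: int = 1000, alpha: float = 0.05,
                         rng: np.random.Generator | None = None):
    """Floor-effect control: intercept-slope correlation per intercept half.

    Combinations are split at the median intercept (odd counts: the lower
    half receives the extra point); per half, the Spearman correlation is
    tested against a permutation null that randomizes the intercepts, with
    BH-FDR correction across the two halves.

    Returns a list of ``(rho, p, significant)`` for (low, high) halves.

    ``intercepts``/``slopes`` here are 1-D, one value per stimulus-site
    combination (e.g. the cross-validated half-1 intercepts with half-2
    slopes); run both directions and average upstream if desired.
    """
    from .stats import fdr_correct, perm_p_two_sided

    intercepts = np.asarray(intercepts, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if intercepts.size < 4:
        raise ValueError("too few combinations for a median split")
    rng = np.random.default_rng() if rng is None else rng
    order = np.argsort(intercepts, kind="stable")
    n_low = (intercepts.size + 1) // 2
    halves = [order[:n_low], order[n_low:]]
    rhos, ps = [], []
    for h in halves:
        rho = sps.spearmanr(intercepts[h], slopes[h]).statistic
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = sps.spearmanr(rng.permutation(intercepts[h]),
                                    slopes[h]).statistic
        ps.append(perm_p_two_sided(rho, null, n_perm))
        rhos.append(rho)
    mask = fdr_correct(np.asarray(ps), alpha=alpha)
    return [(float(r), float(p), bool(m)) for r, p, m in zip(rhos, ps, mask)]
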
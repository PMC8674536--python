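"""Shared inference machinery and behavioral preprocessing.

Permutation tests use 1000 permutations by default; the two-sided p value is
the doubled one-sided exceedance with a floor of 2/n_perm, so the minimal
obtainable two-sided p is 0.002. BH step-up controls the false discovery rate
across frequency/time bins at 0.05. Bootstrap SEMs resample sessions with
replacement (1000 draws) and are reported as the SD of the resampled means;
plots conventionally show +/- 2 SEM.

Behavioral preprocessing: microsaccades are velocity-threshold events at
``lambda * c`` per axis, where c = sqrt(median(v^2) - median(v)^2) is a
median-based robust velocity SD; pupil responses are z-scored against the
single-trial prestimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationTestResult",
    "RegressionSpec",
    "perm_p_two_sided",
    "signflip_test",
    "exchange_test",
    "bootstrap_sem",
    "fdr_correct",
    "fit_block_regression",
    "detect_microsaccades",
    "pupil_response",
    "binned_means",
]


@dataclass
class PermutationTestResult:
    observed: float
    null_draws: np.ndarray
    p: float
    n_perm: int


def perm_p_two_sided(observed: float, null: np.ndarray, n_perm: int) -> float:
    """Two-sided permutation p: doubled one-sided exceedance, floor 2/n_perm."""
    c_ge = int(np.sum(null >= observed))
    c_le = int(np.sum(null <= observed))
    return min(1.0, 2.0 * max(min(c_ge, c_le), 1) / n_perm)


def signflip_test(values: np.ndarray, n_perm: int = 1000,
                  rng: np.random.Generator | None = None) -> PermutationTestResult:
    """Test the mean of session-level values against zero by sign flipping.

    The observed statistic is the mean over sessions (values are expected to
    be averaged over stimuli/animals upstream); each permutation randomly
    flips the sign of each session's value and recomputes the mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng() if rng is None else rng
    obs = v.mean()
    signs = rng.integers(0, 2, size=(n_perm, v.size)) * 2 - 1
    null = (signs * v).mean(axis=1)
    return PermutationTestResult(observed=float(obs), null_draws=null,
                                 p=perm_p_two_sided(obs, null, n_perm),
                                 n_perm=n_perm)


def exchange_test(cond_a: np.ndarray, cond_b: np.ndarray, n_perm: int = 1000,
                  rng: np.random.Generator | None = None) -> PermutationTestResult:
    """Paired two-condition permutation test on session-level values.

    The statistic is the mean difference a - b across sessions; each
    permutation makes an independent random decision per session to exchange
    the two condition values (equivalently, to flip the sign of that
    session's difference).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must be paired (matching shapes)")
    d = a - b
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("need at least 2 paired sessions")
    rng = np.random.default_rng() if rng is None else rng
    obs = d.mean()
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null = (signs * d).mean(axis=1)
    return PermutationTestResult(observed=float(obs), null_draws=null,
                                 p=perm_p_two_sided(obs, null, n_perm),
                                 n_perm=n_perm)


def bootstrap_sem(values: np.ndarray, n_boot: int = 1000,
                  rng: np.random.Generator | None = None) -> float:
    """Bootstrap SEM of the grand mean over (session, stimulus [, ...]) data.

    ``values`` is (session, stimulus) or a list of such arrays (one per
    animal, session counts may differ). Sessions are resampled with
    replacement within each stimulus; resampled session means are averaged
    across stimuli, then across animals. The SEM estimate is the SD of the
    resulting resampling distribution.
    """
    rng = np.random.default_rng() if rng is None else rng
    arrays = values if isinstance(values, (list, tuple)) else [values]
    arrays = [np.atleast_2d(np.asarray(a, dtype=float)) for a in arrays]
    boots = np.empty((n_boot, len(arrays)))
    for j, arr in enumerate(arrays):
        n_sess = arr.shape[0]
        idx = rng.integers(0, n_sess, size=(n_boot, n_sess))
        # resample sessions (with replacement) independently per stimulus
        stim_means = np.nanmean(arr[idx], axis=1)  # (boot, stimulus)
        boots[:, j] = np.nanmean(stim_means, axis=1)
    return float(boots.mean(axis=1).std())


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at the given FDR."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return mask


# ---------------------------------------------------------------------------
# regression models for block designs
# ---------------------------------------------------------------------------

@dataclass
class RegressionSpec:
    """Terms of a single-trial block-design regression.

    ``response`` is the column holding the (positive) response; it is
    log10-transformed. ``log_terms`` are continuous predictors entered as
    log10(x); ``continuous`` enter untransformed; ``categorical`` get
    treatment coding; ``block_indicators`` are 0/1 columns whose main effects
    test intercept shifts (persistence/specificity) and whose interactions
    with the first log term test slope changes.
    """

    response: str
    log_terms: list = field(default_factory=list)
    continuous: list = field(default_factory=list)
    categorical: list = field(default_factory=list)
    block_indicators: list = field(default_factory=list)
    interactions: bool = True

    def formula(self) -> str:
        terms = [f"np.log10({t})" for t in self.log_terms]
        terms += list(self.continuous)
        terms += [f"C({t})" for t in self.categorical]
        terms += list(self.block_indicators)
        if self.interactions and self.log_terms and self.block_indicators:
            first = f"np.log10({self.log_terms[0]})"
            terms += [f"{first}:{b}" for b in self.block_indicators]
        if len(set(terms)) != len(terms):
            raise ValueError("duplicated regression terms")
        return f"np.log10({self.response}) ~ " + " + ".join(terms)


def fit_block_regression(data: pd.DataFrame, spec: RegressionSpec):
    """OLS multiple regression of log responses on task/behavior terms.

    Returns a DataFrame of term-wise coefficients, standard errors, p values
    and partial variance explained (type-II partial eta squared), plus the
    fitted statsmodels results object. Aliased (rank-deficient) terms are
    reported with NaN coefficients.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    res = smf.ols(spec.formula(), data=data).fit()
    table = pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "p": res.pvalues,
    })
    try:
        an = anova_lm(res, typ=2)
        partial = an["sum_sq"] / (an["sum_sq"] + an.loc["Residual", "sum_sq"])
        table["partial_var"] = np.nan
        for term in an.index:
            if term == "Residual":
                continue
            hits = [ix for ix in table.index if term.split("(")[-1].rstrip(")")
                    in ix or ix.startswith(term)]
            for ix in hits:
                table.loc[ix, "partial_var"] = partial[term]
    except Exception:  # rank deficiency: keep coefficient table
        table["partial_var"] = np.nan
    return table, res


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _robust_criterion(v: np.ndarray) -> float:
    """Median-based velocity SD: sqrt(median(v^2) - median(v)^2)."""
    med = np.median(v)
    var = np.median(v ** 2) - med ** 2
    return float(np.sqrt(max(var, 0.0)))


def detect_microsaccades(gaze_x: np.ndarray, gaze_y: np.ndarray, fs: float,
                         lam: float = 6.0, smooth_ms: float = 5.0,
                         diff_ms: float = 10.0):
    """Velocity-threshold microsaccade detection.

    Gaze traces (trial, time; dva) are smoothed with a +/- ``smooth_ms``
    rectangular window; velocities are differences across samples separated
    by ``diff_ms``. Per trial and axis the threshold is ``lam * c`` with the
    median-based criterion c; samples where |v| exceeds threshold on either
    axis are events, and contiguous runs merge into single events.

    Returns a DataFrame (trial, onset_index, offset_index, onset_time_s) with
    onset times relative to the trial start.
    """
    if gaze_x.shape != gaze_y.shape:
        raise ValueError("gaze traces must have matching shapes")
    half = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    k = max(int(round(diff_ms / 1000.0 * fs / 2.0)), 1)
    n_t = gaze_x.shape[1]
    # need the filter/differencing support plus enough samples for a stable
    # median-velocity criterion
    if n_t < max(2 * half + 2 * k + 1, int(0.05 * fs)):
        raise ValueError("trace shorter than the smoothing/differencing support")
    rows = []
    for tr in range(gaze_x.shape[0]):
        vs = []
        for g in (gaze_x[tr], gaze_y[tr]):
            sm = uniform_filter1d(g.astype(float), size=2 * half + 1,
                                  mode="nearest")
            v = np.zeros_like(sm)
            v[k:-k] = (sm[2 * k:] - sm[:-2 * k]) * fs / (2 * k)
            vs.append(v)
        above = np.zeros(n_t, dtype=bool)
        for v in vs:
            c = _robust_criterion(v)
            above |= np.abs(v) > lam * c
        # merge contiguous threshold-crossing runs into events
        edges = np.diff(above.astype(int))
        onsets = np.flatnonzero(edges == 1) + 1
        offsets = np.flatnonzero(edges == -1) + 1
        if above[0]:
            onsets = np.r_[0, onsets]
        if above[-1]:
            offsets = np.r_[offsets, n_t]
        for on, off in zip(onsets, offsets):
            rows.append((tr, int(on), int(off), on / fs))
    return pd.DataFrame(rows, columns=["trial", "onset_index", "offset_index",
                                       "onset_time_s"])


def pupil_response(pupil: np.ndarray, time: np.ndarray,
                   baseline=(-1.0, 0.0)):
    """z-score pupil traces against the single-trial prestimulus baseline.

    Returns ``(z, degenerate)``: ``z`` is (trial, time); trials whose baseline
    window has zero variance are flagged in ``degenerate`` and come back NaN.
    """
    mask = (time >= baseline[0]) & (time < baseline[1])
    if not mask.any():
        raise ValueError("baseline window outside the time axis")
    base = pupil[:, mask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (pupil - mu) / sd
    z[degenerate] = np.nan
    return z, degenerate


def binned_means(values: np.ndarray, trial_numbers: np.ndarray,
                 half_width: int = 3) -> np.ndarray:
    """Centered +/- half_width moving-bin means over trial-in-block numbers.

    Used by the location-block analyses, which bin responses in bins of
    +/- 3 trials around each trial number before block contrasts.
    """
    values = np.asarray(values, dtype=float)
    trial_numbers = np.asarray(trial_numbers)
    out = np.full(values.shape, np.nan)
    for i, t in enumerate(trial_numbers):
        sel = np.abs(trial_numbers - t) <= half_width
        out[i] = np.nanmean(values[sel], axis=0)
    return out
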
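"""Stimulus specificity of repetition effects: split-half correlation.

The statistic: per session, site and stimulus, the repetition trajectory of a
response feature is z-scored across repetitions, averaged over sites, and the
per-stimulus trajectories are concatenated in a fixed (canonical) stimulus
order into one session vector. Sessions are split into two random halves
(s = 100 splits), the half-average vectors are Pearson-correlated, and the s
correlations are averaged; with several animals the per-animal values are
averaged. Stimulus-specific trajectories make the correlation positive;
trajectories that transfer fully between stimuli do not, because the
z-scoring removes per-stimulus offsets.

The null reshuffles stimulus identity: each of 1000 permutation iterations
re-orders the stimulus blocks of the session vectors randomly (independently
per session) and recomputes the split-half statistic over the same s splits,
averaging over splits (and animals) exactly as for the observed value. This
gives a two-sided randomization test (alpha = 0.05) that is exact under the
null of stimulus-exchangeable trajectories, with BH-FDR correction across
frequency/time bins for resolved analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repmetrics import _segment_mask, zscore_trajectory
from .stats import fdr_correct, perm_p_two_sided

__all__ = [
    "CorrelationResult",
    "build_session_vectors",
    "split_half_correlation",
    "permutation_null",
    "correlation_spectrum",
]


@dataclass
class CorrelationResult:
    observed_r: np.ndarray
    null_r: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    bins: np.ndarray
    n_splits: int
    n_perm: int

    def __post_init__(self) -> None:
        self.observed_r = np.atleast_1d(np.asarray(self.observed_r, float))
        self.p = np.atleast_1d(np.asarray(self.p, float))


def build_session_vectors(responses: np.ndarray, min_coverage: float = 0.5,
                          segment: str = "all") -> np.ndarray:
    """Session vectors of z-scored, site-averaged, concatenated trajectories.

    ``responses`` is (session, stimulus, site, repetition) with NaN for
    missing data, stimuli already in the canonical (fixed) order. Each
    (session, stimulus, site) trajectory is z-scored across the repetitions
    of the requested segment, averaged across sites, and the stimuli are
    concatenated. Sessions whose vector holds less than ``min_coverage``
    finite data are dropped.

    Returns (n_kept_sessions, n_stimuli * n_reps_in_segment).
    """
    resp = np.asarray(responses, dtype=float)
    if resp.ndim != 4:
        raise ValueError("responses must be (session, stimulus, site, rep)")
    n_sess, n_stim, n_site, n_rep = resp.shape
    reps = np.arange(1, n_rep + 1)
    sel = _segment_mask(reps.astype(float), segment)
    resp = resp[..., sel]
    n_rep = sel.sum()
    z = np.full(resp.shape, np.nan)
    for k in range(n_sess):
        for s in range(n_stim):
            for c in range(n_site):
                y = resp[k, s, c]
                if np.isfinite(y).sum() >= 2:
                    z[k, s, c], _ = zscore_trajectory(y)
    site_avg = np.nanmean(z, axis=2)  # (session, stimulus, rep)
    vectors = site_avg.reshape(n_sess, n_stim * n_rep)
    coverage = np.isfinite(vectors).mean(axis=1)
    keep = coverage >= min_coverage
    if not keep.any():
        raise ValueError("no session passes the coverage threshold")
    return vectors[keep]


def _splits(n_sess: int, s: int, rng: np.random.Generator):
    """s random equal-size session splits (odd counts: floor/ceil halves)."""
    half = n_sess // 2
    out = []
    for _ in range(s):
        perm = rng.permutation(n_sess)
        out.append((perm[:half], perm[half:]))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over entries finite in both vectors."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    aa, bb = a[ok] - a[ok].mean(), b[ok] - b[ok].mean()
    denom = np.sqrt((aa ** 2).sum() * (bb ** 2).sum())
    return float((aa * bb).sum() / denom) if denom > 0 else np.nan


def split_half_correlation(vectors: np.ndarray, s: int = 100,
                           rng: np.random.Generator | None = None) -> float:
    """Mean Pearson correlation of half-average vectors over s random splits."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng() if rng is None else rng
    rs = []
    for h1, h2 in _splits(vectors.shape[0], s, rng):
        rs.append(_pearson(np.nanmean(vectors[h1], axis=0),
                           np.nanmean(vectors[h2], axis=0)))
    return float(np.nanmean(rs))


def _corr_split_means(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of paired half-average vectors (..., L)."""
    a = m1 - m1.mean(axis=-1, keepdims=True)
    b = m2 - m2.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a ** 2).sum(axis=-1) * (b ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=-1) / denom


def _null_one_animal(vectors: np.ndarray, n_stimuli: int, s: int,
                     n_perm: int, rng: np.random.Generator):
    """Observed r and n_perm null draws for one animal's session vectors.

    The null re-randomizes stimulus identity: each permutation iteration
    draws an independent stimulus order for every session, relabels the
    session vectors' stimulus blocks accordingly, and recomputes the full
    split-half statistic over the same s splits as the observed value.
    Because the null hypothesis (repetition trajectories carry no stimulus
    identity) makes the per-session stimulus blocks exchangeable, this
    relabeling is a distribution-preserving group action and the resulting
    Monte-Carlo randomization test is exact.
    """
    n_sess, length = vectors.shape
    if length % n_stimuli:
        raise ValueError("vector length not divisible by the stimulus count")
    n_rep = length // n_stimuli
    splits = _splits(n_sess, s, rng)
    clean = not np.isnan(vectors).any()
    if clean:
        w1 = np.zeros((s, n_sess))
        w2 = np.zeros((s, n_sess))
        for i, (h1, h2) in enumerate(splits):
            w1[i, h1] = 1.0 / h1.size
            w2[i, h2] = 1.0 / h2.size
        obs = float(np.nanmean(_corr_split_means(w1 @ vectors, w2 @ vectors)))
        v3 = vectors.reshape(n_sess, n_stimuli, n_rep)
        null = np.empty(n_perm)
        chunk = max(1, int(2e7 // (s * length)))
        for lo in range(0, n_perm, chunk):
            m = min(chunk, n_perm - lo)
            orders = np.argsort(rng.random((m, n_sess, n_stimuli)), axis=-1)
            vp = np.take_along_axis(v3[None], orders[..., None], axis=2)
            vp = vp.reshape(m, n_sess, length)
            m1 = np.einsum("sk,pkl->psl", w1, vp)
            m2 = np.einsum("sk,pkl->psl", w2, vp)
            null[lo:lo + m] = np.nanmean(_corr_split_means(m1, m2), axis=1)
        return obs, null
    # general (NaN-tolerant) path
    obs_per_split = np.full(s, np.nan)
    null = np.full((n_perm, s), np.nan)
    v3 = vectors.reshape(n_sess, n_stimuli, n_rep)
    for i, (h1, h2) in enumerate(splits):
        obs_per_split[i] = _pearson(np.nanmean(vectors[h1], axis=0),
                                    np.nanmean(vectors[h2], axis=0))
    for p in range(n_perm):
        vp = np.stack([v3[k][rng.permutation(n_stimuli)].reshape(-1)
                       for k in range(n_sess)])
        for i, (h1, h2) in enumerate(splits):
            null[p, i] = _pearson(np.nanmean(vp[h1], axis=0),
                                  np.nanmean(vp[h2], axis=0))
    return float(np.nanmean(obs_per_split)), np.nanmean(null, axis=1)


def permutation_null(vectors, n_stimuli: int, s: int = 100,
                     n_perm: int = 1000, alpha: float = 0.05,
                     rng: np.random.Generator | None = None,
                     ) -> CorrelationResult:
    """Split-half correlation with its stimulus-reshuffling permutation null.

    ``vectors`` is one session-vector matrix or a list of them (one per
    animal); observed values and null draws are averaged across animals
    before the two-sided comparison.
    """
    if n_stimuli < 2:
        raise ValueError("permutation degenerate with fewer than 2 stimuli")
    rng = np.random.default_rng() if rng is None else rng
    mats = vectors if isinstance(vectors, (list, tuple)) else [vectors]
    obs_all, null_all = [], []
    for mat in mats:
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] < 2:
            raise ValueError("need at least 2 sessions per animal")
        o, n = _null_one_animal(mat, n_stimuli, s, n_perm, rng)
        obs_all.append(o)
        null_all.append(n)
    obs = float(np.mean(obs_all))
    null = np.mean(null_all, axis=0)
    p = perm_p_two_sided(obs, null, n_perm)
    return CorrelationResult(observed_r=np.array([obs]), null_r=null[:, None],
                             p=np.array([p]),
                             fdr_mask=np.array([p < alpha]),
                             bins=np.array([0.0]), n_splits=s, n_perm=n_perm)


def correlation_spectrum(features, bins: np.ndarray, n_stimuli: int | None = None,
                         s: int = 100, n_perm: int = 1000, alpha: float = 0.05,
                         segment: str = "all", min_coverage: float = 0.5,
                         rng: np.random.Generator | None = None,
                         ) -> CorrelationResult:
    """Run the split-half procedure per frequency/time bin.

    ``features`` is (session, stimulus, site, repetition, bin) or a list of
    such arrays (one per animal). Per bin, session vectors are built for the
    requested repetition segment and the correlation plus its permutation
    null is computed; p values are BH-FDR corrected across bins.
    """
    rng = np.random.default_rng() if rng is None else rng
    mats = features if isinstance(features, (list, tuple)) else [features]
    mats = [np.asarray(m, dtype=float) for m in mats]
    if n_stimuli is None:
        n_stimuli = mats[0].shape[1]
    n_bins = mats[0].shape[-1]
    if n_bins != len(bins):
        raise ValueError("bin axis does not match the bin labels")
    obs = np.full(n_bins, np.nan)
    pvals = np.full(n_bins, np.nan)
    null = np.full((n_perm, n_bins), np.nan)
    for ib in range(n_bins):
        vecs = [build_session_vectors(m[..., ib], min_coverage=min_coverage,
                                      segment=segment) for m in mats]
        res = permutation_null(vecs, n_stimuli=n_stimuli, s=s, n_perm=n_perm,
                               alpha=alpha, rng=rng)
        obs[ib] = res.observed_r[0]
        pvals[ib] = res.p[0]
        null[:, ib] = res.null_r[:, 0]
    return CorrelationResult(observed_r=obs, null_r=null, p=pvals,
                             fdr_mask=fdr_correct(pvals, alpha=alpha),
                             bins=np.asarray(bins), n_splits=s, n_perm=n_perm)
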
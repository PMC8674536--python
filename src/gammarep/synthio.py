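"""Synthetic task sequences and V1-like recordings.

This module generates everything the analysis side consumes: trial tables for
the three task designs (constrained-lag natural-image interleaving, ABA/BBA
grating blocks, In/Out location blocks), ground-truth effect parameters, and
synthetic multi-site LFP / MUA-envelope recordings plus eye traces with the
statistical structure the analysis assumes:

* LFP = 1/f background + stimulus-gated narrowband gamma whose power and peak
  frequency drift with (log-)repetition number, with stimulus-specific
  trajectories that can be mixed across stimuli (``specificity_transfer``).
* MUA = non-negative envelope with an onset transient and a sustained rate
  that decays with repetition, sitting on a per-site noise floor, and
  phase-modulated by the LFP gamma (drives MUA-LFP phase locking).
* Eye traces = fixation jitter + injected microsaccade-like steps + a
  stimulus-locked pupil constriction, with injected events recorded for
  detector validation.

All randomness flows through a single :class:`numpy.random.Generator` derived
from an explicit seed; synthesis is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "GroundTruth",
    "RecordingSession",
    "EyeTrace",
    "generate_natural_sequence",
    "sample_change_time",
    "generate_block_sequence",
    "simulate_correctness",
    "compute_trial_gains",
    "synthesize_recording",
    "synthesize_gamma_trajectories",
    "synthesize_eye_traces",
    "grid_neighbors",
    "write_trials_csv",
    "read_trials_csv",
    "save_session",
    "load_session",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "trial_index",
    "stimulus_id",
    "repetition_number",
    "trial_in_block",
    "correct",
    "lag",
    "block_id",
    "block_type",
    "location",
    "change_time",
    "session_id",
    "animal_id",
]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-stimulus effect parameters used to synthesize a recording.

    Slopes are expressed as fractional change of the response gain per unit of
    the repetition axis: per repetition for ``x_transform='repetition'``
    (hinge at repetition 4, separate early/late slopes), or per decade of
    trial-in-block for ``x_transform='log10_trial_in_block'`` (block designs,
    where only the late slope is used).

    ``specificity_transfer`` in [0, 1] mixes each stimulus's repetition
    trajectory with the across-stimulus mean trajectory: 0 = fully
    stimulus-specific, 1 = fully shared (no specificity).
    ``persistence`` in [0, 1] is the fraction of the repetition-induced gamma
    gain that survives an intervening block of a different stimulus/location.
    """

    stimuli: list[str]
    gamma_peak_hz: np.ndarray
    gamma_base_power: np.ndarray
    gamma_early_slope: np.ndarray
    gamma_late_slope: np.ndarray
    gamma_freq_shift_hz: np.ndarray
    mua_base: np.ndarray
    mua_decay_early: np.ndarray
    mua_decay_late: np.ndarray
    specificity_transfer: float = 0.0
    persistence: float = 0.0
    x_transform: str = "repetition"
    noise_1f_exponent: float = 1.0
    mua_noise_floor: np.ndarray | float = 5.0
    mua_locking: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.stimuli)
        for name in (
            "gamma_peak_hz",
            "gamma_base_power",
            "gamma_early_slope",
            "gamma_late_slope",
            "gamma_freq_shift_hz",
            "mua_base",
            "mua_decay_early",
            "mua_decay_late",
        ):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 1:
                arr = np.full(n, float(arr[0]))
            if arr.size != n:
                raise ValueError(f"{name} must have one value per stimulus")
            setattr(self, name, arr)
        if np.any(self.gamma_base_power < 0):
            raise ValueError("gamma_base_power must be >= 0")
        if not 0.0 <= self.specificity_transfer <= 1.0:
            raise ValueError("specificity_transfer must be in [0, 1]")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if self.x_transform not in ("repetition", "log10_trial_in_block"):
            raise ValueError(f"unknown x_transform: {self.x_transform!r}")

    @classmethod
    def random(cls, stimuli, rng: np.random.Generator, **overrides) -> "GroundTruth":
        """Draw realistic per-stimulus parameters.

        Gamma peaks 45-75 Hz, stimulus/baseline power ratios 2-4 at the peak,
        variable early gamma slopes (mean slightly negative) and positive late
        slopes, MUA decaying a few percent per early repetition.
        """
        stimuli = list(stimuli)
        n = len(stimuli)
        params = dict(
            stimuli=stimuli,
            gamma_peak_hz=rng.uniform(45.0, 75.0, n),
            gamma_base_power=rng.uniform(2.0, 4.0, n),
            gamma_early_slope=rng.normal(-0.03, 0.06, n),
            gamma_late_slope=rng.normal(0.02, 0.025, n),
            gamma_freq_shift_hz=rng.normal(2.0, 1.0, n),
            mua_base=rng.uniform(25.0, 60.0, n),
            mua_decay_early=rng.normal(-0.04, 0.015, n),
            mua_decay_late=rng.normal(-0.004, 0.003, n),
            seed=0,
        )
        params.update(overrides)
        return cls(**params)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class RecordingSession:
    """Site x trial x time LFP and MUA arrays plus the trial table.

    ``time`` is peri-stimulus in seconds (stimulus onset at 0); ``truth``
    carries the generating parameters when the session is synthetic.
    """

    lfp: np.ndarray
    mua: np.ndarray
    fs: float
    time: np.ndarray
    sites: list[str]
    trials: pd.DataFrame
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.lfp.shape != self.mua.shape:
            raise ValueError("lfp and mua must have identical shapes")
        n_sites, n_trials, n_time = self.lfp.shape
        if n_sites != len(self.sites):
            raise ValueError("site axis does not match site labels")
        if n_trials != len(self.trials):
            raise ValueError("trial axis does not match trial table")
        if n_time != self.time.size:
            raise ValueError("time axis does not match time vector")
        if np.any(self.mua < 0):
            raise ValueError("mua envelope must be non-negative")
        if self.time[0] > -1.0 or self.time[-1] < 1.5 - 1.0 / self.fs:
            raise ValueError("time axis must cover at least [-1.0, 1.5] s")


@dataclass
class EyeTrace:
    """Gaze (dva) and pupil (a.u.) traces, trial x time, with injected events."""

    gaze_x: np.ndarray
    gaze_y: np.ndarray
    pupil: np.ndarray
    fs: float
    time: np.ndarray
    injected_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValueError("eye-trace sampling rate must be >= 100 Hz")
        for arr in (self.gaze_x, self.gaze_y, self.pupil):
            if not np.all(np.isfinite(arr)):
                raise ValueError("eye traces must be finite")


# ---------------------------------------------------------------------------
# task sequences
# ---------------------------------------------------------------------------

def sample_change_time(a: float, b: float, rng: np.random.Generator,
                       size=None, offset: float = 0.0):
    """Draw stimulus-change times from a Weibull distribution.

    Standard parameterization with scale ``a`` and shape ``b``:
    f(t) = (b/a) (t/a)^(b-1) exp(-(t/a)^b), hazard h(t) = (b/a)(t/a)^(b-1)
    (linear in t for b = 2, i.e. an increasing hazard of the change).
    ``offset`` shifts the draws by a fixed minimum stimulus duration.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Weibull parameters must be positive")
    return offset + a * rng.weibull(b, size=size)


def _finalize_trials(seq, session_id, animal_id, rng, change_a=0.27,
                     change_b=2.0, change_offset=1.8, block_ids=None,
                     block_types=None, locations=None, trial_in_block=None,
                     repetition_number=None):
    """Assemble a canonical trial table from a stimulus sequence."""
    n = len(seq)
    seq = list(seq)
    last_pos: dict = {}
    lag = np.full(n, np.nan)
    rep = np.zeros(n, dtype=int)
    counts: dict = {}
    for i, s in enumerate(seq):
        counts[s] = counts.get(s, 0) + 1
        rep[i] = counts[s]
        if s in last_pos:
            lag[i] = i - last_pos[s] - 1
        last_pos[s] = i
    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "stimulus_id": seq,
            "repetition_number": rep if repetition_number is None else repetition_number,
            "trial_in_block": np.arange(1, n + 1) if trial_in_block is None else trial_in_block,
            "correct": True,
            "lag": lag,
            "block_id": "b01" if block_ids is None else block_ids,
            "block_type": "natural" if block_types is None else block_types,
            "location": "n/a" if locations is None else locations,
            "change_time": sample_change_time(change_a, change_b, rng, size=n,
                                              offset=change_offset),
            "session_id": session_id,
            "animal_id": animal_id,
        }
    )
    return df[TRIAL_COLUMNS]


def generate_natural_sequence(n_stimuli: int, reps_per_stim: int = 20,
                              subset_size: int = 3, max_lag: int = 4,
                              seed: int = 0, dummy_prefix: bool = False,
                              session_id: str = "s01", animal_id: str = "A",
                              ) -> pd.DataFrame:
    """Pseudorandom constrained-lag interleaving of natural-image trials.

    Each trial's stimulus is drawn from a rolling subset of ``subset_size``
    stimuli; exhausted stimuli (``reps_per_stim`` presentations) are replaced
    by fresh ones from the full set. A stimulus whose lag (count of
    other-stimulus trials since its previous presentation) has reached
    ``max_lag`` is drawn next, which guarantees the lag constraint: among
    already-presented subset members the lags are pairwise distinct, so at
    most one stimulus is ever at the deadline.

    With ``dummy_prefix`` the session starts with two additional, unchanging
    dummy stimuli with a reduced repetition count interleaved with the first
    set stimulus, so that set stimuli do not all start simultaneously.
    """
    if not (n_stimuli >= subset_size >= 1):
        raise ValueError("need n_stimuli >= subset_size >= 1")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if subset_size > max_lag + 1 and reps_per_stim > 1 and n_stimuli > 1:
        # with > max_lag+1 concurrently active presented stimuli, some lag
        # must exceed max_lag (pigeonhole over distinct lags)
        raise ValueError(
            f"infeasible: subset_size={subset_size} requires max_lag >= {subset_size - 1}"
        )
    rng = np.random.default_rng(seed)
    stimuli = [f"s{i + 1:02d}" for i in range(n_stimuli)]
    pool = list(rng.permutation(stimuli))
    reps = {s: reps_per_stim for s in stimuli}
    subset = [pool.pop(0) for _ in range(subset_size)]
    if dummy_prefix:
        for j, d in enumerate(("dummy1", "dummy2")):
            reps[d] = int(rng.integers(max(2, reps_per_stim // 4),
                                       max(3, reps_per_stim // 2)))
        # dummies replace all but the first set stimulus at session start
        returned = subset[1:subset_size]
        pool = returned + pool
        subset = [subset[0], "dummy1", "dummy2"][: max(subset_size, 2)]
    seq: list[str] = []
    remaining = dict(reps)
    last_pos: dict = {}
    t = 0
    while subset:
        forced = None
        for s in subset:
            if s in last_pos:
                cur_lag = t - last_pos[s] - 1
                if cur_lag > max_lag:  # pragma: no cover - guarded by design
                    raise RuntimeError("lag constraint violated during generation")
                if cur_lag == max_lag:
                    forced = s
        s = forced if forced is not None else subset[rng.integers(len(subset))]
        seq.append(s)
        last_pos[s] = t
        remaining[s] -= 1
        if remaining[s] == 0:
            subset.remove(s)
            if pool:
                subset.append(pool.pop(0))
        t += 1
    return _finalize_trials(seq, session_id, animal_id, rng)


_LOCATION_TOKENS = ("Out", "In")


def _parse_design(design: str) -> tuple[list[str], str]:
    """Split a design string into block tokens; returns (tokens, kind)."""
    if design and set(design) <= {"A", "B"}:
        return list(design), "stimulus"
    tokens = []
    rest = design
    while rest:
        for tok in _LOCATION_TOKENS:
            if rest.startswith(tok):
                tokens.append(tok)
                rest = rest[len(tok):]
                break
        else:
            raise ValueError(f"unknown design token in {design!r}")
    if not tokens:
        raise ValueError("empty design string")
    return tokens, "location"


def _bracket_label(tokens, i) -> str:
    return "".join(f"[{t}]" if j == i else t for j, t in enumerate(tokens))


def generate_block_sequence(design: str, trials_per_block: int = 100,
                            stimuli=("g1", "g2"), seed: int = 0,
                            session_id: str = "s01", animal_id: str = "H",
                            swap_stimuli: bool = False) -> pd.DataFrame:
    """Block designs: grating-identity blocks (ABA, BBA, ...) or location
    blocks (InIn, OutIn, InOutIn, OutOutIn, ...).

    Blocks of ``trials_per_block`` trials share one stimulus (or location);
    ``block_type`` carries the bracket notation (second block of ABA ->
    "A[B]A"). ``swap_stimuli`` is the counterbalancing hook that exchanges
    which grating plays the role of A vs B. ``repetition_number`` counts
    consecutive same-stimulus (or same-location) trials, continuing across
    adjacent identical blocks.
    """
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    tokens, kind = _parse_design(design)
    rng = np.random.default_rng(seed)
    n = trials_per_block * len(tokens)
    if kind == "stimulus":
        if len(stimuli) < 2:
            raise ValueError("stimulus block designs need two stimuli")
        assignment = {"A": stimuli[1] if swap_stimuli else stimuli[0],
                      "B": stimuli[0] if swap_stimuli else stimuli[1]}
    else:
        assignment = {}
    seq, block_ids, block_types, locations, tib = [], [], [], [], []
    for i, tok in enumerate(tokens):
        stim = assignment[tok] if kind == "stimulus" else stimuli[0]
        seq.extend([stim] * trials_per_block)
        block_ids.extend([f"b{i + 1:02d}"] * trials_per_block)
        block_types.extend([_bracket_label(tokens, i)] * trials_per_block)
        locations.extend([tok if kind == "location" else "n/a"] * trials_per_block)
        tib.extend(range(1, trials_per_block + 1))
    # consecutive repetition count: resets when the block token changes
    rep = np.zeros(n, dtype=int)
    run = 0
    for i in range(n):
        tok_i = tokens[i // trials_per_block]
        prev_tok = tokens[(i - 1) // trials_per_block] if i else None
        run = run + 1 if tok_i == prev_tok or (i % trials_per_block) else 1
        rep[i] = run
    df = _finalize_trials(seq, session_id, animal_id, rng, change_offset=1.5,
                          change_a=0.27, change_b=2.0, block_ids=block_ids,
                          block_types=block_types, locations=locations,
                          trial_in_block=tib, repetition_number=rep)
    # grating tasks use a uniformly distributed change interval
    df["change_time"] = rng.uniform(1.5, 2.3, n)
    return df


def simulate_correctness(trials: pd.DataFrame, p_error_early: float = 0.25,
                         p_error: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Mark trials incorrect as independent Bernoulli draws, with a higher
    error rate on the first three repetitions, and recount
    ``repetition_number`` over correct trials only (errors get NaN)."""
    rng = np.random.default_rng(seed)
    out = trials.copy()
    p = np.where(out["repetition_number"].to_numpy() <= 3, p_error_early, p_error)
    out["correct"] = rng.random(len(out)) >= p
    rep = np.full(len(out), np.nan)
    counts: dict = {}
    for i, (stim, ok) in enumerate(zip(out["stimulus_id"], out["correct"])):
        if ok:
            counts[stim] = counts.get(stim, 0) + 1
            rep[i] = counts[stim]
    out["repetition_number"] = rep
    return out


# ---------------------------------------------------------------------------
# trajectory model
# ---------------------------------------------------------------------------

def _hinge_gain(rep, early_slope, late_slope):
    """Piecewise-linear gain vs repetition number, hinge at repetition 4."""
    rep = np.asarray(rep, dtype=float)
    return (1.0 + early_slope * (np.minimum(rep, 4) - 1)
            + late_slope * np.maximum(rep - 4, 0))


def compute_trial_gains(trials: pd.DataFrame, truth: GroundTruth):
    """Per-trial gamma gain, gamma peak frequency, and MUA gain.

    For ``x_transform='repetition'`` the gain is piecewise linear in the
    repetition number with a hinge at repetition 4 (early vs late slopes).
    For ``'log10_trial_in_block'`` the gain is 1 + offset + b*log10(trial in
    block), with the offset implementing persistence: when a stimulus (or
    location) re-appears after an intervening block, a fraction
    ``truth.persistence`` of its previously accrued gamma gain carries over.
    Stimulus-specific trajectories are mixed with the across-stimulus mean
    trajectory according to ``specificity_transfer``.
    """
    stim_idx = np.array([truth.stimuli.index(s) for s in trials["stimulus_id"]])
    n = len(trials)
    tf = truth.specificity_transfer
    if truth.x_transform == "repetition":
        rep = trials["repetition_number"].to_numpy(dtype=float)
        rep = np.where(np.isfinite(rep), rep, 1.0)
        own_g = _hinge_gain(rep, truth.gamma_early_slope[stim_idx],
                            truth.gamma_late_slope[stim_idx])
        own_m = _hinge_gain(rep, truth.mua_decay_early[stim_idx],
                            truth.mua_decay_late[stim_idx])
        all_g = np.stack([_hinge_gain(rep, e, l) for e, l in
                          zip(truth.gamma_early_slope, truth.gamma_late_slope)])
        all_m = np.stack([_hinge_gain(rep, e, l) for e, l in
                          zip(truth.mua_decay_early, truth.mua_decay_late)])
        gamma_gain = (1 - tf) * own_g + tf * all_g.mean(axis=0)
        mua_gain = (1 - tf) * own_m + tf * all_m.mean(axis=0)
        xlog = np.log10(rep)
    else:
        tib = trials["trial_in_block"].to_numpy(dtype=float)
        slope = truth.gamma_late_slope
        gamma_gain = np.empty(n)
        mua_gain = np.empty(n)
        carry: dict = {}  # stimulus (or location) -> gain accrued above 1
        key_col = ("location" if (trials["location"] != "n/a").any()
                   else "stimulus_id")
        for bid, block in trials.groupby("block_id", sort=False):
            idx = block.index.to_numpy()
            s = stim_idx[trials.index.get_indexer(idx)]
            key = block[key_col].iloc[0]
            offset = carry.get(key, 0.0)
            tb = block["trial_in_block"].to_numpy(dtype=float)
            g = 1.0 + offset + slope[s] * np.log10(tb)
            m = _hinge_gain(np.minimum(tb, 200),
                            truth.mua_decay_early[s], truth.mua_decay_late[s])
            pos = trials.index.get_indexer(idx)
            gamma_gain[pos] = g
            mua_gain[pos] = m
            carry[key] = g[-1] - 1.0
            # memory of other stimuli decays by `persistence` per intervening block
            for other in list(carry):
                if other != key:
                    carry[other] = truth.persistence * carry[other]
        if tf > 0:
            mean_g = gamma_gain.mean()
            gamma_gain = (1 - tf) * gamma_gain + tf * mean_g
        xlog = np.log10(tib)
    gamma_freq = (truth.gamma_peak_hz[stim_idx]
                  + truth.gamma_freq_shift_hz[stim_idx] * xlog)
    return (np.maximum(gamma_gain, 0.02), gamma_freq,
            np.maximum(mua_gain, 0.02))


def synthesize_gamma_trajectories(truth: GroundTruth, n_sessions: int,
                                  n_reps: int = 15, noise_sd: float = 0.25,
                                  seed: int = 0) -> np.ndarray:
    """Session x stimulus x repetition gamma-band responses (trajectory level).

    Lightweight counterpart of :func:`synthesize_recording` for simulation
    studies that operate directly on repetition trajectories: the noiseless
    trajectory is ``gamma_base_power * gain(rep)`` (with specificity mixing
    from ``truth``), plus i.i.d. session noise whose SD is ``noise_sd`` times
    each stimulus's own mean trajectory level — response variability scales
    with response strength, as it does for neural power measures (and as the
    z-scoring step of the specificity analysis assumes).
    """
    rng = np.random.default_rng(seed)
    reps = np.arange(1, n_reps + 1, dtype=float)
    tf = truth.specificity_transfer
    own = np.stack([_hinge_gain(reps, e, l) for e, l in
                    zip(truth.gamma_early_slope, truth.gamma_late_slope)])
    mixed = (1 - tf) * own + tf * own.mean(axis=0, keepdims=True)
    base = truth.gamma_base_power[:, None]
    clean = base * mixed  # stimulus x rep
    scale = noise_sd * clean.mean(axis=1, keepdims=True)
    return clean[None] + scale * rng.standard_normal((n_sessions,) + clean.shape)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng, shape, nt, fs, exponent):
    """1/f^exponent noise, unit variance, along the last axis."""
    freqs = np.fft.rfftfreq(nt, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    z = rng.standard_normal(shape + (freqs.size,)) + 1j * rng.standard_normal(
        shape + (freqs.size,))
    x = np.fft.irfft(z * amp, n=nt, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _narrowband(rng, n_trials, nt, fs, f0, bw_hz):
    """Unit-variance narrowband Gaussian noise centered per-trial at f0."""
    freqs = np.fft.rfftfreq(nt, 1.0 / fs)
    # amplitude envelope: sqrt of a Gaussian PSD with spectral SD bw_hz
    amp = np.exp(-((freqs[None, :] - np.asarray(f0)[:, None]) ** 2)
                 / (4.0 * bw_hz ** 2))
    z = rng.standard_normal((n_trials, freqs.size)) + 1j * rng.standard_normal(
        (n_trials, freqs.size))
    x = np.fft.irfft(z * amp, n=nt, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def synthesize_recording(trials: pd.DataFrame, truth: GroundTruth,
                         n_sites: int = 4, fs: float = 500.0, seed: int = 0,
                         t_start: float = -1.3, t_stop: float = 1.5,
                         lfp_noise_sd: float = 1.0, mua_noise_sd: float = 1.0,
                         gamma_bandwidth_hz: float = 5.0,
                         session_gain_sd: float = 0.1,
                         rf_out_gain: float = 0.1) -> RecordingSession:
    """Synthesize a multi-site LFP/MUA session for a trial table.

    The narrowband gamma component is calibrated so that the stimulus-window
    power spectrum at the peak frequency, divided by the baseline spectrum,
    approximates ``gamma_base_power * gain(repetition)``. The gamma waveform
    is shared across sites (scaled by a fixed per-site gain) and multiplies
    the sustained MUA rate through ``truth.mua_locking``, producing MUA-LFP
    phase locking at the gamma frequency. ``session_gain_sd`` adds a single
    multiplicative session-level jitter per stimulus trajectory, emulating
    day-to-day variability. Trials with ``location == 'Out'`` (stimulus off
    the receptive fields) drive gamma and MUA only at ``rf_out_gain``.
    """
    if fs < 4 * float(np.max(truth.gamma_peak_hz) + 20):
        raise ValueError("fs too low for the requested gamma frequencies")
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    nt = int(round((t_stop - t_start) * fs))
    time = t_start + np.arange(nt) / fs
    n_trials = len(trials)
    stim_idx = np.array([truth.stimuli.index(s) for s in trials["stimulus_id"]])

    gamma_gain, gamma_freq, mua_gain = compute_trial_gains(trials, truth)
    sess_jit = 1.0 + session_gain_sd * rng.standard_normal(len(truth.stimuli))
    gamma_gain = gamma_gain * sess_jit[stim_idx]

    # background 1/f noise, per site and trial
    lfp = lfp_noise_sd * _pink_noise(rng, (n_sites, n_trials), nt, fs,
                                     truth.noise_1f_exponent)

    # expected baseline PSD at each gamma frequency, from the 1/f shaping:
    # periodogram of the shaped noise is proportional to f^-exponent; estimate
    # the proportionality constant via the variance normalization on a Welch
    # grid (250 ms segments), then read off the density at f0.
    from scipy.signal import welch

    base_mask = (time >= -1.0) & (time < 0.0)
    f_w, p_w = welch(lfp[:, : min(n_trials, 20), base_mask], fs=fs,
                     nperseg=int(0.25 * fs), axis=-1)
    p_noise = p_w.mean(axis=(0, 1))
    psd_at = np.interp(gamma_freq, f_w, p_noise)

    # stimulus gate with a 20 ms cosine ramp
    gate = np.clip(time / 0.02, 0.0, 1.0)
    gate = 0.5 - 0.5 * np.cos(np.pi * gate)

    gamma_unit = _narrowband(rng, n_trials, nt, fs, gamma_freq,
                             gamma_bandwidth_hz)
    # receptive-field gating: Out-of-RF stimulation barely drives the sites
    rf = np.where(trials["location"].to_numpy() == "Out", rf_out_gain, 1.0)
    # gamma variance so that the stimulus/baseline power ratio at the peak,
    # as seen by the +/-10 Hz multitaper estimator (which averages the
    # narrowband bump over 2W of bandwidth), equals gamma_base_power * gain
    from scipy.special import erf

    ratio = 1.0 + (truth.gamma_base_power[stim_idx] * gamma_gain - 1.0) * rf
    w_est = 10.0
    frac_in_band = erf(w_est / (gamma_bandwidth_hz * np.sqrt(2.0)))
    var_needed = np.maximum(ratio - 1.0, 0.0) * psd_at * 2 * w_est / frac_in_band
    amp = np.sqrt(var_needed)
    site_gain = 1.0 + 0.1 * rng.standard_normal(n_sites)
    gamma_sig = gamma_unit * gate[None, :] * amp[:, None]
    lfp = lfp + site_gain[:, None, None] * gamma_sig[None, :, :]

    # MUA envelope: floor + spontaneous + stimulus-driven rate, gamma-modulated
    floor = np.broadcast_to(np.atleast_1d(np.asarray(truth.mua_noise_floor,
                                                     dtype=float)),
                            (n_sites,)).copy()
    if np.ndim(truth.mua_noise_floor) == 0:
        floor = floor * rng.uniform(0.6, 1.4, n_sites)
    spont = rng.uniform(8.0, 14.0, n_sites)
    transient = 1.8 * np.exp(-((time - 0.07) ** 2) / (2 * 0.025 ** 2))
    sustained = np.where(time > 0, 1.0 - np.exp(-np.maximum(time, 0) / 0.05), 0.0)
    profile = (transient + sustained) * gate
    drive = (truth.mua_base[stim_idx] * mua_gain * rf)[:, None] * profile[None, :]
    lock = 1.0 + truth.mua_locking * np.clip(gamma_unit, -2.0, 2.0) * (
        gate[None, :])
    rate = (floor[:, None, None] + spont[:, None, None]
            + drive[None, :, :] * lock[None, :, :])
    mua = rate + mua_noise_sd * np.sqrt(np.maximum(rate, 0.0)) * \
        rng.standard_normal(rate.shape)
    mua = np.maximum(mua, 0.0)

    sites = [f"ch{i + 1:02d}" for i in range(n_sites)]
    return RecordingSession(lfp=lfp, mua=mua, fs=float(fs), time=time,
                            sites=sites, trials=trials.reset_index(drop=True),
                            truth=truth)


def grid_neighbors(n_sites: int) -> list[tuple[int, int]]:
    """Array-neighbor graph used for MUA-LFP pairing (linear chain)."""
    return [(i, i + 1) for i in range(n_sites - 1)]


def synthesize_eye_traces(trials: pd.DataFrame, events_per_trial: int = 2,
                          pupil_constriction: float = 1.0,
                          pupil_latency: float = 0.4, jitter_sd: float = 0.02,
                          amp_range=(0.3, 1.0), fs: float = 500.0,
                          t_start: float = -1.3, t_stop: float = 1.5,
                          seed: int = 0) -> EyeTrace:
    """Fixation jitter + injected microsaccade-like steps + pupil constriction.

    Injected steps (time, amplitude in dva, random direction) are recorded in
    ``injected_events`` as ``(trial, onset_s, amplitude)`` for detector
    validation. The pupil trace shows a stimulus-locked constriction of
    amplitude ``pupil_constriction`` (in baseline-SD-comparable a.u.) peaking
    at ``pupil_latency`` seconds after stimulus onset.
    """
    rng = np.random.default_rng(seed)
    nt = int(round((t_stop - t_start) * fs))
    time = t_start + np.arange(nt) / fs
    n_trials = len(trials)
    gaze_x = jitter_sd * rng.standard_normal((n_trials, nt))
    gaze_y = jitter_sd * rng.standard_normal((n_trials, nt))
    events = []
    for tr in range(n_trials):
        for _ in range(events_per_trial):
            onset = rng.uniform(time[0] + 0.1, time[-1] - 0.1)
            amp = rng.uniform(*amp_range)
            theta = rng.uniform(0, 2 * np.pi)
            step = time >= onset
            gaze_x[tr, step] += amp * np.cos(theta)
            gaze_y[tr, step] += amp * np.sin(theta)
            events.append((tr, float(onset), float(amp)))
    pupil = 10.0 + 0.05 * rng.standard_normal((n_trials, nt))
    constr = pupil_constriction * np.exp(
        -((time - pupil_latency) ** 2) / (2 * 0.12 ** 2))
    pupil -= np.where(time > 0, constr, 0.0)[None, :] * 0.05 / 0.05
    return EyeTrace(gaze_x=gaze_x, gaze_y=gaze_y, pupil=pupil, fs=float(fs),
                    time=time, injected_events=events)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    # "n/a" is a meaningful location label, not missing data
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=[""], dtype={"location": str})
    for col in ("trial_index", "repetition_number", "trial_in_block", "lag",
                "change_time"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(str).str.lower().isin(
            ["true", "1"])
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]


def save_session(session: RecordingSession, path) -> None:
    """HDF5 container: /lfp, /mua, /time datasets, /trials column group,
    fs and seed as attributes, ground truth as a JSON attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp, compression="gzip")
        f.create_dataset("mua", data=session.mua, compression="gzip")
        f.create_dataset("time", data=session.time)
        f.attrs["fs"] = session.fs
        f.attrs["sites"] = json.dumps(session.sites)
        g = f.create_group("trials")
        for col in session.trials.columns:
            vals = session.trials[col].to_numpy()
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)
        if session.truth is not None:
            d = dataclasses.asdict(session.truth)
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    d[k] = v.tolist()
            f.attrs["truth"] = json.dumps(d)


def load_session(path) -> RecordingSession:
    with h5py.File(path, "r") as f:
        cols = {}
        for col in f["trials"]:
            vals = f["trials"][col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
        trials = pd.DataFrame(cols)[TRIAL_COLUMNS]
        truth = None
        if "truth" in f.attrs:
            truth = GroundTruth(**json.loads(f.attrs["truth"]))
        return RecordingSession(
            lfp=f["lfp"][()], mua=f["mua"][()], fs=float(f.attrs["fs"]),
            time=f["time"][()], sites=json.loads(f.attrs["sites"]),
            trials=trials, truth=truth)
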
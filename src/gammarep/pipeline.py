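"""End-to-end experiments on synthetic data.

``run_dataset1_analysis`` reproduces the natural-image workflow: synthesize
interleaved constrained-lag sessions, compute dMUA and relative LFP power,
detect and validate per-stimulus gamma peaks, fit early/late repetition
slopes and RRCs, test them with sign-flip/exchange permutation tests, run
the cross-validated drive-dependence correlation, and compute the split-half
stimulus-specificity correlation (scalar gamma band plus a correlation
spectrum over frequencies and a dMUA time course).

``run_block_analysis`` covers the grating block designs: ABA/BBA stimulus
blocks (specificity and persistence contrasts on log-trial fits, plus a
single-trial regression model) and In/Out location blocks (location
specificity and persistence with +/- 3 trial binning).

Everything is driven by a :class:`RunConfig`; results are data-first
(dicts of scalars and DataFrames, serialized to JSON/CSV); runs are
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gamma_peaks as gp
from . import preprocess as pp
from . import repmetrics as rm
from . import specificity as sp
from . import stats as st
from . import synthio as sio
from .spectral import DPSS_250MS, taper_power

__all__ = ["RunConfig", "run_dataset1_analysis", "run_block_analysis",
           "write_report"]


@dataclass
class RunConfig:
    """Generator + analysis parameters for one experiment run.

    Times in seconds, frequencies in Hz. ``analysis_reps`` truncates natural
    sequences to the first N repetitions per stimulus (matching the practice
    of analyzing only the first 15 of 20).
    """

    design: str = "natural"  # natural | aba | location
    n_sessions: int = 6
    n_stimuli: int = 6
    reps_per_stim: int = 18
    analysis_reps: int = 15
    subset_size: int = 3
    max_lag: int = 4
    trials_per_block: int = 100
    n_sites: int = 4
    fs: float = 500.0
    specificity_transfer: float = 0.0
    persistence: float = 0.4
    simulate_errors: bool = False
    stim_window: tuple = (0.5, 1.5)
    base_window: tuple = (-1.0, 0.0)
    mua_window: tuple = (0.05, 1.0)
    mua_base_window: tuple = (-0.95, 0.0)
    n_perm: int = 1000
    s_splits: int = 100
    n_boot: int = 1000
    seed: int = 1
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.design not in ("natural", "aba", "location"):
            raise ValueError(f"unknown design: {self.design!r}")
        if self.n_sessions < 2:
            raise ValueError("need at least 2 sessions")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stim_window", "base_window", "mua_window",
                    "mua_base_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# per-session feature extraction
# ---------------------------------------------------------------------------

def _relative_power(session: sio.RecordingSession, cfg: RunConfig):
    """Trial-wise stimulus power / session-average baseline power.

    Returns ``(rel, freqs)`` with rel shaped (site, trial, freq)."""
    lfp = session.lfp
    stim_ep = pp.epoch(lfp, session.time, session.fs, cfg.stim_window,
                       DPSS_250MS.epoch_len, origin="stimulus")
    base_ep = pp.epoch(lfp, session.time, session.fs, cfg.base_window,
                       DPSS_250MS.epoch_len, origin="baseline")
    p_stim = taper_power(stim_ep, DPSS_250MS)  # (trial, site, freq)
    p_base = taper_power(base_ep, DPSS_250MS)
    norm = pp.baseline_normalize(p_stim.power.transpose(1, 0, 2),
                                 p_base.power.transpose(1, 0, 2))
    return norm.values, p_stim.freqs


def _dmua_response(session: sio.RecordingSession, cfg: RunConfig):
    """Site x trial stimulation/baseline dMUA ratio, plus the binned
    time-resolved ratio (site, trial, bin) and bin centers."""
    dmua, centers = pp.compute_dmua(session.mua, session.time, session.fs)
    stim_mask = (centers >= cfg.mua_window[0]) & (centers < cfg.mua_window[1])
    base_mask = (centers >= cfg.mua_base_window[0]) & (centers < cfg.mua_base_window[1])
    num = dmua[:, :, stim_mask].mean(axis=2, keepdims=True)
    base = dmua[:, :, base_mask].mean(axis=2, keepdims=True)
    scalar = pp.baseline_normalize(num, base).values[:, :, 0]
    resolved = pp.baseline_normalize(dmua, base).values
    return scalar, resolved, centers


def _traj_matrix(trials: pd.DataFrame, values: np.ndarray, stimuli: list,
                 n_reps: int) -> np.ndarray:
    """Arrange per-trial values (site, trial[, bin]) into a
    (stimulus, site, rep[, bin]) matrix over correct trials."""
    extra = values.shape[2:]
    out = np.full((len(stimuli), values.shape[0], n_reps) + extra, np.nan)
    rep = trials["repetition_number"].to_numpy(dtype=float)
    ok = trials["correct"].to_numpy(dtype=bool) & np.isfinite(rep)
    for i in np.flatnonzero(ok):
        r = int(rep[i])
        if 1 <= r <= n_reps:
            s = stimuli.index(trials["stimulus_id"].iloc[i])
            out[s, :, r - 1] = values[:, i]
    return out


def _make_truth(cfg: RunConfig, rng: np.random.Generator, stimuli,
                x_transform: str) -> sio.GroundTruth:
    overrides = dict(specificity_transfer=cfg.specificity_transfer,
                     persistence=cfg.persistence, x_transform=x_transform,
                     seed=cfg.seed)
    if x_transform == "log10_trial_in_block":
        # ~50% gamma increase over a 100-trial block: 1 + 2b = 1.5
        n = len(stimuli)
        overrides.update(gamma_late_slope=rng.normal(0.25, 0.05, n),
                         gamma_freq_shift_hz=rng.normal(1.0, 0.5, n))
    return sio.GroundTruth.random(stimuli, rng, **overrides)


# ---------------------------------------------------------------------------
# dataset-1 style analysis (natural images)
# ---------------------------------------------------------------------------

def run_dataset1_analysis(cfg: RunConfig) -> dict:
    if cfg.design != "natural":
        raise ValueError("run_dataset1_analysis requires design='natural'")
    rng = np.random.default_rng(cfg.seed)
    stimuli = [f"s{i + 1:02d}" for i in range(cfg.n_stimuli)]
    truth = _make_truth(cfg, rng, stimuli, "repetition")
    exclusions = {"low_coverage_sessions": 0, "unvalidated_stimuli": 0,
                  "degenerate_rrc": 0}

    sessions, rels, dmua_scalar, dmua_resolved = [], [], [], []
    freqs = centers = None
    for k in range(cfg.n_sessions):
        sub = int(rng.integers(2 ** 31 - 1))
        trials = sio.generate_natural_sequence(
            cfg.n_stimuli, cfg.reps_per_stim, cfg.subset_size, cfg.max_lag,
            seed=sub, session_id=f"s{k + 1:02d}")
        if cfg.simulate_errors:
            trials = sio.simulate_correctness(trials, seed=sub + 1)
        ses = sio.synthesize_recording(trials, truth, n_sites=cfg.n_sites,
                                       fs=cfg.fs, seed=sub + 2)
        rel, freqs = _relative_power(ses, cfg)
        scalar, resolved, centers = _dmua_response(ses, cfg)
        sessions.append(ses)
        rels.append(rel)
        dmua_scalar.append(scalar)
        dmua_resolved.append(resolved)

    # per-stimulus gamma peak: grand-average relative spectrum, validated on
    # trials pooled across sessions
    peaks = {}
    peak_rows = []
    for s, stim in enumerate(stimuli):
        pooled = []
        for ses, rel in zip(sessions, rels):
            sel = (ses.trials["stimulus_id"] == stim).to_numpy()
            pooled.append(rel[:, sel, :].mean(axis=0))  # site-avg, (trial, freq)
        pooled = np.concatenate(pooled, axis=0)
        found = gp.find_peaks(pooled.mean(axis=0), freqs, stimulus_id=stim)
        validated, p = False, np.nan
        if found:
            validated, p = gp.validate_peak(pooled, freqs, found[0].freq_hz,
                                            n_perm=cfg.n_perm, rng=rng)
        if found and validated:
            peaks[stim] = found[0].freq_hz
        else:
            exclusions["unvalidated_stimuli"] += 1
        for pk in found:
            peak_rows.append(dict(stimulus_id=stim, freq_hz=pk.freq_hz,
                                  rank=pk.rank, height=pk.height,
                                  p_perm=p if pk.rank == 1 else np.nan,
                                  validated=validated if pk.rank == 1 else False))
    peak_table = pd.DataFrame(peak_rows)

    # gamma-band response per trial (site x trial), peak +/- 16 Hz
    n_reps = cfg.analysis_reps
    gamma_traj, mua_traj, mua_time_traj = [], [], []
    for ses, rel, scalar, resolved in zip(sessions, rels, dmua_scalar,
                                          dmua_resolved):
        gam = np.full((cfg.n_sites, len(ses.trials)), np.nan)
        for stim, pk in peaks.items():
            sel = (ses.trials["stimulus_id"] == stim).to_numpy()
            gam[:, sel] = gp.band_mean(rel[:, sel, :], freqs, pk, 16.0)
        gamma_traj.append(_traj_matrix(ses.trials, gam, stimuli, n_reps))
        mua_traj.append(_traj_matrix(ses.trials, scalar, stimuli, n_reps))
        # coarse 100 ms bins for the time-resolved specificity analysis
        coarse_idx = [(centers >= t) & (centers < t + 0.1)
                      for t in np.arange(0.0, 1.0, 0.1)]
        coarse = np.stack([resolved[:, :, m].mean(axis=2) for m in coarse_idx],
                          axis=2)
        mua_time_traj.append(_traj_matrix(ses.trials, coarse, stimuli, n_reps))
    gamma_traj = np.stack(gamma_traj)  # (session, stim, site, rep)
    mua_traj = np.stack(mua_traj)
    mua_time_traj = np.stack(mua_time_traj)  # (..., rep, timebin)

    # early/late slopes per session & stimulus (site-averaged responses)
    def slope_table(traj, x_transform="repetition"):
        rows = []
        for k in range(cfg.n_sessions):
            for s, stim in enumerate(stimuli):
                y = np.nanmean(traj[k, s], axis=0)
                for seg in ("early", "late", "all"):
                    f = rm.fit_slopes(y, segment=seg, x_transform=x_transform,
                                      stimulus_id=stim,
                                      session_id=f"s{k + 1:02d}")
                    if f is not None:
                        val = rm.rrc(f)
                        rows.append(dict(session_id=f.session_id,
                                         stimulus_id=stim, segment=seg,
                                         slope=f.slope, intercept=f.intercept,
                                         rrc=val))
        return pd.DataFrame(rows)

    gamma_fits = slope_table(gamma_traj)
    mua_fits = slope_table(mua_traj)
    exclusions["degenerate_rrc"] = int(gamma_fits["rrc"].isna().sum()
                                       + mua_fits["rrc"].isna().sum())

    def seg_test(fits, seg):
        sub = fits[fits["segment"] == seg]
        per_sess = sub.groupby("session_id")["slope"].mean().to_numpy()
        t = st.signflip_test(per_sess, n_perm=cfg.n_perm, rng=rng)
        sem = st.bootstrap_sem(
            sub.pivot_table(index="session_id", columns="stimulus_id",
                            values="slope").to_numpy(),
            n_boot=cfg.n_boot, rng=rng)
        return dict(mean_slope=t.observed, p=t.p, sem=sem)

    tests = {f"gamma_{seg}": seg_test(gamma_fits, seg)
             for seg in ("early", "late")}
    tests.update({f"dmua_{seg}": seg_test(mua_fits, seg)
                  for seg in ("early", "late")})
    # early vs late contrast (exchange test over sessions)
    for name, fits in (("gamma", gamma_fits), ("dmua", mua_fits)):
        piv = fits.pivot_table(index="session_id", columns="segment",
                               values="slope")
        t = st.exchange_test(piv["early"].to_numpy(), piv["late"].to_numpy(),
                             n_perm=cfg.n_perm, rng=rng)
        tests[f"{name}_early_vs_late"] = dict(mean_diff=t.observed, p=t.p)

    # drive dependence
    drive = {}
    for name, traj in (("gamma", gamma_traj), ("dmua", mua_traj)):
        try:
            rho, slopes, intercepts = rm.crossval_drive_dependence(traj, "all")
            halves = rm.median_split_control(intercepts[:, 1], slopes[:, 0],
                                             n_perm=cfg.n_perm, rng=rng)
            drive[name] = dict(rho=rho, median_split=halves)
        except ValueError as err:
            drive[name] = dict(error=str(err))

    # specificity: gamma-band scalar, correlation spectrum, dMUA time course
    gamma_vec = sp.build_session_vectors(gamma_traj)
    spec_scalar = sp.permutation_null(gamma_vec, n_stimuli=cfg.n_stimuli,
                                      s=cfg.s_splits, n_perm=cfg.n_perm,
                                      rng=rng)
    band = (freqs >= 20) & (freqs <= 100)
    rel_traj = []
    for ses, rel in zip(sessions, rels):
        rel_traj.append(_traj_matrix(ses.trials, rel[:, :, band], stimuli,
                                     n_reps))
    rel_traj = np.stack(rel_traj)  # (session, stim, site, rep, freq)
    spec_spectrum = sp.correlation_spectrum(rel_traj, freqs[band],
                                            s=cfg.s_splits, n_perm=cfg.n_perm,
                                            rng=rng)
    spec_time = sp.correlation_spectrum(mua_time_traj,
                                        np.arange(0.05, 1.0, 0.1),
                                        s=cfg.s_splits, n_perm=cfg.n_perm,
                                        rng=rng)

    report = dict(
        config=dataclasses.asdict(cfg),
        truth_summary=dict(
            specificity_transfer=truth.specificity_transfer,
            gamma_peaks_hz={s: float(f) for s, f in
                            zip(stimuli, truth.gamma_peak_hz)}),
        peaks=peak_table,
        gamma_fits=gamma_fits,
        dmua_fits=mua_fits,
        tests=tests,
        drive_dependence=drive,
        specificity=dict(
            gamma_band_r=float(spec_scalar.observed_r[0]),
            gamma_band_p=float(spec_scalar.p[0]),
            spectrum=pd.DataFrame(dict(freq_hz=spec_spectrum.bins,
                                       r=spec_spectrum.observed_r,
                                       p=spec_spectrum.p,
                                       significant=spec_spectrum.fdr_mask)),
            dmua_time=pd.DataFrame(dict(time_s=spec_time.bins,
                                        r=spec_time.observed_r,
                                        p=spec_time.p,
                                        significant=spec_time.fdr_mask))),
        exclusions=exclusions,
    )
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
    return report


# ---------------------------------------------------------------------------
# block designs (datasets 2 and 3)
# ---------------------------------------------------------------------------

def _session_gamma_per_trial(ses: sio.RecordingSession, cfg: RunConfig,
                             half_band: float = 8.0):
    """Site-averaged gamma-band relative power per trial, peak +/- 8 Hz
    determined per stimulus and session."""
    rel, freqs = _relative_power(ses, cfg)
    out = np.full(len(ses.trials), np.nan)
    for stim in ses.trials["stimulus_id"].unique():
        sel = (ses.trials["stimulus_id"] == stim).to_numpy()
        if ses.trials.loc[sel, "location"].iloc[0] == "Out" and \
                (ses.trials["location"] != "n/a").any():
            # peak determination uses RF-stimulated trials only
            sel_peak = sel & (ses.trials["location"] == "In").to_numpy()
        else:
            sel_peak = sel
        if not sel_peak.any():
            sel_peak = sel
        mean_spec = rel[:, sel_peak, :].mean(axis=(0, 1))
        found = gp.find_peaks(mean_spec, freqs, stimulus_id=stim)
        pk = found[0].freq_hz if found else 60.0
        out[sel] = gp.band_mean(rel[:, sel, :], freqs, pk, half_band).mean(axis=0)
    return out


def _block_fits(trials: pd.DataFrame, gamma: np.ndarray):
    """Log-trial fit per block: intercept, slope, RRC (trials 1-4 excluded)."""
    rows = []
    for bid, block in trials.groupby("block_id", sort=False):
        idx = trials.index.get_indexer(block.index.to_numpy())
        f = rm.fit_slopes(gamma[idx], reps=block["trial_in_block"].to_numpy(float),
                          segment="late", x_transform="log10_trial_in_block")
        if f is None:
            continue
        rows.append(dict(block_id=bid, block_type=block["block_type"].iloc[0],
                         stimulus_id=block["stimulus_id"].iloc[0],
                         location=block["location"].iloc[0],
                         intercept=f.intercept, slope=f.slope, rrc=rm.rrc(f)))
    return pd.DataFrame(rows)


def _paired_contrast(table: pd.DataFrame, type_a: str, type_b: str,
                     value: str, n_perm: int, rng, within: bool = False):
    """Exchange test of ``value`` between two block types.

    Between-session contrasts pair the i-th session containing type_a with
    the i-th containing type_b; within-session contrasts require both types
    in the same session.
    """
    a = table[table["block_type"] == type_a]
    b = table[table["block_type"] == type_b]
    if a.empty or b.empty:
        raise ValueError(f"design lacks contrast blocks {type_a} vs {type_b}")
    if within:
        merged = a.merge(b, on="session_id", suffixes=("_a", "_b"))
        va = merged[f"{value}_a"].to_numpy()
        vb = merged[f"{value}_b"].to_numpy()
    else:
        n = min(len(a), len(b))
        va = a[value].to_numpy()[:n]
        vb = b[value].to_numpy()[:n]
    t = st.exchange_test(va, vb, n_perm=n_perm, rng=rng)
    return dict(mean_a=float(np.nanmean(va)), mean_b=float(np.nanmean(vb)),
                diff=t.observed, p=t.p, n_pairs=int(len(va)))


def _nuisance_columns(trials: pd.DataFrame, rng) -> pd.DataFrame:
    """Behavioral / timing covariates for the regression models."""
    out = trials.copy()
    eye = sio.synthesize_eye_traces(trials, events_per_trial=2,
                                    seed=int(rng.integers(2 ** 31 - 1)))
    ms = st.detect_microsaccades(eye.gaze_x, eye.gaze_y, eye.fs)
    rate = np.zeros(len(trials))
    if len(ms):
        counts = ms.groupby("trial").size()
        rate[counts.index.to_numpy()] = counts.to_numpy()
    dur = eye.time[-1] - eye.time[0]
    out["ms_rate"] = rate / dur
    z, _ = st.pupil_response(eye.pupil, eye.time)
    out["pupil"] = np.nanmean(z, axis=1)
    out["isi"] = rng.uniform(2.0, 3.0, len(trials))
    out["prev_duration"] = np.r_[np.nan, out["change_time"].to_numpy()[:-1]]
    out["reaction_time"] = rng.lognormal(-1.0, 0.2, len(trials))
    out["trial_num"] = out["trial_index"]
    return out


def run_block_analysis(cfg: RunConfig, dataset: int = 2) -> dict:
    """Grating block designs: stimulus blocks (dataset 2: ABA/BBA) or
    location blocks (dataset 3: InIn / OutIn / InOutIn / OutOutIn)."""
    if dataset not in (2, 3):
        raise ValueError("dataset must be 2 or 3")
    if cfg.design not in ("aba", "location"):
        raise ValueError("run_block_analysis requires design 'aba' or 'location'")
    rng = np.random.default_rng(cfg.seed)
    if dataset == 2:
        stimuli = ["g1", "g2"]
        designs = ["ABA", "BBA"]
        tpb = cfg.trials_per_block
    else:
        stimuli = ["g1"]
        designs = ["InIn", "OutIn", "InOutIn", "OutOutIn"]
        tpb = min(cfg.trials_per_block, 50)
    truth = _make_truth(cfg, rng, stimuli, "log10_trial_in_block")

    fit_rows, trial_frames = [], []
    for k in range(cfg.n_sessions):
        design = designs[k % len(designs)]
        sub = int(rng.integers(2 ** 31 - 1))
        trials = sio.generate_block_sequence(design, tpb, stimuli=stimuli,
                                             seed=sub,
                                             session_id=f"s{k + 1:02d}",
                                             swap_stimuli=bool(k % 2) and dataset == 2)
        ses = sio.synthesize_recording(trials, truth, n_sites=cfg.n_sites,
                                       fs=cfg.fs, seed=sub + 1)
        gamma = _session_gamma_per_trial(ses, cfg)
        if dataset == 3:
            # responses binned +/- 3 trials within each block
            for bid, block in trials.groupby("block_id", sort=False):
                idx = trials.index.get_indexer(block.index.to_numpy())
                gamma[idx] = st.binned_means(
                    gamma[idx], block["trial_in_block"].to_numpy())
        fits = _block_fits(trials, gamma)
        fits["session_id"] = f"s{k + 1:02d}"
        fits["design"] = design
        fit_rows.append(fits)
        tf = trials.copy()
        tf["gamma"] = gamma
        tf["design"] = design
        trial_frames.append(tf)
    fit_table = pd.concat(fit_rows, ignore_index=True)
    all_trials = pd.concat(trial_frames, ignore_index=True)

    contrasts = {}
    if dataset == 2:
        pairs = [("A[B]A", "B[B]A", False, "stimulus_specificity"),
                 ("AB[A]", "BB[A]", False, "persistence_between"),
                 ("AB[A]", "[A]BA", True, "persistence_within")]
    else:
        pairs = [("Out[In]", "In[In]", False, "location_specificity"),
                 ("InOut[In]", "OutOut[In]", False, "persistence_location")]
    for type_a, type_b, within, name in pairs:
        res = {}
        for value in ("intercept", "rrc", "slope"):
            try:
                res[value] = _paired_contrast(fit_table, type_a, type_b, value,
                                              cfg.n_perm, rng, within=within)
            except ValueError as err:
                res[value] = dict(error=str(err))
        contrasts[name] = res

    # single-trial regression model
    reg_trials = _nuisance_columns(all_trials, rng)
    if dataset == 2:
        reg_trials["immediate_rep"] = (reg_trials["block_type"] == "B[B]A").astype(int)
        reg_trials["delayed_rep"] = (reg_trials["block_type"] == "AB[A]").astype(int)
        spec = st.RegressionSpec(
            response="gamma", log_terms=["repetition_number"],
            continuous=["trial_num", "ms_rate", "pupil", "isi",
                        "reaction_time"],
            categorical=["session_id", "stimulus_id"],
            block_indicators=["immediate_rep", "delayed_rep"])
        reg_data = reg_trials
    else:
        # model only RF-stimulated trials of the contrast blocks
        keep = reg_trials["block_type"].isin(["Out[In]", "In[In]",
                                              "InOut[In]", "OutOut[In]"])
        reg_data = reg_trials[keep & (reg_trials["location"] == "In")].copy()
        reg_data["local_rep"] = reg_data["trial_in_block"]
        spec = st.RegressionSpec(
            response="gamma", log_terms=["local_rep", "trial_num"],
            continuous=["ms_rate", "pupil"],
            categorical=["session_id"], block_indicators=[],
            interactions=False)
    reg_data = reg_data[np.isfinite(reg_data["gamma"]) & (reg_data["gamma"] > 0)]
    reg_table, _ = st.fit_block_regression(reg_data, spec)

    report = dict(config=dataclasses.asdict(cfg), dataset=dataset,
                  block_fits=fit_table, contrasts=contrasts,
                  regression=reg_table.reset_index().rename(
                      columns={"index": "term"}),
                  exclusions={"degenerate_rrc":
                              int(fit_table["rrc"].isna().sum())})
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
    return report


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return None  # written separately as CSV
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(report: dict, out_dir) -> None:
    """Serialize a report: scalars to report.json, tables to CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scalars = {}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=False)
        elif isinstance(val, dict):
            sub = {}
            for k2, v2 in val.items():
                if isinstance(v2, pd.DataFrame):
                    v2.to_csv(out / f"{key}_{k2}.csv", index=False)
                else:
                    sub[k2] = _jsonable(v2)
            scalars[key] = sub
        else:
            scalars[key] = _jsonable(val)
    with open(out / "report.json", "w") as fh:
        json.dump(scalars, fh, indent=1)
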
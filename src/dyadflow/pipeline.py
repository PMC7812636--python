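"""End-to-end orchestration: raw recordings -> node series -> screening ->
link networks -> effectiveness and correlation.

The analysis replicates the study design: (1) *screening* compares dyad-level
block GC against 100 phase-randomized surrogate ensembles for every candidate
model (a model = SCL + RR + one neurometric per subject) and flags the models
significant in both cooperative conditions; (2) *link analysis* runs
pairwise-conditional GC on the flagged models, thresholds links with the
asymptotic chi-squared test and compares between-subject densities across
conditions; (3) *effectiveness* pools cooperative scores, labels the
quartile extremes and correlates dyad GC with performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import granger, network, prep, preprocessing as pre
from .behavior import label_effectiveness
from .io import Montage, default_montage
from .neurometrics import (
    BAND_NAMES,
    ModelSpec,
    compute_psd,
    define_bands,
    engagement_series,
    enumerate_model_specs,
    estimate_iaf,
    roi_band_series,
    workload_series,
)
from .synthetic import CONDITIONS, EYES_CLOSED, REST, TASK_START, SyntheticCohort

__all__ = [
    "PipelineConfig",
    "PreparedSubject",
    "PreparedCohort",
    "prepare_session",
    "prepare_cohort",
    "build_dyad_matrix",
    "run_screening",
    "run_link_analysis",
    "run_effectiveness",
    "run_all",
]


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study's stated settings."""

    ecg_band: tuple[float, float] = (5.0, 20.0)
    eeg_band: tuple[float, float] = (1.0, 35.0)
    filter_order: int = 5
    notch: bool = True
    artifact_amp_uv: float = 100.0
    artifact_slope_uv_s: float = 10.0
    artifact_step_uv: float = 25.0
    blink_correction: bool = False
    scl_divide_baseline: bool = False
    p_max: int = 5
    n_surrogates: int = 100
    alpha: float = 0.05
    seed: int = 0
    run_adf: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PreparedSubject:
    """One subject's node series for one dyad/condition."""

    subject_id: str
    scl: tuple[np.ndarray, np.ndarray]  # (integer-second times, values)
    rr: tuple[np.ndarray, np.ndarray]
    neuro: dict  # spec name -> (times, values)
    iaf: float
    level_means: dict  # raw (pre-normalization) series means for group stats
    rejected_fraction: float


@dataclass
class PreparedCohort:
    subjects: dict  # (dyad_id, condition, 'a'|'b') -> PreparedSubject
    dyads: list
    conditions: list
    montage: Montage
    behaviour: pd.DataFrame
    config: PipelineConfig
    log: list = field(default_factory=list)


def _task_window(rec, duration: float) -> np.ndarray:
    lo = int(round((TASK_START - rec.t0) * rec.fs))
    hi = lo + int(round(duration * rec.fs))
    return rec.data[lo:hi]


def prepare_session(session, config: PipelineConfig, montage: Montage):
    """Extract both subjects' six node series from one session's recordings."""
    manifest = session.manifest
    duration = manifest.duration
    out = {}
    for subj_key, sid in zip("ab", sorted(session.recordings)):
        mods = session.recordings[sid]

        # --- ECG -> RR tachogram on the 1 Hz grid
        ecg = mods["ECG"]
        filtered = pre.butter_bandpass(
            ecg.data[:, 0], ecg.fs, *config.ecg_band, order=config.filter_order
        )
        task_ecg = filtered[int((TASK_START - ecg.t0) * ecg.fs) : int((TASK_START + duration - ecg.t0) * ecg.fs)]
        rr_series = pre.clean_ectopic_rr(pre.pan_tompkins_rpeaks(task_ecg, ecg.fs))
        rr_times, rr_vals = prep.resample_to_1hz(rr_series.rr, rr_series.midpoints)
        rr_times = rr_times + TASK_START

        # --- EDA -> double-differenced tonic SCL on the 1 Hz grid
        eda = mods["EDA"]
        scl = pre.extract_tonic_scl(eda.data[:, 0], eda.fs)
        scl.times = scl.times + eda.t0
        scl = pre.baseline_normalize_scl(scl, REST, divide=config.scl_divide_baseline)
        in_task = (scl.times >= TASK_START) & (scl.times < TASK_START + duration)
        scl_t, scl_v = prep.resample_to_1hz(scl.values[in_task], scl.times[in_task])
        scl_node = prep.second_difference(scl_v)
        scl_times = scl_t[2:]

        # --- EEG -> per-epoch neurometrics
        eeg = mods["EEG"]
        x = pre.butter_bandpass(eeg.data, eeg.fs, *config.eeg_band, order=config.filter_order)
        if config.notch:
            x = pre.notch50(x, eeg.fs)
        epochs = pre.epoch_signal(x, eeg.fs, eeg.channel_names)
        if config.blink_correction:
            epochs = pre.eyeblink_regress(epochs)
        epochs = pre.reject_artifacts(
            epochs,
            amp_uv=config.artifact_amp_uv,
            slope_uv_per_s=config.artifact_slope_uv_s,
            step_uv=config.artifact_step_uv,
        )
        psd = compute_psd(epochs)

        ec_lo = int(EYES_CLOSED[0] - eeg.t0)
        ec_hi = int(EYES_CLOSED[1] - eeg.t0)
        rest_psd = type(psd)(
            psd=psd.psd[ec_lo:ec_hi], freqs=psd.freqs, channel_names=psd.channel_names
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iaf = estimate_iaf(rest_psd)
        bands = define_bands(iaf)

        t_lo = int(TASK_START - eeg.t0)
        task_psd = type(psd)(
            psd=psd.psd[t_lo : t_lo + int(duration)], freqs=psd.freqs, channel_names=psd.channel_names
        )
        neuro: dict = {}
        level_means: dict = {}
        epoch_times = TASK_START + np.arange(task_psd.psd.shape[0], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series_by_name = {
                "Workload": workload_series(task_psd, bands),
                "Engagement": engagement_series(task_psd, bands),
            }
            for roi in montage.roi_registry:
                for band in BAND_NAMES:
                    series_by_name[f"{roi}:{band}"] = roi_band_series(
                        task_psd, montage, roi, band, bands
                    )
        for name, values in series_by_name.items():
            level_means[name] = float(np.nanmean(values))
            neuro[name] = (epoch_times, prep.interpolate_nan_spline(values))
        level_means["RR"] = float(np.mean(rr_series.rr))
        level_means["SCL"] = float(np.mean(scl.values[in_task]))

        out[subj_key] = PreparedSubject(
            subject_id=sid,
            scl=(scl_times, scl_node),
            rr=(rr_times, rr_vals),
            neuro=neuro,
            iaf=iaf,
            level_means=level_means,
            rejected_fraction=epochs.rejected_fraction,
        )
    return out


def prepare_cohort(cohort: SyntheticCohort, config: PipelineConfig | None = None,
                   montage: Montage | None = None) -> PreparedCohort:
    """Run preprocessing and time-series preparation for a whole cohort."""
    config = config or PipelineConfig()
    montage = montage or default_montage()
    subjects: dict = {}
    log: list = []
    for (dyad_id, condition), session in sorted(cohort.sessions.items()):
        pair = prepare_session(session, config, montage)
        for subj_key, prepared in pair.items():
            subjects[(dyad_id, condition, subj_key)] = prepared
        log.append(
            {
                "dyad": dyad_id,
                "condition": condition,
                "rejected_a": pair["a"].rejected_fraction,
                "rejected_b": pair["b"].rejected_fraction,
            }
        )
    dyads = sorted({k[0] for k in subjects})
    conditions = [c for c in CONDITIONS if any(k[1] == c for k in subjects)]
    return PreparedCohort(
        subjects=subjects,
        dyads=dyads,
        conditions=conditions,
        montage=montage,
        behaviour=pd.DataFrame(cohort.behaviour),
        config=config,
        log=log,
    )


def build_dyad_matrix(prepared: PreparedCohort, dyad_id: str, condition: str,
                      spec: ModelSpec | str, run_adf: bool | None = None) -> prep.DyadMatrix:
    """Assemble the 6-column matrix for one dyad/condition and model."""
    name = str(spec)
    a = prepared.subjects[(dyad_id, condition, "a")]
    b = prepared.subjects[(dyad_id, condition, "b")]
    nodes = {
        "SCLa": a.scl,
        "RRa": a.rr,
        "NEUROa": a.neuro[name],
        "SCLb": b.scl,
        "RRb": b.rr,
        "NEUROb": b.neuro[name],
    }
    do_adf = prepared.config.run_adf if run_adf is None else run_adf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prep.assemble_dyad_matrix(nodes, dyad_id=dyad_id, condition=condition, run_adf=do_adf)


def _common_order(prepared: PreparedCohort, dyad_id: str, condition: str) -> int:
    """One VAR order per dyad/condition, selected by BIC on the four
    autonomic columns shared by every candidate model."""
    any_spec = next(iter(prepared.subjects[(dyad_id, condition, "a")].neuro))
    Y = build_dyad_matrix(prepared, dyad_id, condition, any_spec, run_adf=False).values
    return granger.select_order(Y[:, [0, 1, 3, 4]], p_max=prepared.config.p_max)


def run_screening(prepared: PreparedCohort, specs: list[ModelSpec] | None = None) -> pd.DataFrame:
    """Dyad-level real-vs-surrogate GC for every candidate model x condition.

    Returns one row per (model, condition) with the paired-t statistics and
    a ``flagged`` column marking models significant (real above surrogate)
    in every cooperative condition present.
    """
    config = prepared.config
    specs = specs if specs is not None else enumerate_model_specs(prepared.montage)
    orders = {
        (d, c): _common_order(prepared, d, c)
        for d in prepared.dyads
        for c in prepared.conditions
    }
    rows = []
    for spec in specs:
        name = str(spec)
        for condition in prepared.conditions:
            real, surr = [], []
            for di, dyad_id in enumerate(prepared.dyads):
                Y = build_dyad_matrix(prepared, dyad_id, condition, name, run_adf=False)
                p = orders[(dyad_id, condition)]
                real.append(granger.dyad_gc(Y.values, p).summary)
                seed = _stable_seed(config.seed, name, condition, dyad_id)
                ens = granger.phase_randomize_surrogates(Y.values, config.n_surrogates, seed)
                surr.append(float(np.mean(granger.dyad_gc_batch(ens.data, p))))
            res = granger.empirical_surrogate_test(real, surrogate_means=surr)
            rows.append(
                {
                    "model": name,
                    "condition": condition,
                    "real_mean": float(np.mean(real)),
                    "real_sd": float(np.std(real, ddof=1)),
                    "surr_mean": float(np.mean(surr)),
                    "surr_sd": float(np.std(surr, ddof=1)),
                    "t": res.t,
                    "p": res.p,
                    "d": res.d,
                    "significant": bool(res.p < config.alpha and np.mean(real) > np.mean(surr)),
                }
            )
    table = pd.DataFrame(rows)
    coop = [c for c in prepared.conditions if c != "Alone"]
    flagged = []
    for name in table["model"].unique():
        sub = table[(table["model"] == name) & table["condition"].isin(coop)]
        flagged.append(bool(len(sub) == len(coop) and sub["significant"].all()))
    flag_map = dict(zip(table["model"].unique(), flagged))
    table["flagged"] = table["model"].map(flag_map)
    return table


def _stable_seed(seed: int, *keys) -> int:
    import zlib

    h = zlib.crc32("|".join(str(k) for k in keys).encode())
    return int((seed * 1_000_003 + h) % (2**31))


def run_link_analysis(prepared: PreparedCohort, flagged_models: list[str]) -> dict:
    """Pairwise-conditional GC networks, densities and condition tests for
    each flagged model."""
    if len(prepared.conditions) < 2:
        raise ValueError("link analysis needs at least two conditions")
    config = prepared.config
    results: dict = {}
    if not flagged_models:
        return {"models": {}, "note": "no flagged models"}
    for name in flagged_models:
        per_model: dict = {"networks": {}, "densities": None, "prevalence": {}}
        density_rows = {}
        adjacency_by_cond = {c: [] for c in prepared.conditions}
        for dyad_id in prepared.dyads:
            density_rows[dyad_id] = {}
            for condition in prepared.conditions:
                Y = build_dyad_matrix(prepared, dyad_id, condition, name, run_adf=False)
                p = granger.select_order(Y.values[:, [0, 1, 3, 4]], p_max=config.p_max)
                pw = granger.pairwise_conditional_gc(Y.values, p)
                net = network.build_network(
                    pw.F, pw.pvalues, alpha=config.alpha, condition=condition, dyad_id=dyad_id
                )
                per_model["networks"][(dyad_id, condition)] = net
                density_rows[dyad_id][condition] = net.density_between
                adjacency_by_cond[condition].append(net.adjacency)
        densities = pd.DataFrame.from_dict(density_rows, orient="index")[list(prepared.conditions)]
        per_model["densities"] = densities
        per_model["prevalence"] = {
            c: network.link_prevalence(adjs) for c, adjs in adjacency_by_cond.items()
        }
        per_model["condition_test"] = network.compare_densities(densities, alpha=config.alpha)
        results[name] = per_model
    return {"models": results}


def run_effectiveness(prepared: PreparedCohort, flagged_models: list[str]) -> dict:
    """Quartile labelling of pooled cooperative scores, rank-sum group
    comparisons and the GC-vs-score correlation."""
    behaviour = prepared.behaviour
    coop = behaviour[behaviour["condition"] != "Alone"].reset_index(drop=True)
    if coop.empty:
        raise ValueError("no cooperative behavioural scores")
    scores = coop["score"].to_numpy(float)
    if np.ptp(scores) == 0:
        warnings.warn("degenerate score distribution", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels, (q1, q3) = label_effectiveness(scores)
    coop = coop.assign(label=labels)

    report: dict = {"q1": q1, "q3": q3, "labels": coop, "rank_sum": {}, "correlation": {}}

    # rank-sum comparisons of raw levels between effective and ineffective instances
    eff_idx = coop[coop["label"] == "effective"][["dyad_id", "condition"]]
    ineff_idx = coop[coop["label"] == "ineffective"][["dyad_id", "condition"]]

    def _levels(index: pd.DataFrame, metric: str) -> np.ndarray:
        vals = []
        for _, row in index.iterrows():
            for subj in "ab":
                sub = prepared.subjects[(row["dyad_id"], row["condition"], subj)]
                vals.append(sub.level_means[metric])
        return np.asarray(vals)

    metrics = ["RR", "SCL", "Workload", "Engagement"] + flagged_models
    for metric in dict.fromkeys(metrics):
        if metric not in next(iter(prepared.subjects.values())).level_means:
            continue
        a, b = _levels(eff_idx, metric), _levels(ineff_idx, metric)
        if a.size and b.size and (np.ptp(np.concatenate([a, b])) > 0):
            stat = stats.mannwhitneyu(a, b, alternative="two-sided")
            report["rank_sum"][metric] = {"U": float(stat.statistic), "p": float(stat.pvalue)}

    # dyad GC vs score, per flagged model, over cooperative instances
    for name in flagged_models:
        gc_vals, sc = [], []
        for _, row in coop.iterrows():
            Y = build_dyad_matrix(prepared, row["dyad_id"], row["condition"], name, run_adf=False)
            p = granger.select_order(Y.values[:, [0, 1, 3, 4]], p_max=prepared.config.p_max)
            gc_vals.append(granger.dyad_gc(Y.values, p).summary)
            sc.append(row["score"])
        rho, pval = network.spearman_gc_vs_score(gc_vals, sc)
        report["correlation"][name] = {"rho": rho, "p": pval, "n": len(sc)}
    return report


def run_all(cohort: SyntheticCohort, config: PipelineConfig | None = None) -> dict:
    """The full analysis on one cohort; returns all stage outputs plus a
    provenance block."""
    config = config or PipelineConfig()
    prepared = prepare_cohort(cohort, config)
    screening = run_screening(prepared)
    flagged = sorted(screening[screening["flagged"]]["model"].unique())
    links = run_link_analysis(prepared, flagged) if flagged else {"models": {}}
    effectiveness = run_effectiveness(prepared, flagged)
    return {
        "prepared": prepared,
        "screening": screening,
        "flagged": flagged,
        "links": links,
        "effectiveness": effectiveness,
        "provenance": {"config": config.as_dict(), "seed": config.seed, "log": prepared.log},
    }
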
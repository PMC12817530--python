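"""End-to-end orchestration: simulate -> prep -> mechanics -> cci/coupling
-> statistics, with the study's trial-selection rules.

Protocol rules enforced here:

* Block (session) 1 runs until the first successful trial; blocks 2 and 3
  until three successful trials, each within at most seven attempts.
* A participant who cannot meet those counts is excluded from analysis
  (recorded in the report) and the run continues.
* The block-1 session value is the single first-success trial; blocks 2-3
  average the first three successful trials.
* EMG envelopes are normalized per participant-muscle to the maximum over
  all of that participant's successful trials.
* The two-way 1D waveform ANOVA requires a balanced design; the surplus
  group is trimmed via :func:`perturbalance.inference.balance_design`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cocontraction import cci_trial
from .core import TimeSeries
from .coupling import coupling_trial
from .errors import DataError
from .inference import (
    balance_design,
    mann_whitney_attempts,
    mixed_anova_scalar,
    pearson_cait,
    sensitivity_leave_one_out,
    spm_rm_anova_1d,
)
from .mechanics import (
    MosSeries,
    TorqueSeries,
    ankle_torque_frontal,
    com_trajectory,
    hip_torque_frontal,
    mos,
    xcom,
)
from .signal_prep import detect_onsets, emg_envelope, extract_window, normalize_envelopes
from .synthdata import (
    EMG_RATE,
    KIN_RATE,
    ParticipantProfile,
    SimConfig,
    TrialRecording,
    body_model_for,
    generate_cohort,
    reference_templates,
    simulate_trial,
)

__all__ = [
    "RunConfig",
    "TrialLedger",
    "select_trials",
    "simulate_participant",
    "process_trial",
    "run_pipeline",
    "PipelineReport",
]

SCALAR_OUTCOMES = ["cci_ta_pl", "cci_ta_sol",
                   "r_mos_ankle_w1", "r_mos_ankle_w2",
                   "r_mos_hip_w1", "r_mos_hip_w2"]
WAVEFORM_OUTCOMES = ["mos", "ankle_torque", "hip_torque"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    alpha: float = 0.05
    n_permutations: int = 500
    common_rate: float = KIN_RATE      # Hz of the derived 1-s window base
    max_attempts: int = 7              # per block
    successes_block1: int = 1
    successes_practice: int = 3
    zero_phase_filtering: bool = True  # causal EMG filtering if False
    signed_mos: bool = False           # use signed XCoM-CoP distance
    run_spm: bool = True
    run_sensitivity: bool = False
    out_dir: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class TrialLedger:
    """Attempt bookkeeping for one participant-session."""

    participant_id: str
    session: int
    attempts: int = 0
    success_flags: list[bool] = field(default_factory=list)
    selected: list[int] = field(default_factory=list)  # attempt numbers (1-based)
    complete: bool = False


def select_trials(success_flags: list[bool], session: int,
                  successes_block1: int = 1, successes_practice: int = 3) -> list[int]:
    """First-k-successes selection by attempt order (1-based attempt ids).

    Block 1 selects the first success; blocks 2-3 the first three. Raises
    ``DataError`` when the flags do not contain enough successes (the caller
    records the participant as excluded).
    """
    needed = successes_block1 if session == 1 else successes_practice
    selected = [i + 1 for i, ok in enumerate(success_flags) if ok][:needed]
    if len(selected) < needed:
        raise DataError(
            f"session {session}: {len(selected)} successes, need {needed}")
    return selected


# ---------------------------------------------------------------------------
# per-trial processing
# ---------------------------------------------------------------------------

@dataclass
class DerivedTrial:
    """Aligned 1-s window waveforms for one successful trial."""

    participant_id: str
    session: int
    attempt: int
    envelopes: dict[str, TimeSeries]   # normalized, window base
    mos_series: MosSeries
    torques: TorqueSeries
    cci_ta_pl: float
    cci_ta_sol: float
    coupling: dict[str, float]         # r by "pairing_window" key (signed)


def _perturbation_start(accel: TimeSeries, freq: float) -> float:
    """Perturbation start time from the platform accelerometer.

    The peak |acceleration| of the displacement sinusoid occurs a quarter
    period after onset (negative lobe) or three quarters after (positive
    lobe); the sign of the acceleration at the detected peak disambiguates
    the two.
    """
    onset = detect_onsets(accel, target_rate=EMG_RATE, n_expected=1)[0]
    value = accel.interp_at(np.array([onset]))[0]
    quarter = 1.0 / (4.0 * freq)
    return onset - quarter if value < 0 else onset - 3.0 * quarter


def process_trial(
    rec: TrialRecording,
    profile: ParticipantProfile,
    norm_envelopes: dict[str, TimeSeries],
    config: RunConfig,
) -> DerivedTrial:
    """Mechanics + CCI + coupling for one successful trial.

    ``norm_envelopes`` holds the trial's already-normalized full-length
    envelopes (normalization constants come from all successful trials of
    the participant, computed by the caller).
    """
    model = body_model_for(profile)
    rate = config.common_rate
    start = _perturbation_start(rec.accel, config.sim.platform_freq)
    duration = config.sim.perturb_duration

    # common-base full-trial channels
    kin = {k: ts.resample(rate) if abs(ts.rate - rate) > 1e-9 else ts
           for k, ts in rec.kinematics.items()}
    n_common = min(len(ts) for ts in kin.values())
    kin = {k: TimeSeries(ts.samples[:n_common], rate=rate, units=ts.units)
           for k, ts in kin.items()}

    def to_common(ts: TimeSeries) -> TimeSeries:
        r = ts.resample(rate)
        return TimeSeries(r.samples[:n_common], rate=rate, units=ts.units)

    fz = to_common(rec.grf_fz)
    cop_lab = kin["platform_x"].with_samples(
        to_common(rec.cop_platform).samples + kin["platform_x"].samples, units="m")

    com = com_trajectory(kin, model)
    xc = xcom(com, model)
    mos_full = mos(xc, cop_lab, signed=config.signed_mos)
    tau_ankle = ankle_torque_frontal(fz, cop_lab, kin["platform_x"])
    tau_hip = hip_torque_frontal(fz, cop_lab, kin["platform_x"], kin["hip_x"],
                                 kin["limb_com_x"], kin["hat_com_x"], model)

    w = lambda ts: extract_window(ts, start, duration, rate)
    mos_win = MosSeries(mos=w(mos_full.mos), xcom=w(mos_full.xcom),
                        bos=w(mos_full.bos),
                        signed=w(mos_full.signed) if mos_full.signed else None)
    tor_win = TorqueSeries(ankle_frontal=w(tau_ankle), hip_frontal=w(tau_hip))
    env_win = {m: w(ts) for m, ts in norm_envelopes.items()}

    trial_id = f"{rec.participant_id}-s{rec.session}-a{rec.attempt}"
    c_pl, c_sol = cci_trial(env_win, window=(0.0, duration), trial_id=trial_id)
    mos_for_coupling = (mos_win.signed if (config.signed_mos and mos_win.signed)
                       else mos_win.mos)
    coup = coupling_trial(MosSeries(mos=mos_for_coupling, xcom=mos_win.xcom,
                                    bos=mos_win.bos), tor_win, trial_id=trial_id)
    coup_map = {f"{c.pairing}_{c.window}": c.r for c in coup}
    return DerivedTrial(
        participant_id=rec.participant_id, session=rec.session,
        attempt=rec.attempt, envelopes=env_win, mos_series=mos_win,
        torques=tor_win, cci_ta_pl=c_pl.value, cci_ta_sol=c_sol.value,
        coupling=coup_map)


# ---------------------------------------------------------------------------
# participant-level simulation + processing
# ---------------------------------------------------------------------------

def simulate_participant(
    profile: ParticipantProfile,
    config: RunConfig,
) -> tuple[list[TrialRecording], list[TrialLedger]]:
    """Simulate all blocks for one participant under the attempt rules."""
    recs: list[TrialRecording] = []
    ledgers: list[TrialLedger] = []
    sim = config.sim
    for session in range(1, sim.sessions + 1):
        needed = (config.successes_block1 if session == 1
                  else config.successes_practice)
        ledger = TrialLedger(participant_id=profile.id, session=session)
        template = reference_templates(profile, sim, session)
        successes = 0
        for attempt in range(1, config.max_attempts + 1):
            rec, _ = simulate_trial(profile, sim, session, attempt, template=template)
            recs.append(rec)
            ledger.attempts = attempt
            ledger.success_flags.append(rec.success)
            successes += rec.success
            if successes >= needed:
                break
        try:
            ledger.selected = select_trials(
                ledger.success_flags, session,
                config.successes_block1, config.successes_practice)
            ledger.complete = True
        except DataError:
            ledger.complete = False
        ledgers.append(ledger)
    return recs, ledgers


def _participant_derived(
    profile: ParticipantProfile,
    recs: list[TrialRecording],
    ledgers: list[TrialLedger],
    config: RunConfig,
) -> list[DerivedTrial]:
    """Envelope-normalize and process a participant's selected trials."""
    successful = [r for r in recs if r.success]
    raw_envs = [
        {m: emg_envelope(ts, zero_phase=config.zero_phase_filtering)
         for m, ts in r.emg.items()}
        for r in successful
    ]
    norm_envs = normalize_envelopes(raw_envs, [True] * len(raw_envs))
    env_by_key = {(r.session, r.attempt): env
                  for r, env in zip(successful, norm_envs)}
    selected_keys = {(led.session, att) for led in ledgers if led.complete
                     for att in led.selected}
    derived = []
    for rec in successful:
        key = (rec.session, rec.attempt)
        if key in selected_keys:
            derived.append(process_trial(rec, profile, env_by_key[key], config))
    return derived


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineReport:
    config: RunConfig
    cohort: pd.DataFrame
    trials: pd.DataFrame            # per selected trial scalars
    sessions: pd.DataFrame          # per participant-session aggregates
    summary: pd.DataFrame           # Table-2-style mean +- SD per group-session
    anova: dict                     # outcome -> list[AnovaResult]
    spm: dict                       # outcome -> {design/effect -> Spm1dResult}
    correlations: dict              # CAIT vs CCI results
    attempts_tests: dict            # Mann-Whitney U outcomes
    excluded: list[str]
    balance_note: str
    waveforms: dict                 # outcome -> (ids, groups, array (N, b, K))
    manifest: dict


def _aggregate_sessions(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (pid, group, session), sub in trials.groupby(["participant", "group", "session"]):
        row = {"participant": pid, "group": group, "session": session,
               "n_trials": len(sub)}
        for col in SCALAR_OUTCOMES:
            row[col] = sub[col].mean()
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["group", "participant", "session"],
                                          ignore_index=True)


def _table2_summary(sessions: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for outcome in SCALAR_OUTCOMES:
        for (group, session), sub in sessions.groupby(["group", "session"]):
            rows.append({"outcome": outcome, "group": group, "session": session,
                         "mean": sub[outcome].mean(), "sd": sub[outcome].std(ddof=1),
                         "n": len(sub)})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full pipeline on a simulated cohort.

    Deterministic for a fixed ``config`` (the simulation seed drives every
    random element, including the permutation inference).
    """
    sim = config.sim
    profiles = generate_cohort(sim)
    cohort_df = pd.DataFrame([
        dict(id=p.id, group=p.group, cait=p.cait, mass_kg=p.mass,
             height_m=p.height, leg_length_m=p.leg_length, test_side=p.test_side)
        for p in profiles])

    trial_rows = []
    attempts_rows = []
    excluded: list[str] = []
    waveform_store: dict[str, dict[str, np.ndarray]] = {o: {} for o in WAVEFORM_OUTCOMES}
    kept_profiles: list[ParticipantProfile] = []

    for profile in profiles:
        recs, ledgers = simulate_participant(profile, config)
        if not all(led.complete for led in ledgers):
            excluded.append(profile.id)
            continue
        kept_profiles.append(profile)
        attempts_rows.append({
            "participant": profile.id, "group": profile.group,
            "block1_attempts": ledgers[0].attempts,
            "practice_attempts": sum(l.attempts for l in ledgers[1:]),
        })
        derived = _participant_derived(profile, recs, ledgers, config)
        per_session_waves: dict[str, dict[int, list[np.ndarray]]] = {
            o: {} for o in WAVEFORM_OUTCOMES}
        for d in derived:
            trial_rows.append({
                "participant": d.participant_id, "group": profile.group,
                "session": d.session, "attempt": d.attempt,
                "cci_ta_pl": d.cci_ta_pl, "cci_ta_sol": d.cci_ta_sol,
                "r_mos_ankle_w1": abs(d.coupling["MoS_Ankle_W1"]),
                "r_mos_ankle_w2": abs(d.coupling["MoS_Ankle_W2"]),
                "r_mos_hip_w1": abs(d.coupling["MoS_Hip_W1"]),
                "r_mos_hip_w2": abs(d.coupling["MoS_Hip_W2"]),
            })
            waves = {"mos": d.mos_series.mos.samples,
                     "ankle_torque": d.torques.ankle_frontal.samples,
                     "hip_torque": d.torques.hip_frontal.samples}
            for o, wv in waves.items():
                per_session_waves[o].setdefault(d.session, []).append(wv)
        for o in WAVEFORM_OUTCOMES:
            sess_means = [np.mean(per_session_waves[o][s], axis=0)
                          for s in sorted(per_session_waves[o])]
            waveform_store[o][profile.id] = np.stack(sess_means)

    trials_df = pd.DataFrame(trial_rows)
    sessions_df = _aggregate_sessions(trials_df)
    summary_df = _table2_summary(sessions_df)
    attempts_df = pd.DataFrame(attempts_rows)

    # ---- scalar inference ------------------------------------------------
    anova: dict[str, list] = {}
    for outcome in SCALAR_OUTCOMES:
        long = sessions_df.rename(columns={outcome: "value"})[
            ["participant", "group", "session", "value"]]
        anova[outcome] = mixed_anova_scalar(
            long, dv="value", within="session", subject="participant",
            between="group", alpha=config.alpha)

    # ---- waveform inference ---------------------------------------------
    spm: dict[str, dict] = {}
    groups_map = {p.id: p.group for p in kept_profiles}
    kept_ids = [p.id for p in kept_profiles]
    bal_ids, bal_dropped, balance_note = balance_design(groups_map, seed=sim.seed)
    waveforms_out = {}
    if config.run_spm:
        for outcome in WAVEFORM_OUTCOMES:
            store = waveform_store[outcome]
            y_bal = np.stack([store[i] for i in bal_ids])
            g_bal = [groups_map[i] for i in bal_ids]
            res = {"two_way": spm_rm_anova_1d(
                y_bal, groups=g_bal, design="two-way",
                n_permutations=config.n_permutations, alpha=config.alpha,
                seed=sim.seed, node_rate=config.common_rate)}
            for grp in ("CAI", "HC"):
                ids_g = [i for i in kept_ids if groups_map[i] == grp]
                y_g = np.stack([store[i] for i in ids_g])
                res[f"one_way_{grp}"] = spm_rm_anova_1d(
                    y_g, design="one-way",
                    n_permutations=config.n_permutations, alpha=config.alpha,
                    seed=sim.seed, node_rate=config.common_rate)
            spm[outcome] = res
            waveforms_out[outcome] = (
                kept_ids, [groups_map[i] for i in kept_ids],
                np.stack([store[i] for i in kept_ids]))

    sensitivity = None
    if config.run_spm and config.run_sensitivity and bal_dropped:
        sensitivity = sensitivity_leave_one_out(
            np.stack([waveform_store["mos"][i] for i in kept_ids]),
            kept_ids, groups_map, effect="interaction",
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=sim.seed, node_rate=config.common_rate)

    # ---- CAIT correlations (CAI group) -----------------------------------
    cai_sessions = sessions_df[sessions_df.group == "CAI"]
    cai_means = cai_sessions.groupby("participant")[
        ["cci_ta_pl", "cci_ta_sol"]].mean()
    cait_map = cohort_df.set_index("id")["cait"]
    cait = cait_map.loc[cai_means.index].to_numpy(dtype=float)
    correlations = {}
    for outcome in ("cci_ta_pl", "cci_ta_sol"):
        r, p = pearson_cait(cait, cai_means[outcome].to_numpy())
        correlations[outcome] = {"r": r, "p": p, "n": len(cai_means)}

    # ---- attempt-count tests ----------------------------------------------
    attempts_tests = {}
    for col in ("block1_attempts", "practice_attempts"):
        u, z, p = mann_whitney_attempts(
            attempts_df.loc[attempts_df.group == "CAI", col],
            attempts_df.loc[attempts_df.group == "HC", col])
        attempts_tests[col] = {"U": u, "Z": z, "p": p}

    manifest = {
        "package_version": __version__,
        "seed": sim.seed,
        "alpha": config.alpha,
        "n_permutations": config.n_permutations,
        "n_participants": len(kept_profiles),
        "excluded": excluded,
        "balance_dropped": bal_dropped,
        "sensitivity": sensitivity,
    }
    report = PipelineReport(
        config=config, cohort=cohort_df, trials=trials_df,
        sessions=sessions_df, summary=summary_df, anova=anova, spm=spm,
        correlations=correlations, attempts_tests=attempts_tests,
        excluded=excluded, balance_note=balance_note,
        waveforms=waveforms_out, manifest=manifest)
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _write_outputs(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.cohort.to_csv(out / "cohort.csv", index=False, float_format="%.6f")
    report.trials.to_csv(out / "trials.csv", index=False, float_format="%.6f")
    report.sessions.to_csv(out / "sessions.csv", index=False, float_format="%.6f")
    report.summary.to_csv(out / "summary_table.csv", index=False, float_format="%.6f")

    stats: dict = {"anova": {}, "spm": {}, "correlations": report.correlations,
                   "attempts_tests": report.attempts_tests,
                   "excluded": report.excluded,
                   "balance_note": report.balance_note}
    for outcome, results in report.anova.items():
        stats["anova"][outcome] = [
            {"effect": r.effect, "F": r.F, "df": list(r.df), "p": r.p,
             "partial_eta_sq": r.partial_eta_sq, "posthoc": r.posthoc}
            for r in results]
    for outcome, designs in report.spm.items():
        stats["spm"][outcome] = {
            design: {eff: {"threshold": res.threshold, "p_max": res.p_max,
                           "clusters": res.clusters, "cluster_p": res.cluster_p}
                     for eff, res in effects.items()}
            for design, effects in designs.items()}
    (out / "stats.json").write_text(json.dumps(stats, indent=1, default=float))
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=1,
                                                  default=str))
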
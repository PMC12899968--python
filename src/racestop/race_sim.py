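"""Independent-race simulation of stop-signal task behavior and cohort synthesis.

The generative model is the classic independent horse-race: on every trial a
go process with an ex-Gaussian finishing-time distribution races the
stimulus clock; on stop trials a stop process, launched at the current
stop-signal delay (SSD) with a truncated-normal finishing time, races the go
process and a response is emitted only if the go process wins. A
1-up/1-down staircase moves the SSD by one step after every stop trial
(up after successful inhibition, down after a failure), tracking the 50%
inhibition point.

The cohort layer synthesizes a two-group study: a regular-physical-activity
group (RPG) and an inactive group (IAG) with a configurable true SSRT
shift, demographic and questionnaire covariates drawn per group, and
ROI-level BOLD contrast values with a configurable group x stimulus
structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring
from .task_design import DesignSpec, build_condition

TRIAL_LOG_COLUMNS = [
    "index",
    "condition",
    "trial_type",
    "stimulus_id",
    "variant",
    "correct_key",
    "iti_ms",
    "onset_ms",
    "ssd_ms",
    "responded",
    "response_key",
    "rt_ms",
    "correct",
]


@dataclass(frozen=True)
class RaceParams:
    """Latent per-participant parameters of the independent-race process.

    go_mu/go_sigma/go_tau parameterize the ex-Gaussian go finishing time
    (normal component mean/sd plus exponential tail mean, all ms);
    ssrt_mean/ssrt_sd the stop process finishing time (normal truncated at
    0). Trigger failures (stop process never launched), go omissions and
    choice errors are pathology rates, zero by default.

    Defaults give a mean go RT of 530 ms and a true SSRT of 220 ms,
    matching typical young-adult SST performance.
    """

    go_mu: float = 440.0
    go_sigma: float = 50.0
    go_tau: float = 90.0
    ssrt_mean: float = 220.0
    ssrt_sd: float = 30.0
    p_trigger_failure: float = 0.0
    p_go_omission: float = 0.0
    p_choice_error: float = 0.0

    def validate(self) -> None:
        if not (self.go_mu > 0 and self.go_sigma > 0 and self.go_tau >= 0):
            raise ValueError("go_mu, go_sigma must be > 0 and go_tau >= 0")
        if not (self.ssrt_mean > 0 and self.ssrt_sd >= 0):
            raise ValueError("ssrt_mean must be > 0 and ssrt_sd >= 0")
        for name in ("p_trigger_failure", "p_go_omission", "p_choice_error"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {p}")

    def replace(self, **kw) -> "RaceParams":
        return dataclasses.replace(self, **kw)


@dataclass
class StaircaseState:
    """Current SSD and step/bounds of the 1-up/1-down tracking staircase."""

    current_ssd_ms: float = 250.0
    step_ms: float = 50.0
    lo_ms: float = 50.0
    hi_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.lo_ms <= self.current_ssd_ms <= self.hi_ms):
            raise ValueError("current_ssd_ms outside [lo_ms, hi_ms]")


def update_staircase(state: StaircaseState, stop_succeeded: bool) -> StaircaseState:
    """One staircase move: up a step after successful inhibition, down after
    a failure, clamped to [lo, hi]."""
    delta = state.step_ms if stop_succeeded else -state.step_ms
    new_ssd = min(state.hi_ms, max(state.lo_ms, state.current_ssd_ms + delta))
    return StaircaseState(new_ssd, state.step_ms, state.lo_ms, state.hi_ms)


def _ex_gaussian(params: RaceParams, rng: np.random.Generator) -> float:
    t = rng.normal(params.go_mu, params.go_sigma)
    if params.go_tau > 0:
        t += rng.exponential(params.go_tau)
    return t


def _trunc_normal_pos(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    while True:  # rejection sampling; acceptance ~1 for mean >> sd
        t = rng.normal(mean, sd)
        if t > 0:
            return t


def simulate_trial(
    plan_row: dict,
    params: RaceParams,
    state: StaircaseState,
    rng: np.random.Generator,
    max_stim_ms: float = 1000.0,
) -> tuple[dict, StaircaseState]:
    """Simulate one trial of the race process.

    Go trial: the go finishing time T_go is ex-Gaussian; no response if a
    go omission fires or T_go exceeds the response window; otherwise the
    response lands at T_go, with the wrong key at the choice-error rate.
    Stop trial: the stop process finishes at SSD + T_stop unless a trigger
    failure occurs; a response is emitted iff the stop process never
    started or the go process beats it, and only within the response
    window. The staircase advances on every stop trial.
    """
    rec = dict(plan_row)
    is_stop = rec["trial_type"] == "stop"

    t_go = _ex_gaussian(params, rng)

    if not is_stop:
        rec["ssd_ms"] = np.nan
        omitted = rng.random() < params.p_go_omission or t_go > max_stim_ms
        if omitted:
            rec.update(responded=False, response_key=None, rt_ms=np.nan, correct=False)
        else:
            wrong = rng.random() < params.p_choice_error
            key = _other_key(rec["correct_key"]) if wrong else rec["correct_key"]
            rec.update(
                responded=True, response_key=key, rt_ms=float(t_go), correct=not wrong
            )
        return rec, state

    ssd = state.current_ssd_ms
    rec["ssd_ms"] = float(ssd)
    if rng.random() < params.p_trigger_failure:
        stop_finish = np.inf  # stop process never launched
    else:
        stop_finish = ssd + _trunc_normal_pos(params.ssrt_mean, params.ssrt_sd, rng)

    responded = t_go < stop_finish and t_go <= max_stim_ms
    if responded:
        wrong = rng.random() < params.p_choice_error
        key = _other_key(rec["correct_key"]) if wrong else rec["correct_key"]
        rec.update(responded=True, response_key=key, rt_ms=float(t_go), correct=False)
    else:
        rec.update(responded=False, response_key=None, rt_ms=np.nan, correct=True)

    new_state = update_staircase(state, stop_succeeded=not responded)
    return rec, new_state


def _other_key(key: str) -> str:
    return "key3" if key == "key1" else "key1"


def simulate_condition(
    params: RaceParams, spec: DesignSpec, seed: int
) -> pd.DataFrame:
    """Run one condition: build the trial plan, then race every trial under
    a fresh staircase (initial SSD from the spec). Onsets accumulate
    fixation + stimulus time (terminated at response) + ITI."""
    params.validate()
    plan = build_condition(spec, seed)
    rng = np.random.default_rng([seed, 0x5ACE])
    state = StaircaseState(
        current_ssd_ms=float(spec.ssd_initial_ms),
        step_ms=float(spec.ssd_step_ms),
        lo_ms=float(spec.ssd_min_ms),
        hi_ms=float(spec.ssd_max_ms),
    )
    rows = []
    t = 0.0
    for row in plan.to_dict("records"):
        t += spec.fixation_ms
        row["onset_ms"] = t
        rec, state = simulate_trial(row, params, state, rng, spec.max_stim_ms)
        consumed = rec["rt_ms"] if rec["responded"] else spec.max_stim_ms
        t += consumed + rec["iti_ms"]
        rows.append(rec)
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def simulate_participant(
    params: RaceParams,
    spec: DesignSpec | None = None,
    seed: int = 0,
    conditions: tuple[str, ...] = ("food", "neutral"),
) -> dict[str, pd.DataFrame]:
    """Simulate one participant over one or both conditions, each with its
    own trial sequence and fresh staircase; deterministic under seed."""
    spec = spec or DesignSpec()
    out = {}
    for k, cond in enumerate(conditions):
        cond_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        out[cond] = simulate_condition(params, spec.replace(condition=cond), cond_seed)
    return out


# ---------------------------------------------------------------------------
# Cohort synthesis


@dataclass
class GroupCovariates:
    """Per-group sampling distributions for the participant table
    (means/sds on the scales of the published demographics table)."""

    age: tuple[float, float] = (21.0, 3.0)
    bmi: tuple[float, float] = (29.0, 5.5)
    waist_cm: tuple[float, float] = (91.0, 12.5)
    visceral_fat_cm2: tuple[float, float] = (115.0, 50.0)
    bdi_ii: tuple[float, float] = (8.0, 5.5)
    appetite_item: tuple[float, float] = (57.0, 18.0)
    p_male: float = 0.67


@dataclass
class RoiEffect:
    """ROI contrast-value generator: one mean per (group, condition) cell,
    Gaussian noise, and an optional correlation with MET-minutes."""

    cell_means: dict = field(default_factory=dict)  # (group, condition) -> mean
    noise_sd: float = 1.0
    mets_rho: float = 0.0


def default_roi_effects() -> dict[str, RoiEffect]:
    """Null a-priori inferior frontal ROI plus caudate and precuneus ROIs
    whose default cell patterns mirror the group x stimulus crossover
    structure the analysis is designed to detect."""
    return {
        "r_ifg": RoiEffect(noise_sd=1.0),
        "l_caudate": RoiEffect(
            cell_means={
                ("RPG", "food"): -0.3,
                ("RPG", "neutral"): 0.3,
                ("IAG", "food"): 0.3,
                ("IAG", "neutral"): -0.3,
            },
            noise_sd=1.0,
        ),
        "precuneus": RoiEffect(
            cell_means={
                ("RPG", "food"): 0.3,
                ("RPG", "neutral"): -0.3,
                ("IAG", "food"): -0.3,
                ("IAG", "neutral"): 0.3,
            },
            noise_sd=1.0,
        ),
    }


@dataclass
class CohortSpec:
    """Study-level generative configuration.

    Defaults emulate the published cohort: 30 regular-activity (RPG) and 31
    inactive (IAG) participants, a 33 ms true SSRT disadvantage for IAG,
    covariates on the demographics-table scales, and ROI contrast values
    with a group x stimulus interaction pattern.
    """

    n_rpg: int = 30
    n_iag: int = 31
    group_ssrt_shift_ms: float = 33.0
    ssrt_base_ms: float = 220.0
    ssrt_between_sd_ms: float = 35.0
    go_mu_between_sd_ms: float = 55.0
    base_params: RaceParams = field(default_factory=RaceParams)
    rpg_covariates: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(
            age=(21.3, 3.5), bmi=(27.4, 5.4), waist_cm=(88.5, 12.4),
            visceral_fat_cm2=(99.6, 52.0), bdi_ii=(7.5, 5.4),
            appetite_item=(57.0, 16.4), p_male=24 / 30,
        )
    )
    iag_covariates: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(
            age=(20.7, 2.2), bmi=(30.7, 6.1), waist_cm=(94.8, 13.0),
            visceral_fat_cm2=(134.2, 49.3), bdi_ii=(8.9, 5.7),
            appetite_item=(57.9, 18.9), p_male=17 / 31,
        )
    )
    roi_effects: dict[str, RoiEffect] = field(default_factory=default_roi_effects)
    design: DesignSpec = field(default_factory=DesignSpec)
    simulate_trials: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_rpg < 2 or self.n_iag < 2:
            raise ValueError("need at least 2 participants per group")
        for roi in self.roi_effects.values():
            if roi.noise_sd <= 0:
                raise ValueError("roi noise_sd must be > 0")


_MAX_DRAW_RETRIES = 100


def _draw_ipaq(group: str, rng: np.random.Generator) -> dict:
    """Draw IPAQ answers so the participant satisfies (RPG) or violates
    (IAG) the activity-classification rules; bounded rejection sampling."""
    for _ in range(_MAX_DRAW_RETRIES):
        if group == "RPG":
            rec = {
                "days_mvpa_per_wk": int(rng.integers(3, 8)),
                "session_min": float(np.round(rng.uniform(30, 90))),
                "moderate_min_wk": float(max(0.0, rng.normal(330, 190))),
                "vigorous_min_wk": float(max(0.0, rng.normal(150, 110))),
                "six_month_regular": True,
            }
        else:
            rec = {
                "days_mvpa_per_wk": int(rng.integers(0, 3)),
                "session_min": float(np.round(rng.uniform(0, 25))),
                "moderate_min_wk": float(max(0.0, rng.normal(70, 55))),
                "vigorous_min_wk": float(max(0.0, rng.normal(15, 25))),
                "six_month_regular": False,
            }
        rec["mets"] = scoring.compute_mets(rec["moderate_min_wk"], rec["vigorous_min_wk"])
        probe = dict(rec, ipaq_refused=False)
        if scoring.classify_group(probe) == group:
            return rec
    raise RuntimeError(f"could not draw IPAQ answers consistent with group {group}")


def _clip01(x: float, lo: float = 0.0, hi: float = 100.0) -> float:
    return float(min(hi, max(lo, x)))


def simulate_cohort(
    cohort: CohortSpec,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Synthesize a full two-group study.

    Returns ``(participants, trial_logs, roi_values)``: a participant table
    with demographics, questionnaire scores and group labels; per
    (participant, condition) trial logs from the race simulation (empty
    dict when ``simulate_trials`` is off); and a long ROI table of contrast
    values per participant x condition x ROI.

    One RNG stream per participant is derived from (cohort seed,
    participant index), so the cohort is reproducible and participants are
    independent.
    """
    cohort.validate()
    groups = ["RPG"] * cohort.n_rpg + ["IAG"] * cohort.n_iag

    part_rows, logs = [], {}
    mets_all = []
    for idx, group in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, idx]))
        cov = cohort.rpg_covariates if group == "RPG" else cohort.iag_covariates
        pid = f"sub-{idx + 1:03d}"

        ipaq = _draw_ipaq(group, rng)
        mets_all.append(ipaq["mets"])
        hunger = _clip01(rng.normal(*cov.appetite_item))
        fullness = _clip01(rng.normal(100 - cov.appetite_item[0], cov.appetite_item[1]))
        desire = _clip01(rng.normal(*cov.appetite_item))
        prospective = _clip01(rng.normal(*cov.appetite_item))

        row = {
            "participant_id": pid,
            "group": group,
            "age": float(np.round(rng.normal(*cov.age), 1)),
            "sex": "male" if rng.random() < cov.p_male else "female",
            "bmi": float(np.round(rng.normal(*cov.bmi), 2)),
            "waist_cm": float(np.round(rng.normal(*cov.waist_cm), 1)),
            "visceral_fat_cm2": float(np.round(rng.normal(*cov.visceral_fat_cm2), 1)),
            "bdi_ii": float(max(0.0, np.round(rng.normal(*cov.bdi_ii)))),
            "hunger": hunger,
            "fullness": fullness,
            "desire": desire,
            "prospective": prospective,
            "composite_appetite": scoring.composite_appetite(
                hunger, fullness, desire, prospective
            ),
            "ipaq_refused": False,
            **ipaq,
        }

        shift = cohort.group_ssrt_shift_ms if group == "IAG" else 0.0
        ssrt_i = max(
            80.0,
            cohort.ssrt_base_ms + shift + rng.normal(0.0, cohort.ssrt_between_sd_ms),
        )
        go_mu_i = max(
            200.0,
            cohort.base_params.go_mu + rng.normal(0.0, cohort.go_mu_between_sd_ms),
        )
        params = cohort.base_params.replace(ssrt_mean=ssrt_i, go_mu=go_mu_i)
        row["true_ssrt_ms"] = ssrt_i
        part_rows.append(row)

        if cohort.simulate_trials:
            pseed = int(
                np.random.SeedSequence([cohort.seed, idx, 7]).generate_state(1)[0]
                % (2**31)
            )
            for cond, log in simulate_participant(params, cohort.design, pseed).items():
                log = log.copy()
                log.insert(0, "participant_id", pid)
                logs[(pid, cond)] = log

    participants = pd.DataFrame(part_rows)

    # ROI contrast values: cell mean + optional METs coupling + noise
    z_mets = np.asarray(mets_all, dtype=float)
    z_mets = (z_mets - z_mets.mean()) / (z_mets.std(ddof=0) or 1.0)
    roi_rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 10**6]))
    roi_rows = []
    for i, row in participants.iterrows():
        for cond in ("food", "neutral"):
            for roi_name, eff in cohort.roi_effects.items():
                mu = eff.cell_means.get((row["group"], cond), 0.0)
                rho = eff.mets_rho
                noise = roi_rng.normal()
                value = mu + eff.noise_sd * (
                    rho * z_mets[i] + np.sqrt(max(0.0, 1 - rho**2)) * noise
                )
                roi_rows.append(
                    {
                        "participant_id": row["participant_id"],
                        "condition": cond,
                        "roi": roi_name,
                        "value": float(value),
                    }
                )
    roi_values = pd.DataFrame(roi_rows)
    return participants, logs, roi_values


def write_cohort(
    participants: pd.DataFrame,
    logs: dict[tuple[str, str], pd.DataFrame],
    roi_values: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write participant/ROI tables as CSV and one events-style TSV trial
    log per participant x condition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants.to_csv(out / "participants.csv", index=False)
    roi_values.to_csv(out / "roi_values.csv", index=False)
    for (pid, cond), log in logs.items():
        log.to_csv(out / f"{pid}_{cond}_events.tsv", sep="\t", index=False)


def read_trial_logs(data_dir: str | Path) -> dict[tuple[str, str], pd.DataFrame]:
    logs = {}
    for p in sorted(Path(data_dir).glob("*_events.tsv")):
        pid, cond, _ = p.name.rsplit("_", 2)
        logs[(pid, cond)] = pd.read_csv(p, sep="\t")
    return logs
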
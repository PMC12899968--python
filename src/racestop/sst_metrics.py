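"""Per-participant stop-signal task metrics: integration-method SSRT and QC.

The integration method treats the go-RT distribution as the finishing-time
distribution of the go process. With p = p(respond|signal), the nth RT is
the order statistic at rank ceil(p x N) of the ascending-sorted go RTs
(after replacing omissions and over-window RTs with the participant's
maximum valid go RT), and

    SSRT = nth RT - mean SSD.

Metrics are computed separately per stimulus condition. QC excludes a
participant when (1) mean RT on failed stop trials exceeds mean go RT,
(2) p(respond|signal) is below 25% or above 75%, or (3) the go omission
rate exceeds 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd


class ScoringError(ValueError):
    """Raised when a trial log cannot be scored (no stop trials, no valid
    go RTs, ...)."""


@dataclass
class SSTSummary:
    """Behavioral summary of one participant x condition."""

    participant_id: str
    condition: str
    ssrt_ms: float
    mean_ssd_ms: float
    p_respond_signal: float
    go_rt_ms: float
    go_accuracy: float
    omission_rate: float
    mean_failed_stop_rt_ms: float
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)


def replace_omissions(
    go_rts: Iterable[float | None], max_stim_ms: float = 1000.0
) -> np.ndarray:
    """Replace omitted (absent/NaN) and over-window go RTs with the
    participant-specific maximum valid go RT."""
    rts = np.array(
        [np.nan if r is None else float(r) for r in go_rts], dtype=float
    )
    valid = rts[(rts > 0) & (rts <= max_stim_ms) & ~np.isnan(rts)]
    if valid.size == 0:
        raise ScoringError("no valid go RT in (0, max_stim_ms]; participant unscoreable")
    out = rts.copy()
    out[np.isnan(out) | (out > max_stim_ms) | (out <= 0)] = valid.max()
    return out


def nth_rt(
    go_rts: Iterable[float],
    p_respond_signal: float,
    rule: Literal["ceil", "floor", "linear"] = "ceil",
) -> float:
    """Order statistic of the ascending-sorted go-RT distribution at the
    p(respond|signal) percentile.

    The default rank rule is ceil(p x N) (rank 1 when that gives 0), the
    consensus integration-method convention; floor and linear
    interpolation are available as alternatives.
    """
    rts = np.sort(np.asarray(list(go_rts), dtype=float))
    n = rts.size
    if n == 0:
        raise ScoringError("empty go-RT list")
    if not (0.0 <= p_respond_signal <= 1.0):
        raise ValueError(f"p_respond_signal must be in [0, 1], got {p_respond_signal}")
    if rule == "ceil":
        rank = max(1, math.ceil(p_respond_signal * n))
        return float(rts[min(rank, n) - 1])
    if rule == "floor":
        rank = max(1, math.floor(p_respond_signal * n))
        return float(rts[min(rank, n) - 1])
    if rule == "linear":
        return float(np.quantile(rts, p_respond_signal))
    raise ValueError(f"unknown rank rule {rule!r}")


def integration_ssrt(
    trials: pd.DataFrame,
    max_stim_ms: float = 1000.0,
    go_rts: Literal["all", "correct-only"] = "all",
    rank_rule: Literal["ceil", "floor", "linear"] = "ceil",
    participant_id: str = "",
) -> SSTSummary:
    """Score one condition's trial log.

    ``trials`` must carry trial_type, responded, rt_ms, correct and (for
    stop trials) ssd_ms. All responded go RTs enter the distribution by
    default (``go_rts='correct-only'`` restricts to correct responses);
    stop-trial responses never do.
    """
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if len(stop) == 0:
        raise ScoringError("no stop trials in log")
    if len(go) == 0:
        raise ScoringError("no go trials in log")

    responded_go = go[go["responded"].astype(bool)]
    p_respond = float(stop["responded"].astype(bool).mean())
    mean_ssd = float(stop["ssd_ms"].mean())

    pool = responded_go
    if go_rts == "correct-only":
        pool = responded_go[responded_go["correct"].astype(bool)]
    # omissions (and over-window RTs) re-enter as NaN for replacement
    rt_list = list(pool["rt_ms"]) + [np.nan] * int((~go["responded"].astype(bool)).sum())
    rts = replace_omissions(rt_list, max_stim_ms)
    ssrt = nth_rt(rts, p_respond, rank_rule) - mean_ssd

    failed = stop[stop["responded"].astype(bool)]
    cond = trials["condition"].iloc[0] if "condition" in trials else ""
    return SSTSummary(
        participant_id=participant_id,
        condition=str(cond),
        ssrt_ms=float(ssrt),
        mean_ssd_ms=mean_ssd,
        p_respond_signal=p_respond,
        go_rt_ms=float(responded_go["rt_ms"].mean()) if len(responded_go) else np.nan,
        go_accuracy=float(
            (responded_go["correct"].astype(bool)).sum() / len(go)
        ),
        omission_rate=float((~go["responded"].astype(bool)).mean()),
        mean_failed_stop_rt_ms=float(failed["rt_ms"].mean()) if len(failed) else np.nan,
    )


QC_P_LO = 0.25
QC_P_HI = 0.75
QC_MAX_OMISSION = 0.20


def qc_exclude(summary: SSTSummary) -> SSTSummary:
    """Apply the three behavioral exclusion rules (strict inequalities)."""
    reasons = []
    if (
        not np.isnan(summary.mean_failed_stop_rt_ms)
        and summary.mean_failed_stop_rt_ms > summary.go_rt_ms
    ):
        reasons.append("mean failed-stop RT > mean go RT")
    if summary.p_respond_signal < QC_P_LO:
        reasons.append("p(respond|signal) < 25%")
    if summary.p_respond_signal > QC_P_HI:
        reasons.append("p(respond|signal) > 75%")
    if summary.omission_rate > QC_MAX_OMISSION:
        reasons.append("go omission rate > 20%")
    summary.qc_reasons = reasons
    summary.qc_pass = not reasons
    return summary


def score_logs(
    logs: dict[tuple[str, str], pd.DataFrame],
    max_stim_ms: float = 1000.0,
    go_rts: Literal["all", "correct-only"] = "all",
    exclude_whole_participant: bool = True,
) -> pd.DataFrame:
    """Score a set of (participant, condition) trial logs into a summary
    table with QC flags.

    A participant failing QC in either condition is excluded in both when
    ``exclude_whole_participant`` (the default), mirroring whole-person
    exclusion from a two-condition study.
    """
    rows = []
    for (pid, cond), log in logs.items():
        s = qc_exclude(
            integration_ssrt(log, max_stim_ms, go_rts=go_rts, participant_id=pid)
        )
        if not s.condition:
            s.condition = cond
        rows.append(asdict(s))
    df = pd.DataFrame(rows)
    if exclude_whole_participant and len(df):
        failed = set(df.loc[~df["qc_pass"], "participant_id"])
        mask = df["participant_id"].isin(failed)
        df.loc[mask, "qc_pass"] = False
        df.loc[mask & (df["qc_reasons"].str.len() == 0), "qc_reasons"] = df.loc[
            mask & (df["qc_reasons"].str.len() == 0), "qc_reasons"
        ].apply(lambda _: ["excluded: QC failure in other condition"])
    return df


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    out = summaries.copy()
    out["qc_reasons"] = out["qc_reasons"].apply("; ".join)
    out.to_csv(path, index=False)
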
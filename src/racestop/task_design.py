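"""Trial sequence construction for one stop-signal task (SST) condition.

A condition presents 25 images, each in four visual variants (white or gray
background crossed with a red or yellow frame), every configuration twice,
for 200 trials: 150 go (75%) and 50 stop (25%). Go responses are a
two-alternative frame-colour choice (key 1 for red frames, key 3 for
yellow); on stop trials the gray-background version of the stimulus appears
after a variable stop-signal delay as the signal to withhold the response.

The ``variant`` column of a trial plan is the configuration label used for
counterbalancing: the displayed go stimulus is always the white-background
version of the image, and on stop trials the gray version of the same
configuration is shown as the stop signal.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VARIANTS = ("white_red", "white_yellow", "gray_red", "gray_yellow")
RED_KEY = "key1"
YELLOW_KEY = "key3"

PLAN_COLUMNS = [
    "index",
    "condition",
    "trial_type",
    "stimulus_id",
    "variant",
    "correct_key",
    "iti_ms",
]


class DesignError(ValueError):
    """Raised when a design specification is internally inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one SST condition.

    Defaults are the published task: 25 images x 4 variants x 2 repeats =
    200 trials, 150 go / 50 stop, 500 ms fixation, 1000 ms response window,
    jittered ITI from {1500, 1700, 2000} ms, staircase-driven stop-signal
    delay starting at 250 ms moving in 50 ms steps within [50, 1000] ms.
    """

    n_images: int = 25
    n_variants: int = 4
    repeats_per_config: int = 2
    n_go: int = 150
    n_stop: int = 50
    fixation_ms: int = 500
    max_stim_ms: int = 1000
    iti_set_ms: tuple[int, ...] = (1500, 1700, 2000)
    ssd_initial_ms: int = 250
    ssd_step_ms: int = 50
    ssd_min_ms: int = 50
    ssd_max_ms: int = 1000
    condition: str = "food"
    max_consecutive_stops: int | None = None

    @property
    def n_trials(self) -> int:
        return self.n_go + self.n_stop

    def validate(self) -> None:
        n_cfg = self.n_images * self.n_variants * self.repeats_per_config
        if self.n_go + self.n_stop != n_cfg:
            raise DesignError(
                f"n_go + n_stop = {self.n_go + self.n_stop} must equal "
                f"n_images * n_variants * repeats_per_config = {n_cfg}"
            )
        if not (self.ssd_min_ms <= self.ssd_initial_ms <= self.ssd_max_ms):
            raise DesignError(
                "ssd_min_ms <= ssd_initial_ms <= ssd_max_ms violated: "
                f"{self.ssd_min_ms} <= {self.ssd_initial_ms} <= {self.ssd_max_ms}"
            )
        if self.ssd_step_ms <= 0:
            raise DesignError(f"ssd_step_ms must be positive, got {self.ssd_step_ms}")
        if self.n_variants > len(VARIANTS):
            raise DesignError(
                f"n_variants = {self.n_variants} exceeds the {len(VARIANTS)} defined variants"
            )
        if self.condition not in ("food", "neutral"):
            raise DesignError(f"condition must be 'food' or 'neutral', got {self.condition!r}")
        if not self.iti_set_ms:
            raise DesignError("iti_set_ms must be nonempty")

    def replace(self, **kw) -> "DesignSpec":
        return dataclasses.replace(self, **kw)


def correct_key_for(variant: str) -> str:
    """Key 1 for red frames, key 3 for yellow frames."""
    if variant.endswith("red"):
        return RED_KEY
    if variant.endswith("yellow"):
        return YELLOW_KEY
    raise DesignError(f"unknown variant {variant!r}")


def build_condition(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Build the randomized trial sequence of one condition.

    Every (stimulus_id, variant) configuration appears exactly
    ``repeats_per_config`` times; stop trials are interleaved uniformly at
    random (optionally capped at ``max_consecutive_stops`` in a row); each
    trial draws its ITI uniformly from ``iti_set_ms``. Deterministic for a
    given seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    configs = [
        (img, var)
        for img in range(1, spec.n_images + 1)
        for var in VARIANTS[: spec.n_variants]
        for _ in range(spec.repeats_per_config)
    ]
    order = rng.permutation(len(configs))
    configs = [configs[i] for i in order]

    trial_types = _interleave_stops(spec, rng)
    itis = rng.choice(np.asarray(spec.iti_set_ms), size=spec.n_trials)

    rows = []
    for i, ((img, var), ttype, iti) in enumerate(zip(configs, trial_types, itis)):
        rows.append(
            {
                "index": i,
                "condition": spec.condition,
                "trial_type": ttype,
                "stimulus_id": img,
                "variant": var,
                "correct_key": correct_key_for(var),
                "iti_ms": int(iti),
            }
        )
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def _interleave_stops(spec: DesignSpec, rng: np.random.Generator) -> list[str]:
    n = spec.n_trials
    stop_pos = rng.choice(n, size=spec.n_stop, replace=False)
    types = np.array(["go"] * n, dtype=object)
    types[stop_pos] = "stop"
    m = spec.max_consecutive_stops
    if m is None:
        return list(types)
    if m < 1:
        raise DesignError("max_consecutive_stops must be >= 1")
    # feasibility: k stops need enough go separators for runs of length <= m
    if math.ceil(spec.n_stop / m) - 1 > spec.n_go:
        raise DesignError(
            f"could not place {spec.n_stop} stop trials with "
            f"max_consecutive_stops={m}"
        )
    # repair pass: relocate stops out of over-long runs into legal slots
    for _ in range(100 * n):
        bad = _first_overlong_run(types, m)
        if bad is None:
            return list(types)
        legal = [
            i
            for i in np.flatnonzero(types == "go")
            if _placement_legal(types, i, m)
        ]
        types[bad] = "go"
        types[rng.choice(legal)] = "stop"
    raise DesignError(
        f"could not place {spec.n_stop} stop trials with "
        f"max_consecutive_stops={m}"
    )


def _first_overlong_run(types: np.ndarray, m: int) -> int | None:
    run = 0
    for i, t in enumerate(types):
        run = run + 1 if t == "stop" else 0
        if run > m:
            return i
    return None


def _placement_legal(types: np.ndarray, i: int, m: int) -> bool:
    probe = types.copy()
    probe[i] = "stop"
    lo = max(0, i - m)
    hi = min(len(types), i + m + 1)
    run = 0
    for t in probe[lo:hi]:
        run = run + 1 if t == "stop" else 0
        if run > m:
            return False
    return True


def counterbalance_sessions(participant_index: int) -> tuple[str, str]:
    """Alternate session order: food-first for even indices, neutral-first for odd.

    Over any even-sized cohort this yields an exact 50/50 split of session
    orders; odd cohorts differ by one.
    """
    if participant_index % 2 == 0:
        return ("food", "neutral")
    return ("neutral", "food")


def write_plan(plan: pd.DataFrame, path: str | Path) -> None:
    """Write a trial plan as tab-separated text."""
    plan.to_csv(path, sep="\t", index=False)


def read_plan(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
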
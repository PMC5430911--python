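"""Trial-sequence generation for the intention-inference tasks.

Each run of the experiment has an *induction* phase (long, unambiguous action
clips that install a 2:1 prior on one of the two intentions) followed by a
*testing* phase (shortened clips at three levels of visuomotor evidence),
with colour-judgement control trials randomly interleaved.  Four task
variants share this structure and differ only in the intention pair:

* ``basic``          — transport vs. rotate (simple motor goal)
* ``superordinate``  — pattern1 vs. pattern2 (abstract goal reached via the
  same two motor acts)
* ``nonsocial``      — transport vs. rotate (object-directed)
* ``social``         — cooperate vs. defect; a first actor moves, and the
  second actor mirrors that move (tit-for-tat) with raised probability, so
  the "likely" intention is defined relative to the first actor's move.

Visuomotor evidence is operationalised as the action-clip duration: four
levels, 1480 / 1560 / 1640 / 1880 ms after movement onset.  Testing trials
use only the three shortened levels; induction trials use the very-high
level.  The 66/33 bias is realised as an exact 2:1 integer allocation, not
Bernoulli sampling, so every run has identical cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "TaskConfig",
    "TrialRecord",
    "SessionDesign",
    "INTENTION_PAIRS",
    "EVENT_NAMES",
    "generate_run",
    "generate_tft_sequence",
    "export_events",
    "load_events",
    "assemble_session",
]


class ConfigError(ValueError):
    """Invalid task configuration; the message names the offending field."""


#: intention alphabet per task variant (first element is the default "likely"
#: intention for the non-social tasks; in the social task "likely" means the
#: second actor mirrored the first, so the alphabet is symmetric)
INTENTION_PAIRS = {
    "basic": ("transport", "rotate"),
    "superordinate": ("pattern1", "pattern2"),
    "nonsocial": ("transport", "rotate"),
    "social": ("cooperate", "defect"),
}

#: within-trial events, in order
EVENT_NAMES = ("fixation", "preparation", "action", "delay", "response")

_RESPONSE_WINDOW_S = 1.5


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of one run of one task variant.

    Defaults reproduce the study design: 36 induction trials at the
    very-high evidence level, 108 testing trials split evenly over the three
    shortened levels, a 2/3 bias on the likely intention, and uniformly
    jittered event timings (fixation 500-2500 ms, preparation 1000-1500 ms,
    delay 500-1000 ms, response window 1500 ms).
    """

    task_type: str = "basic"
    n_induction: int = 36
    n_testing: int = 108
    bias: float = 2.0 / 3.0
    evidence_levels_ms: tuple[int, ...] = (1480, 1560, 1640, 1880)
    induction_level_ms: int = 1880
    tft_prob: float = 2.0 / 3.0
    n_control: int = 12
    fixation_bounds_s: tuple[float, float] = (0.5, 2.5)
    preparation_bounds_s: tuple[float, float] = (1.0, 1.5)
    delay_bounds_s: tuple[float, float] = (0.5, 1.0)
    response_window_s: float = _RESPONSE_WINDOW_S
    likely_intention: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task_type not in INTENTION_PAIRS:
            raise ConfigError(
                f"task_type: unknown task {self.task_type!r}; "
                f"expected one of {sorted(INTENTION_PAIRS)}"
            )
        if not 0.5 < self.bias < 1.0:
            raise ConfigError(f"bias: must lie in (0.5, 1), got {self.bias}")
        levels = tuple(self.evidence_levels_ms)
        if len(levels) < 2 or any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigError(
                f"evidence_levels_ms: must be strictly increasing, got {levels}"
            )
        if self.induction_level_ms not in levels:
            raise ConfigError(
                "induction_level_ms: must be one of evidence_levels_ms, "
                f"got {self.induction_level_ms}"
            )
        n_testing_levels = len(levels) - 1
        if self.n_testing % n_testing_levels != 0:
            raise ConfigError(
                f"n_testing: {self.n_testing} not divisible by the "
                f"{n_testing_levels} testing evidence levels"
            )
        if self.n_induction < 0 or self.n_control < 0:
            raise ConfigError("n_induction/n_control: counts must be >= 0")
        if not 0.0 <= self.tft_prob <= 1.0:
            raise ConfigError(f"tft_prob: must lie in [0, 1], got {self.tft_prob}")
        for name in ("fixation_bounds_s", "preparation_bounds_s", "delay_bounds_s"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(
                    f"{name}: bounds must be positive with lower <= upper, got {(lo, hi)}"
                )
        if self.response_window_s <= 0:
            raise ConfigError("response_window_s: must be positive")
        if (
            self.likely_intention is not None
            and self.likely_intention not in INTENTION_PAIRS[self.task_type]
        ):
            raise ConfigError(
                f"likely_intention: {self.likely_intention!r} not in "
                f"{INTENTION_PAIRS[self.task_type]}"
            )

    @property
    def intentions(self) -> tuple[str, str]:
        return INTENTION_PAIRS[self.task_type]

    @property
    def testing_levels_ms(self) -> tuple[int, ...]:
        """The shortened durations used in the testing phase."""
        return tuple(d for d in self.evidence_levels_ms if d != self.induction_level_ms)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: its condition labels and its within-trial event timings.

    ``onsets``/``durations`` map event name -> seconds from run start; the
    response event's duration is the response window.  Control trials carry
    ``intention=None`` and ``evidence_level=None``.
    """

    index: int
    phase: str  # induction | testing | control
    intention: Optional[str]
    is_likely: Optional[bool]
    evidence_level: Optional[int]  # ordinal 1..4
    evidence_ms: float
    onsets: dict[str, float] = field(default_factory=dict)
    durations: dict[str, float] = field(default_factory=dict)
    first_actor_move: Optional[str] = None

    @property
    def end_s(self) -> float:
        return self.onsets["response"] + self.durations["response"]


@dataclass(frozen=True)
class SessionDesign:
    """An ordered trial list with its generating configuration and seed."""

    config: TaskConfig
    trials: tuple[TrialRecord, ...]
    total_duration_s: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """One row per trial (condition labels + action onset)."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "trial_index": t.index,
                    "phase": t.phase,
                    "intention": t.intention,
                    "is_likely": t.is_likely,
                    "evidence_level": t.evidence_level,
                    "evidence_ms": t.evidence_ms,
                    "first_actor_move": t.first_actor_move,
                    "onset": t.onsets["action"],
                }
            )
        return pd.DataFrame(rows)

    def task_trials(self) -> tuple[TrialRecord, ...]:
        """Non-control trials in session order."""
        return tuple(t for t in self.trials if t.phase != "control")


def _allocate_likely(n: int, bias: float) -> int:
    return int(round(bias * n))


def generate_tft_sequence(
    first_moves: Sequence[str], tft_prob: float, seed: int
) -> list[str]:
    """Second-actor moves mirroring ``first_moves`` with probability ``tft_prob``.

    Each element independently mirrors (tit-for-tat) the first actor's move
    with probability ``tft_prob`` and anti-mirrors otherwise.  Moves must be
    drawn from the cooperate/defect alphabet.
    """
    if not 0.0 <= tft_prob <= 1.0:
        raise ConfigError(f"tft_prob: must lie in [0, 1], got {tft_prob}")
    pair = INTENTION_PAIRS["social"]
    opposite = {pair[0]: pair[1], pair[1]: pair[0]}
    for m in first_moves:
        if m not in opposite:
            raise ValueError(f"unknown move {m!r}; expected one of {pair}")
    rng = np.random.default_rng(seed)
    mirror = rng.random(len(first_moves)) < tft_prob
    return [m if mi else opposite[m] for m, mi in zip(first_moves, mirror)]


def _phase_cells(config: TaskConfig) -> list[tuple[str, int, int, int]]:
    """(phase, level_ordinal, n_likely, n_unlikely) per design cell."""
    levels = list(config.evidence_levels_ms)
    cells = []
    if config.n_induction:
        n_lik = _allocate_likely(config.n_induction, config.bias)
        ordinal = levels.index(config.induction_level_ms) + 1
        cells.append(("induction", ordinal, n_lik, config.n_induction - n_lik))
    n_levels = len(config.testing_levels_ms)
    per_level = config.n_testing // n_levels
    for dur in config.testing_levels_ms:
        n_lik = _allocate_likely(per_level, config.bias)
        cells.append(("testing", levels.index(dur) + 1, n_lik, per_level - n_lik))
    return cells


def generate_run(config: TaskConfig) -> SessionDesign:
    """Generate one run: biased trial sequence plus jittered event timings.

    Deterministic given ``config.seed``.  Likely/unlikely counts are exact
    integer allocations within every phase x evidence-level cell; trial order
    is randomly permuted within each phase and control trials are interleaved
    at random positions.  Event onsets are drawn uniformly within the
    configured jitter bounds and rounded to the millisecond.
    """
    rng = np.random.default_rng(config.seed)
    social = config.task_type == "social"
    pair = config.intentions

    if social:
        likely_label = None
    elif config.likely_intention is not None:
        likely_label = config.likely_intention
    else:
        likely_label = pair[int(rng.integers(2))]

    # Build per-phase label lists, then permute within phase.
    protos: list[dict] = []
    for phase, ordinal, n_lik, n_unlik in _phase_cells(config):
        dur = config.evidence_levels_ms[ordinal - 1]
        for is_likely in [True] * n_lik + [False] * n_unlik:
            protos.append(
                {
                    "phase": phase,
                    "evidence_level": ordinal,
                    "evidence_ms": float(dur),
                    "is_likely": is_likely,
                }
            )
    induction = [p for p in protos if p["phase"] == "induction"]
    testing = [p for p in protos if p["phase"] == "testing"]
    induction = [induction[i] for i in rng.permutation(len(induction))]
    testing = [testing[i] for i in rng.permutation(len(testing))]
    ordered = induction + testing

    # Interleave control trials at random positions across the whole run.
    lo, hi = config.evidence_levels_ms[0], config.evidence_levels_ms[-1]
    controls = [
        {
            "phase": "control",
            "evidence_level": None,
            "evidence_ms": float(rng.integers(lo, hi + 1)),
            "is_likely": None,
        }
        for _ in range(config.n_control)
    ]
    positions = np.sort(rng.integers(0, len(ordered) + 1, size=len(controls)))
    for offset, (pos, ctl) in enumerate(zip(positions, controls)):
        ordered.insert(int(pos) + offset, ctl)

    # Assign intentions.
    for proto in ordered:
        if proto["phase"] == "control":
            proto["intention"] = None
            proto["first_actor_move"] = None
        elif social:
            first = pair[int(rng.integers(2))]
            opposite = pair[1] if first == pair[0] else pair[0]
            proto["first_actor_move"] = first
            proto["intention"] = first if proto["is_likely"] else opposite
        else:
            proto["first_actor_move"] = None
            proto["intention"] = (
                likely_label
                if proto["is_likely"]
                else (pair[1] if likely_label == pair[0] else pair[0])
            )

    # Timings: sequential trials, uniform jitter within bounds, ms rounding.
    trials = []
    clock = 0.0
    for idx, proto in enumerate(ordered):
        fix = round(rng.uniform(*config.fixation_bounds_s), 3)
        prep = round(rng.uniform(*config.preparation_bounds_s), 3)
        act = round(proto["evidence_ms"] / 1000.0, 3)
        delay = round(rng.uniform(*config.delay_bounds_s), 3)
        resp = config.response_window_s
        onsets, durations = {}, {}
        t = clock
        for name, dur in zip(EVENT_NAMES, (fix, prep, act, delay, resp)):
            onsets[name] = round(t, 3)
            durations[name] = dur
            t = round(t + dur, 3)
        clock = t
        trials.append(
            TrialRecord(
                index=idx,
                phase=proto["phase"],
                intention=proto["intention"],
                is_likely=proto["is_likely"],
                evidence_level=proto["evidence_level"],
                evidence_ms=proto["evidence_ms"],
                onsets=onsets,
                durations=durations,
                first_actor_move=proto["first_actor_move"],
            )
        )
    return SessionDesign(
        config=config, trials=tuple(trials), total_duration_s=clock, seed=config.seed
    )


def assemble_session(
    designs: Sequence[SessionDesign], order: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Concatenate per-condition runs into one session-level event table.

    Onsets of later runs are offset by the cumulative duration of earlier
    runs; a ``condition`` column records each run's task type.
    """
    if order is None:
        order = range(len(designs))
    frames = []
    offset = 0.0
    for k in order:
        d = designs[k]
        ev = events_frame(d)
        ev["onset"] = ev["onset"] + offset
        ev["condition"] = d.config.task_type
        offset += d.total_duration_s
        frames.append(ev)
    return pd.concat(frames, ignore_index=True)


def events_frame(design: SessionDesign) -> pd.DataFrame:
    """Long-format event table: one row per within-trial event."""
    rows = []
    for t in design.trials:
        for name in EVENT_NAMES:
            rows.append(
                {
                    "onset": t.onsets[name],
                    "duration": t.durations[name],
                    "trial_type": name,
                    "trial_index": t.index,
                    "phase": t.phase,
                    "intention": t.intention,
                    "is_likely": t.is_likely,
                    "evidence_level": t.evidence_level,
                    "first_actor_move": t.first_actor_move,
                }
            )
    cols = [
        "onset",
        "duration",
        "trial_type",
        "trial_index",
        "phase",
        "intention",
        "is_likely",
        "evidence_level",
        "first_actor_move",
    ]
    return pd.DataFrame(rows, columns=cols)


def export_events(design: SessionDesign, path) -> None:
    """Write the design as a BIDS-style tab-separated events file."""
    ev = events_frame(design)
    ev = ev.copy()
    # BIDS uses n/a for missing values
    ev["is_likely"] = ev["is_likely"].map(
        lambda v: "n/a" if v is None or (isinstance(v, float) and np.isnan(v)) else str(bool(v))
    )
    ev.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.3f")


def load_events(path) -> pd.DataFrame:
    """Read an events file written by :func:`export_events`."""
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if "is_likely" in ev.columns:
        ev["is_likely"] = ev["is_likely"].map(
            {"True": True, "False": False, True: True, False: False}
        )
        ev["is_likely"] = ev["is_likely"].astype(object).where(ev["is_likely"].notna(), None)
    return ev
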
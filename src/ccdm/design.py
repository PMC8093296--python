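"""Experimental design: display space, old/new sets, and session schedules.

The visual-search experiment places one target and three distractors on
8 possible locations (4 per hemifield).  Displays are constrained so that
each hemifield receives exactly two items: two distractors on one side,
the target plus one distractor on the other.  "Old" displays repeat
identically in every block; "new" displays reuse a fixed set of target
positions but receive freshly randomised distractors each block, so only
old displays carry predictive context.

Location indexing is abstract: positions ``0 .. 2s-1`` with the left side
``0 .. s-1`` and the right side ``s .. 2s-1`` (no screen geometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DisplayConfiguration",
    "SessionSchedule",
    "Trial",
    "WaveformSpec",
    "UNISENSORY",
    "MULTISENSORY",
    "UNI_VISUAL",
    "MS_VISUAL",
    "MS_TACTILE",
    "enumerate_configurations",
    "sample_display_sets",
    "build_session_schedule",
    "validate_schedule",
    "tactile_waveform",
    "schedule_to_frame",
]

UNISENSORY = "unisensory"
MULTISENSORY = "multisensory"

UNI_VISUAL = "unisensory_visual"
MS_VISUAL = "multisensory_visual"
MS_TACTILE = "multisensory_visuotactile"

N_BLOCKS = 32
BLOCKS_PER_EPOCH = 4
TRIALS_PER_BLOCK = 8
N_EPOCHS = N_BLOCKS // BLOCKS_PER_EPOCH


class GeometryError(ValueError):
    """Raised for display layouts that cannot satisfy the side-balance rule."""


class FeasibilityError(ValueError):
    """Raised when display-set sampling constraints cannot be met."""


def epoch_of_block(block: int) -> int:
    """Epoch index (1-based) of a 1-based block: four blocks per epoch."""
    return math.ceil(block / BLOCKS_PER_EPOCH)


@dataclass(frozen=True, order=True)
class DisplayConfiguration:
    """One spatial arrangement: a target and three distractors over 2s locations.

    Invariants: the target is not a distractor; exactly one distractor shares
    the target's side, the other two lie on the opposite side.
    """

    target_position: int
    distractor_positions: tuple[int, ...]
    n_per_side: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "distractor_positions", tuple(sorted(self.distractor_positions))
        )
        s = self.n_per_side
        if s < 2:
            raise GeometryError("need at least 2 positions per side")
        positions = (self.target_position, *self.distractor_positions)
        if len(self.distractor_positions) != 3:
            raise GeometryError("exactly 3 distractors required")
        if len(set(positions)) != 4:
            raise GeometryError("target and distractors must occupy distinct positions")
        if any(p < 0 or p >= 2 * s for p in positions):
            raise GeometryError(f"positions must lie in 0..{2 * s - 1}")
        same = sum(1 for d in self.distractor_positions if self.side_of(d) == self.target_side)
        if same != 1:
            raise GeometryError(
                "side balance violated: need exactly one distractor on the "
                "target side and two on the opposite side"
            )

    def side_of(self, position: int) -> str:
        return "left" if position < self.n_per_side else "right"

    @property
    def target_side(self) -> str:
        return self.side_of(self.target_position)


def enumerate_configurations(
    n_positions_per_side: int = 4, target_position: int | None = None
) -> list[DisplayConfiguration]:
    """Enumerate every side-balanced display configuration.

    With ``s`` positions per side there are ``2s`` target choices, ``s - 1``
    same-side distractor choices and ``C(s, 2)`` opposite-side pairs, i.e.
    ``2 s (s - 1) C(s, 2)`` configurations in total (144 for s = 4).

    Parameters
    ----------
    n_positions_per_side
        Locations per hemifield (>= 2).
    target_position
        If given, restrict the enumeration to displays with this target.
    """
    s = n_positions_per_side
    if s < 2:
        raise GeometryError("need at least 2 positions per side")
    left = range(s)
    right = range(s, 2 * s)
    targets = range(2 * s) if target_position is None else [target_position]
    out: list[DisplayConfiguration] = []
    for tgt in targets:
        same_side, other_side = (left, right) if tgt < s else (right, left)
        for d_same in same_side:
            if d_same == tgt:
                continue
            for d_opp in combinations(other_side, 2):
                out.append(DisplayConfiguration(tgt, (d_same, *d_opp), n_per_side=s))
    return out


def sample_display_sets(
    seed: int | np.random.Generator,
    exclude: Iterable[DisplayConfiguration] = (),
    n_per_side: int = 4,
) -> tuple[tuple[DisplayConfiguration, ...], tuple[int, ...]]:
    """Draw the four "old" displays and the complementary "new" target positions.

    Old targets occupy four positions, two per side; the remaining four
    positions (again two per side) are reserved for new displays.  Displays
    listed in ``exclude`` (e.g. the other session's old set) are never reused.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    excluded = set(exclude)
    by_target: dict[int, list[DisplayConfiguration]] = {}
    for cfg in enumerate_configurations(n_per_side):
        if cfg in excluded:
            continue
        by_target.setdefault(cfg.target_position, []).append(cfg)

    sides = (range(n_per_side), range(n_per_side, 2 * n_per_side))
    old_positions: list[int] = []
    for side in sides:
        feasible = [p for p in side if by_target.get(p)]
        if len(feasible) < 2:
            raise FeasibilityError(
                "exclusion leaves fewer than two feasible target positions on one side"
            )
        chosen = rng.choice(len(feasible), size=2, replace=False)
        old_positions.extend(feasible[i] for i in sorted(chosen))

    old_set = tuple(
        by_target[p][rng.integers(len(by_target[p]))] for p in old_positions
    )
    new_positions = tuple(
        p for p in range(2 * n_per_side) if p not in old_positions
    )
    return old_set, new_positions


@dataclass(frozen=True)
class Trial:
    """One scheduled trial (design labels only; no behavioral outcome)."""

    session: str
    block: int
    epoch: int
    trial_index: int
    trial_type: str
    configuration: str  # "old" | "new"
    display: DisplayConfiguration
    display_id: str
    target_orientation: str  # "left" | "right"


@dataclass
class SessionSchedule:
    session_kind: str
    trials: list[Trial]
    old_set: tuple[DisplayConfiguration, ...]
    new_target_positions: tuple[int, ...]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)


def _balanced_orientations(n: int, rng: np.random.Generator) -> list[str]:
    seq = ["left"] * (n // 2) + ["right"] * (n - n // 2)
    rng.shuffle(seq)
    return seq


def build_session_schedule(
    session_kind: str,
    old_set: Sequence[DisplayConfiguration],
    new_target_positions: Sequence[int],
    seed: int,
) -> SessionSchedule:
    """Build one session: 32 blocks x 8 trials (4 old + 4 new per block).

    Old displays repeat verbatim in every block; new displays are regenerated
    each block with random distractor placement at the designated new target
    positions.  In the multisensory session half the trials of each block are
    visuotactile, counterbalanced within block pairs so every old display (and
    every new target position) is seen 16 times per trial type.  Target
    orientation is balanced by construction within each display/position-by-
    trial-type stream.
    """
    if session_kind not in (UNISENSORY, MULTISENSORY):
        raise ValueError(f"unknown session kind: {session_kind!r}")
    if len(old_set) != 4:
        raise ValueError("old_set must contain exactly 4 displays")
    old_targets = {cfg.target_position for cfg in old_set}
    if len(old_targets) != 4 or old_targets & set(new_target_positions):
        raise ValueError("old and new target positions must be 4 + 4 disjoint")
    rng = np.random.default_rng(seed)
    n_per_side = old_set[0].n_per_side

    new_cfg_pool = {
        p: enumerate_configurations(n_per_side, target_position=p)
        for p in new_target_positions
    }

    # Trial-type assignment per (block, slot).  Slots 0-3 = old displays,
    # 4-7 = new target positions.  Multisensory: within each pair of blocks
    # every slot is visuotactile exactly once (random half per pair), so each
    # old display accrues 16 trials per trial type over the 32 blocks.
    slot_types: dict[tuple[int, int], str] = {}
    for block in range(1, N_BLOCKS + 1):
        for slot in range(8):
            slot_types[(block, slot)] = UNI_VISUAL
    if session_kind == MULTISENSORY:
        for pair_start in range(1, N_BLOCKS + 1, 2):
            for base in (0, 4):
                half = rng.choice(4, size=2, replace=False)
                for offset in range(4):
                    slot = base + offset
                    tactile_first = offset in half
                    slot_types[(pair_start, slot)] = (
                        MS_TACTILE if tactile_first else MS_VISUAL
                    )
                    slot_types[(pair_start + 1, slot)] = (
                        MS_VISUAL if tactile_first else MS_TACTILE
                    )

    # Balanced orientation streams per (slot, trial_type).
    stream_counts: dict[tuple[int, str], int] = {}
    for (block, slot), ttype in slot_types.items():
        stream_counts[(slot, ttype)] = stream_counts.get((slot, ttype), 0) + 1
    orientation_streams = {
        key: iter(_balanced_orientations(n, rng)) for key, n in stream_counts.items()
    }

    trials: list[Trial] = []
    trial_index = 0
    for block in range(1, N_BLOCKS + 1):
        epoch = epoch_of_block(block)
        block_trials: list[Trial] = []
        for slot in range(8):
            ttype = slot_types[(block, slot)]
            orientation = next(orientation_streams[(slot, ttype)])
            if slot < 4:
                display = old_set[slot]
                configuration = "old"
                display_id = f"old{slot + 1}"
            else:
                position = new_target_positions[slot - 4]
                pool = new_cfg_pool[position]
                display = pool[rng.integers(len(pool))]
                configuration = "new"
                display_id = f"new_p{position}_b{block}"
            block_trials.append(
                Trial(
                    session=session_kind,
                    block=block,
                    epoch=epoch,
                    trial_index=-1,
                    trial_type=ttype,
                    configuration=configuration,
                    display=display,
                    display_id=display_id,
                    target_orientation=orientation,
                )
            )
        order = rng.permutation(len(block_trials))
        for i in order:
            trial_index += 1
            t = block_trials[i]
            trials.append(
                Trial(
                    session=t.session,
                    block=t.block,
                    epoch=t.epoch,
                    trial_index=trial_index,
                    trial_type=t.trial_type,
                    configuration=t.configuration,
                    display=t.display,
                    display_id=t.display_id,
                    target_orientation=t.target_orientation,
                )
            )

    schedule = SessionSchedule(
        session_kind=session_kind,
        trials=trials,
        old_set=tuple(old_set),
        new_target_positions=tuple(new_target_positions),
        seed=seed,
    )
    validate_schedule(schedule)
    return schedule


def validate_schedule(schedule: SessionSchedule) -> None:
    """Independent recount of every schedule invariant; raises on violation.

    Checks trial/block totals, per-block old/new composition, old-display
    repetition, target-position balance and (multisensory) trial-type and
    orientation counts.  Deliberately recounts from the trial list rather
    than trusting the builder.
    """
    trials = schedule.trials
    if len(trials) != N_BLOCKS * TRIALS_PER_BLOCK:
        raise AssertionError(f"expected 256 trials, got {len(trials)}")
    blocks: dict[int, list[Trial]] = {}
    for t in trials:
        blocks.setdefault(t.block, []).append(t)
    if sorted(blocks) != list(range(1, N_BLOCKS + 1)):
        raise AssertionError("blocks must be 1..32")
    old_counts: dict[DisplayConfiguration, int] = {}
    for b, bt in blocks.items():
        if len(bt) != TRIALS_PER_BLOCK:
            raise AssertionError(f"block {b} has {len(bt)} trials")
        olds = [t for t in bt if t.configuration == "old"]
        news = [t for t in bt if t.configuration == "new"]
        if len(olds) != 4 or len(news) != 4:
            raise AssertionError(f"block {b} lacks the 4 old + 4 new composition")
        if {t.display for t in olds} != set(schedule.old_set):
            raise AssertionError(f"block {b} does not show each old display once")
        if {t.display.target_position for t in news} != set(schedule.new_target_positions):
            raise AssertionError(f"block {b} new target positions off-balance")
        for t in bt:
            if t.epoch != epoch_of_block(t.block):
                raise AssertionError("epoch label inconsistent with block")
        for t in olds:
            old_counts[t.display] = old_counts.get(t.display, 0) + 1
    if any(c != N_BLOCKS for c in old_counts.values()):
        raise AssertionError("each old display must occur exactly 32 times")
    old_positions = {c.target_position for c in schedule.old_set}
    n_per_side = schedule.old_set[0].n_per_side
    for positions in (old_positions, set(schedule.new_target_positions)):
        left = sum(1 for p in positions if p < n_per_side)
        if len(positions) != 4 or left != 2:
            raise AssertionError("target positions must be 4 per set, 2 per side")
    if schedule.session_kind == MULTISENSORY:
        by_type: dict[str, int] = {}
        orient: dict[tuple[str, str], int] = {}
        for t in trials:
            by_type[t.trial_type] = by_type.get(t.trial_type, 0) + 1
            key = (t.trial_type, t.target_orientation)
            orient[key] = orient.get(key, 0) + 1
        if by_type != {MS_VISUAL: 128, MS_TACTILE: 128}:
            raise AssertionError(f"multisensory trial-type split must be 128/128, got {by_type}")
        if any(orient.get((tt, o), 0) != 64 for tt in (MS_VISUAL, MS_TACTILE) for o in ("left", "right")):
            raise AssertionError("orientation must appear 64 times per trial type")
    else:
        if any(t.trial_type != UNI_VISUAL for t in trials):
            raise AssertionError("unisensory session must contain only visual trials")


@dataclass(frozen=True)
class WaveformSpec:
    """Specification-level description of a tactile vibration pattern.

    ``mean_cycle_rate`` is the average envelope-cycle rate including any
    silent gap inserted after every two cycles:
    ``2 / (2 * period + gap)`` with ``period = 1 / envelope_hz``.
    """

    carrier_hz: float
    envelope_hz: float | None
    duty_cycle: float
    gap_ms: float
    mean_cycle_rate: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.envelope_hz is not None and self.mean_cycle_rate is None:
            period = 1.0 / self.envelope_hz
            rate = 2.0 / (2.0 * period + self.gap_ms / 1000.0)
            object.__setattr__(self, "mean_cycle_rate", rate)


def tactile_waveform(kind: str) -> WaveformSpec:
    """Stimulus waveforms: T1 and T2 target vibrations and the distractor hum.

    T1 is a 150-Hz carrier gated by a 5-Hz square wave at 30% duty cycle
    (mean rate 5 Hz); T2 uses a 60% duty cycle with a 200-ms pause after
    every two cycles, giving a mean rate of 10/3 Hz (~3.3 Hz); distractors
    vibrate continuously at 150 Hz.
    """
    if kind == "T1":
        return WaveformSpec(carrier_hz=150.0, envelope_hz=5.0, duty_cycle=0.30, gap_ms=0.0)
    if kind == "T2":
        return WaveformSpec(carrier_hz=150.0, envelope_hz=5.0, duty_cycle=0.60, gap_ms=200.0)
    if kind == "distractor":
        return WaveformSpec(carrier_hz=150.0, envelope_hz=None, duty_cycle=1.0, gap_ms=0.0)
    raise ValueError(f"unknown waveform kind: {kind!r}")


def schedule_to_frame(schedule: SessionSchedule, subject: int) -> pd.DataFrame:
    """Serialize a schedule to the canonical delimited trial table."""
    rows = [
        {
            "subject": subject,
            "session": t.session,
            "block": t.block,
            "epoch": t.epoch,
            "trial_index": t.trial_index,
            "trial_type": t.trial_type,
            "configuration": t.configuration,
            "display_id": t.display_id,
            "target_position": t.display.target_position,
            "target_orientation": t.target_orientation,
        }
        for t in schedule.trials
    ]
    return pd.DataFrame(rows)
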
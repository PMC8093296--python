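"""Synthetic trial-level cohorts with the structure the analysis assumes.

A cohort is generated from an explicit :class:`GroundTruth`: per condition
cell (3 trial types x old/new) a group-mean drift rate and non-decision
time with between-subject normal variability, and a boundary separation
that declines linearly over epochs, ``a(N) = beta0 + beta1(cell) * N``.
Every trial is drawn from the diffusion process of :mod:`ccdm.ddm_core`
on schedules built by :mod:`ccdm.design`, so downstream preprocessing,
learning-curve fitting and hierarchical inference can all be exercised
against a known truth.

Error responses are lower-boundary absorptions of the same process
(accuracy coding; the upper boundary is the correct response), consistent
with the unbiased start point z = a/2.  The RT clock starts at visual
onset: any tactile preview affects only the non-decision time, never an
additive offset on simulated RTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .ddm_core import _simulate_kernel

__all__ = ["CELLS", "GroundTruth", "default_ground_truth", "simulate_cohort"]

# Canonical condition-cell order used throughout the package.
CELLS: tuple[tuple[str, str], ...] = (
    (design.UNI_VISUAL, "old"),
    (design.UNI_VISUAL, "new"),
    (design.MS_VISUAL, "old"),
    (design.MS_VISUAL, "new"),
    (design.MS_TACTILE, "old"),
    (design.MS_TACTILE, "new"),
)

CELL_INDEX = {cell: i for i, cell in enumerate(CELLS)}


class GenerationError(ValueError):
    """Raised when a ground truth implies an invalid diffusion parameter."""


@dataclass(frozen=True)
class GroundTruth:
    """Group-level generating parameters for a synthetic cohort.

    ``v_mean`` / ``t_mean`` map condition cells (trial_type, configuration)
    to group means; ``v_sd`` / ``t_sd`` are between-subject SDs shared
    across cells.  Boundary separation follows ``a(N) = beta0 +
    beta1[cell] * N`` with the intercept and slopes shared across subjects.
    Units: evidence in unit-diffusion scale, times in seconds.
    """

    v_mean: dict[tuple[str, str], float]
    t_mean: dict[tuple[str, str], float]
    beta0: float
    beta1: dict[tuple[str, str], float]
    v_sd: float = 0.15
    t_sd: float = 0.05
    n_subjects: int = 14
    timeout_s: float = 6.0

    def __post_init__(self) -> None:
        if self.v_sd < 0 or self.t_sd < 0:
            raise ValueError("between-subject SDs must be non-negative")
        for cell in CELLS:
            for name, table in (("v_mean", self.v_mean), ("t_mean", self.t_mean), ("beta1", self.beta1)):
                if cell not in table:
                    raise ValueError(f"{name} missing cell {cell}")
            for epoch in (1, design.N_EPOCHS):
                if self.boundary(cell, epoch) <= 0:
                    raise GenerationError(
                        f"implied boundary a(epoch={epoch}) <= 0 in cell {cell}"
                    )

    def boundary(self, cell: tuple[str, str], epoch: int) -> float:
        return self.beta0 + self.beta1[cell] * epoch

    def to_records(self) -> pd.DataFrame:
        """Flat key/value table of every generating parameter."""
        rows = [
            {"parameter": "beta0", "trial_type": "", "configuration": "", "value": self.beta0},
            {"parameter": "v_sd", "trial_type": "", "configuration": "", "value": self.v_sd},
            {"parameter": "t_sd", "trial_type": "", "configuration": "", "value": self.t_sd},
            {"parameter": "n_subjects", "trial_type": "", "configuration": "", "value": self.n_subjects},
        ]
        for (tt, cfg) in CELLS:
            rows.append({"parameter": "v_mean", "trial_type": tt, "configuration": cfg, "value": self.v_mean[(tt, cfg)]})
            rows.append({"parameter": "t_mean", "trial_type": tt, "configuration": cfg, "value": self.t_mean[(tt, cfg)]})
            rows.append({"parameter": "beta1", "trial_type": tt, "configuration": cfg, "value": self.beta1[(tt, cfg)]})
        return pd.DataFrame(rows)


def default_ground_truth(scenario: str = "paper_like", n_subjects: int = 14) -> GroundTruth:
    """Reference generating scenarios.

    ``"null"``: all six condition cells identical -- no contextual-cueing
    and no multisensory effect (a nonzero common boundary slope still
    encodes procedural speed-up with practice).

    ``"paper_like"``: qualitative structure of the multisensory
    contextual-cueing findings -- higher drift for old than new displays,
    the old-display drift advantage strongest on multisensory-visual
    trials, a shorter non-decision time in the multisensory session, and
    boundary slopes below -0.063 per epoch in every cell, more negative
    for old displays.
    """
    uni, msv, mst = design.UNI_VISUAL, design.MS_VISUAL, design.MS_TACTILE
    if scenario == "null":
        v = {cell: 1.8 for cell in CELLS}
        t = {cell: 0.42 for cell in CELLS}
        b1 = {cell: -0.08 for cell in CELLS}
        return GroundTruth(v_mean=v, t_mean=t, beta0=2.0, beta1=b1, n_subjects=n_subjects)
    if scenario == "paper_like":
        # Modest constant drift advantages for old displays (so the epoch-1
        # cueing effect stays small, as observed) with the bulk of the
        # practice-dependent cueing carried by steeper boundary decline for
        # old displays.
        v = {
            (uni, "old"): 1.80,
            (uni, "new"): 1.60,
            (msv, "old"): 2.00,
            (msv, "new"): 1.60,
            (mst, "old"): 1.95,
            (mst, "new"): 1.65,
        }
        t = {
            (uni, "old"): 0.45,
            (uni, "new"): 0.45,
            (msv, "old"): 0.40,
            (msv, "new"): 0.40,
            (mst, "old"): 0.40,
            (mst, "new"): 0.40,
        }
        b1 = {
            (uni, "old"): -0.105,
            (uni, "new"): -0.070,
            (msv, "old"): -0.105,
            (msv, "new"): -0.064,
            (mst, "old"): -0.105,
            (mst, "new"): -0.068,
        }
        return GroundTruth(v_mean=v, t_mean=t, beta0=2.0, beta1=b1, n_subjects=n_subjects)
    raise ValueError(f"unknown scenario: {scenario!r}")


def _session_kinds_for_cells() -> dict[str, str]:
    return {
        design.UNI_VISUAL: design.UNISENSORY,
        design.MS_VISUAL: design.MULTISENSORY,
        design.MS_TACTILE: design.MULTISENSORY,
    }


def simulate_cohort(truth: GroundTruth, seed: int, dt: float = 1e-3) -> pd.DataFrame:
    """Simulate a full cohort: both sessions per subject, trial by trial.

    Subject-level drift and non-decision time are drawn per condition cell
    from the group distributions (t truncated at 50 ms); boundary follows
    the shared linear epoch trend.  Display schedules come from
    :func:`ccdm.design.build_session_schedule` with disjoint old sets
    across the two sessions.  Deterministic for a fixed seed.

    Returns the canonical trial table with added outcome columns
    ``response``, ``correct``, ``rt_ms`` and ``timeout``.
    """
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    for subject in range(1, truth.n_subjects + 1):
        sub_rng = np.random.default_rng(rng.integers(2**31 - 1))
        old1, new1 = design.sample_display_sets(sub_rng)
        old2, new2 = design.sample_display_sets(sub_rng, exclude=old1)
        schedules = {
            design.UNISENSORY: design.build_session_schedule(
                design.UNISENSORY, old1, new1, seed=int(sub_rng.integers(2**31 - 1))
            ),
            design.MULTISENSORY: design.build_session_schedule(
                design.MULTISENSORY, old2, new2, seed=int(sub_rng.integers(2**31 - 1))
            ),
        }
        # subject-level parameters per cell
        v_sub = {
            cell: truth.v_mean[cell] + truth.v_sd * sub_rng.standard_normal()
            for cell in CELLS
        }
        t_sub = {
            cell: max(0.05, truth.t_mean[cell] + truth.t_sd * sub_rng.standard_normal())
            for cell in CELLS
        }
        for kind, schedule in schedules.items():
            table = design.schedule_to_frame(schedule, subject)
            rts = np.empty(len(table))
            correct = np.empty(len(table), dtype=int)
            timeout = np.empty(len(table), dtype=bool)
            grouped = table.groupby(["trial_type", "configuration", "epoch"]).indices
            for (ttype, cfg, epoch), idx in grouped.items():
                cell = (ttype, cfg)
                a = truth.boundary(cell, int(epoch))
                if a <= 0:
                    raise GenerationError(
                        f"implied boundary <= 0 for cell {cell} at epoch {epoch}"
                    )
                r, up, to = _simulate_kernel(
                    v_sub[cell],
                    a,
                    a / 2.0,
                    t_sub[cell],
                    len(idx),
                    truth.timeout_s,
                    dt,
                    int(sub_rng.integers(2**31 - 1)),
                )
                rts[idx] = r
                correct[idx] = up
                timeout[idx] = to
            correct[timeout] = 0
            table["correct"] = correct
            opposite = table["target_orientation"].map({"left": "right", "right": "left"})
            table["response"] = np.where(
                timeout, "none", np.where(correct == 1, table["target_orientation"], opposite)
            )
            table["rt_ms"] = np.minimum(rts * 1000.0, truth.timeout_s * 1000.0)
            table["timeout"] = timeout
            frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    return out
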
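"""Behavioral preprocessing, epoch aggregation, and repeated-measures stats.

Trials are filtered by the study's outlier rule: error trials (for the RT
analysis), RTs below 200 ms, and RTs outside 2.5 SDs of the individual's
mean.  Blocks are collapsed four at a time into epochs; the
contextual-cueing effect is the per-epoch RT difference new - old.  The
within-subject ANOVA is computed via statsmodels' repeated-measures
decomposition, augmented with partial eta squared and Greenhouse-Geisser
sphericity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "ExclusionReport",
    "filter_trials",
    "aggregate_epochs",
    "contextual_cueing",
    "rm_anova",
    "pairwise_posthoc",
]

RT_FLOOR_MS = 200.0
SD_CRITERION = 2.5


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts for one filtering pass."""

    purpose: str
    n_input: int
    n_timeout: int
    n_error: int
    n_floor: int
    n_sd_rule: int
    n_retained: int
    n_sd_rule_subject_overall: int  # alternative trimming scope, logged only

    @property
    def excluded_fraction(self) -> float:
        return 1.0 - self.n_retained / self.n_input

    @property
    def extreme_rt_fraction(self) -> float:
        """Fraction of all input trials hit by the RT rules (floor + SD)."""
        return (self.n_floor + self.n_sd_rule) / self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _sd_rule_mask(rt: pd.Series, group: pd.Series) -> pd.Series:
    """True for trials within 2.5 SD of their group's mean (one pass).

    Group statistics are computed once on the post-floor distribution and
    applied in a single pass (not iterated).  A zero-SD group excludes
    nothing.
    """
    m = rt.groupby(group).transform("mean")
    s = rt.groupby(group).transform("std").fillna(0.0)
    keep = (rt - m).abs() <= SD_CRITERION * s
    return keep | (s == 0)


def filter_trials(
    table: pd.DataFrame, purpose: str = "rt_analysis"
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the study's trial-exclusion rules.

    purpose="rt_analysis": drop timeouts, error trials, RTs < 200 ms, then
    RTs beyond 2.5 SD of the subject's (per-session) mean, where mean/SD
    are computed on correct post-floor trials.

    purpose="ddm": keep errors (the diffusion likelihood uses both
    response types); apply only the timeout, floor and SD rules, with
    subject statistics over correct and error trials jointly.

    Returns the filtered table and an :class:`ExclusionReport` with
    per-rule counts.  The SD rule's trimming scope is per subject per
    session; the per-subject-overall count is also computed and logged in
    the report for comparison.
    """
    if purpose not in ("rt_analysis", "ddm"):
        raise ValueError("purpose must be 'rt_analysis' or 'ddm'")
    n_input = len(table)
    df = table.copy()
    if "timeout" in df:
        to_mask = df["timeout"].astype(bool)
        n_timeout = int(to_mask.sum())
        df = df.loc[~to_mask]
    else:
        n_timeout = 0
    if purpose == "rt_analysis":
        err_mask = df["correct"].astype(int) == 0
        n_error = int(err_mask.sum())
        df = df.loc[~err_mask]
    else:
        n_error = 0
    floor_mask = df["rt_ms"] < RT_FLOOR_MS
    n_floor = int(floor_mask.sum())
    df = df.loc[~floor_mask]

    counts = df.groupby("subject").size()
    too_few = counts[counts < 2]
    if len(too_few):
        raise ValueError(
            f"subject(s) {sorted(too_few.index.tolist())} have fewer than 2 usable trials"
        )

    session_group = df["subject"].astype(str) + "/" + df["session"].astype(str)
    keep = _sd_rule_mask(df["rt_ms"], session_group)
    n_sd = int((~keep).sum())
    keep_overall = _sd_rule_mask(df["rt_ms"], df["subject"].astype(str))
    n_sd_overall = int((~keep_overall).sum())
    df = df.loc[keep]

    report = ExclusionReport(
        purpose=purpose,
        n_input=n_input,
        n_timeout=n_timeout,
        n_error=n_error,
        n_floor=n_floor,
        n_sd_rule=n_sd,
        n_retained=len(df),
        n_sd_rule_subject_overall=n_sd_overall,
    )
    return df.reset_index(drop=True), report


def aggregate_epochs(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse trials into subject x trial_type x configuration x epoch cells.

    Returns one row per cell with mean RT, accuracy and trial count.
    Raises if any of the 8 epochs is empty for some cell combination
    present in the data.
    """
    grouped = table.groupby(
        ["subject", "trial_type", "configuration", "epoch"], as_index=False
    ).agg(rt_ms=("rt_ms", "mean"), accuracy=("correct", "mean"), n_trials=("rt_ms", "size"))
    expected = pd.MultiIndex.from_product(
        [
            grouped["subject"].unique(),
            grouped["trial_type"].unique(),
            grouped["configuration"].unique(),
            range(1, 9),
        ],
        names=["subject", "trial_type", "configuration", "epoch"],
    )
    have = pd.MultiIndex.from_frame(grouped[["subject", "trial_type", "configuration", "epoch"]])
    missing = expected.difference(have)
    if len(missing):
        raise ValueError(f"empty epoch cell(s): {list(missing[:5])}")
    return grouped


def contextual_cueing(epochs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contextual-cueing effect: mean RT(new) - mean RT(old) per cell.

    Returns ``(per_subject, summary)``: the per-subject effect for every
    trial_type x epoch, and the group summary with mean and SEM.  A
    positive value is an old-display advantage.
    """
    wide = epochs.pivot_table(
        index=["subject", "trial_type", "epoch"], columns="configuration", values="rt_ms"
    )
    if not {"old", "new"} <= set(wide.columns):
        raise ValueError("need both old and new configurations")
    per_subject = (wide["new"] - wide["old"]).rename("cc_ms").reset_index()
    summary = per_subject.groupby(["trial_type", "epoch"], as_index=False).agg(
        cc_ms=("cc_ms", "mean"),
        sem=("cc_ms", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        n=("cc_ms", "size"),
    )
    return per_subject, summary


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows span the ones-complement)."""
    return linalg.null_space(np.ones((1, k))).T


def _gg_epsilon(cellmat: np.ndarray, levels: list[int]) -> float:
    """Greenhouse-Geisser epsilon for one within-subject effect.

    ``cellmat`` is subjects x cells (cells ordered with the effect's
    factors varying as in a Kronecker product of their levels).
    """
    C = np.array([[1.0]])
    for k in levels:
        C = np.kron(C, _orthonormal_contrast(k))
    Y = cellmat @ C.T
    S = np.cov(Y, rowvar=False)
    S = np.atleast_2d(S)
    d = S.shape[0]
    tr = np.trace(S)
    denom = d * np.trace(S @ S)
    if denom <= 0:
        return 1.0
    return float(tr**2 / denom)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
) -> pd.DataFrame:
    """Fully-crossed within-subject ANOVA with effect sizes.

    One row per effect with F, (df1, df2), p, partial eta squared
    (``SS_effect / (SS_effect + SS_error)``), the Greenhouse-Geisser
    epsilon, and the epsilon-corrected p-value.  Uncorrected integer
    degrees of freedom are the primary output.  Input must contain exactly
    one value per subject x cell (aggregate first if not).
    """
    cells = data.groupby([subject, *within], as_index=False)[dv].mean()
    n_subj = cells[subject].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    counts = cells.groupby(within).size()
    if counts.nunique() != 1 or (counts != n_subj).any():
        raise ValueError("design must be fully crossed with every cell present")
    res = AnovaRM(cells, depvar=dv, subject=subject, within=within).fit()
    table = res.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )
    levels = {f: sorted(cells[f].unique().tolist()) for f in within}
    rows = []
    for effect, row in table.iterrows():
        factors = effect.split(":")
        F, df1, df2 = float(row["F"]), float(row["df1"]), float(row["df2"])
        pes = (F * df1) / (F * df1 + df2)
        eff_levels = [len(levels[f]) for f in factors]
        pivot = cells.pivot_table(
            index=subject, columns=factors, values=dv, aggfunc="mean"
        )
        # order columns as a Kronecker product over the effect's factors
        order = pd.MultiIndex.from_product([levels[f] for f in factors]) if len(factors) > 1 else pd.Index(levels[factors[0]])
        pivot = pivot.reindex(columns=order)
        eps = _gg_epsilon(pivot.to_numpy(), eff_levels)
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))
        rows.append(
            {
                "effect": effect,
                "F": F,
                "df1": int(round(df1)),
                "df2": int(round(df2)),
                "p": float(row["p"]),
                "partial_eta_sq": pes,
                "gg_epsilon": eps,
                "p_gg": p_gg,
            }
        )
    return pd.DataFrame(rows)


def pairwise_posthoc(
    data: pd.DataFrame, dv: str, factor: str, subject: str = "subject"
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests over all level pairs of a factor."""
    cells = data.groupby([subject, factor], as_index=False)[dv].mean()
    wide = cells.pivot(index=subject, columns=factor, values=dv)
    pairs = list(combinations(wide.columns, 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": float((wide[a] - wide[b]).mean()),
                "t": float(t),
                "p": float(p),
                "p_bonferroni": min(1.0, float(p) * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
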
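"""Hierarchical Bayesian drift-diffusion estimation and model comparison.

The model space crosses three diffusion parameters (drift ``v``, boundary
separation ``a``, non-decision time ``t``; start point fixed at ``a/2``)
with three kinds of dependence:

* ``fixed`` -- one value per subject, shared across all conditions;
* ``by_condition`` -- one value per subject per condition cell
  (3 trial types x old/new = 6 cells);
* ``epoch_covariate`` -- a linear epoch trend ``par = beta0 +
  beta1(cell) * N`` with a common intercept and one slope per cell,
  capturing practice-related change over the 8 epochs.

This yields exactly 15 admissible models: the all-fixed baseline, six
partial models, the full by-condition model, and seven covariate models.
Subject-level parameters are partially pooled toward group means with
weakly informative priors; sampling is adaptive Metropolis-within-Gibbs
(proposal scales tuned during burn-in only, frozen afterwards).  Model
comparison uses the conditional DIC (deviance evaluated at subject-level
parameters); hypothesis tests report the posterior mass of the stated
inequality; convergence is monitored with rank-normalized split R-hat.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .ddm_core import _loglik_array, _simulate_kernel
from .synthetic_data import CELLS, CELL_INDEX

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "ModelComparisonResult",
    "ContrastResult",
    "build_model_space",
    "fit_hierarchical",
    "compute_dic",
    "posterior_probability",
    "rhat",
    "posterior_predictive",
]

PARAMS = ("v", "a", "t")
FIXED, BY_CONDITION, EPOCH_COVARIATE = "fixed", "by_condition", "epoch_covariate"
N_CELLS = 6
EPOCH_MIN, EPOCH_MAX = 1.0, 8.0
RHAT_FLAG = 1.1

# weakly informative group priors: (mean, sd, truncated_at_zero)
_MU_PRIORS = {
    "v": (2.0, 3.0, False),
    "a": (1.5, 1.0, True),
    "t": (0.4, 0.35, True),
    "slope": (0.0, 0.5, False),
}
_SIGMA_PRIOR_SCALE = 0.5  # half-normal


def _cell_label(i: int) -> str:
    tt, cfg = CELLS[i]
    short = {"unisensory_visual": "uni", "multisensory_visual": "msv", "multisensory_visuotactile": "mst"}[tt]
    return f"{short}:{cfg}"


@dataclass(frozen=True)
class ModelSpec:
    """Per-parameter dependence declaration for one candidate model."""

    model_id: int
    dependence: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.dependence) != set(PARAMS):
            raise ValueError("dependence must cover v, a and t")
        for p, dep in self.dependence.items():
            if dep not in (FIXED, BY_CONDITION, EPOCH_COVARIATE):
                raise ValueError(f"unknown dependence {dep!r} for {p}")

    @property
    def name(self) -> str:
        parts = []
        for p in PARAMS:
            dep = self.dependence[p]
            if dep == BY_CONDITION:
                parts.append(f"{p}~condition")
            elif dep == EPOCH_COVARIATE:
                parts.append(f"{p}~epoch:C(condition)")
            else:
                parts.append(f"{p} fixed")
        return ", ".join(parts)

    def __str__(self) -> str:
        return f"Model {self.model_id}: {self.name}"


def build_model_space() -> list[ModelSpec]:
    """Enumerate the 15-model space.

    Model 1 is the all-fixed baseline; models 2-7 let one or two
    parameters vary by condition; model 8 is the full by-condition model;
    models 9-15 put one, two or all three parameters on the linear epoch
    covariate with the remainder by condition.  Model 9 is the boundary
    covariate model (``a ~ epoch:C(condition)``, ``v`` and ``t`` by
    condition).
    """
    specs: list[ModelSpec] = []
    specs.append(ModelSpec(1, {p: FIXED for p in PARAMS}))
    partial_sets = [("v",), ("a",), ("t",), ("v", "a"), ("v", "t"), ("a", "t")]
    for i, subset in enumerate(partial_sets, start=2):
        specs.append(
            ModelSpec(i, {p: BY_CONDITION if p in subset else FIXED for p in PARAMS})
        )
    specs.append(ModelSpec(8, {p: BY_CONDITION for p in PARAMS}))
    covariate_sets = [("a",), ("v",), ("t",), ("v", "a"), ("a", "t"), ("v", "t"), ("v", "a", "t")]
    for i, subset in enumerate(covariate_sets, start=9):
        specs.append(
            ModelSpec(
                i,
                {p: EPOCH_COVARIATE if p in subset else BY_CONDITION for p in PARAMS},
            )
        )
    return specs


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _TrialArrays:
    rt: np.ndarray  # seconds
    upper: np.ndarray  # bool, True = correct (accuracy coding)
    subj: np.ndarray  # 0..S-1
    cell: np.ndarray  # 0..5
    epoch: np.ndarray  # float 1..8
    n_subjects: int
    subject_labels: np.ndarray
    # index structures: trials sorted per grouping with reduceat offsets
    idx_all: np.ndarray
    off_all: np.ndarray
    idx_cell: list[np.ndarray]
    off_cell: list[np.ndarray]
    data_hash: str


def _prepare(data: pd.DataFrame, require_all_cells: bool = False) -> _TrialArrays:
    required = {"subject", "trial_type", "configuration", "epoch", "correct", "rt_ms"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    if "timeout" in data:
        data = data.loc[~data["timeout"].astype(bool)]
    labels = np.sort(data["subject"].unique())
    smap = {s: i for i, s in enumerate(labels)}
    subj = data["subject"].map(smap).to_numpy()
    cell = (
        data[["trial_type", "configuration"]]
        .apply(lambda r: CELL_INDEX[(r["trial_type"], r["configuration"])], axis=1)
        .to_numpy()
    )
    rt = data["rt_ms"].to_numpy(dtype=float) / 1000.0
    upper = data["correct"].to_numpy(dtype=int).astype(bool)
    epoch = data["epoch"].to_numpy(dtype=float)
    S = len(labels)
    present = set(zip(subj.tolist(), cell.tolist()))
    cells_present = list(range(N_CELLS)) if require_all_cells else sorted({c for _, c in present})
    for s in range(S):
        for c in cells_present:
            if (s, c) not in present:
                raise ValueError(
                    f"subject {labels[s]} has no trials in cell {CELLS[c]}"
                )
    order_all = np.argsort(subj, kind="stable")
    off_all = np.searchsorted(subj[order_all], np.arange(S))
    idx_cell, off_cell = [], []
    for c in range(N_CELLS):
        mask = cell == c
        idx = np.nonzero(mask)[0]
        idx = idx[np.argsort(subj[idx], kind="stable")]
        idx_cell.append(idx)
        off_cell.append(np.searchsorted(subj[idx], np.arange(S)))
    h = hashlib.sha256(
        np.ascontiguousarray(np.column_stack([rt, upper, subj, cell, epoch])).tobytes()
    ).hexdigest()[:16]
    return _TrialArrays(
        rt=rt,
        upper=upper,
        subj=subj,
        cell=cell,
        epoch=epoch,
        n_subjects=S,
        subject_labels=labels,
        idx_all=order_all,
        off_all=off_all,
        idx_cell=idx_cell,
        off_cell=off_cell,
        data_hash=h,
    )


# ---------------------------------------------------------------------------
# sampler state
# ---------------------------------------------------------------------------


class _Block:
    """State of one diffusion parameter under a given dependence."""

    def __init__(self, name: str, dep: str, S: int, init_base: np.ndarray, init_slope: float):
        self.name = name
        self.dep = dep
        self.nb = N_CELLS if dep == BY_CONDITION else 1
        self.has_slope = dep == EPOCH_COVARIATE
        self.base = np.tile(init_base.reshape(S, 1), (1, self.nb)).astype(float)
        self.slope = np.full((S, N_CELLS), init_slope) if self.has_slope else np.zeros((S, 0))
        self.mu_base = self.base.mean(axis=0).copy()
        self.sigma_base = 0.2
        self.mu_slope = self.slope.mean(axis=0).copy() if self.has_slope else np.zeros(0)
        self.sigma_slope = 0.05
        # adaptive proposal scales
        scale0 = {"v": 0.25, "a": 0.15, "t": 0.03}[name]
        self.sc_base = np.full((S, self.nb), scale0)
        self.sc_slope = np.full((S, N_CELLS), 0.02) if self.has_slope else np.zeros((S, 0))
        self.acc_base = np.zeros((S, self.nb))
        self.acc_slope = np.zeros((S, N_CELLS)) if self.has_slope else np.zeros((S, 0))
        self.sc_mu = np.full(self.nb, scale0 / 2.0)
        self.sc_mu_sl = np.full(N_CELLS, 0.02) if self.has_slope else np.zeros(0)
        self.sc_lsig = 0.3
        self.sc_lsig_sl = 0.3
        self.acc_mu = np.zeros(self.nb)
        self.acc_mu_sl = np.zeros(N_CELLS) if self.has_slope else np.zeros(0)
        self.acc_lsig = 0.0
        self.acc_lsig_sl = 0.0
        # ridge move: shift the intercept and counter-shift the slopes so the
        # mid-epoch value is preserved (decorrelates beta0 and beta1)
        self.sc_ridge = np.full(S, scale0 / 2.0)
        self.acc_ridge = np.zeros(S)
        self.sc_gridge = scale0 / 4.0
        self.acc_gridge = 0.0

    def trial_values(self, arr: _TrialArrays, idx: np.ndarray) -> np.ndarray:
        s, c, n = arr.subj[idx], arr.cell[idx], arr.epoch[idx]
        if self.dep == FIXED:
            return self.base[s, 0]
        if self.dep == BY_CONDITION:
            return self.base[s, c]
        return self.base[s, 0] + self.slope[s, c] * n

    def group_columns(self) -> list[str]:
        cols = []
        if self.dep == BY_CONDITION:
            cols += [f"{self.name}_mu[{_cell_label(c)}]" for c in range(N_CELLS)]
        elif self.dep == FIXED:
            cols += [f"{self.name}_mu"]
        else:
            cols += [f"{self.name}_beta0_mu"]
        cols += [f"{self.name}_sigma"]
        if self.has_slope:
            cols += [f"{self.name}_beta1_mu[{_cell_label(c)}]" for c in range(N_CELLS)]
            cols += [f"{self.name}_beta1_sigma"]
        return cols

    def group_values(self) -> list[float]:
        vals = list(self.mu_base) + [self.sigma_base]
        if self.has_slope:
            vals += list(self.mu_slope) + [self.sigma_slope]
        return vals

    def subject_valid(self, base: np.ndarray, slope: np.ndarray) -> np.ndarray:
        """Validity of per-subject parameter sets (a > 0, t >= 0 at all epochs)."""
        S = base.shape[0]
        if self.name == "v":
            return np.ones(S, dtype=bool)
        lo = 0.0 if self.name == "a" else -1e-12
        if self.has_slope:
            v1 = base[:, [0]] + slope * EPOCH_MIN
            v8 = base[:, [0]] + slope * EPOCH_MAX
            return (v1.min(axis=1) > lo) & (v8.min(axis=1) > lo)
        return base.min(axis=1) > lo


def _norm_logpdf(x: np.ndarray, mu: float | np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)


@dataclass
class PosteriorSamples:
    """MCMC draws and bookkeeping for one fitted model."""

    spec: ModelSpec
    group_draws: pd.DataFrame  # columns: group parameters + 'chain'
    deviance: np.ndarray  # per retained draw (-2 log likelihood)
    subject_mean: dict[str, dict[str, np.ndarray]]  # posterior means of subject params
    subject_snapshots: list[dict[str, dict[str, np.ndarray]]]
    n_draws: int
    n_burn_in: int
    n_chains: int
    seed: int
    rhat_values: pd.Series
    converged: bool
    warnings: list[str]
    n_trials: int
    n_timeout_excluded: int
    data_hash: str
    subject_labels: np.ndarray

    def manifest(self) -> dict:
        return {
            "model_id": self.spec.model_id,
            "model_name": self.spec.name,
            "n_draws": self.n_draws,
            "n_burn_in": self.n_burn_in,
            "n_chains": self.n_chains,
            "seed": self.seed,
            "data_hash": self.data_hash,
            "n_trials": self.n_trials,
            "n_timeout_excluded": self.n_timeout_excluded,
            "max_rhat": float(self.rhat_values.max()),
            "converged": self.converged,
        }


def _full_loglik(blocks: dict[str, _Block], arr: _TrialArrays) -> np.ndarray:
    idx = np.arange(len(arr.rt))
    v = blocks["v"].trial_values(arr, idx)
    a = blocks["a"].trial_values(arr, idx)
    t = blocks["t"].trial_values(arr, idx)
    return _loglik_array(arr.rt, arr.upper, v, a, t, 0.5)


def _run_chain(
    spec: ModelSpec,
    arr: _TrialArrays,
    n_draws: int,
    n_burn: int,
    seed: int,
    thin_store: int,
) -> tuple[np.ndarray, np.ndarray, dict, list, list[str]]:
    rng = np.random.default_rng(seed)
    S = len(arr.subject_labels)
    n_trials = len(arr.rt)

    # subject-specific starting values keeping the likelihood finite
    t_init = np.empty(S)
    for s in range(S):
        lo, hi = arr.off_all[s], arr.off_all[s + 1] if s + 1 < S else n_trials
        t_init[s] = np.clip(0.5 * arr.rt[arr.idx_all[lo:hi]].min(), 0.08, 0.6)
    inits = {
        "v": (np.full(S, 1.5), 0.0),
        "a": (np.full(S, 2.0 if spec.dependence["a"] == EPOCH_COVARIATE else 1.8), -0.04),
        "t": (t_init, -0.002),
    }
    blocks = {p: _Block(p, spec.dependence[p], S, inits[p][0], inits[p][1]) for p in PARAMS}

    ll_trial = _full_loglik(blocks, arr)
    if not np.all(np.isfinite(ll_trial)):
        bad = ~np.isfinite(ll_trial)
        raise RuntimeError(f"non-finite initial likelihood on {bad.sum()} trials")

    group_cols: list[str] = []
    for p in PARAMS:
        group_cols += blocks[p].group_columns()
    n_keep = n_draws - n_burn
    draws = np.empty((n_keep, len(group_cols)))
    deviance = np.empty(n_keep)
    run_mean = {p: {"base": np.zeros_like(blocks[p].base), "slope": np.zeros_like(blocks[p].slope)} for p in PARAMS}
    snapshots: list[dict] = []
    warnings: list[str] = []

    adapt_win = 50

    def affected(block: _Block, col: int, is_slope: bool):
        if is_slope or block.dep == BY_CONDITION:
            return arr.idx_cell[col], arr.off_cell[col]
        return arr.idx_all, arr.off_all

    def mh_subject(block: _Block, col: int, is_slope: bool) -> None:
        idx, off = affected(block, col, is_slope)
        cur_field = block.slope if is_slope else block.base
        scale = block.sc_slope if is_slope else block.sc_base
        prop_val = cur_field[:, col] + scale[:, col] * rng.standard_normal(S)
        # candidate parameter state for validity check
        if is_slope:
            cand_base, cand_slope = block.base, block.slope.copy()
            cand_slope[:, col] = prop_val
        else:
            cand_base, cand_slope = block.base.copy(), block.slope
            cand_base[:, col] = prop_val
        valid = block.subject_valid(cand_base, cand_slope)

        s_i, c_i, n_i = arr.subj[idx], arr.cell[idx], arr.epoch[idx]
        vals = {p: blocks[p].trial_values(arr, idx) for p in PARAMS if p != block.name}
        if is_slope:
            mine = cand_base[s_i, 0] + cand_slope[s_i, c_i] * n_i
        elif block.dep == BY_CONDITION:
            mine = prop_val[s_i]
        elif block.dep == FIXED:
            mine = prop_val[s_i]
        else:  # covariate intercept
            mine = prop_val[s_i] + block.slope[s_i, c_i] * n_i
        trip = {block.name: mine, **vals}
        ll_prop = _loglik_array(arr.rt[idx], arr.upper[idx], trip["v"], trip["a"], trip["t"], 0.5)
        d_ll = np.add.reduceat(ll_prop - ll_trial[idx], off)
        if is_slope:
            mu, sd = block.mu_slope[col], block.sigma_slope
        else:
            mu, sd = block.mu_base[col], block.sigma_base
        d_prior = _norm_logpdf(prop_val, mu, sd) - _norm_logpdf(cur_field[:, col], mu, sd)
        log_alpha = np.where(valid, d_ll + d_prior, -np.inf)
        accept = np.log(rng.uniform(size=S)) < log_alpha
        if accept.any():
            cur_field[accept, col] = prop_val[accept]
            acc_tr = accept[s_i]
            ll_trial[idx[acc_tr]] = ll_prop[acc_tr]
        acc = block.acc_slope if is_slope else block.acc_base
        acc[:, col] += accept

    ridge_center = 0.5 * (EPOCH_MIN + EPOCH_MAX)

    def mh_translate(block: _Block, col: int, is_slope: bool) -> None:
        # hierarchical translation: shift the group mean and every subject's
        # value together (subject-to-group offsets unchanged), curing the
        # slow joint drift of pooled parameters
        idx, off = affected(block, col, is_slope)
        scale = (block.sc_mu_sl[col] if is_slope else block.sc_mu[col]) * 2.0
        delta = scale * rng.standard_normal()
        if is_slope:
            cand_base, cand_slope = block.base, block.slope.copy()
            cand_slope[:, col] += delta
            mu_cur = block.mu_slope[col]
            m0, s0, trunc = _MU_PRIORS["slope"]
        else:
            cand_base, cand_slope = block.base.copy(), block.slope
            cand_base[:, col] += delta
            mu_cur = block.mu_base[col]
            m0, s0, trunc = _MU_PRIORS[block.name]
        mu_prop = mu_cur + delta
        if trunc and mu_prop <= 0:
            return
        if not block.subject_valid(cand_base, cand_slope).all():
            return
        s_i, c_i, n_i = arr.subj[idx], arr.cell[idx], arr.epoch[idx]
        vals = {p: blocks[p].trial_values(arr, idx) for p in PARAMS if p != block.name}
        if is_slope:
            mine = cand_base[s_i, 0] + cand_slope[s_i, c_i] * n_i
        elif block.dep == BY_CONDITION:
            mine = cand_base[s_i, c_i]
        elif block.dep == FIXED:
            mine = cand_base[s_i, 0]
        else:
            mine = cand_base[s_i, 0] + block.slope[s_i, c_i] * n_i
        trip = {block.name: mine, **vals}
        ll_prop = _loglik_array(arr.rt[idx], arr.upper[idx], trip["v"], trip["a"], trip["t"], 0.5)
        d = float(
            np.sum(ll_prop - ll_trial[idx])
            + _norm_logpdf(np.float64(mu_prop), m0, s0)
            - _norm_logpdf(np.float64(mu_cur), m0, s0)
        )
        if np.log(rng.uniform()) < d:
            if is_slope:
                block.slope[:, col] = cand_slope[:, col]
                block.mu_slope[col] = mu_prop
            else:
                block.base[:, col] = cand_base[:, col]
                block.mu_base[col] = mu_prop
            ll_trial[idx] = ll_prop

    def mh_subject_ridge(block: _Block) -> None:
        # joint beta0 / beta1 proposal along the posterior correlation ridge:
        # par(N) changes by delta * (1 - N / center), leaving par(center) fixed
        delta = block.sc_ridge * rng.standard_normal(S)
        cand_base = block.base.copy()
        cand_base[:, 0] += delta
        cand_slope = block.slope - delta[:, None] / ridge_center
        valid = block.subject_valid(cand_base, cand_slope)
        idx, off = arr.idx_all, arr.off_all
        s_i, c_i, n_i = arr.subj[idx], arr.cell[idx], arr.epoch[idx]
        vals = {p: blocks[p].trial_values(arr, idx) for p in PARAMS if p != block.name}
        mine = cand_base[s_i, 0] + cand_slope[s_i, c_i] * n_i
        trip = {block.name: mine, **vals}
        ll_prop = _loglik_array(arr.rt[idx], arr.upper[idx], trip["v"], trip["a"], trip["t"], 0.5)
        d_ll = np.add.reduceat(ll_prop - ll_trial[idx], off)
        d_prior = (
            _norm_logpdf(cand_base[:, 0], block.mu_base[0], block.sigma_base)
            - _norm_logpdf(block.base[:, 0], block.mu_base[0], block.sigma_base)
            + np.sum(
                _norm_logpdf(cand_slope, block.mu_slope[None, :], block.sigma_slope)
                - _norm_logpdf(block.slope, block.mu_slope[None, :], block.sigma_slope),
                axis=1,
            )
        )
        log_alpha = np.where(valid, d_ll + d_prior, -np.inf)
        accept = np.log(rng.uniform(size=S)) < log_alpha
        if accept.any():
            block.base[accept, 0] = cand_base[accept, 0]
            block.slope[accept] = cand_slope[accept]
            acc_tr = accept[s_i]
            ll_trial[idx[acc_tr]] = ll_prop[acc_tr]
        block.acc_ridge += accept

    def mh_group_ridge(block: _Block) -> None:
        delta = block.sc_gridge * rng.standard_normal()
        mu0p = block.mu_base[0] + delta
        _, _, trunc = _MU_PRIORS[block.name]
        if trunc and mu0p <= 0:
            return
        slp = block.mu_slope - delta / ridge_center
        m0, s0, _ = _MU_PRIORS[block.name]
        msl, ssl, _ = _MU_PRIORS["slope"]
        d = float(
            np.sum(
                _norm_logpdf(block.base[:, 0], mu0p, block.sigma_base)
                - _norm_logpdf(block.base[:, 0], block.mu_base[0], block.sigma_base)
            )
            + np.sum(
                _norm_logpdf(block.slope, slp[None, :], block.sigma_slope)
                - _norm_logpdf(block.slope, block.mu_slope[None, :], block.sigma_slope)
            )
            + _norm_logpdf(np.float64(mu0p), m0, s0)
            - _norm_logpdf(np.float64(block.mu_base[0]), m0, s0)
            + np.sum(_norm_logpdf(slp, msl, ssl) - _norm_logpdf(block.mu_slope, msl, ssl))
        )
        if np.log(rng.uniform()) < d:
            block.mu_base[0] = mu0p
            block.mu_slope = slp
            block.acc_gridge += 1

    def mh_group_mu(block: _Block, col: int, is_slope: bool) -> None:
        if is_slope:
            cur, sd = block.mu_slope[col], block.sigma_slope
            vals = block.slope[:, col]
            m0, s0, trunc = _MU_PRIORS["slope"]
            scale = block.sc_mu_sl[col]
        else:
            cur, sd = block.mu_base[col], block.sigma_base
            vals = block.base[:, col]
            m0, s0, trunc = _MU_PRIORS[block.name]
            scale = block.sc_mu[col]
        prop = cur + scale * rng.standard_normal()
        if trunc and prop <= 0:
            return
        d = float(
            np.sum(_norm_logpdf(vals, prop, sd) - _norm_logpdf(vals, cur, sd))
            + _norm_logpdf(np.float64(prop), m0, s0)
            - _norm_logpdf(np.float64(cur), m0, s0)
        )
        if np.log(rng.uniform()) < d:
            if is_slope:
                block.mu_slope[col] = prop
                block.acc_mu_sl[col] += 1
            else:
                block.mu_base[col] = prop
                block.acc_mu[col] += 1

    def mh_group_sigma(block: _Block, is_slope: bool) -> None:
        cur = block.sigma_slope if is_slope else block.sigma_base
        scale = block.sc_lsig_sl if is_slope else block.sc_lsig
        prop = float(np.exp(np.log(cur) + scale * rng.standard_normal()))
        if is_slope:
            vals, mu = block.slope, block.mu_slope[None, :]
        else:
            vals, mu = block.base, block.mu_base[None, :]
        d = float(
            np.sum(_norm_logpdf(vals, mu, prop) - _norm_logpdf(vals, mu, cur))
            - 0.5 * (prop**2 - cur**2) / _SIGMA_PRIOR_SCALE**2
            + np.log(prop)
            - np.log(cur)
        )
        if np.log(rng.uniform()) < d:
            if is_slope:
                block.sigma_slope = prop
                block.acc_lsig_sl += 1
            else:
                block.sigma_base = prop
                block.acc_lsig += 1

    def adapt(counts: np.ndarray | float, scales, key=None):
        rate = counts / adapt_win
        factor = np.exp(np.clip(rate - 0.35, -0.5, 0.5))
        return scales * factor

    keep_i = 0
    for it in range(n_draws):
        for p in PARAMS:
            b = blocks[p]
            for col in range(b.nb):
                mh_subject(b, col, is_slope=False)
            for col in range(N_CELLS if b.has_slope else 0):
                mh_subject(b, col, is_slope=True)
            if b.has_slope:
                mh_subject_ridge(b)
            for col in range(b.nb):
                mh_group_mu(b, col, is_slope=False)
                mh_translate(b, col, is_slope=False)
            for col in range(N_CELLS if b.has_slope else 0):
                mh_group_mu(b, col, is_slope=True)
                mh_translate(b, col, is_slope=True)
            if b.has_slope:
                mh_group_ridge(b)
            mh_group_sigma(b, is_slope=False)
            if b.has_slope:
                mh_group_sigma(b, is_slope=True)
        if it < n_burn and (it + 1) % adapt_win == 0:
            for p in PARAMS:
                b = blocks[p]
                b.sc_base = adapt(b.acc_base, b.sc_base)
                b.acc_base[:] = 0
                b.sc_mu = adapt(b.acc_mu, b.sc_mu)
                b.acc_mu[:] = 0
                b.sc_lsig = float(adapt(b.acc_lsig, b.sc_lsig))
                b.acc_lsig = 0.0
                if b.has_slope:
                    b.sc_slope = adapt(b.acc_slope, b.sc_slope)
                    b.acc_slope[:] = 0
                    b.sc_mu_sl = adapt(b.acc_mu_sl, b.sc_mu_sl)
                    b.acc_mu_sl[:] = 0
                    b.sc_lsig_sl = float(adapt(b.acc_lsig_sl, b.sc_lsig_sl))
                    b.acc_lsig_sl = 0.0
                    b.sc_ridge = adapt(b.acc_ridge, b.sc_ridge)
                    b.acc_ridge[:] = 0
                    b.sc_gridge = float(adapt(b.acc_gridge, b.sc_gridge))
                    b.acc_gridge = 0.0
        if it >= n_burn:
            row = []
            for p in PARAMS:
                row += blocks[p].group_values()
            draws[keep_i] = row
            deviance[keep_i] = -2.0 * ll_trial.sum()
            for p in PARAMS:
                run_mean[p]["base"] += blocks[p].base
                run_mean[p]["slope"] += blocks[p].slope
            if thin_store and keep_i % thin_store == 0:
                snapshots.append(
                    {p: {"base": blocks[p].base.copy(), "slope": blocks[p].slope.copy()} for p in PARAMS}
                )
            keep_i += 1
    for p in PARAMS:
        run_mean[p]["base"] /= n_keep
        run_mean[p]["slope"] /= n_keep
    return draws, deviance, run_mean, snapshots, warnings, group_cols


def fit_hierarchical(
    spec: ModelSpec,
    data: pd.DataFrame,
    mcmc: dict | None = None,
) -> PosteriorSamples:
    """Fit one model spec to a ddm-filtered trial table.

    ``mcmc`` keys (defaults in parentheses): ``n_draws`` total MCMC
    samples per chain (15000), ``n_burn_in`` discarded (5000),
    ``n_chains`` (2), ``seed`` (0).  Timeout trials are excluded from the
    likelihood with their count recorded.  Returns group-level draws plus
    posterior means and thinned snapshots of subject-level parameters.
    A group-parameter R-hat above 1.1 flags the result (with a warning
    recorded) but never fails silently.
    """
    cfg = {"n_draws": 15000, "n_burn_in": 5000, "n_chains": 2, "seed": 0}
    if mcmc:
        cfg.update(mcmc)
    n_draws, n_burn = int(cfg["n_draws"]), int(cfg["n_burn_in"])
    n_chains, seed = int(cfg["n_chains"]), int(cfg["seed"])
    if n_burn >= n_draws:
        raise ValueError("n_burn_in must be smaller than n_draws")
    n_timeout = int(data["timeout"].astype(bool).sum()) if "timeout" in data else 0
    needs_cells = any(dep != FIXED for dep in spec.dependence.values())
    arr = _prepare(data, require_all_cells=needs_cells)
    n_keep = n_draws - n_burn
    thin_store = max(1, n_keep // 100)

    all_draws, all_dev, all_snaps = [], [], []
    mean_accum = None
    for chain in range(n_chains):
        draws, dev, run_mean, snaps, warn, cols = _run_chain(
            spec, arr, n_draws, n_burn, seed + 1000 * chain, thin_store
        )
        df = pd.DataFrame(draws, columns=cols)
        df["chain"] = chain
        all_draws.append(df)
        all_dev.append(dev)
        all_snaps.extend(snaps)
        if mean_accum is None:
            mean_accum = run_mean
        else:
            for p in PARAMS:
                mean_accum[p]["base"] += run_mean[p]["base"]
                mean_accum[p]["slope"] += run_mean[p]["slope"]
    for p in PARAMS:
        mean_accum[p]["base"] /= n_chains
        mean_accum[p]["slope"] /= n_chains

    group = pd.concat(all_draws, ignore_index=True)
    rh = rhat(group)
    warnings_list: list[str] = []
    converged = bool((rh <= RHAT_FLAG).all())
    if not converged:
        bad = rh[rh > RHAT_FLAG]
        warnings_list.append(
            f"R-hat > {RHAT_FLAG} on group parameter(s): {dict(bad.round(3))}"
        )
    return PosteriorSamples(
        spec=spec,
        group_draws=group,
        deviance=np.concatenate(all_dev),
        subject_mean=mean_accum,
        subject_snapshots=all_snaps,
        n_draws=n_draws,
        n_burn_in=n_burn,
        n_chains=n_chains,
        seed=seed,
        rhat_values=rh,
        converged=converged,
        warnings=warnings_list,
        n_trials=len(arr.rt),
        n_timeout_excluded=n_timeout,
        data_hash=arr.data_hash,
        subject_labels=arr.subject_labels,
    )


def rhat(group_draws: pd.DataFrame) -> pd.Series:
    """Rank-normalized split R-hat per group parameter.

    Expects a ``chain`` column; a single chain is split in half with a
    warning-free fallback (the split statistic is still informative).
    """
    import arviz as az

    chains = sorted(group_draws["chain"].unique()) if "chain" in group_draws else [0]
    cols = [c for c in group_draws.columns if c != "chain"]
    out = {}
    for c in cols:
        if len(chains) >= 2:
            mat = np.stack(
                [group_draws.loc[group_draws["chain"] == ch, c].to_numpy() for ch in chains]
            )
        else:
            x = group_draws[c].to_numpy()
            half = len(x) // 2
            mat = np.stack([x[:half], x[half : 2 * half]])
        out[c] = float(az.rhat(az.convert_to_dataset(mat))["x"].values.item())
    return pd.Series(out)


@dataclass(frozen=True)
class ModelComparisonResult:
    """Per-model DIC decomposition: DIC = D_bar + pD, pD = D_bar - D_hat."""

    model_id: int
    name: str
    dic: float
    d_bar: float
    p_d: float
    d_hat: float
    n_nonfinite_draws: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "name": self.name,
            "dic": self.dic,
            "d_bar": self.d_bar,
            "p_d": self.p_d,
            "d_hat": self.d_hat,
            "n_nonfinite_draws": self.n_nonfinite_draws,
        }


def compute_dic(samples: PosteriorSamples, data: pd.DataFrame) -> ModelComparisonResult:
    """Conditional DIC from the stored per-draw deviances.

    ``D_bar`` is the posterior-mean deviance; ``D_hat`` plugs in the
    posterior means of the subject-level parameters; ``pD = D_bar -
    D_hat``; ``DIC = D_bar + pD``.  Non-finite deviance draws are dropped
    with their count reported.
    """
    dev = samples.deviance
    finite = np.isfinite(dev)
    n_bad = int((~finite).sum())
    d_bar = float(dev[finite].mean())
    arr = _prepare(data)
    blocks = {}
    for p in PARAMS:
        b = _Block(p, samples.spec.dependence[p], arr.n_subjects, np.zeros(arr.n_subjects), 0.0)
        b.base = samples.subject_mean[p]["base"]
        b.slope = samples.subject_mean[p]["slope"]
        blocks[p] = b
    d_hat = float(-2.0 * _full_loglik(blocks, arr).sum())
    p_d = d_bar - d_hat
    return ModelComparisonResult(
        model_id=samples.spec.model_id,
        name=samples.spec.name,
        dic=d_bar + p_d,
        d_bar=d_bar,
        p_d=p_d,
        d_hat=d_hat,
        n_nonfinite_draws=n_bad,
    )


@dataclass(frozen=True)
class ContrastResult:
    """Posterior mass of a directional hypothesis over group parameters."""

    description: str
    p_percent: float  # P_P|D in percent

    @property
    def complement_percent(self) -> float:
        return 100.0 - self.p_percent


def posterior_probability(
    samples: PosteriorSamples,
    contrast: dict[str, float] | Callable[[pd.DataFrame], np.ndarray],
    description: str = "",
) -> ContrastResult:
    """P_P|D: fraction of posterior draws satisfying an inequality.

    ``contrast`` is either a mapping of group-parameter column names to
    weights (the hypothesis is ``sum_i w_i * theta_i > 0``) or a callable
    returning a boolean vector over the draws.
    """
    df = samples.group_draws
    if callable(contrast):
        mask = np.asarray(contrast(df), dtype=bool)
    else:
        missing = [c for c in contrast if c not in df.columns]
        if missing:
            raise KeyError(f"unknown group parameter(s): {missing}")
        acc = np.zeros(len(df))
        for col, w in contrast.items():
            acc += w * df[col].to_numpy()
        mask = acc > 0
        if not description:
            description = " + ".join(f"{w:+g}*{c}" for c, w in contrast.items()) + " > 0"
    return ContrastResult(description=description, p_percent=100.0 * float(mask.mean()))


def cell_columns(samples: PosteriorSamples, param: str, which: str = "mu") -> list[str]:
    """Group-mean column names of one parameter across the 6 cells."""
    b_dep = samples.spec.dependence[param]
    if which == "beta1":
        return [f"{param}_beta1_mu[{_cell_label(c)}]" for c in range(N_CELLS)]
    if b_dep == BY_CONDITION:
        return [f"{param}_mu[{_cell_label(c)}]" for c in range(N_CELLS)]
    raise ValueError(f"{param} has no per-cell group means under {b_dep}")


def old_new_contrast(samples: PosteriorSamples, param: str = "v") -> ContrastResult:
    """P_P|D that the parameter's group mean is higher for old than new displays."""
    cols = cell_columns(samples, param)
    weights = {}
    for c, col in enumerate(cols):
        weights[col] = 1.0 / 3.0 if CELLS[c][1] == "old" else -1.0 / 3.0
    return posterior_probability(
        samples, weights, description=f"{param}(old) > {param}(new), averaged over trial types"
    )


def posterior_predictive(
    samples: PosteriorSamples,
    data: pd.DataFrame,
    n_rep: int = 20,
    seed: int = 0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Observed vs. predicted mean RT per subject x condition cell.

    Draws ``n_rep`` stored posterior snapshots of the subject-level
    parameters, simulates a full replica dataset per snapshot with the
    shared diffusion kernel (one simulated trial per observed trial, at
    the trial's epoch), and averages the simulated mean RTs.  Returns one
    row per subject x cell with observed and predicted mean RT (ms).
    """
    arr = _prepare(data)
    rng = np.random.default_rng(seed)
    snaps = samples.subject_snapshots
    if not snaps:
        raise ValueError("samples carry no subject-level snapshots")
    pick = rng.choice(len(snaps), size=min(n_rep, len(snaps)), replace=False)

    obs = pd.DataFrame(
        {
            "subject": arr.subject_labels[arr.subj],
            "cell": arr.cell,
            "rt_ms": arr.rt * 1000.0,
        }
    ).groupby(["subject", "cell"], as_index=False)["rt_ms"].mean()

    groups: dict[tuple[int, int, float], np.ndarray] = {}
    key_arr = np.stack([arr.subj, arr.cell, arr.epoch], axis=1)
    uniq, inv, counts = np.unique(key_arr, axis=0, return_inverse=True, return_counts=True)

    pred_sum = np.zeros(len(arr.rt))
    pred_cnt = np.zeros(len(arr.rt))
    for snap_i in pick:
        snap = snaps[snap_i]
        blocks = {}
        for p in PARAMS:
            b = _Block(p, samples.spec.dependence[p], arr.n_subjects, np.zeros(arr.n_subjects), 0.0)
            b.base = snap[p]["base"]
            b.slope = snap[p]["slope"]
            blocks[p] = b
        for g, (s, c, n) in enumerate(uniq):
            idx = np.nonzero(inv == g)[0]
            one = np.array([idx[0]])
            v = float(blocks["v"].trial_values(arr, one)[0])
            a = float(blocks["a"].trial_values(arr, one)[0])
            t = float(blocks["t"].trial_values(arr, one)[0])
            if a <= 0 or t < 0:
                continue
            rts, _, to = _simulate_kernel(
                v, a, a / 2.0, t, len(idx), 6.0, dt, int(rng.integers(2**31 - 1))
            )
            ok = ~to
            if ok.any():
                pred_sum[idx] += rts[ok].mean()
                pred_cnt[idx] += 1
    pred_trial = np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)
    pred = pd.DataFrame(
        {
            "subject": arr.subject_labels[arr.subj],
            "cell": arr.cell,
            "pred_rt_ms": pred_trial * 1000.0,
        }
    ).groupby(["subject", "cell"], as_index=False)["pred_rt_ms"].mean()
    out = obs.merge(pred, on=["subject", "cell"])
    out["trial_type"] = [CELLS[c][0] for c in out["cell"]]
    out["configuration"] = [CELLS[c][1] for c in out["cell"]]
    return out.rename(columns={"rt_ms": "observed_rt_ms"})[
        ["subject", "trial_type", "configuration", "observed_rt_ms", "pred_rt_ms"]
    ]
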
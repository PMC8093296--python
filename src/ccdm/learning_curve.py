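"""Exponential (law-of-practice) learning curves for epoch-wise mean RTs.

The model is ``RT_N = RT_a + (RT_0 - RT_a) * exp(-alpha * N)`` with epoch
number ``N`` running 1..8: ``RT_0`` is the starting level, ``RT_a`` the
post-learning asymptote and ``alpha`` the learning rate.  Because every
display is novel before the experiment, ``RT_0`` is constrained to be one
shared free parameter across all condition cells; ``RT_a`` and ``alpha``
are fitted per cell.  The shared start forces the fitted contextual-cueing
curve (new minus old) through zero at epoch 0.

Fit quality is the scatter index, SI = (RMSE / mean observed value) x 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LearningCurveFit",
    "CueingCurve",
    "FitQuality",
    "fit_exponential",
    "cc_curve",
    "scatter_index",
    "amplitude_ci",
]

EPOCHS = np.arange(1, 9, dtype=float)


@dataclass(frozen=True)
class FitQuality:
    rmse: float
    si_percent: float


@dataclass
class LearningCurveFit:
    """Joint exponential fit over condition cells with a shared RT_0."""

    rt0: float
    rt_a: dict[tuple[str, str], float]
    alpha: dict[tuple[str, str], float]
    residuals: dict[tuple[str, str], np.ndarray]
    converged: bool
    objective: float
    epochs: np.ndarray

    def predict(self, cell: tuple[str, str], n: np.ndarray | float) -> np.ndarray | float:
        n = np.asarray(n, dtype=float)
        return self.rt_a[cell] + (self.rt0 - self.rt_a[cell]) * np.exp(-self.alpha[cell] * n)

    @property
    def cells(self) -> list[tuple[str, str]]:
        return list(self.rt_a)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            obs = self.predict(cell, self.epochs) + self.residuals[cell]
            q = scatter_index_from_values(self.predict(cell, self.epochs), obs)
            rows.append(
                {
                    "trial_type": cell[0],
                    "configuration": cell[1],
                    "rt0": self.rt0,
                    "rt_a": self.rt_a[cell],
                    "alpha": self.alpha[cell],
                    "rmse": q.rmse,
                    "si_percent": q.si_percent,
                }
            )
        return pd.DataFrame(rows)


def _pack(rt0: float, rt_a: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    return np.concatenate([[rt0], rt_a, alpha])


def _residual_vector(theta: np.ndarray, y: np.ndarray, epochs: np.ndarray, k: int) -> np.ndarray:
    rt0 = theta[0]
    rt_a = theta[1 : 1 + k]
    alpha = theta[1 + k :]
    pred = rt_a[:, None] + (rt0 - rt_a[:, None]) * np.exp(-alpha[:, None] * epochs[None, :])
    return (y - pred).ravel()


def fit_exponential(
    epoch_means: dict[tuple[str, str], np.ndarray] | pd.DataFrame,
    epochs: np.ndarray | None = None,
    n_starts: int = 20,
) -> LearningCurveFit:
    """Least-squares exponential fit with RT_0 shared across all cells.

    Parameters
    ----------
    epoch_means
        Either a mapping cell -> observed mean RTs over the epochs, or a
        DataFrame with columns trial_type, configuration, epoch, rt_ms.
    epochs
        Epoch grid (default 1..8); at least 3 epochs required.
    n_starts
        Multi-start count; starting learning rates are spread
        log-uniformly over [0.05, 3] (the objective is mildly multimodal
        in alpha).
    """
    if isinstance(epoch_means, pd.DataFrame):
        table = epoch_means.groupby(["trial_type", "configuration", "epoch"])["rt_ms"].mean()
        cells = sorted({(tt, cfg) for tt, cfg, _ in table.index})
        epochs_ = np.array(sorted({e for _, _, e in table.index}), dtype=float)
        data = {
            cell: np.array([table[(cell[0], cell[1], e)] for e in epochs_]) for cell in cells
        }
    else:
        data = {cell: np.asarray(y, dtype=float) for cell, y in epoch_means.items()}
        cells = list(data)
        epochs_ = EPOCHS if epochs is None else np.asarray(epochs, dtype=float)
    if len(epochs_) < 3:
        raise ValueError("need at least 3 epochs")
    if any(len(y) != len(epochs_) for y in data.values()):
        raise ValueError("every cell must provide one mean per epoch")

    y = np.vstack([data[c] for c in cells])
    k = len(cells)
    lo_a, hi_a = y.min() - 200.0, y.max() + 200.0
    lower = _pack(0.0, np.full(k, lo_a), np.full(k, 0.05))
    upper = _pack(max(hi_a * 2, 1.0), np.full(k, hi_a), np.full(k, 3.0))

    best = None
    rng = np.random.default_rng(0)
    alpha_starts = np.geomspace(0.05, 3.0, n_starts)
    for i, a0 in enumerate(alpha_starts):
        rt0_0 = float(y[:, 0].mean())
        rta_0 = y[:, -1].astype(float)
        if i >= n_starts // 2:  # jittered restarts explore the amplitude axis
            rta_0 = rta_0 + rng.normal(0, 20, size=k)
        x0 = np.clip(_pack(rt0_0, rta_0, np.full(k, a0)), lower + 1e-9, upper - 1e-9)
        sol = least_squares(
            _residual_vector,
            x0,
            args=(y, epochs_, k),
            bounds=(lower, upper),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError(f"learning-curve fit failed to converge: {best}")

    rt0 = float(best.x[0])
    rt_a = {c: float(best.x[1 + i]) for i, c in enumerate(cells)}
    alpha = {c: float(best.x[1 + k + i]) for i, c in enumerate(cells)}
    fit = LearningCurveFit(
        rt0=rt0,
        rt_a=rt_a,
        alpha=alpha,
        residuals={},
        converged=bool(best.success),
        objective=float(best.cost),
        epochs=epochs_,
    )
    fit.residuals = {c: data[c] - np.asarray(fit.predict(c, epochs_)) for c in cells}
    return fit


@dataclass(frozen=True)
class CueingCurve:
    """Fitted contextual-cueing curve for one trial type.

    ``curve(N) = RT_new(N) - RT_old(N)``; the shared RT_0 forces
    ``curve(0) = 0``.  The amplitude is the asymptotic effect
    ``RT_a(new) - RT_a(old)``.
    """

    trial_type: str
    grid: np.ndarray
    values: np.ndarray
    amplitude: float
    rt0: float
    rt_a_old: float
    rt_a_new: float
    alpha_old: float
    alpha_new: float

    def __call__(self, n: np.ndarray | float) -> np.ndarray | float:
        n = np.asarray(n, dtype=float)
        new = self.rt_a_new + (self.rt0 - self.rt_a_new) * np.exp(-self.alpha_new * n)
        old = self.rt_a_old + (self.rt0 - self.rt_a_old) * np.exp(-self.alpha_old * n)
        return new - old


def cc_curve(fit: LearningCurveFit, trial_type: str, step: float = 0.1) -> CueingCurve:
    """Contextual-cueing curve (new minus old) on the epoch grid 0..8."""
    old_cell, new_cell = (trial_type, "old"), (trial_type, "new")
    for cell in (old_cell, new_cell):
        if cell not in fit.rt_a:
            raise KeyError(f"fit is missing cell {cell}")
    grid = np.arange(0.0, fit.epochs.max() + step / 2, step)
    values = np.asarray(fit.predict(new_cell, grid)) - np.asarray(fit.predict(old_cell, grid))
    amplitude = fit.rt_a[new_cell] - fit.rt_a[old_cell]
    return CueingCurve(
        trial_type=trial_type,
        grid=grid,
        values=values,
        amplitude=amplitude,
        rt0=fit.rt0,
        rt_a_old=fit.rt_a[old_cell],
        rt_a_new=fit.rt_a[new_cell],
        alpha_old=fit.alpha[old_cell],
        alpha_new=fit.alpha[new_cell],
    )


def scatter_index_from_values(predicted: np.ndarray, observed: np.ndarray) -> FitQuality:
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must align")
    mean_obs = observed.mean()
    if mean_obs == 0:
        raise ZeroDivisionError("mean observed value is zero; SI undefined")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    return FitQuality(rmse=rmse, si_percent=100.0 * rmse / abs(mean_obs))


def scatter_index(
    fit: LearningCurveFit, observed: dict[tuple[str, str], np.ndarray] | np.ndarray, cell: tuple[str, str] | None = None
) -> FitQuality:
    """Scatter index SI = (RMSE / mean observed) * 100% for one cell."""
    if cell is None:
        raise ValueError("cell must name the condition to score")
    obs = observed[cell] if isinstance(observed, dict) else observed
    return scatter_index_from_values(np.asarray(fit.predict(cell, fit.epochs)), obs)


def cueing_scatter_index(fit: LearningCurveFit, observed_cc: np.ndarray, trial_type: str) -> FitQuality:
    """SI of the fitted cueing curve against observed per-epoch effects."""
    curve = cc_curve(fit, trial_type)
    pred = np.interp(fit.epochs, curve.grid, curve.values)
    return scatter_index_from_values(pred, observed_cc)


def trial_type_scatter_index(
    fit: LearningCurveFit, observed: dict[tuple[str, str], np.ndarray], trial_type: str
) -> FitQuality:
    """SI of one trial type's RT fits over its old and new cells jointly.

    RMSE pools the old- and new-configuration epoch means (16 points),
    normalised by their grand mean -- the few-percent scale on which the
    exponential fits are judged.
    """
    cells = [(trial_type, "old"), (trial_type, "new")]
    pred = np.concatenate([np.asarray(fit.predict(c, fit.epochs)) for c in cells])
    obs = np.concatenate([np.asarray(observed[c], dtype=float) for c in cells])
    return scatter_index_from_values(pred, obs)


def amplitude_ci(
    epoch_table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    n_starts: int = 6,
) -> pd.DataFrame:
    """Subject-level percentile bootstrap CI for the cueing amplitudes.

    Resamples subjects with replacement from the per-subject epoch table,
    recomputes group epoch means, refits the joint exponential model, and
    collects the cueing amplitude for every trial type.  Deterministic for
    a fixed seed.
    """
    import warnings

    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    subjects = np.array(sorted(epoch_table["subject"].unique()))
    trial_types = sorted(epoch_table["trial_type"].unique())

    def group_fit(tbl: pd.DataFrame) -> LearningCurveFit:
        means = tbl.groupby(["trial_type", "configuration", "epoch"], as_index=False)["rt_ms"].mean()
        return fit_exponential(means, n_starts=n_starts)

    point = group_fit(epoch_table)
    point_amp = {tt: cc_curve(point, tt).amplitude for tt in trial_types}

    draws: dict[str, list[float]] = {tt: [] for tt in trial_types}
    by_subject = {s: g for s, g in epoch_table.groupby("subject")}
    for _ in range(n_boot):
        sample = rng.choice(subjects, size=len(subjects), replace=True)
        tbl = pd.concat(
            [by_subject[s].assign(subject=i) for i, s in enumerate(sample)], ignore_index=True
        )
        fit = group_fit(tbl)
        for tt in trial_types:
            draws[tt].append(cc_curve(fit, tt).amplitude)
    alpha = (1.0 - level) / 2.0
    rows = []
    for tt in trial_types:
        arr = np.array(draws[tt])
        rows.append(
            {
                "trial_type": tt,
                "amplitude_ms": point_amp[tt],
                "ci_low": float(np.quantile(arr, alpha)),
                "ci_high": float(np.quantile(arr, 1.0 - alpha)),
                "n_boot": n_boot,
            }
        )
    return pd.DataFrame(rows)
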
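"""Stage-two survival models mapping encodings Z to survival curves.

Three heads, all consuming a fixed-length per-subject feature table:

* :class:`CoxPH` — proportional hazards with Breslow tie handling and a
  Breslow baseline survival estimate, S(t|Z) = S0(t)^exp(Z.beta);
* :class:`SurvivalForest` — random survival forest with log-rank splitting
  and Kaplan–Meier leaf curves (1,000 trees, min split 32, min leaf 16);
* :class:`DiscreteTimeNN` — a two-layer feed-forward network with a softmax
  over time intervals, trained with the discrete-time negative
  log-likelihood; censored subjects contribute the conditional survival
  probability given they were at risk at their training landmark.

Every head emits :class:`SurvivalCurves`: right-continuous step functions,
non-increasing in t and equal to 1 before the first mass point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, Linear, Tensor, log_softmax, relu

__all__ = [
    "SurvivalCurves",
    "CoxPH",
    "SurvivalForest",
    "DiscreteTimeNN",
    "failure_from_probs",
    "FitError",
]


class FitError(RuntimeError):
    """A survival head failed to fit (e.g. Cox non-convergence/separation)."""


@dataclass(frozen=True)
class SurvivalCurves:
    """Predicted survival S(t|Z_i) per subject on a sorted time grid."""

    subject_ids: np.ndarray
    time_grid: np.ndarray
    values: np.ndarray  # (n_subjects, n_times)

    def __post_init__(self):
        v = self.values
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(v, axis=1) > 1e-9):
            raise ValueError("survival curves must be non-increasing")

    def at(self, t: float) -> np.ndarray:
        """S(t) per subject via right-continuous step lookup (1 before grid)."""
        j = int(np.searchsorted(self.time_grid, t, side="right")) - 1
        if j < 0:
            return np.ones(len(self.subject_ids))
        return self.values[:, j].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.time_grid)


def _as_matrix(Z: pd.DataFrame) -> np.ndarray:
    X = Z.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("encodings contain non-finite values")
    return X


def _surv_y(times, events):
    from sksurv.util import Surv

    return Surv.from_arrays(event=np.asarray(events).astype(bool), time=np.asarray(times, float))


def _step_lookup(xs: np.ndarray, ys: np.ndarray, grid: np.ndarray, before: float) -> np.ndarray:
    """Evaluate the right-continuous step function (xs, ys) on ``grid``."""
    idx = np.searchsorted(xs, grid, side="right") - 1
    out = np.where(idx >= 0, ys[np.clip(idx, 0, len(ys) - 1)], before)
    return out


class CoxPH:
    """Cox proportional hazards with Breslow baseline survival.

    Constant feature columns are dropped with a warning (they are not
    identifiable); with no usable features the baseline survival reduces to
    exp(-Nelson-Aalen) of the training data.  ``ridge`` adds an optional L2
    penalty (default 0, i.e. the unregularized partial likelihood).
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge
        self.coef_: pd.Series | None = None
        self.baseline_x_: np.ndarray | None = None  # step times of H0
        self.baseline_h_: np.ndarray | None = None  # cumulative baseline hazard

    def fit(self, Z: pd.DataFrame, times, events) -> "CoxPH":
        times = np.asarray(times, float)
        events = np.asarray(events).astype(int)
        if events.sum() == 0:
            raise FitError("no events in the training data")
        keep = [c for c in Z.columns if Z[c].nunique() > 1]
        dropped = [c for c in Z.columns if c not in keep]
        if dropped:
            warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
        self.feature_names_ = keep
        if keep:
            from sksurv.linear_model import CoxPHSurvivalAnalysis

            model = CoxPHSurvivalAnalysis(alpha=self.ridge, ties="breslow", n_iter=200)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", category=UserWarning)
                    model.fit(_as_matrix(Z[keep]), _surv_y(times, events))
            except Exception as err:  # singularity, separation, non-convergence
                raise FitError(f"Cox fit failed: {err}") from err
            self.coef_ = pd.Series(model.coef_, index=keep)
            bh = model.cum_baseline_hazard_
            self.baseline_x_, self.baseline_h_ = np.asarray(bh.x), np.asarray(bh.y)
        else:
            from sksurv.nonparametric import nelson_aalen_estimator

            self.coef_ = pd.Series(dtype=float)
            x, y = nelson_aalen_estimator(events.astype(bool), times)
            self.baseline_x_, self.baseline_h_ = np.asarray(x), np.asarray(y)
        return self

    def baseline_survival(self, grid) -> np.ndarray:
        """Breslow baseline survival S0 = exp(-H0) on ``grid``."""
        h = _step_lookup(self.baseline_x_, self.baseline_h_, np.asarray(grid, float), 0.0)
        return np.exp(-h)

    def linear_predictor(self, Z: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names_ if c not in Z.columns]
        if missing:
            raise ValueError(f"encoding lacks training features: {missing}")
        if not self.feature_names_:
            return np.zeros(len(Z))
        return _as_matrix(Z[self.feature_names_]) @ self.coef_.to_numpy()

    def predict_curves(self, Z: pd.DataFrame, grid) -> SurvivalCurves:
        grid = np.asarray(grid, float)
        s0 = self.baseline_survival(grid)
        lp = self.linear_predictor(Z)
        vals = np.clip(s0[None, :] ** np.exp(lp)[:, None], 0.0, 1.0)
        return SurvivalCurves(np.asarray(Z.index), grid, vals)


class SurvivalForest:
    """Random survival forest (log-rank splits, Kaplan-Meier leaves)."""

    def __init__(
        self,
        n_trees: int = 1000,
        min_samples_split: int = 32,
        min_samples_leaf: int = 16,
        max_features="sqrt",
        seed: int = 0,
        n_jobs: int = 1,
    ):
        from sksurv.ensemble import RandomSurvivalForest

        self._model = RandomSurvivalForest(
            n_estimators=n_trees,
            min_samples_split=min_samples_split,
            min_samples_leaf=min_samples_leaf,
            max_features=max_features,
            random_state=seed,
            n_jobs=n_jobs,
        )

    def fit(self, Z: pd.DataFrame, times, events) -> "SurvivalForest":
        self.feature_names_ = list(Z.columns)
        self._model.fit(_as_matrix(Z), _surv_y(times, events))
        return self

    def predict_curves(self, Z: pd.DataFrame, grid) -> SurvivalCurves:
        missing = [c for c in self.feature_names_ if c not in Z.columns]
        if missing:
            raise ValueError(f"encoding lacks training features: {missing}")
        grid = np.asarray(grid, float)
        arr = self._model.predict_survival_function(_as_matrix(Z[self.feature_names_]), return_array=True)
        xs = np.asarray(self._model.unique_times_)
        idx = np.searchsorted(xs, grid, side="right") - 1
        vals = np.where(idx[None, :] >= 0, arr[:, np.clip(idx, 0, len(xs) - 1)], 1.0)
        vals = np.minimum.accumulate(np.clip(vals, 0, 1), axis=1)
        return SurvivalCurves(np.asarray(Z.index), grid, vals)


def failure_from_probs(p: np.ndarray, landmark_interval: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Conditional failure/survival on interval boundaries from interval masses.

    Given P(T = interval m) for m = 0..B-1 and the landmark interval index k
    (the subject is known at risk at the start of interval k), returns
    (F, S) evaluated at the B+1 interval boundaries:
    F(tau_j) = sum_{k <= m < j} p_m / P(T >= interval k).
    """
    p = np.asarray(p, float)
    k = int(landmark_interval)
    denom = p[k:].sum()
    if denom <= 0:
        raise ZeroDivisionError("P(T > landmark) is zero; conditioning undefined")
    F = np.zeros(len(p) + 1)
    F[k + 1 :] = np.cumsum(p[k:]) / denom
    S = 1.0 - F
    return F, S


def _dropout(t: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0:
        return t
    mask = (rng.uniform(size=t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


class SoftmaxHead:
    """2 fully connected layers (32 hidden, ReLU + dropout) with softmax output.

    Shared between the standalone discrete-time head and the jointly trained
    recurrent encoder: exposes the raw log-probabilities and the discrete
    negative log-likelihood so gradients can flow into upstream encoders.
    """

    def __init__(self, n_in: int, n_intervals: int, rng: np.random.Generator,
                 n_hidden: int = 32, dropout: float = 0.3):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_intervals, rng)
        self.dropout = dropout
        self.n_intervals = n_intervals

    @property
    def parameters(self):
        return self.fc1.parameters + self.fc2.parameters

    def log_probs(self, z: Tensor, rng: np.random.Generator, train: bool) -> Tensor:
        h = _dropout(relu(self.fc1(z)), self.dropout, rng, train)
        return log_softmax(self.fc2(h))

    def nll(self, z: Tensor, event_idx: np.ndarray, event: np.ndarray,
            risk_idx: np.ndarray, rng: np.random.Generator, train: bool = True) -> Tensor:
        """Mean discrete-time NLL over the batch.

        Events contribute -log P(T = interval of T_i); censored subjects
        contribute -log [P(T > interval of T_i) / P(T >= landmark interval)].
        """
        ls = self.log_probs(z, rng, train)
        p = ls.exp()
        n, B = ls.shape
        ev = event.astype(bool)
        terms = []
        if ev.any():
            rows = np.flatnonzero(ev)
            terms.append(-ls.take(rows, event_idx[rows]).sum())
        if (~ev).any():
            rows = np.flatnonzero(~ev)
            beyond = np.arange(B)[None, :] > event_idx[rows][:, None]
            at_risk = np.arange(B)[None, :] >= risk_idx[rows][:, None]
            eps = 1e-12
            p_rows = Tensor(np.eye(n)[rows]) @ p  # select censored rows
            s_num = (p_rows * Tensor(beyond.astype(float))).sum(axis=1)
            s_den = (p_rows * Tensor(at_risk.astype(float))).sum(axis=1)
            terms.append(-((s_num + eps).log() - (s_den + eps).log()).sum())
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * (1.0 / n)


class DiscreteTimeNN:
    """Discrete-time neural survival model on half-unit interval bins.

    Interval boundaries are multiples of ``interval_width`` covering the
    observed time range, plus one overflow interval for mass beyond the last
    boundary.  Trained with Adam (lr 1e-3, weight decay 1e-5) in batches of
    32 for ``epochs`` epochs; deterministic under ``seed``.
    """

    def __init__(self, interval_width: float = 0.5, n_hidden: int = 32, dropout: float = 0.3,
                 lr: float = 1e-3, weight_decay: float = 1e-5, epochs: int = 100,
                 batch_size: int = 32, seed: int = 0):
        self.interval_width = interval_width
        self.n_hidden = n_hidden
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.boundaries_: np.ndarray | None = None

    # -- interval helpers -------------------------------------------------
    def _make_boundaries(self, times: np.ndarray) -> np.ndarray:
        w = self.interval_width
        top = np.ceil((times.max() + 1e-12) / w) * w
        return np.round(np.arange(0.0, top + w / 2, w), 10)

    def interval_of(self, t) -> np.ndarray:
        """Index of the interval [b_m, b_{m+1}) containing t (overflow = B-1)."""
        b = self.boundaries_
        idx = np.searchsorted(b, np.atleast_1d(np.asarray(t, float)), side="right") - 1
        return np.clip(idx, 0, len(b) - 1)  # last index = overflow interval

    def fit(self, Z: pd.DataFrame, times, events, landmarks=None,
            epoch_sampler=None) -> "DiscreteTimeNN":
        """Fit the head on encodings Z with observed (times, events).

        ``landmarks`` (per-sample landmark times) condition the censored
        likelihood terms; ``epoch_sampler``, if given, is called once per
        epoch as ``f(epoch, rng) -> (Z, landmarks)`` to support per-epoch
        random truncation of the training histories.
        """
        times = np.asarray(times, float)
        events = np.asarray(events).astype(int)
        self.feature_names_ = list(Z.columns)
        self.boundaries_ = self._make_boundaries(times)
        n_int = len(self.boundaries_)  # B-1 finite bins + overflow
        rng = np.random.default_rng(self.seed)
        self.head_ = SoftmaxHead(Z.shape[1], n_int, rng, self.n_hidden, self.dropout)
        opt = Adam(self.head_.parameters, lr=self.lr, weight_decay=self.weight_decay)
        ev_idx_all = self.interval_of(times)

        def prepare(Zc, lms):
            X = _as_matrix(Zc)
            if lms is None:
                rk = np.zeros(len(times), dtype=int)
            else:
                rk = self.interval_of(np.asarray(lms, float))
            bad = ev_idx_all < rk
            if bad.any():
                warnings.warn(
                    f"skipping {bad.sum()} samples with event before landmark interval",
                    stacklevel=2,
                )
            ok = ~bad
            return X[ok], ev_idx_all[ok], events[ok], rk[ok]

        if epoch_sampler is None:
            fixed = prepare(Z, landmarks)
        for epoch in range(self.epochs):
            if epoch_sampler is not None:
                Zc, lms = epoch_sampler(epoch, rng)
                X, ev_idx, ev, rk_idx = prepare(Zc[self.feature_names_], lms)
            else:
                X, ev_idx, ev, rk_idx = fixed
            order = rng.permutation(len(X))
            for start in range(0, len(X), self.batch_size):
                sel = order[start : start + self.batch_size]
                loss = self.head_.nll(Tensor(X[sel]), ev_idx[sel], ev[sel], rk_idx[sel], rng)
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict_interval_probs(self, Z: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names_ if c not in Z.columns]
        if missing:
            raise ValueError(f"encoding lacks training features: {missing}")
        rng = np.random.default_rng(0)
        ls = self.head_.log_probs(Tensor(_as_matrix(Z[self.feature_names_])), rng, train=False)
        return np.exp(ls.value)

    def predict_curves(self, Z: pd.DataFrame, grid, landmark: float = 0.0) -> SurvivalCurves:
        grid = np.asarray(grid, float)
        b = self.boundaries_
        if grid.max() > b[-1]:
            warnings.warn("evaluation grid extends beyond the last interval boundary; "
                          "curves extended flat", stacklevel=2)
        probs = self.predict_interval_probs(Z)
        k = int(self.interval_of(landmark)[0])
        vals = np.empty((len(probs), len(grid)))
        for i, p in enumerate(probs):
            _, S = failure_from_probs(p, k)
            vals[i] = _step_lookup(b, S, grid, 1.0)
        vals = np.minimum.accumulate(np.clip(vals, 0, 1), axis=1)
        return SurvivalCurves(np.asarray(Z.index), grid, vals)
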
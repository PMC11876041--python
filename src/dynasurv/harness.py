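"""Experiment orchestration: two-stage pipelines under landmarking strategies.

A pipeline couples a longitudinal encoder (baseline, last_visit, mfpca,
rnn_long, rnn) with a survival head (cph, rsf, fnn) and a training strategy:

* ``none``   — one fit on the full histories (evaluation still landmarks the
  test data, reproducing the optimism/bias this strategy suffers from);
* ``strict`` — one fit per landmark on the landmarked training data;
* ``super``  — one fit on the stacked landmarked copies;
* ``random`` — one fit with per-epoch random truncation of each subject's
  visit history (iteratively trained, i.e. RNN-based, encoders only).

`run_simulation_study` reproduces the simulation protocol (replicated
training sets, one shared evaluation set, mean +/- SD aggregation) and
`run_crossval_study` the real-data protocol (subject-level k-fold CV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import encoders as enc
from .data import (
    LandmarkedView,
    LongitudinalDataset,
    as_view,
    kfold_split,
    landmark,
    random_truncate,
    super_landmark,
)
from .metrics import brier_ipcw, censoring_km, conditional_risk, mse_vs_truth, tdauc_ipcw, true_risks
from .simulate import ScenarioConfig, SimulationTruth, simulate_scenario
from .survival import CoxPH, DiscreteTimeNN, FitError, SurvivalForest

__all__ = [
    "ExperimentConfig",
    "ResultsBundle",
    "run_two_stage",
    "run_simulation_study",
    "run_crossval_study",
    "random_hyperparameter_search",
    "aggregate_metrics",
]

ENCODERS = ("baseline", "last_visit", "mfpca", "rnn_long", "rnn")
HEADS = ("cph", "rsf", "fnn")
STRATEGIES = ("none", "strict", "super", "random")


@dataclass
class ExperimentConfig:
    """One pipeline cell: encoder x head x landmarking strategy."""

    encoder: str = "baseline"
    head: str = "cph"
    strategy: str = "strict"
    landmarks: tuple = (1.0, 2.0, 3.0, 4.0)
    horizon_offsets: tuple = tuple(np.round(np.arange(0.5, 5.01, 0.5), 10))
    seed: int = 0
    rnn_hparams: enc.RNNHyperparams = field(default_factory=enc.RNNHyperparams)
    head_params: dict = field(default_factory=dict)
    mfpca_params: dict = field(default_factory=dict)
    ridge: float = 0.0

    def __post_init__(self):
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.head not in HEADS:
            raise ValueError(f"unknown head {self.head!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "random" and self.encoder not in ("rnn", "rnn_long"):
            raise ValueError("strategy 'random' requires an iteratively trained "
                             "(RNN-based) encoder")
        if self.encoder == "rnn" and self.head != "fnn":
            raise ValueError("the jointly trained encoder 'rnn' pairs with head 'fnn'")

    @property
    def label(self) -> str:
        return f"{self.encoder}-{self.head}"


@dataclass
class ResultsBundle:
    """Tidy metric rows plus provenance (config, seeds, failures, logs)."""

    metrics: pd.DataFrame
    config: object
    seeds: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    models: dict = field(default_factory=dict)
    logs: list = field(default_factory=list)


def _fit_encoder(cfg: ExperimentConfig, view: LandmarkedView, train_ds: LongitudinalDataset):
    """Returns (state, encode_fn(view)->Z)."""
    name = cfg.encoder
    if name in ("baseline", "last_visit"):
        means = view.data.visits[view.data.long_cols].mean()
        fn = enc.encode_baseline if name == "baseline" else enc.encode_last_visit
        return means, lambda v: fn(v, means)
    if name == "mfpca":
        model = enc.fit_mfpca(view, **cfg.mfpca_params)
        return model, lambda v: enc.mfpca_encode(model, v)
    mode = "combined" if name == "rnn" else "long_only"
    if cfg.strategy == "random":
        model = enc.fit_rnn(train_ds, mode, cfg.rnn_hparams, cfg.seed, strategy="random")
    else:
        model = enc.fit_rnn(view, mode, cfg.rnn_hparams, cfg.seed)
    return model, lambda v: enc.rnn_encode(model, v)


def _fit_head(cfg: ExperimentConfig, Z: pd.DataFrame, view: LandmarkedView,
              epoch_sampler=None):
    out = view.data.outcomes
    times, events = out["time"].to_numpy(float), out["event"].to_numpy(int)
    if cfg.head == "cph":
        return CoxPH(ridge=cfg.ridge).fit(Z, times, events)
    if cfg.head == "rsf":
        params = dict(n_trees=1000, min_samples_split=32, min_samples_leaf=16,
                      seed=cfg.seed)
        params.update(cfg.head_params)
        return SurvivalForest(**params).fit(Z, times, events)
    params = dict(seed=cfg.seed)
    params.update(cfg.head_params)
    lm = None if view.strategy == "none" else view.landmarks.loc[Z.index].to_numpy(float)
    return DiscreteTimeNN(**params).fit(Z, times, events, landmarks=lm,
                                        epoch_sampler=epoch_sampler)


class _FittedCell:
    """Fitted pipeline(s) for one config: per-landmark under strict, else one."""

    def __init__(self, cfg: ExperimentConfig, train: LongitudinalDataset):
        self.cfg = cfg
        self.parts = {}
        rng = np.random.default_rng(cfg.seed)
        if cfg.strategy == "strict":
            fit_views = {l: landmark(train, l) for l in cfg.landmarks}
        elif cfg.strategy == "super":
            fit_views = {None: super_landmark(train, list(cfg.landmarks))}
        elif cfg.strategy == "random":
            fit_views = {None: random_truncate(train, rng)}
        else:
            fit_views = {None: as_view(train)}
        for key, view in fit_views.items():
            if view.data.n_subjects == 0:
                self.parts[key] = None
                continue
            state, encode = _fit_encoder(cfg, view, train)
            if cfg.encoder == "rnn":  # jointly trained survival head
                self.parts[key] = (state, encode, state)
                continue
            sampler = None
            if cfg.strategy == "random" and cfg.encoder == "rnn_long":
                # heads see encodings of random truncations: iteratively
                # trained heads redraw per epoch, others use one fixed draw
                view = random_truncate(train, rng)
                if cfg.head == "fnn":
                    def sampler(epoch, _rng, _enc=encode, _tr=train):
                        v = random_truncate(_tr, rng)
                        return _enc(v), v.landmarks.loc[v.data.baseline.index].to_numpy(float)
            Z = encode(view)
            head = _fit_head(cfg, Z, view, epoch_sampler=sampler)
            self.parts[key] = (state, encode, head)

    def _part(self, l):
        key = l if self.cfg.strategy == "strict" else None
        part = self.parts.get(key)
        if part is None:
            raise FitError(f"no fitted pipeline at landmark {l}")
        return part

    def predict_risks(self, test_view: LandmarkedView, l: float, horizons) -> pd.DataFrame:
        """Conditional risks R(t|l) for all horizons; rows = test subjects."""
        state, encode, head = self._part(l)
        Z = encode(test_view)
        grid = np.unique(np.concatenate([[l], np.asarray(horizons, float)]))
        if self.cfg.encoder == "rnn":
            curves = enc.rnn_predict_curves(state, test_view, grid, landmark=l)
        elif isinstance(head, DiscreteTimeNN):
            curves = head.predict_curves(Z, grid, landmark=l)
        else:
            curves = head.predict_curves(Z, grid)
        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in horizons:
                out[t] = conditional_risk(curves, l, t)
        return pd.DataFrame(out, index=Z.index)


def run_two_stage(config: ExperimentConfig, train: LongitudinalDataset,
                  test: LongitudinalDataset, truth: SimulationTruth | None = None,
                  replicate=0) -> ResultsBundle:
    """Fit one pipeline on ``train`` and evaluate it on landmarked ``test``.

    For every configured landmark l the test set is landmarked, encoded and
    scored at each horizon with IPCW tdAUC, IPCW Brier (censoring KM from the
    training data only) and, when simulation truth is supplied, the MSE
    against the true conditional risks.
    """
    overlap = set(train.subject_ids) & set(test.subject_ids)
    if overlap:
        raise ValueError("train and test sets share subjects")
    cell = _FittedCell(config, train)
    G = censoring_km(train.outcomes["time"], train.outcomes["event"])
    rows, failures = [], []
    for l in config.landmarks:
        horizons = [l + o for o in config.horizon_offsets]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test_view = landmark(test, l)
        if test_view.data.n_subjects == 0:
            failures.append((config.label, config.strategy, l, "no test subjects at risk"))
            continue
        try:
            risks = cell.predict_risks(test_view, l, horizons)
        except (FitError, ValueError) as err:
            failures.append((config.label, config.strategy, l, str(err)))
            continue
        out = test_view.data.outcomes
        T, d = out["time"].to_numpy(float), out["event"].to_numpy(int)
        for t in horizons:
            r = risks[t].to_numpy(float)
            base = dict(model=config.label, encoder=config.encoder, head=config.head,
                        strategy=config.strategy, landmark=l, horizon=t,
                        replicate=replicate)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append({**base, "metric": "tdAUC",
                             "value": tdauc_ipcw(r, T, d, G, t)})
                rows.append({**base, "metric": "Brier",
                             "value": brier_ipcw(r, T, d, G, t)})
                if truth is not None:
                    rt = true_risks(truth, out.index, l, t)
                    rows.append({**base, "metric": "MSE",
                                 "value": mse_vs_truth(r, rt)})
    return ResultsBundle(pd.DataFrame(rows), config, seeds={"seed": config.seed},
                         failures=failures)


def aggregate_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD over replicates/folds per (model, strategy, landmark, horizon, metric)."""
    keys = ["model", "encoder", "head", "strategy", "landmark", "horizon", "metric"]
    g = df.groupby(keys)["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out


def run_simulation_study(scenarios=(1,), configs=None, n_train: int = 1000,
                         replicates: int = 10, n_eval: int = 3000, seed: int = 0,
                         landmarks=(1.0, 2.0, 3.0, 4.0),
                         horizon_offsets=tuple(np.round(np.arange(0.5, 5.01, 0.5), 10)),
                         shared_eval: bool = True) -> ResultsBundle:
    """Replicated simulation study over a grid of pipeline configs.

    Per scenario one shared evaluation set of ``n_eval`` subjects is drawn;
    each replicate gets a fresh training set of ``n_train`` subjects.  Failed
    cells are recorded and the study continues.
    """
    if configs is None:
        configs = [ExperimentConfig(encoder="baseline", head="cph", strategy="strict")]
    all_rows, failures, seeds = [], [], {}
    ss = np.random.SeedSequence(seed)
    for sc in scenarios:
        sc_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        eval_ds, eval_truth = simulate_scenario(
            ScenarioConfig(scenario=sc, n_subjects=n_eval, seed=sc_seed)
        )
        seeds[f"scenario{sc}_eval"] = sc_seed
        for rep in range(replicates):
            if shared_eval:
                ev_ds, ev_truth = eval_ds, eval_truth
            else:
                s = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                ev_ds, ev_truth = simulate_scenario(
                    ScenarioConfig(scenario=sc, n_subjects=n_eval, seed=s))
            tr_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            seeds[f"scenario{sc}_rep{rep}"] = tr_seed
            # distinct seeds guarantee disjoint synthetic populations; ids are
            # re-labelled so train/test never collide
            train, _ = simulate_scenario(
                ScenarioConfig(scenario=sc, n_subjects=n_train, seed=tr_seed))
            train = _relabel(train, prefix=f"tr{rep}_")
            for cfg in configs:
                cfg_r = replace(cfg, landmarks=tuple(landmarks),
                                horizon_offsets=tuple(horizon_offsets),
                                seed=cfg.seed + rep)
                try:
                    bundle = run_two_stage(cfg_r, train, ev_ds, truth=ev_truth,
                                           replicate=rep)
                except (FitError, ValueError) as err:
                    failures.append((sc, rep, cfg.label, cfg.strategy, str(err)))
                    continue
                df = bundle.metrics
                if len(df):
                    df = df.assign(scenario=sc)
                    all_rows.append(df)
                failures.extend((sc, rep) + f for f in bundle.failures)
    metrics = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    return ResultsBundle(metrics, dict(scenarios=scenarios, n_train=n_train,
                                       replicates=replicates, n_eval=n_eval),
                         seeds=seeds, failures=failures)


def _relabel(ds: LongitudinalDataset, prefix: str) -> LongitudinalDataset:
    mapping = {s: f"{prefix}{s}" for s in ds.subject_ids}
    baseline = ds.baseline.rename(index=mapping)
    outcomes = ds.outcomes.rename(index=mapping)
    visits = ds.visits.copy()
    visits["subject_id"] = visits["subject_id"].map(mapping)
    return LongitudinalDataset(baseline, visits, outcomes)


def run_crossval_study(ds: LongitudinalDataset, configs, k: int = 10, seed: int = 0,
                       landmarks=(1.0, 2.0, 3.0, 4.0),
                       horizon_offsets=tuple(np.round(np.arange(0.5, 5.01, 0.5), 10))
                       ) -> ResultsBundle:
    """Subject-level k-fold cross-validation on a real (or synthetic) cohort."""
    all_rows, failures = [], []
    for fold, (train, test) in enumerate(kfold_split(ds, k, seed)):
        for cfg in configs:
            cfg_r = replace(cfg, landmarks=tuple(landmarks),
                            horizon_offsets=tuple(horizon_offsets), seed=cfg.seed + fold)
            try:
                bundle = run_two_stage(cfg_r, train, test, replicate=fold)
            except (FitError, ValueError) as err:
                failures.append((fold, cfg.label, cfg.strategy, str(err)))
                continue
            if len(bundle.metrics):
                all_rows.append(bundle.metrics)
            failures.extend((fold,) + f for f in bundle.failures)
    metrics = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    return ResultsBundle(metrics, dict(k=k), seeds={"seed": seed}, failures=failures)


def random_hyperparameter_search(space: dict, base_config: ExperimentConfig,
                                 train: LongitudinalDataset, n_draws: int = 100,
                                 seed: int = 0, val_fraction: float = 0.2):
    """Random search scored on a held-out validation split of the training set.

    ``space`` maps config attribute paths (e.g. ``"rnn_hparams.dropout"`` or
    ``"head_params.n_hidden"``) to samplers ``f(rng) -> value``.  Each of the
    ``n_draws`` samples is trained on 80% of the subjects and scored by the
    mean tdAUC over the landmark/horizon grid on the remaining 20%; the
    argmax config is returned.  Test data must be kept aside by the caller.
    """
    if not space:
        warnings.warn("empty search space: returning the base config", stacklevel=2)
    rng = np.random.default_rng(seed)
    ids = np.array(train.subject_ids)
    perm = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids))))
    val_ids, tr_ids = ids[perm[:n_val]], ids[perm[n_val:]]
    tr, val = train.subset(tr_ids), train.subset(val_ids)
    records = []
    best = (None, -np.inf)
    for draw in range(max(n_draws, 1)):
        cfg = replace(base_config, seed=base_config.seed + draw)
        sampled = {}
        for path, sampler in space.items():
            value = sampler(rng)
            sampled[path] = value
            head, _, attr = path.partition(".")
            if attr:
                target = getattr(cfg, head)
                if isinstance(target, dict):
                    target[attr] = value
                else:
                    setattr(target, attr, value)
            else:
                cfg = replace(cfg, **{path: value})
        try:
            bundle = run_two_stage(cfg, tr, val, replicate=draw)
            score = bundle.metrics.query("metric == 'tdAUC'")["value"].mean()
        except (FitError, ValueError) as err:
            records.append(dict(draw=draw, score=np.nan, error=str(err), **sampled))
            continue
        records.append(dict(draw=draw, score=score, **sampled))
        if np.isfinite(score) and score > best[1]:
            best = (cfg, score)
    table = pd.DataFrame(records)
    chosen = best[0] if best[0] is not None else base_config
    return chosen, ResultsBundle(table, base_config, seeds={"seed": seed})
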
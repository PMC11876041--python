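"""Longitudinal encoders: benchmarks, MFPCA/PACE and the recurrent encoder."""

import numpy as np
import pandas as pd
import pytest

import dynasurv as dv
from dynasurv.data import LandmarkedView, landmark
from dynasurv.encoders import (
    RNNHyperparams,
    _ElmanLayer,
    RNNEncoderModel,
    encode_baseline,
    encode_last_visit,
    fit_mfpca,
    fit_rnn,
    mfpca_encode,
    rnn_encode,
)

from conftest import make_dataset


class TestBenchmarks:
    def test_baseline_concatenation(self):
        ds = make_dataset(times=[2.0], events=[1], n_long=2,
                          baseline=pd.DataFrame({"b1": [1.0]}))
        ds.visits.loc[ds.visits["time"] == 0.0, ["y0", "y1"]] = [2.0, 3.0]
        Z = encode_baseline(ds)
        np.testing.assert_array_equal(Z.to_numpy(), [[1.0, 2.0, 3.0]])

    def test_baseline_is_landmark_invariant(self, sim1):
        ds, _ = sim1
        z2 = encode_baseline(landmark(ds, 2.0))
        z4 = encode_baseline(landmark(ds, 4.0))
        common = z4.index
        pd.testing.assert_frame_equal(z2.loc[common], z4)

    def test_last_visit_picks_max_time_below_landmark(self):
        ds = make_dataset(times=[3.0], events=[1], n_long=1)
        ds.visits["y0"] = [10.0, 11.0, 12.0]  # times 0, 1, 2
        Z = encode_last_visit(landmark(ds, 1.5))
        assert Z["last_y0"].iloc[0] == 11.0

    def test_last_visit_before_second_visit_equals_baseline(self, sim1):
        ds, _ = sim1
        view = landmark(ds, 0.2)  # only the baseline visit is retained
        zb = encode_baseline(view)
        zl = encode_last_visit(view)
        np.testing.assert_array_equal(zb.to_numpy(), zl.to_numpy())

    def test_last_visit_argmax_oracle(self):
        ds = make_dataset(times=[4.0, 2.5, 6.0, 3.5], events=[1, 1, 0, 1], n_long=1)
        l = 2.0
        Z = encode_last_visit(landmark(ds, l))
        for sid in Z.index:
            grp = ds.visits[ds.visits["subject_id"] == sid]
            elig = grp[grp["time"] <= l]
            expected = elig.loc[elig["time"].idxmax(), "y0"]
            assert Z.loc[sid, "last_y0"] == expected

    def test_missing_after_imputation_raises(self):
        ds = make_dataset(times=[2.0], events=[1], n_long=1)
        ds.visits["y0"] = [np.nan, np.nan]
        with pytest.raises(ValueError):
            encode_baseline(ds)

    def test_leading_gap_filled_with_training_mean(self):
        ds = make_dataset(times=[2.0, 2.0], events=[1, 1], n_long=1)
        ds.visits["y0"] = [np.nan, 4.0, 2.0, 2.0]
        means = ds.visits[["y0"]].mean()
        Z = encode_baseline(ds, means)
        assert Z["bl_y0"].iloc[0] == pytest.approx(means["y0"])


def _functional_dataset(n=80, noise=0.0, score_sd=2.0, seed=0, n_vis=21):
    """Rank-1 functional data: Y_i(t) = mu(t) + s_i * phi(t) (+ noise)."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0, 10, n_vis)
    h = grid[1] - grid[0]
    phi = np.sin(np.pi * grid / 10)
    phi = phi / np.sqrt(np.sum(phi**2) * h)  # unit integral norm
    mu = 1.0 + 0.3 * grid
    scores = rng.normal(0, score_sd, n)
    rows = []
    for i in range(n):
        y = mu + scores[i] * phi + noise * rng.standard_normal(len(grid))
        for t, val in zip(grid, y):
            rows.append({"subject_id": f"s{i}", "time": t, "y0": val})
    visits = pd.DataFrame(rows)
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    baseline = pd.DataFrame({"b1": np.zeros(n) + rng.normal(size=n)}, index=idx)
    outcomes = pd.DataFrame({"time": np.full(n, 11.0), "event": np.ones(n, int)}, index=idx)
    ds = dv.LongitudinalDataset(baseline, visits, outcomes).validate()
    return ds, grid, phi, mu, scores


class TestMFPCA:
    def test_rank1_eigenstructure_recovery(self):
        ds, grid, phi, mu, scores = _functional_dataset(n=150, noise=0.05, seed=1)
        model = fit_mfpca(ds)
        uni = model.uni["y0"]
        assert uni.eigenvalues[0] == pytest.approx(np.var(scores), rel=0.05)
        phi_hat = np.interp(grid, uni.grid, uni.eigenfunctions[0])
        corr = np.corrcoef(phi_hat, phi)[0, 1]
        assert abs(corr) > 0.99
        assert model.explained_variance.sum() >= 0.95

    def test_pace_matches_quadrature_on_dense_data(self):
        ds, grid, phi, mu, scores = _functional_dataset(n=120, noise=0.05, seed=2)
        model = fit_mfpca(ds)
        uni = model.uni["y0"]
        h = grid[1] - grid[0]
        pace, quad = [], []
        for sid, grp in ds.visits.groupby("subject_id", sort=False):
            t, y = grp["time"].to_numpy(), grp["y0"].to_numpy()
            pace.append(uni.pace_scores(t, y)[0])
            resid = y - uni.mean_at(t)
            phi_hat = uni.phi_at(t)[0]
            quad.append(np.sum(resid * phi_hat) * h)
        assert np.corrcoef(pace, quad)[0, 1] > 0.99

    def test_scores_recover_generating_scores_up_to_sign(self):
        ds, grid, phi, mu, scores = _functional_dataset(n=120, noise=0.0, seed=3)
        model = fit_mfpca(ds)
        Z = mfpca_encode(model, ds)
        est = Z["rho_1"].to_numpy()
        corr = np.corrcoef(est, scores)[0, 1]
        assert abs(corr) > 0.99

    def test_truncation_shrinks_scores_toward_zero(self):
        ds, grid, phi, mu, scores = _functional_dataset(n=100, noise=1.0, seed=4)
        model = fit_mfpca(ds)
        uni = model.uni["y0"]
        full_mag, trunc_mag = [], []
        for sid, grp in list(ds.visits.groupby("subject_id", sort=False))[:30]:
            t, y = grp["time"].to_numpy(), grp["y0"].to_numpy()
            full_mag.append(abs(uni.pace_scores(t, y)[0]))
            trunc_mag.append(abs(uni.pace_scores(t[:1], y[:1])[0]))
        assert np.mean(trunc_mag) < np.mean(full_mag)

    def test_encoding_dimension_contract(self, sim1):
        ds, _ = sim1
        view = landmark(ds, 3.0)
        model = fit_mfpca(view)
        Z = mfpca_encode(model, view)
        K = ds.baseline.shape[1]
        Q = len(ds.long_cols)
        assert Z.shape[1] == K + Q + model.n_components
        assert np.isfinite(Z.to_numpy()).all()

    def test_constant_variable_falls_back_to_mean_only(self):
        ds, *_ = _functional_dataset(n=40, noise=0.0, score_sd=0.0, seed=5)
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_mfpca(ds)
        assert len(model.uni["y0"].eigenvalues) == 0
        Z = mfpca_encode(model, ds)
        assert model.n_components == 0


class TestRNN:
    def test_scalar_recurrence_oracle(self):
        """1-layer width-1 recurrence equals hand-iterated tanh(w0 y + b0 + w1 h + b1)."""
        rng = np.random.default_rng(0)
        layer = _ElmanLayer(1, 1, rng)
        w0, b0 = 0.7, 0.1
        w1, b1 = -0.4, 0.2
        layer.W_in.value[:] = w0
        layer.b_in.value[:] = b0
        layer.W_hh.value[:] = w1
        layer.b_hh.value[:] = b1
        hp = RNNHyperparams(n_layers=1, hidden=1, include_time=False)
        ds = make_dataset(times=[3.0], events=[1], n_long=1,
                          baseline=pd.DataFrame({"b": [0.0]}))
        ys = [0.5, -1.0, 2.0]
        ds.visits["y0"] = ys
        model = RNNEncoderModel([layer], None, hp, "long_only", ["y0"], ["b"],
                                ds.visits[["y0"]].mean(), "none")
        Z = rnn_encode(model, ds)
        h = 0.0
        for y in ys:
            h = np.tanh(w0 * y + b0 + w1 * h + b1)
        assert Z["h_1"].iloc[0] == pytest.approx(h, abs=1e-12)

    def test_single_visit_recurrence_base_case(self):
        rng = np.random.default_rng(1)
        layer = _ElmanLayer(1, 1, rng)
        hp = RNNHyperparams(n_layers=1, hidden=1, include_time=False)
        ds = make_dataset(times=[0.5], events=[1], n_long=1,
                          baseline=pd.DataFrame({"b": [0.0]}))
        ds.visits["y0"] = [1.5]
        model = RNNEncoderModel([layer], None, hp, "long_only", ["y0"], ["b"],
                                ds.visits[["y0"]].mean(), "none")
        Z = rnn_encode(model, ds)
        expected = np.tanh(1.5 * layer.W_in.value[0, 0] + layer.b_in.value[0]
                           + layer.b_hh.value[0])
        assert Z["h_1"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_architecture_defaults(self, sim1):
        ds, _ = sim1
        view = landmark(ds, 2.0)
        model = fit_rnn(view, mode="long_only",
                        hparams=RNNHyperparams(epochs=1), seed=0)
        Q = len(ds.long_cols)
        assert len(model.layers) == 2
        assert model.hidden == 5 + Q
        Z = rnn_encode(model, view)
        assert Z.shape[1] == ds.baseline.shape[1] + (5 + Q)

    def test_training_reduces_longitudinal_loss(self):
        """On linear noise-free trajectories the next-visit MSE drops >= 10x."""
        rng = np.random.default_rng(6)
        n = 60
        rows, ids = [], []
        for i in range(n):
            a, b = rng.normal(0, 0.3), rng.normal(0.2, 0.05)
            for t in np.arange(0.0, 5.0, 1.0):
                rows.append({"subject_id": f"s{i}", "time": t, "y0": a + b * t})
            ids.append(f"s{i}")
        visits = pd.DataFrame(rows)
        idx = pd.Index(ids, name="subject_id")
        ds = dv.LongitudinalDataset(
            pd.DataFrame({"b1": np.zeros(n)}, index=idx),
            visits,
            pd.DataFrame({"time": np.full(n, 6.0), "event": np.ones(n, int)}, index=idx),
        ).validate()
        model = fit_rnn(ds, mode="long_only",
                        hparams=RNNHyperparams(epochs=150, dropout=0.0), seed=0)
        assert model.history_[-1] < model.history_[0] / 10

    def test_deterministic_under_seed(self, sim1):
        ds, _ = sim1
        view = landmark(ds, 2.0)
        hp = RNNHyperparams(epochs=2)
        m1 = fit_rnn(view, mode="long_only", hparams=hp, seed=5)
        m2 = fit_rnn(view, mode="long_only", hparams=hp, seed=5)
        for p1, p2 in zip(m1.parameters, m2.parameters):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_long_only_requires_multi_visit_subject(self):
        ds = make_dataset(times=[0.5, 0.5], events=[1, 1])
        with pytest.raises(ValueError):
            fit_rnn(ds, mode="long_only", hparams=RNNHyperparams(epochs=1), seed=0)

    def test_variable_mismatch_rejected(self, sim1):
        ds, _ = sim1
        view = landmark(ds, 2.0)
        model = fit_rnn(view, mode="long_only", hparams=RNNHyperparams(epochs=1), seed=0)
        other = make_dataset(times=[2.0], events=[1], n_long=1)
        with pytest.raises(ValueError):
            rnn_encode(model, other)

    def test_truncation_only_affects_truncated_subject(self, sim1):
        """Encoders are pure per-subject functions of the retained history."""
        ds, _ = sim1
        view = landmark(ds, 3.0)
        model = fit_rnn(view, mode="long_only", hparams=RNNHyperparams(epochs=1), seed=0)
        z_full = rnn_encode(model, view)
        z_trunc = rnn_encode(model, landmark(ds, 1.0))
        shared = z_trunc.index.intersection(z_full.index)
        changed = (z_trunc.loc[shared] - z_full.loc[shared]).abs().sum(axis=1)
        # subjects whose history is identical in both views encode identically
        full_counts = view.data.n_visits
        trunc_counts = landmark(ds, 1.0).data.n_visits
        same_hist = shared[(full_counts.loc[shared] == trunc_counts.loc[shared])]
        assert (changed.loc[same_hist] < 1e-12).all()
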
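"""LSTM cell, wavelet feature expansion, selection, PCA, full pipeline."""

import numpy as np
import pandas as pd
import pytest

from eswcnn.signal_pipeline import (
    DEFAULT_FAMILIES,
    FeatureTable,
    LSTMClassifier,
    LSTMClassifierConfig,
    LSTMParams,
    SignalPipeline,
    SignalPipelineConfig,
    _LSTMLayer,
    expected_feature_count,
    feature_select_vote,
    lstm_forward,
    pca_reduce,
    ttest_screen,
    wavelet_feature_expand,
)
from eswcnn.synthetic_data import default_signal_specs, gen_signal_dataset

from conftest import finite_diff_params


def _random_params(h, d, rng):
    return LSTMParams(
        *[rng.normal(size=(h, d)) for _ in range(4)],
        *[rng.normal(size=(h, h)) for _ in range(4)],
        *[rng.normal(size=h) for _ in range(4)],
    )


class TestLSTMCell:
    def test_zero_parameters_keep_states_at_zero(self):
        p = LSTMParams(
            *[np.zeros((3, 2))] * 4, *[np.zeros((3, 3))] * 4, *[np.zeros(3)] * 4
        )
        hs, c, h = lstm_forward(np.ones((4, 2)), p)
        assert np.allclose(hs, 0) and np.allclose(c, 0) and np.allclose(h, 0)

    def test_saturated_forget_gate_preserves_memory(self):
        """Scalar cell, zero weights, large forget bias: c1 stays near c0."""
        p = LSTMParams(
            *[np.zeros((1, 1))] * 4, *[np.zeros((1, 1))] * 4,
            np.zeros(1), np.full(1, 50.0), np.zeros(1), np.zeros(1),
        )
        _, c1, _ = lstm_forward(np.zeros((1, 1)), p, c0=np.array([2.0]))
        assert c1[0] == pytest.approx(2.0, abs=1e-6)

    def test_matches_step_by_step_oracle(self, rng):
        """Vectorized recurrence equals a literal per-gate evaluation."""
        p = _random_params(3, 2, rng)
        seq = rng.normal(size=(5, 2))
        hs, c, h = lstm_forward(seq, p)

        def sig(z):
            return 1 / (1 + np.exp(-z))

        c_ref = np.zeros(3)
        h_ref = np.zeros(3)
        for t, x in enumerate(seq):
            i = sig(p.W_i @ x + p.R_i @ h_ref + p.b_i)
            f = sig(p.W_f @ x + p.R_f @ h_ref + p.b_f)
            g = np.tanh(p.W_g @ x + p.R_g @ h_ref + p.b_g)
            o = sig(p.W_o @ x + p.R_o @ h_ref + p.b_o)
            c_ref = f * c_ref + g * i
            h_ref = o * np.tanh(c_ref)
            assert np.abs(hs[t] - h_ref).max() <= 1e-6
        assert np.abs(c - c_ref).max() <= 1e-6

    def test_hidden_state_bounded_by_one(self, rng):
        p = _random_params(4, 3, rng)
        hs, _, _ = lstm_forward(5 * rng.normal(size=(20, 3)), p)
        assert np.abs(hs).max() <= 1.0

    def test_empty_sequence_error(self, rng):
        with pytest.raises(ValueError, match="empty"):
            lstm_forward(np.zeros((0, 2)), _random_params(3, 2, rng))

    def test_batched_layer_matches_functional_and_gradients(self, rng):
        layer = _LSTMLayer(2, 3, np.random.default_rng(3))
        x = rng.normal(size=(4, 5, 2))
        h = layer.forward(x)
        params = layer.to_params()
        for i in range(4):
            assert np.abs(lstm_forward(x[i], params)[2] - h[i]).max() <= 1e-12
        gout = rng.normal(size=(4, 3))
        layer.zero_grad()
        layer.backward(gout)
        finite_diff_params(layer, lambda: (layer.forward(x) * gout).sum(), eps=1e-6, tol=1e-4)


class TestLSTMClassifier:
    def test_training_loss_descends_and_is_seeded(self):
        signals, labels, _ = gen_signal_dataset(default_signal_specs(), 40, seed=0)
        z = (signals - signals.mean()) / signals.std()
        runs = []
        for _ in range(2):
            clf = LSTMClassifier(LSTMClassifierConfig(seed=1, epochs=8))
            history = clf.fit(z, labels)
            runs.append(clf.predict_proba(z))
            assert history["loss"][-1] < history["loss"][0]
        assert np.array_equal(runs[0], runs[1])

    def test_single_class_error(self):
        clf = LSTMClassifier()
        with pytest.raises(ValueError, match="single class"):
            clf.fit(np.zeros((4, 8)), np.zeros(4, dtype=int))


class TestWaveletFeatures:
    def test_column_count_matches_recipe(self):
        signals = np.random.default_rng(0).normal(size=(5, 64))
        table = wavelet_feature_expand(signals)
        assert table.data.shape[1] == expected_feature_count(len(DEFAULT_FAMILIES))
        assert table.data.shape[1] == 4 + 4 * 8 + 9

    def test_orthogonal_families_conserve_energy(self, rng):
        """Parseval: sum of squared DWT coefficients equals signal energy."""
        import pywt

        sig = rng.normal(size=128)
        for fam in ("db4", "sym5"):
            ca, cd = pywt.dwt(sig, fam, mode="periodization")
            energy = (ca**2).sum() + (cd**2).sum()
            assert energy == pytest.approx((sig**2).sum(), rel=1e-8)
        # the same energies appear in the feature table
        table = wavelet_feature_expand(sig[None], families=("db4",))
        total = table.data.loc[0, "db4|cA|energy"] + table.data.loc[0, "db4|cD|energy"]
        assert total == pytest.approx((sig**2).sum(), rel=1e-8)

    def test_zero_signal_zero_energy_features(self):
        table = wavelet_feature_expand(np.zeros((2, 64)))
        energy_cols = [c for c in table.data.columns if c.endswith(("energy", "std"))]
        assert (table.data[energy_cols] == 0).all().all()

    def test_short_signal_error(self):
        with pytest.raises(ValueError, match="shorter"):
            wavelet_feature_expand(np.zeros((1, 4)), families=("bior3.9",))

    def test_unique_names_no_missing(self, rng):
        table = wavelet_feature_expand(rng.normal(size=(3, 64)))
        assert not table.data.isna().any().any()
        assert table.data.columns.is_unique


def _toy_table(rng, n=60, p=100, informative=5, shift=2.0):
    labels = np.repeat([0, 1], n // 2)
    x = rng.normal(size=(n, p))
    for j in range(informative):
        x[labels == 1, j] += shift
    cols = [f"f{j}" for j in range(p)]
    return FeatureTable(pd.DataFrame(x, columns=cols), labels)


class TestFeatureSelection:
    def test_label_copy_feature_selected_by_all_methods(self, rng):
        table = _toy_table(rng)
        df = table.data.copy()
        df["label_copy"] = table.labels.astype(float)
        table = FeatureTable(df, table.labels)
        report = feature_select_vote(table, seed=0)
        assert "label_copy" in report.rf_top
        assert "label_copy" in report.corr_top
        assert "label_copy" in report.selected

    def test_constant_feature_never_in_correlation_or_variance_sets(self, rng):
        table = _toy_table(rng)
        df = table.data.copy()
        df["constant"] = 1.0
        table = FeatureTable(df, table.labels)
        report = feature_select_vote(table, seed=0)
        assert "constant" not in report.corr_top
        assert "constant" not in report.softmax_var_top

    def test_informative_features_survive_voting(self):
        """Across 10 seeds, at least 4 of the 5 informative features land in
        the final voted set (median)."""
        hits = []
        for seed in range(10):
            table = _toy_table(np.random.default_rng(seed))
            report = feature_select_vote(table, seed=seed)
            hits.append(sum(f"f{j}" in report.selected for j in range(5)))
        assert np.median(hits) >= 4

    def test_voted_set_subset_of_union(self, rng):
        report = feature_select_vote(_toy_table(rng), seed=1)
        union = set(report.rf_top) | set(report.corr_top) | set(report.softmax_var_top)
        assert set(report.selected) <= union

    def test_single_class_error(self, rng):
        table = _toy_table(rng)
        bad = FeatureTable(table.data, np.zeros_like(table.labels))
        with pytest.raises(ValueError, match="2 classes"):
            feature_select_vote(bad)


class TestTTestScreen:
    def test_shifted_feature_ranks_first(self):
        """A 3-sigma group-mean shift outranks 100 noise features."""
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 100)
        x = rng.normal(size=(200, 101))
        x[labels == 1, 0] += 3.0
        table = FeatureTable(
            pd.DataFrame(x, columns=[f"f{j}" for j in range(101)]), labels
        )
        ranked, pvals, top = ttest_screen(table, top_fraction=0.01)
        assert ranked[0] == "f0"
        assert "f0" in top and pvals[0] < 1e-6

    def test_identical_groups_rank_last(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([0, 1], 50)
        x = rng.normal(size=(100, 20))
        x[labels == 1, 3] += 2.0
        shared = rng.normal(size=50)
        x[labels == 0, 7] = shared
        x[labels == 1, 7] = shared  # exactly identical groups for f7
        table = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(20)]), labels)
        ranked, pvals, _ = ttest_screen(table)
        assert ranked[-1] == "f7"
        assert pvals[-1] > 0.99

    def test_null_pvalues_uniform(self):
        """Under the null, p-values pass a KS test for uniformity."""
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 50)
        x = rng.normal(size=(100, 1000))
        table = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(1000)]), labels)
        _, pvals, _ = ttest_screen(table)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_group_requirements(self):
        table = FeatureTable(pd.DataFrame({"a": [1.0, 2, 3]}), np.array([0, 1, 2]))
        with pytest.raises(ValueError, match="2 groups"):
            ttest_screen(table)


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 8))
        scores, _, ratios = pca_reduce(u @ v, k=1)
        assert ratios[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(40, 6))
        scores, loadings, _ = pca_reduce(x, k=6)
        recon = scores @ loadings + x.mean(axis=0)
        assert np.abs(recon - x).max() <= 1e-9

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(200, 10))
        _, _, ratios = pca_reduce(x, k=10)
        cov = np.cov(x, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(ratios, eig / eig.sum(), atol=1e-10)
        assert (np.diff(ratios) <= 1e-12).all()  # nonincreasing

    def test_k_beyond_rank_error(self, rng):
        u = rng.normal(size=(30, 2))
        v = rng.normal(size=(2, 8))
        with pytest.raises(ValueError, match="rank"):
            pca_reduce(u @ v, k=5)


class TestPipeline:
    def test_pipeline_beats_raw_lstm(self):
        """expand -> vote -> t-test -> PCA -> LSTM outperforms an LSTM on the
        raw sequences (median over 5 seeds) on the default signal classes."""
        signals, labels, _ = gen_signal_dataset(default_signal_specs(), 120, seed=2026)
        rng = np.random.default_rng(0)
        idx = rng.permutation(labels.size)
        tr, te = idx[:180], idx[180:]
        z = (signals - signals.mean()) / signals.std()
        pipe_acc, raw_acc = [], []
        for seed in range(5):
            pipe = SignalPipeline(SignalPipelineConfig(seed=seed))
            pipe.fit(signals[tr], labels[tr])
            pipe_acc.append((pipe.predict(signals[te]) == labels[te]).mean())
            raw = LSTMClassifier(LSTMClassifierConfig(seed=seed))
            raw.fit(z[tr], labels[tr])
            raw_acc.append((raw.predict(z[te]) == labels[te]).mean())
        assert np.median(pipe_acc) > np.median(raw_acc)
        assert np.median(pipe_acc) >= 0.90

    def test_pipeline_deterministic(self):
        signals, labels, _ = gen_signal_dataset(default_signal_specs(), 30, seed=5)
        preds = []
        for _ in range(2):
            pipe = SignalPipeline(SignalPipelineConfig(seed=3))
            pipe.fit(signals, labels)
            preds.append(pipe.predict(signals))
        assert np.array_equal(preds[0], preds[1])
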
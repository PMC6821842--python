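import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from facespace import contacts as cm
from facespace import synthdata
from conftest import make_epochs, make_trials

FACE_IDS = [f"face_{i:02d}" for i in range(1, 11)]


def _mixed_epochs(rng, n_channels=4, n_rep=5, effect_channels=(), face_gain=0.0,
                  categories=("faces", "places", "patterns")):
    """Epochs with baseline ~N(1, .1) and optional planted response effects."""
    rows, data = [], []
    n_t = 350  # [-200, 500) at 500 Hz
    for cat in categories:
        for e in range(8):
            for _ in range(n_rep):
                tr = 1 + 0.1 * rng.normal(size=(n_channels, n_t))
                for c in effect_channels:
                    tr[c, 125:] += 1.0  # any-stimulus response
                    if cat == "faces":
                        tr[c, 125:] += face_gain
                rows.append({"stimulus_id": f"{cat}_{e:02d}", "category": cat,
                             "is_repeat": False, "block_id": None, "excluded": False,
                             "onset_ms": 0})
                data.append(tr)
    return make_epochs(np.stack(data), pd.DataFrame(rows))


class TestVisualScreen:
    def test_flat_channels_not_visual(self):
        ep = _mixed_epochs(np.random.default_rng(0))
        table = cm.detect_visual_contacts(ep)
        assert not table["visual_flag"].any()

    def test_planted_effect_passes_gate_with_large_delta(self):
        ep = _mixed_epochs(np.random.default_rng(1), effect_channels=(0, 1))
        table = cm.detect_visual_contacts(ep)
        assert table["visual_flag"].tolist() == [True, True, False, False]
        assert (table["glass_delta"].iloc[:2] > 1).all()

    def test_degenerate_variance_untestable(self):
        ep = _mixed_epochs(np.random.default_rng(2), n_channels=2)
        ep.data[:, 1, :] = 3.0  # constant channel
        table = cm.detect_visual_contacts(ep)
        assert not table["visual_flag"].iloc[1]
        assert np.isnan(table["t_p"].iloc[1])

    def test_null_false_positive_control(self):
        """Pure-noise contacts: raw p<.05 near nominal, FDR+effect gate near zero."""
        raw_rate, fdr_rate, n_runs, n_ch = [], [], 10, 20
        for seed in range(n_runs):
            ep = _mixed_epochs(np.random.default_rng(100 + seed), n_channels=n_ch)
            table = cm.detect_visual_contacts(ep)
            raw_rate.append((table["t_p"] < 0.05).mean())
            fdr_rate.append(table["visual_flag"].mean())
        assert np.mean(raw_rate) < 0.05 + 2 * np.sqrt(0.05 * 0.95 / (n_runs * n_ch))
        assert np.mean(fdr_rate) <= 0.05


class TestFaceScreen:
    def test_planted_face_gain_flagged(self):
        ep = _mixed_epochs(np.random.default_rng(3), effect_channels=(0, 1), face_gain=1.0)
        table = cm.detect_visual_contacts(ep)
        table = cm.detect_face_contacts(table, ep)
        assert table["face_flag"].iloc[0] and table["face_flag"].iloc[1]

    def test_category_unselective_contact_not_flagged(self):
        ep = _mixed_epochs(np.random.default_rng(4), effect_channels=(0,), face_gain=0.0)
        table = cm.detect_visual_contacts(ep)
        table = cm.detect_face_contacts(table, ep)
        assert not table["face_flag"].iloc[0]

    def test_anatomical_exclusions_force_flag_off(self):
        ep = _mixed_epochs(np.random.default_rng(5), effect_channels=(0, 1, 2), face_gain=1.0)
        table = cm.make_contact_table(ep.channel_names,
                                      anatomical_labels=["V1", "fusiform", "fusiform", ""],
                                      depths_mm=[0.0, 12.0, 0.0, 0.0])
        table = cm.detect_visual_contacts(ep, contact_table=table)
        table = cm.detect_face_contacts(table, ep)
        assert not table["face_flag"].iloc[0]  # V1 label
        assert not table["face_flag"].iloc[1]  # deeper than 10 mm
        assert table["face_flag"].iloc[2]

    def test_missing_category_named_in_error(self):
        ep = _mixed_epochs(np.random.default_rng(6), categories=("faces", "patterns"))
        table = cm.detect_visual_contacts(ep)
        with pytest.raises(ValueError, match="places"):
            cm.detect_face_contacts(table, ep)

    def test_full_chain_recovers_planted_face_contacts(self, full_chain):
        table, truth = full_chain["contact_table"], full_chain["truth"]
        planted = truth["face_gain"].values > 0
        assert table.loc[planted, "face_flag"].mean() >= 0.8
        assert table.loc[~planted, "face_flag"].mean() <= 0.4


class TestSelectivityIndex:
    def test_hand_computed_example(self):
        G = np.full((2, 1, 3, 4), np.nan)
        G[0, 0] = np.array([1.0, 2.0, 3.0])[:, None]  # best: mean 2, var 1
        G[1, 0] = np.array([0.0, 1.0, 2.0])[:, None]  # worst: mean 1, var 1
        rm = cm.ResponseMatrix(G, ["a", "b"], ["c1"], np.arange(4))
        idx, _ = cm.exemplar_selectivity_index(rm, "c1", n_perm=10, seed=0)
        assert idx == pytest.approx(1.0)

    def test_invariant_under_positive_affine_transform(self, planted_rm):
        idx, _ = cm.exemplar_selectivity_index(planted_rm, 0, n_perm=1, seed=0)
        scaled = cm.ResponseMatrix(3.0 * planted_rm.G + 7.0, planted_rm.exemplar_ids,
                                   planted_rm.contact_ids, planted_rm.times_ms)
        idx2, _ = cm.exemplar_selectivity_index(scaled, 0, n_perm=1, seed=0)
        assert idx2 == pytest.approx(idx)

    def test_zero_variance_rejected(self):
        G = np.ones((2, 1, 3, 4))
        rm = cm.ResponseMatrix(G, ["a", "b"], ["c1"], np.arange(4))
        with pytest.raises((ZeroDivisionError, ValueError)):
            cm.exemplar_selectivity_index(rm, "c1", n_perm=10, seed=0)

    def test_null_p_values_approximately_uniform(self):
        """KS distance of shuffle-test p-values from U(0,1) under the null."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            G = rng.normal(size=(5, 1, 4, 1))
            rm = cm.ResponseMatrix(G, list("abcde"), ["c1"], np.arange(1))
            _, p = cm.exemplar_selectivity_index(rm, "c1", n_perm=99, seed=int(rng.integers(1 << 30)))
            pvals.append(p)
        assert kstest(pvals, "uniform").statistic < 0.1


class TestResponseMatrix:
    def test_smoothing_leaves_constant_series_unchanged(self):
        x = np.full((1, 1, 2, 50), 3.0)
        assert np.allclose(cm.smooth_running_mean(x, 25), x)

    def test_smoothing_shrinks_white_noise_variance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(200, 500))
        win = 25
        sm = cm.smooth_running_mean(x, win)
        ratio = x[:, 100:-100].var() / sm[:, 100:-100].var()
        assert ratio == pytest.approx(win, rel=0.15)

    def test_built_matrix_shape_and_window(self, full_chain):
        rm = cm.build_response_matrix(full_chain["epochs"], full_chain["contact_table"],
                                      smoothing_ms=50.0, set_id=2)
        n_face = int(full_chain["contact_table"]["face_flag"].sum())
        assert rm.shape[0] == 10 and rm.shape[1] == n_face
        assert rm.shape[3] == 225  # 450 ms at 500 Hz
        assert rm.times_ms[0] == 50 and rm.times_ms[-1] < 500

    def test_missing_repetitions_nan_marked(self, full_chain):
        rm = cm.build_response_matrix(full_chain["epochs"], full_chain["contact_table"],
                                      smoothing_ms=None, set_id=2)
        counts = rm.trial_counts()
        assert counts.min() >= 2 and np.isnan(rm.G).any()

    def test_round_trip(self, tmp_path, planted_rm):
        planted_rm.save(tmp_path / "rm")
        back = cm.ResponseMatrix.load(tmp_path / "rm")
        assert np.allclose(back.G, planted_rm.G, equal_nan=True)
        assert back.exemplar_ids == planted_rm.exemplar_ids
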
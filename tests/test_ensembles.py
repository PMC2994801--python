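"""Fold plans, grid training, ensemble selection, and the two-layer model."""

import math

import numpy as np
import pytest

from betaturn.ensembles import (
    EnsembleSpec,
    audit_no_leakage,
    ensemble_predict,
    load_model,
    make_folds,
    predict_chain,
    save_model,
    select_ensemble,
    train_grid,
    train_layered,
)
from betaturn.features import build_second_layer_track, first_layer_track, window_matrix
from betaturn.network import TrainConfig, TrainedNetwork, forward, init_network
from betaturn.metrics import roc_auc


class TestFoldPlan:
    def test_equal_chains_split_evenly(self):
        lengths = {f"c{i}": 100 for i in range(20)}
        plan = make_folds(lengths, k=10, seed=0)
        counts = [len(plan.chains_in(f)) for f in range(10)]
        assert counts == [2] * 10

    def test_deterministic_given_seed(self):
        lengths = {f"c{i}": 80 for i in range(15)}  # ties: seed decides placement
        assert make_folds(lengths, 5, seed=3).fold_of == make_folds(lengths, 5, seed=3).fold_of
        assert make_folds(lengths, 5, seed=3).fold_of != make_folds(lengths, 5, seed=4).fold_of

    def test_residue_imbalance_bounded_by_longest_chain(self, rng):
        lengths = {f"c{i}": int(rng.integers(40, 200)) for i in range(37)}
        plan = make_folds(lengths, k=5, seed=1)
        loads = [sum(lengths[c] for c in plan.chains_in(f)) for f in range(5)]
        assert max(loads) - min(loads) <= max(lengths.values())

    def test_every_chain_in_exactly_one_fold(self):
        lengths = {f"c{i}": 60 + i for i in range(12)}
        plan = make_folds(lengths, k=4, seed=0)
        assert sorted(c for f in range(4) for c in plan.chains_in(f)) == sorted(lengths)

    def test_too_few_chains_errors(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds({"a": 10, "b": 20}, k=3)


def _fake_net(mcc_value, window=5, hidden=10, fold=0):
    net = TrainedNetwork(
        weights=init_network(TrainConfig(seed=0, hidden=hidden), 10),
        config=TrainConfig(window=window, hidden=hidden),
        n_inputs=10,
        leaveout_mcc=mcc_value,
        fold_id=fold,
    )
    net.name = f"G/w{window}h{hidden}f{fold}"
    return net


class TestSelectEnsemble:
    def test_top_k_keeps_best(self, rng):
        nets = [_fake_net(m, fold=i % 5) for i, m in enumerate(rng.random(30))]
        spec = select_ensemble(nets, size=10, mode="top")
        kept = {n.leaveout_mcc for n in spec.members}
        dropped = {n.leaveout_mcc for n in nets} - kept
        assert min(kept) >= max(dropped)
        assert len(spec.members) == 10

    def test_per_fold_mode_keeps_one_per_fold(self, rng):
        nets = [_fake_net(m, fold=i % 4) for i, m in enumerate(rng.random(16))]
        spec = select_ensemble(nets, mode="per_fold")
        assert sorted(n.fold_id for n in spec.members) == [0, 1, 2, 3]
        for member in spec.members:
            best_in_fold = max(
                n.leaveout_mcc for n in nets if n.fold_id == member.fold_id
            )
            assert member.leaveout_mcc == best_in_fold

    def test_tie_break_is_deterministic(self):
        nets = [
            _fake_net(0.5, window=w, hidden=h, fold=f)
            for w in (9, 5)
            for h in (20, 10)
            for f in (1, 0)
        ]
        spec = select_ensemble(nets, size=3, mode="top")
        key = [(n.config.window, n.config.hidden, n.fold_id) for n in spec.members]
        assert key == [(5, 10, 0), (5, 10, 1), (5, 20, 0)]

    def test_insufficient_members_errors(self):
        with pytest.raises(ValueError, match="at least"):
            select_ensemble([_fake_net(0.1)], size=5, mode="top")


class TestEnsemblePredict:
    def test_single_member_identity(self, small_tracks):
        track = next(iter(small_tracks.values()))
        net = _fake_net(0.5, window=5, hidden=10)
        net.n_inputs = 5 * 25
        net.weights = init_network(TrainConfig(seed=1, hidden=10), 5 * 25)
        spec = EnsembleSpec(members=[net])
        single = forward(net, window_matrix(track, 5))
        assert np.allclose(ensemble_predict(spec, track), single)

    def test_mean_of_two_members(self, small_tracks):
        track = next(iter(small_tracks.values()))
        nets = []
        for seed in (1, 2):
            n = _fake_net(0.5, window=5, hidden=10)
            n.weights = init_network(TrainConfig(seed=seed, hidden=10), 5 * 25)
            n.n_inputs = 5 * 25
            nets.append(n)
        combined = ensemble_predict(EnsembleSpec(members=nets), track)
        a = forward(nets[0], window_matrix(track, 5))
        b = forward(nets[1], window_matrix(track, 5))
        assert np.allclose(combined, (a + b) / 2)
        assert combined.var() <= max(a.var(), b.var()) + 1e-12


@pytest.fixture(scope="module")
def grid_networks(small_tracks, small_labels):
    from betaturn.ensembles import make_folds

    plan = make_folds({c: len(small_labels[c]) for c in small_labels}, k=3, seed=0)
    nets = train_grid(
        small_tracks, small_labels, plan,
        windows=(5, 7), hiddens=(10, 15),
        learning_rate=0.15, max_epochs=8, seed=5,
    )
    return plan, nets


class TestTrainGrid:
    def test_network_count_and_bookkeeping(self, grid_networks):
        plan, nets = grid_networks
        assert len(nets) == 2 * 2 * 3
        assert all(not math.isnan(n.leaveout_mcc) for n in nets)

    def test_fold_test_chains_disjoint_from_train(self, grid_networks):
        plan, nets = grid_networks
        for net in nets:
            test_chains = set(plan.chains_in(net.fold_id))
            assert test_chains.isdisjoint(net.train_chain_ids)
            assert set(net.train_chain_ids) | test_chains == set(plan.fold_of)

    def test_rerun_is_identical(self, grid_networks, small_tracks, small_labels):
        plan, nets = grid_networks
        again = train_grid(
            small_tracks, small_labels, plan,
            windows=(5, 7), hiddens=(10, 15),
            learning_rate=0.15, max_epochs=8, seed=5,
        )
        assert [n.leaveout_mcc for n in nets] == [n.leaveout_mcc for n in again]


@pytest.fixture(scope="module")
def layered(small_dataset):
    return train_layered(
        small_dataset, setup="M", k=3,
        windows=(5,), hiddens=(15,),
        aux_windows=(5,), aux_hiddens=(10,),
        second_windows=(5,), second_hiddens=(10,),
        ensemble_size=2, learning_rate=0.1, max_epochs=5, seed=17,
    )


class TestLayered:
    def test_no_leakage(self, layered):
        assert audit_no_leakage(layered)

    def test_predict_report_shape(self, layered, small_dataset):
        item = small_dataset[0]
        report = predict_chain(
            layered.model, item.sequence, item.profile, item.struct,
            chain_id=item.chain_id,
        )
        assert len(report) == len(item.sequence)
        assert {"turn_score", "call", "I", "IV", "P1", "P4"} <= set(report.columns)
        assert report["turn_score"].between(0, 1).all()
        assert set(report["call"]) <= {0, 1}

    def test_second_layer_not_far_below_first(self, layered):
        order = sorted(layered.labels)
        y = np.concatenate([layered.labels[c] for c in order])
        s1 = np.concatenate([layered.oof_first[c]["G"] for c in order])
        s2 = np.concatenate([layered.oof_second[c] for c in order])
        _, a1 = roc_auc(s1, y)
        _, a2 = roc_auc(s2, y)
        assert a2 >= a1 - 0.02  # tiny fixture; full bound checked at scale

    def test_setup_g_trains_without_profile_channel(self, small_dataset):
        res = train_layered(
            small_dataset, setup="G", k=3,
            windows=(5,), hiddens=(8,),
            aux_windows=(5,), aux_hiddens=(8,),
            second_windows=(5,), second_hiddens=(8,),
            ensemble_size=2, learning_rate=0.1, max_epochs=3, seed=1,
        )
        track = build_second_layer_track(
            "G", gen_scores=res.oof_first[small_dataset[0].chain_id]["G"]
        )
        assert track.width == 2

    def test_unknown_setup_errors(self, small_dataset):
        with pytest.raises(ValueError, match="setup"):
            train_layered(small_dataset, setup="Q", k=3)

    def test_model_bundle_roundtrip(self, layered, small_dataset, tmp_path):
        save_model(layered.model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        item = small_dataset[1]
        a = predict_chain(layered.model, item.sequence, item.profile, item.struct)
        b = predict_chain(loaded, item.sequence, item.profile, item.struct)
        assert np.allclose(a["turn_score"], b["turn_score"])
        assert loaded.threshold == layered.model.threshold
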
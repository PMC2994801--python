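"""Cross-validation, network ensembles, and the two-layer topology.

The full protocol: chains (never residues) are split into K folds; for every
label track a grid of (window x hidden) architectures is trained per fold
with MCC-based epoch selection, giving window*hidden*K fold-networks per
track.  First-layer ensembles keep the top fold-networks ranked by leave-out
MCC; second-layer ensembles keep the single best architecture within each
fold.  Ensemble scores are unweighted means of member scores.

The first layer trains the general turn network (beta-turn-G) and the four
position networks (beta-turn-P) on profile + secondary-structure +
accessibility windows; type-specific networks (beta-turn-S) are optional.
Cross-validated first-layer outputs — every chain scored only by networks
whose training folds exclude it — feed the second layer, whose input
composition is chosen by a lettered setup (default M: position scores +
general score + sec/rsa).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    ResidueFeatureTrack,
    SETUPS,
    SequenceProfile,
    StructTracks,
    build_second_layer_track,
    first_layer_track,
    window_matrix,
)
from .network import (
    TrainConfig,
    TrainedNetwork,
    forward,
    network_from_json,
    network_to_json,
    train_backprop,
)
from .turns import TURN_TYPES, label_sets

__all__ = [
    "FoldPlan",
    "EnsembleSpec",
    "LayeredModel",
    "LayeredResult",
    "make_folds",
    "train_grid",
    "select_ensemble",
    "ensemble_predict",
    "train_layered",
    "predict_chain",
    "audit_no_leakage",
    "save_model",
    "load_model",
]

#: Decision thresholds: default, and the Q_total-optimized "tweak" preset.
DEFAULT_THRESHOLD = 0.50
TWEAK_THRESHOLD = 0.61


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of whole chains to K cross-validation folds."""

    k: int
    fold_of: dict[str, int]

    def chains_in(self, fold: int) -> list[str]:
        return [c for c, f in self.fold_of.items() if f == fold]

    def train_chains(self, fold: int) -> list[str]:
        return [c for c, f in self.fold_of.items() if f != fold]


def make_folds(chain_lengths: dict[str, int], k: int = 10, seed: int = 0) -> FoldPlan:
    """Greedy residue-balanced K-fold split of chains (deterministic in seed).

    Chains are shuffled (seeded), ordered by decreasing length, and assigned
    one at a time to the currently lightest fold, which bounds the residue
    imbalance between folds by the longest chain length.
    """
    if len(chain_lengths) < k:
        raise ValueError(f"need at least {k} chains for {k} folds, got {len(chain_lengths)}")
    rng = np.random.default_rng(seed)
    ids = list(chain_lengths)
    rng.shuffle(ids)
    ids.sort(key=lambda c: -chain_lengths[c])  # stable: seeded order breaks ties
    loads = [0] * k
    fold_of: dict[str, int] = {}
    for cid in ids:
        f = int(np.argmin(loads))
        fold_of[cid] = f
        loads[f] += chain_lengths[cid]
    return FoldPlan(k=k, fold_of=fold_of)


def _net_sort_key(net: TrainedNetwork):
    m = net.leaveout_mcc
    return (-(m if not math.isnan(m) else -math.inf), net.config.window,
            net.config.hidden, net.fold_id)


@dataclass
class EnsembleSpec:
    """Member networks sorted descending by leave-out MCC."""

    members: list[TrainedNetwork]
    mode: str = "top"  # "top" (first layer) or "per_fold" (second layer)

    def members_for_fold(self, fold: int) -> list[TrainedNetwork]:
        return [m for m in self.members if m.fold_id == fold]


def train_grid(
    tracks: dict[str, ResidueFeatureTrack],
    labels: dict[str, np.ndarray],
    plan: FoldPlan,
    windows: tuple[int, ...] = (5, 7, 9, 11, 13),
    hiddens: tuple[int, ...] = (50, 75, 100, 125),
    learning_rate: float = 0.01,
    max_epochs: int = 300,
    seed: int = 0,
    track_name: str = "G",
) -> list[TrainedNetwork]:
    """Train every (window, hidden, fold) combination on one label track.

    Returns len(windows)*len(hiddens)*K networks, each trained on its fold's
    training chains, epoch-selected on its held-out fold, with the leave-out
    MCC recorded.  Network seeds are derived deterministically from `seed`
    and the grid coordinates.
    """
    order = sorted(tracks)
    if set(order) != set(labels) or set(order) != set(plan.fold_of):
        raise ValueError("tracks, labels and fold plan must cover the same chains")
    nets: list[TrainedNetwork] = []
    for ai, (w, h) in enumerate((w, h) for w in windows for h in hiddens):
        xw = {c: window_matrix(tracks[c], w) for c in order}
        for fold in range(plan.k):
            train_ids = [c for c in order if plan.fold_of[c] != fold]
            test_ids = [c for c in order if plan.fold_of[c] == fold]
            x_train = np.vstack([xw[c] for c in train_ids])
            y_train = np.concatenate([labels[c] for c in train_ids])
            x_test = np.vstack([xw[c] for c in test_ids])
            y_test = np.concatenate([labels[c] for c in test_ids])
            cfg = TrainConfig(
                window=w,
                hidden=h,
                learning_rate=learning_rate,
                max_epochs=max_epochs,
                seed=(seed * 1000003 + ai * 101 + fold) % (2**31),
            )
            net = train_backprop(x_train, y_train, x_test, y_test, cfg, fold_id=fold)
            net.name = f"{track_name}/w{w}h{h}f{fold}"
            net.train_chain_ids = tuple(train_ids)
            nets.append(net)
    return nets


def select_ensemble(
    networks: list[TrainedNetwork], size: int | None = None, mode: str = "top"
) -> EnsembleSpec:
    """Rank fold-networks by leave-out MCC and keep the ensemble members.

    ``mode="top"`` keeps the `size` best fold-networks overall (first-layer
    rule); ``mode="per_fold"`` keeps the single best network within each
    fold subset (second-layer rule).  Ties break toward smaller window,
    fewer hidden units, lower fold id.
    """
    ranked = sorted(networks, key=_net_sort_key)
    if mode == "top":
        if size is None:
            raise ValueError("size is required for top-k selection")
        if len(ranked) < size:
            raise ValueError(f"need at least {size} networks, got {len(ranked)}")
        return EnsembleSpec(members=ranked[:size], mode="top")
    if mode == "per_fold":
        folds = sorted({n.fold_id for n in ranked})
        members = []
        for f in folds:
            members.append(next(n for n in ranked if n.fold_id == f))
        members.sort(key=_net_sort_key)
        return EnsembleSpec(members=members, mode="per_fold")
    raise ValueError(f"unknown selection mode {mode!r}")


def ensemble_predict(
    spec: EnsembleSpec | list[TrainedNetwork], track: ResidueFeatureTrack
) -> np.ndarray:
    """Unweighted mean of member scores over one chain track."""
    members = spec.members if isinstance(spec, EnsembleSpec) else spec
    if not members:
        raise ValueError("ensemble has no members")
    scores = np.zeros(len(track))
    for m in members:
        scores += forward(m, window_matrix(track, m.config.window))
    return scores / len(members)


# ---------------------------------------------------------------------------
# Two-layer topology


@dataclass
class LayeredModel:
    """Trained two-layer predictor: first-layer ensembles feeding a second layer."""

    setup: str
    first_layer: dict[str, EnsembleSpec]   # keys: "G", "P1".."P4", optionally "S:<type>"
    second_layer: dict[str, EnsembleSpec]  # keys: "G", optionally "S:<type>"
    threshold: float = DEFAULT_THRESHOLD


@dataclass
class LayeredResult:
    """A LayeredModel plus the cross-validation byproducts used to audit it."""

    model: LayeredModel
    plan: FoldPlan
    first_networks: dict[str, list[TrainedNetwork]]
    second_networks: dict[str, list[TrainedNetwork]]
    oof_first: dict[str, dict[str, np.ndarray]]   # chain -> {"G": (L,), "P": (L,4)}
    oof_second: dict[str, np.ndarray]             # chain -> second-layer G scores
    oof_members: dict[tuple[str, str], list[str]]  # (chain, layer-track) -> member names
    labels: dict[str, np.ndarray]                 # chain -> general turn labels


def _oof_members(
    ensemble: EnsembleSpec, all_networks: list[TrainedNetwork], fold: int
) -> list[TrainedNetwork]:
    """Ensemble members valid for scoring a chain of `fold`; if selection
    dropped every network of that fold, fall back to the fold's best."""
    members = ensemble.members_for_fold(fold)
    if members:
        return members
    fold_nets = [n for n in all_networks if n.fold_id == fold]
    if not fold_nets:
        raise ValueError(f"no networks trained for fold {fold}")
    return [min(fold_nets, key=_net_sort_key)]


def train_layered(
    dataset,
    setup: str = "M",
    k: int = 10,
    windows: tuple[int, ...] = (5, 7, 9, 11, 13),
    hiddens: tuple[int, ...] = (50, 75, 100, 125),
    second_windows: tuple[int, ...] | None = None,
    second_hiddens: tuple[int, ...] | None = None,
    aux_windows: tuple[int, ...] | None = None,
    aux_hiddens: tuple[int, ...] | None = None,
    ensemble_size: int = 100,
    learning_rate: float = 0.01,
    max_epochs: int = 300,
    seed: int = 0,
    train_types: bool = False,
    threshold: float = DEFAULT_THRESHOLD,
) -> LayeredResult:
    """Train the full two-layer method on an annotated dataset.

    `dataset` is a sequence of objects with attributes ``chain_id``,
    ``annotation``, ``profile`` and ``struct`` (e.g. synthetic fixture
    chains).  First-layer G and P1..P4 ensembles (plus S-type ensembles when
    `train_types`) are trained on profile + sec/rsa windows; cross-validated
    first-layer outputs — out-of-fold for every residue — feed the
    second-layer networks composed per `setup`.
    """
    setup = setup.upper()
    if setup not in SETUPS:
        raise ValueError(f"unknown setup {setup!r}; expected one of A..M")
    if second_windows is None:
        second_windows = windows
    if second_hiddens is None:
        second_hiddens = hiddens
    if aux_windows is None:
        aux_windows = windows
    if aux_hiddens is None:
        aux_hiddens = hiddens
    by_id = {item.chain_id: item for item in dataset}
    plan = make_folds({c: len(by_id[c].annotation.in_turn) for c in by_id}, k=k, seed=seed)

    tracks = {c: first_layer_track(by_id[c].profile, by_id[c].struct) for c in by_id}
    gen_labels: dict[str, np.ndarray] = {}
    pos_labels: dict[str, dict[int, np.ndarray]] = {}
    type_labels: dict[str, dict[str, np.ndarray]] = {}
    for c, item in by_id.items():
        general, by_type, by_pos = label_sets(item.annotation)
        gen_labels[c] = general
        pos_labels[c] = by_pos
        type_labels[c] = by_type

    first_track_defs: dict[str, dict[str, np.ndarray]] = {"G": gen_labels}
    for p in (1, 2, 3, 4):
        first_track_defs[f"P{p}"] = {c: pos_labels[c][p] for c in by_id}
    if train_types:
        for t in TURN_TYPES:
            track_labels = {c: type_labels[c][t] for c in by_id}
            if _trainable(track_labels, plan):
                first_track_defs[f"S:{t}"] = track_labels

    first_networks: dict[str, list[TrainedNetwork]] = {}
    first_ens: dict[str, EnsembleSpec] = {}
    for ti, (name, labels) in enumerate(first_track_defs.items()):
        nets = train_grid(
            tracks, labels, plan,
            windows=windows if name == "G" else aux_windows,
            hiddens=hiddens if name == "G" else aux_hiddens,
            learning_rate=learning_rate, max_epochs=max_epochs,
            seed=seed * 37 + ti, track_name=name,
        )
        first_networks[name] = nets
        first_ens[name] = select_ensemble(nets, size=min(ensemble_size, len(nets)), mode="top")

    # cross-validated first-layer outputs (strictly out-of-fold per chain)
    oof_first: dict[str, dict[str, np.ndarray]] = {}
    oof_members: dict[tuple[str, str], list[str]] = {}
    for c in by_id:
        fold = plan.fold_of[c]
        out: dict[str, np.ndarray] = {}
        g_members = _oof_members(first_ens["G"], first_networks["G"], fold)
        out["G"] = ensemble_predict(g_members, tracks[c])
        oof_members[(c, "G")] = [m.name for m in g_members]
        pos_cols = []
        for p in (1, 2, 3, 4):
            members = _oof_members(first_ens[f"P{p}"], first_networks[f"P{p}"], fold)
            pos_cols.append(ensemble_predict(members, tracks[c]))
            oof_members[(c, f"P{p}")] = [m.name for m in members]
        out["P"] = np.column_stack(pos_cols)
        for name in first_track_defs:
            if name.startswith("S:"):
                members = _oof_members(first_ens[name], first_networks[name], fold)
                out[name] = ensemble_predict(members, tracks[c])
                oof_members[(c, name)] = [m.name for m in members]
        oof_first[c] = out

    def _second_track(c: str, extra: np.ndarray | None = None) -> ResidueFeatureTrack:
        item = by_id[c]
        tr = build_second_layer_track(
            setup,
            gen_scores=oof_first[c]["G"],
            pos_scores=oof_first[c]["P"],
            struct=item.struct,
            profile=item.profile,
        )
        if extra is None:
            return tr
        matrix = np.column_stack([tr.matrix, extra])
        pad = np.concatenate([tr.pad_vector, [0.0]])
        return ResidueFeatureTrack(matrix=matrix, pad_vector=pad)

    second_networks: dict[str, list[TrainedNetwork]] = {}
    second_ens: dict[str, EnsembleSpec] = {}
    second_tracks = {c: _second_track(c) for c in by_id}
    nets2 = train_grid(
        second_tracks, gen_labels, plan,
        windows=second_windows, hiddens=second_hiddens,
        learning_rate=learning_rate, max_epochs=max_epochs,
        seed=seed * 37 + 1000, track_name="L2-G",
    )
    second_networks["G"] = nets2
    second_ens["G"] = select_ensemble(nets2, mode="per_fold")
    if train_types:
        for ti, t in enumerate(TURN_TYPES):
            name = f"S:{t}"
            if name not in first_ens:
                continue
            s_tracks = {c: _second_track(c, extra=oof_first[c][name]) for c in by_id}
            s_labels = {c: type_labels[c][t] for c in by_id}
            nets_s = train_grid(
                s_tracks, s_labels, plan,
                windows=second_windows, hiddens=second_hiddens,
                learning_rate=learning_rate, max_epochs=max_epochs,
                seed=seed * 37 + 2000 + ti, track_name=f"L2-{name}",
            )
            second_networks[name] = nets_s
            second_ens[name] = select_ensemble(nets_s, mode="per_fold")

    oof_second: dict[str, np.ndarray] = {}
    for c in by_id:
        fold = plan.fold_of[c]
        members = _oof_members(second_ens["G"], second_networks["G"], fold)
        oof_second[c] = ensemble_predict(members, second_tracks[c])
        oof_members[(c, "L2-G")] = [m.name for m in members]

    model = LayeredModel(
        setup=setup,
        first_layer=first_ens,
        second_layer=second_ens,
        threshold=threshold,
    )
    return LayeredResult(
        model=model,
        plan=plan,
        first_networks=first_networks,
        second_networks=second_networks,
        oof_first=oof_first,
        oof_second=oof_second,
        oof_members=oof_members,
        labels=gen_labels,
    )


def _trainable(labels: dict[str, np.ndarray], plan: FoldPlan) -> bool:
    """Every fold's train and test split must contain both classes."""
    for fold in range(plan.k):
        for ids in (plan.chains_in(fold), plan.train_chains(fold)):
            y = np.concatenate([labels[c] for c in ids])
            if y.all() or (~y).all():
                return False
    return True


def predict_chain(
    model: LayeredModel,
    sequence: str,
    profile: SequenceProfile,
    struct: StructTracks,
    chain_id: str = "A",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Predict per-residue turn scores for a new chain.

    Returns one row per residue with the general (second-layer) turn score,
    the binary call at the model threshold, the nine type scores (NaN when
    type networks were not trained) and the four first-layer position
    scores.
    """
    if len(sequence) != len(profile.sequence) or len(struct) != len(sequence):
        raise ValueError("sequence, profile and structure tracks differ in length")
    if threshold is None:
        threshold = model.threshold
    track = first_layer_track(profile, struct)
    gen = ensemble_predict(model.first_layer["G"], track)
    pos = np.column_stack(
        [ensemble_predict(model.first_layer[f"P{p}"], track) for p in (1, 2, 3, 4)]
    )
    base_l2 = build_second_layer_track(
        model.setup, gen_scores=gen, pos_scores=pos, struct=struct, profile=profile
    )
    final = ensemble_predict(model.second_layer["G"], base_l2)
    out = {
        "chain": chain_id,
        "pos": np.arange(1, len(sequence) + 1),
        "aa": list(sequence),
        "turn_score": final,
        "call": (final >= threshold).astype(int),
    }
    for t in TURN_TYPES:
        key = f"S:{t}"
        if key in model.second_layer:
            first_s = ensemble_predict(model.first_layer[key], track)
            matrix = np.column_stack([base_l2.matrix, first_s])
            pad = np.concatenate([base_l2.pad_vector, [0.0]])
            s_track = ResidueFeatureTrack(matrix=matrix, pad_vector=pad)
            out[t] = ensemble_predict(model.second_layer[key], s_track)
        else:
            out[t] = np.full(len(sequence), np.nan)
    for p in (1, 2, 3, 4):
        out[f"P{p}"] = pos[:, p - 1]
    return pd.DataFrame(out)


def audit_no_leakage(result: LayeredResult) -> bool:
    """Verify that every cross-validated score is out-of-fold.

    For each chain, every network that contributed to its reported first- or
    second-layer score must have the chain's fold as its held-out fold and
    must not list the chain among its training chains.  Raises
    ``AssertionError`` on any violation; returns True otherwise.
    """
    all_nets = {
        n.name: n
        for nets in list(result.first_networks.values())
        + list(result.second_networks.values())
        for n in nets
    }
    for (chain, track), names in result.oof_members.items():
        fold = result.plan.fold_of[chain]
        for name in names:
            net = all_nets[name]
            assert net.fold_id == fold, (
                f"network {name} (fold {net.fold_id}) scored chain {chain} of fold {fold}"
            )
            assert chain not in net.train_chain_ids, (
                f"network {name} was trained on chain {chain} it scored"
            )
    return True


# ---------------------------------------------------------------------------
# Model bundle serialization (text only: manifest + one JSON per network)


def save_model(model: LayeredModel, directory: str | pathlib.Path) -> None:
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"setup": model.setup, "threshold": model.threshold, "ensembles": {}}
    for layer, ensembles in (("first", model.first_layer), ("second", model.second_layer)):
        for name, spec in ensembles.items():
            files = []
            safe = name.replace(":", "-").replace("'", "p")
            for i, net in enumerate(spec.members):
                fname = f"{layer}_{safe}_{i:03d}.json"
                (directory / fname).write_text(network_to_json(net))
                files.append(fname)
            manifest["ensembles"][f"{layer}/{name}"] = {"mode": spec.mode, "files": files}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(directory: str | pathlib.Path) -> LayeredModel:
    directory = pathlib.Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    first: dict[str, EnsembleSpec] = {}
    second: dict[str, EnsembleSpec] = {}
    for key, entry in manifest["ensembles"].items():
        layer, name = key.split("/", 1)
        members = [
            network_from_json((directory / f).read_text()) for f in entry["files"]
        ]
        spec = EnsembleSpec(members=members, mode=entry["mode"])
        (first if layer == "first" else second)[name] = spec
    return LayeredModel(
        setup=manifest["setup"],
        first_layer=first,
        second_layer=second,
        threshold=manifest["threshold"],
    )
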
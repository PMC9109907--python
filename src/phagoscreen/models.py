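"""Model configurations: embedding module + output head, fit and predict.

Seven named configurations pair an embedding family with an output head:

===========  =================  ===========
name         embedding family   output head
===========  =================  ===========
``LinNN``    linear (no bonds)  MLP
``MoRF``     static fingerprint random forest
``MoNN``     static fingerprint MLP
``SAGENN``   GraphSAGE          MLP
``GaNN``     GAT (attention)    MLP
``ENN``      bond-conditioned   MLP
``NeFPNN``   neural fingerprint MLP
===========  =================  ===========

Prediction is ``o = f_out(h_c, d)``: the compound embedding is concatenated
with the dose (linearly rescaled to [0, 1] over the training dose ladder by
default) and passed to the head.  MLP heads are trained by mini-batch
cross-entropy with optional per-epoch majority undersampling; the forest
head is fitted once on static fingerprints plus dose, without undersampling
(forests tolerate the class imbalance).
"""

from __future__ import annotations

import io
import json
import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .molgraph import DEFAULT_FEATURES, MolecularGraph, compute_fingerprint, parse_smiles
from .nn import (
    CompiledGraph,
    batch_graphs,
    compile_graph,
    embed_forward,
    head_forward,
    init_params,
)
from .screenlab import ScreenDataset

__all__ = [
    "EMBEDDING_FAMILIES", "NAMED_CONFIGS", "ModelSpec", "TrainedModel",
    "embed_compound", "fit", "predict", "predict_batch",
    "save_model", "load_model",
]

EMBEDDING_FAMILIES = ("static_fp", "linear", "sage", "gat", "ecc", "nefp")
OUTPUT_HEADS = ("mlp", "forest")

NAMED_CONFIGS = {
    "LinNN": ("linear", "mlp"),
    "MoRF": ("static_fp", "forest"),
    "MoNN": ("static_fp", "mlp"),
    "SAGENN": ("sage", "mlp"),
    "GaNN": ("gat", "mlp"),
    "ENN": ("ecc", "mlp"),
    "NeFPNN": ("nefp", "mlp"),
}

DEFAULT_HYPER = {
    "layers": 2,
    "hidden": 64,
    "readout": "mean",
    "head_hidden": [64],
    "edge_hidden": 16,
    "lr": 3e-3,
    "epochs": 60,
    "batch_size": 64,
    "seed": 0,
    "fp_radius": 3,
    "fp_length": 1024,
    "dose_mode": "scaled",  # or "raw"
    "n_estimators": 200,
    "undersample": True,
}


@dataclass(frozen=True)
class ModelSpec:
    """An (embedding family, output head, hyper-parameters) choice."""

    embedding_family: str
    output_head: str
    hyper_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.embedding_family not in EMBEDDING_FAMILIES:
            raise ValueError(f"unknown embedding family {self.embedding_family!r}")
        if self.output_head not in OUTPUT_HEADS:
            raise ValueError(f"unknown output head {self.output_head!r}")
        if self.output_head == "forest" and self.embedding_family != "static_fp":
            raise ValueError("the forest head is only valid with the static fingerprint embedding")

    @classmethod
    def named(cls, name: str, **hyper) -> "ModelSpec":
        """Construct one of the seven named configurations."""
        if name not in NAMED_CONFIGS:
            raise ValueError(f"unknown configuration {name!r}; choose from {sorted(NAMED_CONFIGS)}")
        family, head = NAMED_CONFIGS[name]
        return cls(family, head, dict(hyper))

    @property
    def hyper(self) -> dict:
        h = dict(DEFAULT_HYPER)
        h.update(self.hyper_params)
        return h

    def with_params(self, **updates) -> "ModelSpec":
        merged = dict(self.hyper_params)
        merged.update(updates)
        return replace(self, hyper_params=merged)


@dataclass
class TrainedModel:
    """A fitted model: spec, parameters, and the vocabularies seen at fit."""

    spec: ModelSpec
    classes: tuple[str, ...]
    doses: tuple[float, ...]
    params: dict | None = None      # name -> np.ndarray (neural path)
    forest: object | None = None    # sklearn RandomForestClassifier
    atom_dim: int = DEFAULT_FEATURES.atom_dim
    bond_dim: int = DEFAULT_FEATURES.bond_dim

    @property
    def is_fitted(self) -> bool:
        return self.params is not None or self.forest is not None

    def scale_dose(self, doses: np.ndarray) -> np.ndarray:
        h = self.spec.hyper
        if h["dose_mode"] == "raw":
            return np.asarray(doses, dtype=float)
        lo, hi = min(self.doses), max(self.doses)
        if hi == lo:
            return np.full(len(doses), 0.5)
        return (np.asarray(doses, dtype=float) - lo) / (hi - lo)


def _graph_of(compound) -> MolecularGraph:
    return parse_smiles(compound) if isinstance(compound, str) else compound


def _static_embedding(spec: ModelSpec, graphs: list[MolecularGraph]) -> np.ndarray:
    h = spec.hyper
    return np.stack(
        [compute_fingerprint(g, h["fp_radius"], h["fp_length"]).bits for g in graphs]
    ).astype(np.float64)


def _check_bond_features(spec: ModelSpec, graphs: list[MolecularGraph]) -> None:
    if spec.embedding_family in ("ecc", "nefp"):
        for g in graphs:
            if g.E.shape[1] == 0:
                raise ValueError(
                    f"{spec.embedding_family} requires bond features, but the graph "
                    f"from {g.source_smiles!r} carries none"
                )


def _neural_embed(
    spec: ModelSpec, params: dict[str, Tensor], compiled: list[CompiledGraph]
) -> Tensor:
    h = spec.hyper
    batch = batch_graphs(compiled, add_self_loops=spec.embedding_family == "gat")
    return embed_forward(
        spec.embedding_family, params, batch,
        layers=h["layers"], hidden=h["hidden"],
        atom_dim=compiled[0].X.shape[1], readout=h["readout"],
    )


def _init_for(spec: ModelSpec, atom_dim: int, bond_dim: int, n_classes: int,
              rng: np.random.Generator) -> dict[str, Tensor]:
    h = spec.hyper
    return init_params(
        spec.embedding_family, atom_dim, bond_dim,
        hidden=h["hidden"], layers=h["layers"], head_hidden=list(h["head_hidden"]),
        n_classes=n_classes, edge_hidden=h["edge_hidden"], rng=rng,
        embedding_dim=h["fp_length"] if spec.embedding_family == "static_fp" else None,
    )


def embed_compound(
    spec: ModelSpec, graph: MolecularGraph | str, params: dict | None = None
) -> np.ndarray:
    """h_c = f_comp(c): the compound embedding vector.

    For ``static_fp`` this is the circular fingerprint.  For the adaptive
    families, ``params`` may be the fitted parameter dict of a
    :class:`TrainedModel`; without it, weights are initialized
    deterministically from the spec's seed (useful for probing the
    architecture's invariances before training).
    """
    graph = _graph_of(graph)
    if graph.is_empty:
        raise ValueError(f"cannot embed an empty graph (from {graph.source_smiles!r})")
    if spec.embedding_family == "static_fp":
        return _static_embedding(spec, [graph])[0]
    _check_bond_features(spec, [graph])
    if params is None:
        rng = np.random.default_rng(spec.hyper["seed"])
        tparams = _init_for(spec, graph.X.shape[1], graph.E.shape[1], 3, rng)
    else:
        tparams = {k: Tensor(np.asarray(v)) for k, v in params.items()}
    return _neural_embed(spec, tparams, [compile_graph(graph)]).data[0]


def fit(
    spec: ModelSpec,
    train: ScreenDataset,
    config: dict | None = None,
    undersampler=None,
) -> TrainedModel:
    """Fit a model on a labeled screen dataset.

    ``undersampler`` is a callback ``(indices, labels, seed, epoch) ->
    subset`` applied before each epoch of neural training (defaults to the
    evaluation module's majority undersampler); the forest path bypasses it.
    All randomness flows from the spec's seed; refitting with the same seed
    reproduces predictions exactly.
    """
    if config:
        spec = spec.with_params(**config)
    h = spec.hyper
    counts = train.class_counts()
    missing = [c for c, k in counts.items() if k == 0]
    if missing:
        raise ValueError(f"training set has no instances of class(es): {missing}")

    classes = tuple(train.classes)
    class_idx = {c: i for i, c in enumerate(classes)}
    labels = np.array([class_idx[r.label] for r in train.records], dtype=np.int64)
    doses = np.array([r.dose for r in train.records], dtype=float)
    graph_cache: dict[str, MolecularGraph] = {}
    graphs = []
    for r in train.records:
        if r.smiles not in graph_cache:
            graph_cache[r.smiles] = parse_smiles(r.smiles)
        graphs.append(graph_cache[r.smiles])
    _check_bond_features(spec, graphs)

    model = TrainedModel(
        spec=spec, classes=classes, doses=tuple(sorted(set(doses.tolist()))),
        atom_dim=graphs[0].X.shape[1], bond_dim=graphs[0].E.shape[1],
    )
    dose_scaled = model.scale_dose(doses)

    if spec.output_head == "forest":
        from sklearn.ensemble import RandomForestClassifier

        Xfp = _static_embedding(spec, graphs)
        X = np.column_stack([Xfp, dose_scaled])
        forest = RandomForestClassifier(
            n_estimators=h["n_estimators"], random_state=h["seed"], n_jobs=1
        )
        forest.fit(X, labels)
        model.forest = forest
        return model

    rng = np.random.default_rng(h["seed"])
    static = spec.embedding_family == "static_fp"
    if static:
        Xfp = _static_embedding(spec, graphs)
        compiled = None
    else:
        compile_cache = {s: compile_graph(g) for s, g in graph_cache.items()}
        compiled = [compile_cache[r.smiles] for r in train.records]

    params = _init_for(spec, graphs[0].X.shape[1], graphs[0].E.shape[1], len(classes), rng)
    opt = Adam(params, lr=h["lr"])
    if undersampler is None and h["undersample"]:
        from .evaluate import undersample_epoch as undersampler  # noqa: PLW0127

    all_idx = np.arange(len(train.records))
    label_list = [r.label for r in train.records]
    n_head = len(h["head_hidden"])
    for epoch in range(h["epochs"]):
        if undersampler is not None and h["undersample"]:
            idx = np.asarray(undersampler(all_idx, label_list, h["seed"], epoch))
        else:
            idx = all_idx
        idx = idx[rng.permutation(len(idx))]
        for start in range(0, len(idx), h["batch_size"]):
            mb = idx[start : start + h["batch_size"]]
            if static:
                h_c = Tensor(Xfp[mb], requires_grad=False)
            else:
                h_c = _neural_embed(spec, params, [compiled[i] for i in mb])
            logits = head_forward(params, h_c, dose_scaled[mb], n_head)
            loss = ad.cross_entropy(logits, labels[mb])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (family={spec.embedding_family}, "
                    f"lr={h['lr']}); lower the learning rate"
                )
            opt.zero_grad()
            ad.backward(loss)
            opt.step()
    model.params = {k: t.data.copy() for k, t in params.items()}
    return model


def predict_batch(
    model: TrainedModel, compounds: list, doses: np.ndarray
) -> np.ndarray:
    """Class-score matrix (n, n_classes) for paired compounds and doses.

    MLP heads return softmax probabilities; the forest head returns vote
    fractions.  Columns follow ``model.classes``.
    """
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    graphs = [_graph_of(c) for c in compounds]
    for g in graphs:
        if g.is_empty:
            raise ValueError(f"cannot embed an empty graph (from {g.source_smiles!r})")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    dose_scaled = model.scale_dose(doses)
    spec = model.spec
    if spec.output_head == "forest":
        X = np.column_stack([_static_embedding(spec, graphs), dose_scaled])
        proba = model.forest.predict_proba(X)
        out = np.zeros((len(graphs), len(model.classes)))
        for j, cls_int in enumerate(model.forest.classes_):
            out[:, int(cls_int)] = proba[:, j]
        return out
    params = {k: Tensor(v, requires_grad=False) for k, v in model.params.items()}
    if spec.embedding_family == "static_fp":
        h_c = Tensor(_static_embedding(spec, graphs), requires_grad=False)
    else:
        _check_bond_features(spec, graphs)
        h_c = _neural_embed(spec, params, [compile_graph(g) for g in graphs])
    logits = head_forward(params, h_c, dose_scaled, len(spec.hyper["head_hidden"]))
    return ad.softmax(logits.data)


def predict(model: TrainedModel, graph: MolecularGraph | str, dose: float) -> np.ndarray:
    """Class-score vector o = f_out(f_comp(c), d) for one compound and dose."""
    return predict_batch(model, [graph], np.array([dose]))[0]


def save_model(model: TrainedModel, path) -> None:
    """Serialize spec + parameters + vocabularies into one .npz archive."""
    meta = {
        "spec": {
            "embedding_family": model.spec.embedding_family,
            "output_head": model.spec.output_head,
            "hyper_params": model.spec.hyper_params,
        },
        "classes": list(model.classes),
        "doses": list(model.doses),
        "atom_dim": model.atom_dim,
        "bond_dim": model.bond_dim,
    }
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if model.params is not None:
        for k, v in model.params.items():
            arrays[f"param::{k}"] = v
    if model.forest is not None:
        arrays["__forest__"] = np.frombuffer(pickle.dumps(model.forest), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)


def load_model(path) -> TrainedModel:
    """Reload a model saved by :func:`save_model`; predictions are bit-stable."""
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        spec = ModelSpec(**meta["spec"])
        model = TrainedModel(
            spec=spec,
            classes=tuple(meta["classes"]),
            doses=tuple(meta["doses"]),
            atom_dim=meta["atom_dim"],
            bond_dim=meta["bond_dim"],
        )
        params = {
            k[len("param::"):]: archive[k] for k in archive.files if k.startswith("param::")
        }
        model.params = params or None
        if "__forest__" in archive.files:
            model.forest = pickle.loads(archive["__forest__"].tobytes())
    return model
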
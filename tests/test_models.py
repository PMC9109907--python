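"""Embedding families, output heads, training, serialization."""

import numpy as np
import pytest
from rdkit import Chem

import phagoscreen as ps
from phagoscreen import autodiff as ad
from phagoscreen.autodiff import Tensor
from phagoscreen.models import (
    ModelSpec,
    NAMED_CONFIGS,
    embed_compound,
    load_model,
    predict_batch,
    save_model,
)
from phagoscreen.nn import batch_graphs, compile_graph, embed_forward

FAMILIES = ("linear", "sage", "gat", "ecc", "nefp")
SMALL = dict(layers=2, hidden=8, head_hidden=[8], epochs=2, seed=0)


def permuted_smiles(smiles, seed):
    mol = Chem.MolFromSmiles(smiles)
    rng = np.random.default_rng(seed)
    return Chem.MolToSmiles(
        Chem.RenumberAtoms(mol, rng.permutation(mol.GetNumAtoms()).tolist()),
        canonical=False,
    )


def test_named_configurations_constructible():
    for name, (family, head) in NAMED_CONFIGS.items():
        spec = ModelSpec.named(name)
        assert spec.embedding_family == family
        assert spec.output_head == head


def test_forest_requires_static_fingerprint():
    with pytest.raises(ValueError, match="forest"):
        ModelSpec("gat", "forest")


@pytest.mark.parametrize("family", FAMILIES + ("static_fp",))
def test_embedding_atom_order_invariance(family):
    """h_c identical for any atom ordering of the same molecule."""
    spec = ModelSpec(family, "mlp", dict(SMALL))
    smiles = "CC(=O)Oc1ccccc1C(=O)O"
    ref = embed_compound(spec, smiles)
    for seed in range(5):
        h = embed_compound(spec, permuted_smiles(smiles, seed))
        assert np.allclose(h, ref, atol=1e-9), family


def test_static_fp_embedding_is_the_fingerprint(benzene):
    spec = ModelSpec.named("MoNN")
    h = embed_compound(spec, benzene)
    assert np.array_equal(h, ps.compute_fingerprint(benzene, 3, 1024).bits)


def test_linear_single_atom_sum_readout_is_atom_transform():
    spec = ModelSpec("linear", "mlp", dict(layers=1, hidden=4, readout="sum", seed=1))
    g = ps.parse_smiles("C")
    h = embed_compound(spec, g)
    # reproduce by hand: relu(x W + b) for the single atom
    rng = np.random.default_rng(1)
    from phagoscreen.nn import init_params

    params = init_params("linear", g.X.shape[1], g.E.shape[1], 4, 1, [], 3, 16, rng)
    expected = np.maximum(
        g.X[0].astype(float) @ params["emb.l0.W"].data + params["emb.l0.b"].data, 0
    )
    assert np.allclose(h, expected)


def test_sage_mean_aggregation_hand_computed():
    """1-layer mean aggregation on a 2-node path with identity-like weights."""
    g = ps.parse_smiles("CO")  # two heavy atoms, one bond
    cg = compile_graph(g)
    d = g.X.shape[1]
    params = {
        "emb.l0.Wself": Tensor(np.zeros((d, d))),
        "emb.l0.Wnb": Tensor(np.eye(d)),
        "emb.l0.b": Tensor(np.zeros(d)),
    }
    batch = batch_graphs([cg])
    H = embed_forward("sage", params, batch, layers=1, hidden=d, atom_dim=d, readout="sum")
    # with W_self = 0 and W_nb = I, each node becomes relu(mean of neighbors)
    expected = np.maximum(g.X[[1, 0]].astype(float), 0).sum(axis=0)
    assert np.allclose(H.data[0], expected)


def test_linear_family_blind_to_bond_rewiring():
    """Same atoms, different wiring: the linear embedding cannot tell."""
    spec = ModelSpec("linear", "mlp", dict(SMALL))
    # n-butylbenzene vs (2-methylpropyl)benzene-like isomer sharing per-atom features
    a = embed_compound(spec, "CCc1ccccc1CC")   # ortho-diethylbenzene
    b = embed_compound(spec, "CCc1ccc(CC)cc1")  # para-diethylbenzene
    assert np.allclose(a, b, atol=1e-9)


def test_graph_families_see_topology():
    for family in ("sage", "gat"):
        spec = ModelSpec(family, "mlp", dict(SMALL))
        a = embed_compound(spec, "CCc1ccccc1CC")
        b = embed_compound(spec, "CCc1ccc(CC)cc1")
        assert not np.allclose(a, b, atol=1e-6), family


def test_bond_conditioned_families_react_to_bond_features():
    """ecc/nefp change when a bond's order changes; sage/gat read only atoms.

    Butene isomers keep every atom's feature vector identical only in
    contrived cases, so compare via direct bond-feature perturbation.
    """
    g = ps.parse_smiles("CCCC")
    cg = compile_graph(g)
    perturbed = compile_graph(g)
    ef = perturbed.efeat.copy()
    ef[0] = np.roll(ef[0], 1)  # flip the first bond's type one-hot
    object.__setattr__(perturbed, "efeat", ef)
    for family, should_change in [("ecc", True), ("nefp", True), ("sage", False)]:
        spec = ModelSpec(family, "mlp", dict(SMALL))
        from phagoscreen.models import _init_for

        params = _init_for(spec, g.X.shape[1], g.E.shape[1], 3, np.random.default_rng(0))
        h0 = embed_forward(family, params, batch_graphs([cg]), 2, 8, g.X.shape[1])
        h1 = embed_forward(family, params, batch_graphs([perturbed]), 2, 8, g.X.shape[1])
        changed = not np.allclose(h0.data, h1.data, atol=1e-9)
        assert changed == should_change, family


def test_empty_graph_rejected():
    spec = ModelSpec("sage", "mlp")
    empty = ps.extract_scaffold(ps.parse_smiles("CCCC"))  # empty scaffold sentinel
    with pytest.raises(ValueError, match="empty"):
        embed_compound(spec, empty)


def test_mlp_head_returns_probability_simplex(tiny_dataset):
    model = ps.fit(ModelSpec("linear", "mlp", dict(SMALL)), tiny_dataset)
    smiles = [r.smiles for r in tiny_dataset.records[:10]]
    doses = np.array([r.dose for r in tiny_dataset.records[:10]])
    scores = predict_batch(model, smiles, doses)
    assert scores.shape == (10, 3)
    assert np.allclose(scores.sum(axis=1), 1.0)
    assert (scores >= 0).all()


def test_single_tree_forest_scores_are_one_hot(tiny_dataset):
    spec = ModelSpec.named("MoRF", n_estimators=1, seed=0)
    model = ps.fit(spec, tiny_dataset)
    scores = predict_batch(
        model,
        [r.smiles for r in tiny_dataset.records[:8]],
        np.array([r.dose for r in tiny_dataset.records[:8]]),
    )
    assert np.isin(scores, (0.0, 1.0)).all()
    assert np.allclose(scores.sum(axis=1), 1.0)


def test_fit_requires_every_class(tiny_dataset):
    only_nc = ps.ScreenDataset(
        records=tuple(r for r in tiny_dataset.records if r.label == "no_change"),
        doses=tiny_dataset.doses,
    )
    with pytest.raises(ValueError, match="no instances"):
        ps.fit(ModelSpec("linear", "mlp", dict(SMALL)), only_nc)


def test_training_loss_decreases(tiny_dataset):
    """Cross-entropy on a fixed subset drops over early epochs."""
    from phagoscreen.models import _neural_embed, _init_for
    from phagoscreen.nn import head_forward

    spec = ModelSpec("linear", "mlp", dict(layers=1, hidden=8, head_hidden=[8], lr=1e-2, seed=0))

    def loss_of(model, ds):
        params = {k: Tensor(v, requires_grad=False) for k, v in model.params.items()}
        graphs = [compile_graph(ps.parse_smiles(r.smiles)) for r in ds.records]
        h = _neural_embed(spec, params, graphs)
        logits = head_forward(params, h, model.scale_dose(np.array([r.dose for r in ds.records])), 1)
        labels = np.array([ds.classes.index(r.label) for r in ds.records])
        return float(ad.cross_entropy(logits, labels).data)

    m1 = ps.fit(spec.with_params(epochs=1, undersample=False), tiny_dataset)
    m15 = ps.fit(spec.with_params(epochs=15, undersample=False), tiny_dataset)
    assert loss_of(m15, tiny_dataset) < loss_of(m1, tiny_dataset)


def test_fit_deterministic_under_seed(tiny_dataset):
    spec = ModelSpec("sage", "mlp", dict(SMALL, epochs=3))
    smiles = [r.smiles for r in tiny_dataset.records[:6]]
    doses = np.array([r.dose for r in tiny_dataset.records[:6]])
    s1 = predict_batch(ps.fit(spec, tiny_dataset), smiles, doses)
    s2 = predict_batch(ps.fit(spec, tiny_dataset), smiles, doses)
    assert np.array_equal(s1, s2)


@pytest.mark.parametrize("name", ["GaNN", "MoRF", "LinNN"])
def test_serialization_round_trip(tmp_path, tiny_dataset, name):
    spec = ModelSpec.named(name, **(SMALL | {"n_estimators": 5}))
    model = ps.fit(spec, tiny_dataset)
    smiles = [r.smiles for r in tiny_dataset.records[:5]]
    doses = np.array([r.dose for r in tiny_dataset.records[:5]])
    before = predict_batch(model, smiles, doses)
    path = tmp_path / "model.ckpt"
    save_model(model, path)
    after = predict_batch(load_model(path), smiles, doses)
    assert np.array_equal(before, after)


def test_unfitted_model_rejected():
    from phagoscreen.models import TrainedModel

    model = TrainedModel(spec=ModelSpec("linear", "mlp"), classes=ps.CLASSES, doses=(1.0,))
    with pytest.raises(ValueError, match="not fitted"):
        ps.predict(model, "CCO", 1.0)


def test_dose_enters_prediction(tiny_dataset):
    """A trained head may respond to dose; the wiring must carry it through."""
    spec = ModelSpec("linear", "mlp", dict(SMALL, epochs=5))
    model = ps.fit(spec, tiny_dataset)
    smiles = tiny_dataset.records[0].smiles
    lo = ps.predict(model, smiles, 1.39)
    hi = ps.predict(model, smiles, 22.22)
    assert lo.shape == hi.shape == (3,)
    # scaled dose endpoints differ, so logits differ unless weights are zero
    assert not np.array_equal(lo, hi)
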
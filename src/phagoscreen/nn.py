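"""Neural building blocks: batched molecular graphs, layers, forward passes.

Graphs in a minibatch are packed into one disjoint-union graph: node feature
rows are stacked, every undirected bond contributes two directed edges, and
a ``graph_id`` vector routes the final node states to a per-graph readout
(mean or sum).  Four message-passing layer families are provided:

* ``sage``  -- neighbor-mean aggregation with separate self/neighbor weights
* ``gat``   -- single-head attention-weighted aggregation (with self-loops)
* ``ecc``   -- bond-conditioned convolution: a small MLP maps each bond's
               feature vector to a per-edge weight matrix
* ``nefp``  -- neural-fingerprint style: neighbor states concatenated with
               bond features are summed, then linearly mixed

plus the topology-blind ``linear`` family (a shared per-atom MLP followed by
readout, no message passing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .molgraph import MolecularGraph

__all__ = ["CompiledGraph", "GraphBatch", "compile_graph", "batch_graphs",
           "init_params", "embed_forward", "head_forward"]


@dataclass(frozen=True)
class CompiledGraph:
    """A MolecularGraph lowered to the arrays the forward pass consumes."""

    X: np.ndarray          # (n_atoms, atom_dim)
    src: np.ndarray        # directed edge sources (2 * n_bonds,)
    dst: np.ndarray        # directed edge targets
    efeat: np.ndarray      # (2 * n_bonds, bond_dim)

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]


def compile_graph(graph: MolecularGraph) -> CompiledGraph:
    if graph.is_empty:
        raise ValueError(f"cannot embed an empty graph (from {graph.source_smiles!r})")
    n_bonds = graph.n_bonds
    if n_bonds:
        pairs = np.array(graph.bonds, dtype=np.int64)
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        efeat = np.concatenate([graph.E, graph.E], axis=0).astype(np.float64)
    else:
        src = np.zeros(0, dtype=np.int64)
        dst = np.zeros(0, dtype=np.int64)
        efeat = np.zeros((0, graph.E.shape[1]), dtype=np.float64)
    return CompiledGraph(X=graph.X.astype(np.float64), src=src, dst=dst, efeat=efeat)


@dataclass(frozen=True)
class GraphBatch:
    X: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    efeat: np.ndarray
    graph_id: np.ndarray
    n_graphs: int


def batch_graphs(graphs: list[CompiledGraph], add_self_loops: bool = False) -> GraphBatch:
    """Pack compiled graphs into one disjoint-union batch graph."""
    Xs, srcs, dsts, efs, gids = [], [], [], [], []
    offset = 0
    for gid, g in enumerate(graphs):
        Xs.append(g.X)
        src, dst, ef = g.src, g.dst, g.efeat
        if add_self_loops:
            loops = np.arange(g.n_atoms, dtype=np.int64)
            src = np.concatenate([src, loops])
            dst = np.concatenate([dst, loops])
            ef = np.concatenate([ef, np.zeros((g.n_atoms, ef.shape[1]))], axis=0)
        srcs.append(src + offset)
        dsts.append(dst + offset)
        efs.append(ef)
        gids.append(np.full(g.n_atoms, gid, dtype=np.int64))
        offset += g.n_atoms
    return GraphBatch(
        X=np.concatenate(Xs, axis=0),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        efeat=np.concatenate(efs, axis=0),
        graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
    )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def init_params(
    family: str,
    atom_dim: int,
    bond_dim: int,
    hidden: int,
    layers: int,
    head_hidden: list[int],
    n_classes: int,
    edge_hidden: int,
    rng: np.random.Generator,
    embedding_dim: int | None = None,
) -> dict[str, Tensor]:
    """Fan-in-scaled initialization of all weights for one model.

    ``embedding_dim`` overrides the head's input embedding width (used for
    the static-fingerprint family, whose embedding is the fingerprint
    itself and has no trainable embedding parameters).
    """
    p: dict[str, np.ndarray] = {}
    din = atom_dim
    if family == "linear":
        for i in range(layers):
            p[f"emb.l{i}.W"] = _glorot(rng, din, hidden)
            p[f"emb.l{i}.b"] = np.zeros(hidden)
            din = hidden
    elif family == "sage":
        for i in range(layers):
            p[f"emb.l{i}.Wself"] = _glorot(rng, din, hidden)
            p[f"emb.l{i}.Wnb"] = _glorot(rng, din, hidden)
            p[f"emb.l{i}.b"] = np.zeros(hidden)
            din = hidden
    elif family == "gat":
        for i in range(layers):
            p[f"emb.l{i}.W"] = _glorot(rng, din, hidden)
            p[f"emb.l{i}.asrc"] = _glorot(rng, hidden, 1)
            p[f"emb.l{i}.adst"] = _glorot(rng, hidden, 1)
            p[f"emb.l{i}.b"] = np.zeros(hidden)
            din = hidden
    elif family == "ecc":
        for i in range(layers):
            p[f"emb.l{i}.Wself"] = _glorot(rng, din, hidden)
            p[f"emb.l{i}.b"] = np.zeros(hidden)
            p[f"emb.l{i}.We1"] = _glorot(rng, bond_dim, edge_hidden)
            p[f"emb.l{i}.be1"] = np.zeros(edge_hidden)
            p[f"emb.l{i}.We2"] = _glorot(rng, edge_hidden, din * hidden)
            p[f"emb.l{i}.be2"] = np.zeros(din * hidden)
            din = hidden
    elif family == "nefp":
        for i in range(layers):
            p[f"emb.l{i}.Wself"] = _glorot(rng, din, hidden)
            p[f"emb.l{i}.Wnb"] = _glorot(rng, din + bond_dim, hidden)
            p[f"emb.l{i}.b"] = np.zeros(hidden)
            din = hidden
    elif family == "static_fp":
        din = embedding_dim if embedding_dim is not None else din
    else:
        raise ValueError(f"unknown embedding family {family!r}")

    hin = din + 1  # embedding concatenated with the (scaled) dose
    for i, h in enumerate(head_hidden):
        p[f"head.l{i}.W"] = _glorot(rng, hin, h)
        p[f"head.l{i}.b"] = np.zeros(h)
        hin = h
    p["head.out.W"] = _glorot(rng, hin, n_classes)
    p["head.out.b"] = np.zeros(n_classes)
    return {k: Tensor(v) for k, v in p.items()}


def _linear_layer(p, prefix: str, H: Tensor) -> Tensor:
    return ad.add(ad.matmul(H, p[f"{prefix}.W"]), p[f"{prefix}.b"])


def _sage_layer(p, i: int, H: Tensor, batch: GraphBatch, n_nodes: int) -> Tensor:
    nb = ad.segment_mean(ad.gather(H, batch.src), batch.dst, n_nodes)
    pre = ad.add(
        ad.add(ad.matmul(H, p[f"emb.l{i}.Wself"]), ad.matmul(nb, p[f"emb.l{i}.Wnb"])),
        p[f"emb.l{i}.b"],
    )
    return ad.relu(pre)


def _gat_layer(p, i: int, H: Tensor, batch: GraphBatch, n_nodes: int) -> Tensor:
    Wh = ad.matmul(H, p[f"emb.l{i}.W"])
    hs = ad.gather(Wh, batch.src)
    hd = ad.gather(Wh, batch.dst)
    logits = ad.leaky_relu(
        ad.add(ad.matmul(hs, p[f"emb.l{i}.asrc"]), ad.matmul(hd, p[f"emb.l{i}.adst"]))
    )
    # numerically-stable softmax over the incoming edges of each node
    seg_max = np.full(n_nodes, -np.inf)
    np.maximum.at(seg_max, batch.dst, logits.data[:, 0])
    seg_max[~np.isfinite(seg_max)] = 0.0
    z = ad.exp(ad.sub(logits, Tensor(seg_max[batch.dst, None], requires_grad=False)))
    denom = ad.segment_sum(z, batch.dst, n_nodes)
    alpha = ad.div(z, ad.gather(denom, batch.dst))
    agg = ad.segment_sum(ad.mul(alpha, hs), batch.dst, n_nodes)
    return ad.relu(ad.add(agg, p[f"emb.l{i}.b"]))


def _ecc_layer(p, i: int, H: Tensor, batch: GraphBatch, n_nodes: int, din: int, hidden: int) -> Tensor:
    ef = Tensor(batch.efeat, requires_grad=False)
    e_h = ad.relu(ad.add(ad.matmul(ef, p[f"emb.l{i}.We1"]), p[f"emb.l{i}.be1"]))
    theta_flat = ad.add(ad.matmul(e_h, p[f"emb.l{i}.We2"]), p[f"emb.l{i}.be2"])
    theta = ad.reshape(theta_flat, (batch.efeat.shape[0], din, hidden))
    msg = ad.edge_matvec(ad.gather(H, batch.src), theta)
    agg = ad.segment_mean(msg, batch.dst, n_nodes)
    pre = ad.add(ad.add(ad.matmul(H, p[f"emb.l{i}.Wself"]), agg), p[f"emb.l{i}.b"])
    return ad.relu(pre)


def _nefp_layer(p, i: int, H: Tensor, batch: GraphBatch, n_nodes: int) -> Tensor:
    hs = ad.gather(H, batch.src)
    nb = ad.segment_sum(
        ad.concat([hs, Tensor(batch.efeat, requires_grad=False)], axis=1),
        batch.dst, n_nodes,
    )
    pre = ad.add(
        ad.add(ad.matmul(H, p[f"emb.l{i}.Wself"]), ad.matmul(nb, p[f"emb.l{i}.Wnb"])),
        p[f"emb.l{i}.b"],
    )
    return ad.relu(pre)


def embed_forward(
    family: str,
    params: dict[str, Tensor],
    batch: GraphBatch,
    layers: int,
    hidden: int,
    atom_dim: int,
    readout: str = "mean",
) -> Tensor:
    """Run the embedding module over a batch; returns (n_graphs, hidden)."""
    n_nodes = batch.X.shape[0]
    H = Tensor(batch.X, requires_grad=False)
    din = atom_dim
    for i in range(layers):
        if family == "linear":
            H = ad.relu(_linear_layer(params, f"emb.l{i}", H))
        elif family == "sage":
            H = _sage_layer(params, i, H, batch, n_nodes)
        elif family == "gat":
            H = _gat_layer(params, i, H, batch, n_nodes)
        elif family == "ecc":
            H = _ecc_layer(params, i, H, batch, n_nodes, din, hidden)
        elif family == "nefp":
            H = _nefp_layer(params, i, H, batch, n_nodes)
        else:
            raise ValueError(f"unknown embedding family {family!r}")
        din = hidden
    if readout == "mean":
        return ad.segment_mean(H, batch.graph_id, batch.n_graphs)
    if readout == "sum":
        return ad.segment_sum(H, batch.graph_id, batch.n_graphs)
    raise ValueError(f"unknown readout {readout!r}")


def head_forward(
    params: dict[str, Tensor],
    h_c: Tensor,
    dose_scaled: np.ndarray,
    n_head_layers: int,
) -> Tensor:
    """MLP output head on the concatenation [h_c, d]; returns logits."""
    H = ad.concat([h_c, Tensor(dose_scaled[:, None], requires_grad=False)], axis=1)
    for i in range(n_head_layers):
        H = ad.relu(_linear_layer(params, f"head.l{i}", H))
    return _linear_layer(params, "head.out", H)
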
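"""The GCAP network.

Seven representations of a (drug, ADR) pair are learned and fused:

* ``f_GNN^drug`` — a Multi-level Graph Attention (MGA) encoder over the
  molecular graph: edge-level attention, neighbor-level attention (each
  followed by a GRU state update) and a supernode readout attended over all
  atoms;
* ``f_CNN^drug`` — a multi-scale residual CNN over the embedded one-hot
  SMILES matrix (parallel filter banks of sizes 1/3/5/7, same-length
  padding, residual links, final max-pool);
* ``f_interaction/f_seriousness^drug`` — the drug's rows of R_interaction /
  R_seriousness through fully connected projections;
* ``f_semantic/f_interaction/f_seriousness^ADR`` — the ADR's multi-hot
  semantic vector and matrix columns, likewise projected.

The seven width-d vectors are stacked into a 7 x d matrix M, fused by
multi-head scaled dot-product self-attention, pooled, and fed to two MLP
heads: a 1-unit sigmoid for serious/non-serious and a 7-unit sigmoid for the
seriousness classes (OT..DE order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .featurize.graphs import MolecularGraph
from .nn import Adam, Conv1dSame, GRUCell, Linear, MLPHead, Module, uniform_init


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_width`` must be divisible by both ``fusion_heads`` (head
    concatenation) and the number of CNN scales (channel concatenation);
    scales must be odd so the same-length padding (h-1)/2 is integral.
    """

    hidden_width: int = 64
    mga_layers: int = 2
    supernode_layers: int = 2
    cnn_layers: int = 2
    cnn_scales: tuple[int, ...] = (1, 3, 5, 7)
    fusion_heads: int = 4
    mlp_hidden: int = 128
    literal_eq9: bool = False
    fusion_pool: str = "mean"  # or "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion_heads < 1:
            raise ValueError("need at least one fusion head")
        if self.hidden_width % self.fusion_heads != 0:
            raise ValueError("hidden_width must be divisible by fusion_heads")
        if any(s % 2 == 0 for s in self.cnn_scales):
            raise ValueError("CNN scales must be odd for same-length padding")
        if self.hidden_width % len(self.cnn_scales) != 0:
            raise ValueError("hidden_width must be divisible by the number of CNN scales")
        if self.fusion_pool not in ("mean", "max"):
            raise ValueError("fusion_pool must be 'mean' or 'max'")


@dataclass
class AttentionRecord:
    """Attention coefficients exported from one forward pass.

    Every entry is a plain array; each softmax group sums to 1.  Supernode
    scores give the per-atom contribution to the molecule readout.
    """

    edge_alphas: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    neighbor_alphas: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    supernode_alphas: list[np.ndarray] = field(default_factory=list)

    def supernode_frame(self) -> pd.DataFrame:
        """Per-atom supernode attention as a table (layer, atom, score)."""
        rows = [
            (layer, atom, float(score))
            for layer, alphas in enumerate(self.supernode_alphas)
            for atom, score in enumerate(alphas)
        ]
        return pd.DataFrame(rows, columns=["layer", "atom", "score"])


@dataclass
class PredictionPair:
    """Serious-outcome probability and the 7 class probabilities (OT..DE)."""

    association_score: float
    class_scores: np.ndarray


@dataclass
class PairFeatures:
    """Featurized inputs of one (drug, ADR) pair, as built by gcap.featurize."""

    drug_id: str
    adr_id: str
    graph: MolecularGraph
    smiles_onehot: np.ndarray        # (L, V)
    drug_row_int: np.ndarray         # (m,)
    drug_row_ser: np.ndarray         # (m,)
    adr_semantic: np.ndarray         # (D,)
    adr_col_int: np.ndarray          # (n,)
    adr_col_ser: np.ndarray          # (n,)


def _segment_matrix(segments: np.ndarray, n_segments: int) -> np.ndarray:
    """0/1 matrix S with S[segments[e], e] = 1, for segment sums via matmul."""
    S = np.zeros((n_segments, len(segments)))
    S[segments, np.arange(len(segments))] = 1.0
    return S


def _segment_softmax(z: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of the (E,1) score tensor within each segment (Eq-4 style)."""
    shift = float(z.data.max()) if z.data.size else 0.0
    m = ad.exp(z - shift)
    S = Tensor(_segment_matrix(segments, n_segments))
    denom = S @ m                                   # (n_segments, 1)
    return m / ad.gather_rows(denom, segments)


class MGAEncoder(Module):
    """Multi-level graph attention over one molecular graph.

    Stage 1 attends over incident edge features, stage 2 over neighbor node
    states, stage 3 over all atoms from a supernode initialized as the sum of
    node states.  Each stage owns one GRU shared by its layers and one scalar
    attention scorer per layer.  Isolated nodes pass through unchanged.
    """

    def __init__(self, atom_width: int, bond_width: int, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.hidden_width
        self.cfg = cfg
        self.atom_proj = Linear(atom_width, d, rng)
        self.bond_proj = Linear(bond_width, d, rng)
        self.edge_attn = [Linear(2 * d, 1, rng) for _ in range(cfg.mga_layers)]
        self.edge_gru = GRUCell(d, d, rng)
        self.nbr_attn = [Linear(2 * d, 1, rng) for _ in range(cfg.mga_layers)]
        self.nbr_gru = GRUCell(d, d, rng)
        self.super_attn = [Linear(2 * d, 1, rng) for _ in range(cfg.supernode_layers)]
        self.super_gru = GRUCell(d, d, rng)
        self.out_fc = Linear(d, d, rng)

    def _attention_layer(
        self,
        H: Tensor,
        feats: Tensor,
        attn: Linear,
        gru: GRUCell,
        inc_node: np.ndarray,
        n_atoms: int,
    ) -> tuple[Tensor, np.ndarray]:
        """One attention + GRU update over incident features (Eqs 3-5)."""
        target = ad.gather_rows(H, inc_node)
        z = ad.relu(attn(ad.concat([target, feats], axis=1)))
        alpha = _segment_softmax(z, inc_node, n_atoms)
        S = Tensor(_segment_matrix(inc_node, n_atoms))
        h0 = ad.relu(S @ (alpha * feats))
        H_new = gru(h0, H)
        # isolated nodes (no incident entries) keep their state
        has_inc = np.zeros((n_atoms, 1))
        has_inc[np.unique(inc_node)] = 1.0
        mask = Tensor(has_inc)
        return mask * H_new + (1.0 - mask) * H, alpha.data.ravel()

    def __call__(self, graph: MolecularGraph) -> tuple[Tensor, AttentionRecord]:
        record = AttentionRecord()
        H = ad.relu(self.atom_proj(Tensor(graph.atom_features)))
        A = graph.n_atoms

        if graph.n_bonds > 0:
            E = ad.relu(self.bond_proj(Tensor(graph.bond_features)))
            inc_node = np.array(
                [i for i in range(A) for _ in graph.incidence[i]], dtype=np.int64
            )
            inc_bond = np.array(
                [b for i in range(A) for b in graph.incidence[i]], dtype=np.int64
            )
            inc_nbr = np.array(
                [j for i in range(A) for j in graph.neighbors[i]], dtype=np.int64
            )
            for attn in self.edge_attn:
                feats = ad.gather_rows(E, inc_bond)
                H, alpha = self._attention_layer(H, feats, attn, self.edge_gru, inc_node, A)
                record.edge_alphas.append((inc_node.copy(), alpha))
            for attn in self.nbr_attn:
                feats = ad.gather_rows(H, inc_nbr)
                H, alpha = self._attention_layer(H, feats, attn, self.nbr_gru, inc_node, A)
                record.neighbor_alphas.append((inc_node.copy(), alpha))

        # supernode: initialized as the sum of all node states, attends over atoms
        s = ad.sum_(H, axis=0, keepdims=True)
        ones = Tensor(np.ones((A, 1)))
        for attn in self.super_attn:
            s_rep = ones @ s
            z = ad.relu(attn(ad.concat([s_rep, H], axis=1)))
            alpha = ad.softmax(z, axis=0)
            agg = ad.relu(ad.sum_(alpha * H, axis=0, keepdims=True))
            s = self.super_gru(agg, s)
            record.supernode_alphas.append(alpha.data.ravel())
        return self.out_fc(s), record


class MultiScaleCNN(Module):
    """Residual multi-scale CNN over embedded one-hot SMILES matrices.

    Each layer runs one filter bank per scale (1, 3, 5, 7 by default) with
    same-length padding, ReLU, concatenates the feature maps back to the
    embedding width and adds a residual link to the layer input.  A final
    max-pool over sequence positions yields the drug latent vector.
    """

    def __init__(self, vocab_size: int, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.hidden_width
        per_scale = d // len(cfg.cnn_scales)
        self.embedding = uniform_init(rng, (vocab_size, d), vocab_size)
        self.layers = [
            [Conv1dSame(d, per_scale, h, rng) for h in cfg.cnn_scales]
            for _ in range(cfg.cnn_layers)
        ]

    def __call__(self, onehot: Tensor) -> Tensor:
        x = onehot @ self.embedding            # (B, L, d)
        for bank in self.layers:
            maps = ad.concat([ad.relu(conv(x)) for conv in bank], axis=-1)
            x = maps + x                       # residual between adjacent layers
        return ad.max_(x, axis=1)              # (B, d)


class FusionModule(Module):
    """Multi-head scaled dot-product self-attention over the 7 x d stack.

    Default scores are softmax(Q K^T / sqrt(L_e)) V; ``literal_eq9`` instead
    computes softmax(Q K^T) / sqrt(L_e) V, which differs only by a global
    scale on the attended values.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.hidden_width
        self.cfg = cfg
        self.head_dim = d // cfg.fusion_heads
        self.w_q = [uniform_init(rng, (d, self.head_dim), d) for _ in range(cfg.fusion_heads)]
        self.w_k = [uniform_init(rng, (d, self.head_dim), d) for _ in range(cfg.fusion_heads)]
        self.w_v = [uniform_init(rng, (d, self.head_dim), d) for _ in range(cfg.fusion_heads)]

    def attention_rows(self, M: Tensor) -> np.ndarray:
        """Row-stochastic attention matrices per head, shape (R, ..., 7, 7)."""
        mats = []
        for wq, wk, wv in zip(self.w_q, self.w_k, self.w_v):
            Q, K = M @ wq, M @ wk
            scores = Q @ ad.swapaxes(K, -1, -2)
            if self.cfg.literal_eq9:
                mats.append(ad.softmax(scores, axis=-1).data)
            else:
                mats.append(ad.softmax(scores / np.sqrt(self.head_dim), axis=-1).data)
        return np.stack(mats)

    def __call__(self, M: Tensor) -> Tensor:
        scale = np.sqrt(self.head_dim)
        heads = []
        for wq, wk, wv in zip(self.w_q, self.w_k, self.w_v):
            Q, K, V = M @ wq, M @ wk, M @ wv
            scores = Q @ ad.swapaxes(K, -1, -2)
            if self.cfg.literal_eq9:
                attended = (ad.softmax(scores, axis=-1) / scale) @ V
            else:
                attended = ad.softmax(scores / scale, axis=-1) @ V
            heads.append(attended)
        fused = ad.concat(heads, axis=-1)       # (..., 7, d)
        if self.cfg.fusion_pool == "mean":
            return ad.mean(fused, axis=-2)
        return ad.max_(fused, axis=-2)


class GCAPModel(Module):
    """End-to-end network for one benchmark geometry (n drugs, m ADRs, D, V)."""

    N_REPRESENTATIONS = 7

    def __init__(
        self,
        atom_width: int,
        bond_width: int,
        smiles_vocab_size: int,
        n_drugs: int,
        n_adrs: int,
        semantic_dim: int,
        config: ModelConfig | None = None,
    ):
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        d = cfg.hidden_width
        self.mga = MGAEncoder(atom_width, bond_width, cfg, rng)
        self.cnn = MultiScaleCNN(smiles_vocab_size, cfg, rng)
        # per-input projection encoders, in stack order
        self.proj_graph = Linear(d, d, rng)
        self.proj_cnn = Linear(d, d, rng)
        self.proj_drug_int = Linear(n_adrs, d, rng)
        self.proj_drug_ser = Linear(n_adrs, d, rng)
        self.proj_semantic = Linear(semantic_dim, d, rng)
        self.proj_adr_int = Linear(n_drugs, d, rng)
        self.proj_adr_ser = Linear(n_drugs, d, rng)
        self.fusion = FusionModule(cfg, rng)
        self.head_association = MLPHead(d, cfg.mlp_hidden, 1, rng)
        self.head_severity = MLPHead(d, cfg.mlp_hidden, 7, rng)

    # -- building blocks exposed for inspection/tests -----------------------

    def encode_stack(
        self,
        graph_vec: Tensor,
        cnn_vec: Tensor,
        drug_row_int: Tensor,
        drug_row_ser: Tensor,
        adr_semantic: Tensor,
        adr_col_int: Tensor,
        adr_col_ser: Tensor,
        activation: bool = True,
    ) -> Tensor:
        """Project the seven inputs to width d and stack them into M.

        Inputs are (B, width_i); output is (B, 7, d).  With
        ``activation=False`` the affine projections are returned without the
        ReLU (used to verify the affine contract).
        """
        parts = [
            self.proj_graph(graph_vec),
            self.proj_cnn(cnn_vec),
            self.proj_drug_int(drug_row_int),
            self.proj_drug_ser(drug_row_ser),
            self.proj_semantic(adr_semantic),
            self.proj_adr_int(adr_col_int),
            self.proj_adr_ser(adr_col_ser),
        ]
        if activation:
            parts = [ad.relu(p) for p in parts]
        B, d = parts[0].shape
        rows = [ad.reshape(p, (B, 1, d)) for p in parts]
        return ad.concat(rows, axis=1)

    def fuse(self, stack: Tensor) -> Tensor:
        return self.fusion(stack)

    def predict(self, joint: Tensor) -> tuple[Tensor, Tensor]:
        """Two MLP heads: association probability and 7 class probabilities."""
        return self.head_association(joint), self.head_severity(joint)

    # -- forward -------------------------------------------------------------

    def forward_batch(
        self, batch: list[PairFeatures]
    ) -> tuple[Tensor, Tensor, list[AttentionRecord]]:
        """Score a batch of pairs; graph encodings are shared per unique drug."""
        if not batch:
            raise ValueError("empty batch")
        drug_order: dict[str, int] = {}
        graph_vecs: list[Tensor] = []
        records: dict[str, AttentionRecord] = {}
        onehots: list[np.ndarray] = []
        for pf in batch:
            if pf.drug_id not in drug_order:
                vec, rec = self.mga(pf.graph)
                drug_order[pf.drug_id] = len(graph_vecs)
                graph_vecs.append(vec)
                records[pf.drug_id] = rec
                onehots.append(pf.smiles_onehot)
        idx = np.array([drug_order[pf.drug_id] for pf in batch], dtype=np.int64)

        graph_all = ad.concat(graph_vecs, axis=0)          # (U, d)
        cnn_all = self.cnn(Tensor(np.stack(onehots)))      # (U, d)
        graph_b = ad.gather_rows(graph_all, idx)
        cnn_b = ad.gather_rows(cnn_all, idx)

        stack = self.encode_stack(
            graph_b,
            cnn_b,
            Tensor(np.stack([pf.drug_row_int for pf in batch])),
            Tensor(np.stack([pf.drug_row_ser for pf in batch])),
            Tensor(np.stack([pf.adr_semantic for pf in batch])),
            Tensor(np.stack([pf.adr_col_int for pf in batch])),
            Tensor(np.stack([pf.adr_col_ser for pf in batch])),
        )
        joint = self.fuse(stack)
        assoc, classes = self.predict(joint)
        return assoc, classes, [records[pf.drug_id] for pf in batch]

    def forward(self, pair: PairFeatures) -> tuple[PredictionPair, AttentionRecord]:
        """Deterministic single-pair forward pass."""
        assoc, classes, recs = self.forward_batch([pair])
        return (
            PredictionPair(
                association_score=float(assoc.data[0, 0]),
                class_scores=classes.data[0].copy(),
            ),
            recs[0],
        )
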
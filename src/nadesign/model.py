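"""Unified protein/DNA/RNA message-passing network.

Encoder layers pass messages over the residue graph and update both node and
edge states; the decoder is a random-order autoregressive stack in which each
position's logits depend only on the structure, on residues held fixed, and
on residues decoded earlier in the order.  The output head spans 26 tokens:
21 protein (20 amino acids + unknown) and 5 shared nucleic tokens, the deoxy
and ribo spellings of each base collapsing onto one id.

Sequence design samples the 4 canonical nucleic tokens at low temperature
with partial fixation; binding-specificity prediction repeats stochastic
decoding with the nucleic sequence hidden and averages the per-position
conditional distributions into a predicted position probability matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .featurize import (
    GraphFeatures,
    N_EDGE_EXTRA,
    N_POLYMER_TYPES,
    N_RBF,
    N_SLOTS,
    build_graph,
)
from .structures import (
    Complex,
    NA_CANONICAL,
    N_TOKENS,
    PolymerClass,
    TOKEN_NA_UNK,
    na_token_to_letter,
)

DESIGN_TEMPERATURE = 0.1
DESIGN_N_SAMPLES = 10
SPECIFICITY_TEMPERATURE = 0.6
SPECIFICITY_N_SAMPLES = 30


@dataclass
class ModelConfig:
    hidden_dim: int = 128
    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    k_neighbors: int = 32
    n_rbf: int = N_RBF
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_dim, self.n_encoder_layers, self.n_decoder_layers, self.k_neighbors) <= 0:
            raise ValueError("model dimensions must be positive")


class ConfigurationError(Exception):
    pass


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(np.float32)


def init_params(cfg: ModelConfig) -> dict:
    """Glorot-initialized parameter set for the full encoder–decoder stack."""
    rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden_dim
    edge_in = N_SLOTS * N_SLOTS * cfg.n_rbf + N_EDGE_EXTRA
    p = {}

    def lin(name, fi, fo, bias=True):
        p[f"{name}.W"] = ad.parameter(_glorot(rng, fi, fo))
        if bias:
            p[f"{name}.b"] = ad.parameter(np.zeros(fo, dtype=np.float32))

    def ln(name, d):
        p[f"{name}.g"] = ad.parameter(np.ones(d, dtype=np.float32))
        p[f"{name}.b"] = ad.parameter(np.zeros(d, dtype=np.float32))

    lin("node_embed0", N_POLYMER_TYPES, h, bias=False)
    ln("node_embed_ln", h)
    lin("node_embed1", h, h)
    lin("edge_embed", edge_in, h)
    ln("edge_embed_ln", h)

    for l in range(cfg.n_encoder_layers):
        lin(f"enc{l}.msg0", 3 * h, h)
        lin(f"enc{l}.msg1", h, h)
        lin(f"enc{l}.msg2", h, h)
        ln(f"enc{l}.norm1", h)
        lin(f"enc{l}.ff0", h, 4 * h)
        lin(f"enc{l}.ff1", 4 * h, h)
        ln(f"enc{l}.norm2", h)
        lin(f"enc{l}.edge0", 3 * h, h)
        lin(f"enc{l}.edge1", h, h)
        lin(f"enc{l}.edge2", h, h)
        ln(f"enc{l}.norm3", h)

    p["seq_embed.W"] = ad.parameter(rng.normal(0.0, 0.05, size=(N_TOKENS, h)).astype(np.float32))
    for l in range(cfg.n_decoder_layers):
        lin(f"dec{l}.msg0", 4 * h, h)
        lin(f"dec{l}.msg1", h, h)
        lin(f"dec{l}.msg2", h, h)
        ln(f"dec{l}.norm1", h)
        lin(f"dec{l}.ff0", h, 4 * h)
        lin(f"dec{l}.ff1", 4 * h, h)
        ln(f"dec{l}.norm2", h)
    lin("out", h, N_TOKENS)
    return p


def _linear(p, name, x, bias=True):
    y = ad.matmul(x, p[f"{name}.W"])
    if bias:
        y = ad.add(y, p[f"{name}.b"])
    return y


def _layernorm(p, name, x):
    return ad.layer_norm(x, p[f"{name}.g"], p[f"{name}.b"])


def _mlp3(p, name, x):
    y = ad.gelu(_linear(p, f"{name}0", x))
    y = ad.gelu(_linear(p, f"{name}1", y))
    return _linear(p, f"{name}2", y)


def _ff(p, name, x):
    return _linear(p, f"{name}1", ad.gelu(_linear(p, f"{name}0", x)))


def _aggregate(msg: Tensor, edge_mask: np.ndarray) -> Tensor:
    """Mean of messages over existing neighbors."""
    m = edge_mask[..., None].astype(msg.data.dtype)
    cnt = np.maximum(edge_mask.sum(axis=1, keepdims=True), 1).astype(msg.data.dtype)
    return ad.mul(ad.sum_(ad.mul(msg, m), axis=1), 1.0 / cnt)


class NAMPNN:
    """Encoder–decoder MPNN over the unified residue graph."""

    def __init__(self, cfg: ModelConfig, params: dict | None = None):
        self.cfg = cfg
        self.params = params if params is not None else init_params(cfg)

    # ---- encoder ---------------------------------------------------------

    def encode(self, g: GraphFeatures, dropout_rng=None):
        """Sequence-independent pass; returns (h_V, h_E) hidden states."""
        p = self.params
        drop = self.cfg.dropout if dropout_rng is not None else 0.0
        nm = g.node_mask[:, None].astype(np.float32)

        hv = _linear(p, "node_embed0", Tensor(g.node_onehot), bias=False)
        hv = _layernorm(p, "node_embed_ln", hv)
        hv = _linear(p, "node_embed1", hv)
        hv = ad.mul(hv, nm)

        edge_in = np.concatenate([g.edge_rbf, g.edge_extra], axis=-1)
        he = _layernorm(p, "edge_embed_ln", _linear(p, "edge_embed", Tensor(edge_in)))

        for l in range(self.cfg.n_encoder_layers):
            hj = ad.gather(hv, g.edge_index)                   # (N,K,h)
            hi = ad.reshape(hv, (g.n_nodes, 1, -1))
            hi_b = ad.mul(hi, np.ones((1, g.edge_index.shape[1], 1), dtype=np.float32))
            hev = ad.concat([hi_b, hj, he], axis=-1)
            msg = _mlp3(p, f"enc{l}.msg", hev)
            agg = _aggregate(msg, g.edge_mask)
            if drop > 0:
                agg = ad.dropout(agg, drop, dropout_rng)
            hv = _layernorm(p, f"enc{l}.norm1", ad.add(hv, agg))
            ff = _ff(p, f"enc{l}.ff", hv)
            if drop > 0:
                ff = ad.dropout(ff, drop, dropout_rng)
            hv = _layernorm(p, f"enc{l}.norm2", ad.add(hv, ff))
            hv = ad.mul(hv, nm)
            # edge update
            hj = ad.gather(hv, g.edge_index)
            hi_b = ad.mul(ad.reshape(hv, (g.n_nodes, 1, -1)),
                          np.ones((1, g.edge_index.shape[1], 1), dtype=np.float32))
            emsg = _mlp3(p, f"enc{l}.edge", ad.concat([hi_b, hj, he], axis=-1))
            if drop > 0:
                emsg = ad.dropout(emsg, drop, dropout_rng)
            he = _layernorm(p, f"enc{l}.norm3", ad.add(he, emsg))
        return hv, he

    # ---- decoder ---------------------------------------------------------

    def decode_logits(self, hv: Tensor, he: Tensor, g: GraphFeatures,
                      tokens: np.ndarray, order_pos: np.ndarray,
                      fixed_mask: np.ndarray, dropout_rng=None) -> Tensor:
        """Teacher-forced decoder pass.

        `order_pos[i]` is residue i's position in the decoding order (fixed
        residues take -1 and are visible to everyone).  Logits at position i
        depend only on structure, fixed tokens, and tokens with smaller
        order position.
        """
        p = self.params
        drop = self.cfg.dropout if dropout_rng is not None else 0.0
        bad = (tokens < 0) | (tokens >= N_TOKENS)
        if np.any(bad):
            raise ValueError("context token outside alphabet")

        n, K = g.edge_index.shape
        j = g.edge_index
        visible = (fixed_mask[j] | (order_pos[j] < order_pos[:, None])) & g.edge_mask
        vis = visible[..., None].astype(np.float32)

        s = ad.gather(self.params["seq_embed.W"], tokens)
        s_j = ad.gather(s, j)                                  # (N,K,h)
        e_np = he
        h_enc_j = ad.gather(hv, j)

        hvd = hv
        for l in range(self.cfg.n_decoder_layers):
            h_dec_j = ad.gather(hvd, j)
            # visible neighbors expose (decoded state, edge, token embedding);
            # hidden ones expose (encoder state, edge, zeros)
            bundle_dec = ad.concat([h_dec_j, e_np, s_j], axis=-1)
            zeros = np.zeros_like(s_j.data)
            bundle_enc = ad.concat([h_enc_j, e_np, Tensor(zeros)], axis=-1)
            bundle = ad.add(ad.mul(bundle_dec, vis), ad.mul(bundle_enc, 1.0 - vis))
            hi_b = ad.mul(ad.reshape(hvd, (n, 1, -1)), np.ones((1, K, 1), dtype=np.float32))
            msg = _mlp3(p, f"dec{l}.msg", ad.concat([hi_b, bundle], axis=-1))
            agg = _aggregate(msg, g.edge_mask)
            if drop > 0:
                agg = ad.dropout(agg, drop, dropout_rng)
            hvd = _layernorm(p, f"dec{l}.norm1", ad.add(hvd, agg))
            ff = _ff(p, f"dec{l}.ff", hvd)
            if drop > 0:
                ff = ad.dropout(ff, drop, dropout_rng)
            hvd = _layernorm(p, f"dec{l}.norm2", ad.add(hvd, ff))
            hvd = ad.mul(hvd, g.node_mask[:, None].astype(np.float32))
        return _linear(p, "out", hvd)

    def forward_logits(self, g: GraphFeatures, tokens: np.ndarray,
                       order_pos: np.ndarray, fixed_mask: np.ndarray,
                       dropout_rng=None) -> Tensor:
        hv, he = self.encode(g, dropout_rng)
        return self.decode_logits(hv, he, g, tokens, order_pos, fixed_mask, dropout_rng)

    # ---- sampling --------------------------------------------------------

    def sample_sequence(self, c: Complex, design_mask: np.ndarray,
                        temperature: float = DESIGN_TEMPERATURE, seed: int = 0,
                        graph: GraphFeatures | None = None):
        """Design nucleic positions autoregressively in a random order.

        Returns (tokens, probs) where probs[i] is the 4-vector over canonical
        bases used at residue i's own decode step (None for fixed positions).
        """
        residues = c.residues
        design_mask = np.asarray(design_mask, dtype=bool)
        for i, r in enumerate(residues):
            if design_mask[i] and r.polymer_class is PolymerClass.PROTEIN:
                raise ValueError("protein residues cannot be designed; they are fixed context")
        with no_grad():
            if graph is None:
                graph = build_graph(c, k=self.cfg.k_neighbors, n_rbf=self.cfg.n_rbf)
            design_mask = design_mask & graph.node_mask
            rng = np.random.default_rng(seed)
            tokens = np.array([r.token for r in residues], dtype=np.int64)
            out_tokens = tokens.copy()
            free = np.flatnonzero(design_mask)
            probs = [None] * len(residues)
            if free.size == 0:
                return out_tokens, probs

            order = rng.permutation(free)
            order_pos = np.full(len(residues), -1, dtype=np.int64)
            order_pos[order] = np.arange(free.size)
            fixed_mask = ~design_mask
            work = out_tokens.copy()
            work[free] = TOKEN_NA_UNK  # placeholder, causally masked anyway

            hv, he = self.encode(graph)
            canon = np.array(NA_CANONICAL)
            for pos in order:
                logits = self.decode_logits(hv, he, graph, work, order_pos, fixed_mask).data
                z = logits[pos, canon].astype(np.float64)
                if temperature < 1e-8:
                    pvec = np.zeros(4)
                    pvec[np.argmax(z)] = 1.0
                else:
                    z = z / temperature
                    z -= z.max()
                    pvec = np.exp(z)
                    pvec /= pvec.sum()
                choice = canon[rng.choice(4, p=pvec)]
                work[pos] = choice
                out_tokens[pos] = choice
                probs[pos] = pvec
            return out_tokens, probs

    def predict_ppm(self, c: Complex, n_samples: int = SPECIFICITY_N_SAMPLES,
                    temperature: float = SPECIFICITY_TEMPERATURE, seed: int = 0) -> dict:
        """Averaged per-position base preferences for every DNA chain.

        The DNA sequence is hidden from the model; decoding is repeated
        `n_samples` times and the conditional distributions recorded at each
        position's own decode step are averaged.  Rows are (A, C, G, T) and
        sum to 1; positions that cannot be designed get a uniform row.
        """
        residues = c.residues
        dna = np.array([r.polymer_class is PolymerClass.DNA for r in residues])
        if not dna.any():
            raise ValueError("complex contains no DNA chain")
        graph = build_graph(c, k=self.cfg.k_neighbors, n_rbf=self.cfg.n_rbf)
        design_mask = dna & graph.node_mask

        acc = np.zeros((len(residues), 4))
        for s in range(n_samples):
            _, probs = self.sample_sequence(
                c, design_mask, temperature=temperature, seed=seed + s, graph=graph
            )
            for i, pv in enumerate(probs):
                if pv is not None:
                    acc[i] += pv
        acc[design_mask] /= n_samples
        acc[~design_mask] = 0.25

        out = {}
        offset = 0
        for chain_id, cls, res in c.chains:
            L = len(res)
            if cls is PolymerClass.DNA or any(r.polymer_class is PolymerClass.DNA for r in res):
                out[chain_id] = acc[offset:offset + L].copy()
            offset += L
        return out

    # ---- persistence -----------------------------------------------------

    def save(self, path):
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "NAMPNN":
        with np.load(path) as f:
            cfg = ModelConfig(**json.loads(bytes(f["__config__"]).decode()))
            params = {k: ad.parameter(f[k]) for k in f.files if k != "__config__"}
        return cls(cfg, params)


def complex_tokens(c: Complex) -> np.ndarray:
    return np.array([r.token for r in c.residues], dtype=np.int64)


def design_fasta(c: Complex, samples: list, header_prefix: str = "design") -> str:
    """FASTA for sampled token arrays, spelled per chain class (U for RNA)."""
    lines = []
    for si, tokens in enumerate(samples):
        offset = 0
        for chain_id, cls, res in c.chains:
            L = len(res)
            if any(r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA) for r in res):
                seq = "".join(
                    na_token_to_letter(int(tokens[offset + i]), res[i].polymer_class)
                    if res[i].polymer_class in (PolymerClass.DNA, PolymerClass.RNA)
                    else "X"
                    for i in range(L)
                )
                lines.append(f">{header_prefix}_{si}_chain_{chain_id}")
                lines.append(seq)
            offset += L
    return "\n".join(lines) + "\n"
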
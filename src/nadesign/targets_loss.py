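"""Training targets, loss, sampling weights, batching, and toy training.

Targets are 26-way distributions over the token alphabet.  Label smoothing
with coefficient 0.1 redistributes mass within polymer classes only (over the
20 canonical amino acids for proteins, over the 4 canonical bases for
nucleic acids), so no probability ever leaks across the protein/nucleic
split.  The specificity variant swaps targets for experimental motif columns
where aligned, drops protein chains with probability 0.5 (uniformizing all
nucleic targets), and uniformizes non-interface nucleic positions without a
motif.  The loss is masked cross-entropy summed over batch and residues and
scaled by a fixed 1/6000 normalizer; examples are drawn into token-budgeted
batches of 6000 with weights that downweight common sequence clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurize import build_graph
from .model import NAMPNN, ModelConfig, complex_tokens
from .ppm_align import AlignedTargetMap
from .structures import (
    Complex,
    NA_CANONICAL,
    N_TOKENS,
    PROTEIN_CANONICAL,
    PolymerClass,
    TOKEN_NA_UNK,
    TOKEN_PROTEIN_UNK,
    interface_mask,
)

logger = logging.getLogger("nadesign")

LABEL_SMOOTHING = 0.1
LOSS_NORMALIZER = 6000.0
TOKEN_BUDGET = 6000
PROTEIN_DROP_PROBABILITY = 0.5
ADAM_BETAS = (0.9, 0.98)
ADAM_EPSILON = 1e-9
GRAD_CLIP_NORM = 1.0

_NA_SET = set(NA_CANONICAL)


class TargetError(Exception):
    pass


@dataclass
class TargetDistribution:
    y: np.ndarray            # (N, 26)
    mask: np.ndarray         # (N,) residue exists and is a design target


def _class_canonicals(token: int) -> tuple:
    if token <= TOKEN_PROTEIN_UNK:
        return PROTEIN_CANONICAL
    return NA_CANONICAL


def smooth_within_class(one_hot: np.ndarray, epsilon: float = LABEL_SMOOTHING) -> np.ndarray:
    """(1-eps) * one-hot + eps * uniform over the class's canonical tokens.

    Unknown tokens get the plain uniform over their class canonicals.  Mass
    outside the class is exactly zero.
    """
    one_hot = np.asarray(one_hot, dtype=np.float64)
    token = int(np.argmax(one_hot))
    canon = _class_canonicals(token)
    y = np.zeros(N_TOKENS)
    if token in (TOKEN_PROTEIN_UNK, TOKEN_NA_UNK):
        y[list(canon)] = 1.0 / len(canon)
        return y
    y[token] = 1.0 - epsilon
    y[list(canon)] += epsilon / len(canon)
    return y


def _token_onehot(token: int) -> np.ndarray:
    v = np.zeros(N_TOKENS)
    v[token] = 1.0
    return v


def _uniform_na() -> np.ndarray:
    y = np.zeros(N_TOKENS)
    y[list(NA_CANONICAL)] = 0.25
    return y


def build_design_targets(c: Complex, epsilon: float = LABEL_SMOOTHING) -> TargetDistribution:
    """Label-smoothed crystal-sequence targets at every existing nucleic position."""
    residues = c.residues
    n = len(residues)
    y = np.zeros((n, N_TOKENS))
    mask = np.zeros(n, dtype=bool)
    for i, r in enumerate(residues):
        if r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA) and r.exists:
            mask[i] = True
            y[i] = smooth_within_class(_token_onehot(r.token), epsilon)
    return TargetDistribution(y, mask)


def build_specificity_targets(c: Complex, aligned: AlignedTargetMap,
                              iface: np.ndarray | None, rng: np.random.Generator,
                              epsilon: float = LABEL_SMOOTHING):
    """Specificity-training targets with the three augmentations.

    Returns (targets, complex_used, protein_dropped).  For nucleic-acid-only
    complexes every position is uniform.  With protein present, all protein
    chains are dropped with probability 0.5 (targets then uniform); otherwise
    aligned experimental motif columns are copied in, interface positions
    without a motif keep the smoothed one-hot, and non-interface positions
    without a motif are uniformized.
    """
    has_protein = any(r.polymer_class is PolymerClass.PROTEIN for r in c.residues)

    def uniform_targets(cx: Complex) -> TargetDistribution:
        n = cx.n_residues
        y = np.zeros((n, N_TOKENS))
        mask = np.zeros(n, dtype=bool)
        for i, r in enumerate(cx.residues):
            if r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA) and r.exists:
                mask[i] = True
                y[i] = _uniform_na()
        return TargetDistribution(y, mask)

    if not has_protein:
        return uniform_targets(c), c, False

    if rng.random() < PROTEIN_DROP_PROBABILITY:
        chains = [
            (cid, cls, res)
            for cid, cls, res in c.chains
            if cls is not PolymerClass.PROTEIN
        ]
        dropped = Complex(chains=chains, resolution=c.resolution, meta=dict(c.meta))
        return uniform_targets(dropped), dropped, True

    if iface is None:
        iface = interface_mask(c)
    residues = c.residues
    n = len(residues)
    y = np.zeros((n, N_TOKENS))
    mask = np.zeros(n, dtype=bool)
    pos_in_chain = {}
    for i, r in enumerate(residues):
        pos_in_chain[i] = (r.chain_id, r.index)
    for i, r in enumerate(residues):
        if r.polymer_class not in (PolymerClass.DNA, PolymerClass.RNA) or not r.exists:
            continue
        mask[i] = True
        col = aligned.get(*pos_in_chain[i]) if aligned is not None else None
        if col is not None:
            v = np.asarray(col.column, dtype=np.float64)
            if abs(v.sum() - 1.0) > 1e-6:
                raise TargetError("aligned PPM column does not sum to 1")
            y[i] = np.zeros(N_TOKENS)
            y[i][list(NA_CANONICAL)] = v
        elif iface[i]:
            y[i] = smooth_within_class(_token_onehot(r.token), epsilon)
        else:
            y[i] = _uniform_na()
    return TargetDistribution(y, mask), c, False


def batch_loss(logprobs_list, targets_list):
    """(1/6000) * sum over examples and residues of masked cross-entropy.

    `logprobs_list` holds per-example (N, 26) log-probabilities from a full
    26-way softmax, as autodiff Tensors (training) or ndarrays (evaluation);
    `targets_list` holds the matching TargetDistributions.
    """
    total = None
    for logp, t in zip(logprobs_list, targets_list):
        if isinstance(logp, Tensor):
            if np.any(np.isnan(logp.data)):
                raise TargetError("NaN logits in batch")
            w = (t.y * t.mask[:, None]).astype(logp.data.dtype)
            term = ad.mul(ad.sum_(ad.mul(logp, w)), -1.0)
        else:
            if np.any(np.isnan(logp)):
                raise TargetError("NaN logits in batch")
            term = Tensor(-(np.asarray(logp) * t.y * t.mask[:, None]).sum())
        total = term if total is None else ad.add(total, term)
    if total is None:
        return Tensor(0.0)
    return ad.mul(total, 1.0 / LOSS_NORMALIZER)


@dataclass
class ClusterInfo:
    degrees: dict            # chain_id -> cluster degree


def sampling_weight(c: Complex, clusters: ClusterInfo) -> float:
    """(1/N_chains) * sum over chains of 1/(1 + cluster degree)."""
    total = 0.0
    for chain_id, _, _ in c.chains:
        if chain_id not in clusters.degrees:
            raise TargetError(f"missing cluster degree for chain {chain_id!r}")
        d = clusters.degrees[chain_id]
        if d < 0:
            raise TargetError("cluster degree must be >= 0")
        total += 1.0 / (1.0 + d)
    return total / len(c.chains)


@dataclass
class TrainingBatch:
    examples: list
    total_tokens: int
    seeds: list = field(default_factory=list)


def assemble_batches(examples: list, weights: list, token_counts: list,
                     rng: np.random.Generator, budget: int = TOKEN_BUDGET):
    """Infinite stream of token-budgeted batches drawn by weighted sampling.

    A batch closes when the next drawn example would push it past `budget`;
    examples larger than the budget are skipped with a warning.
    """
    w = np.asarray(weights, dtype=np.float64)
    usable = [i for i, t in enumerate(token_counts) if t <= budget]
    for i, t in enumerate(token_counts):
        if t > budget:
            logger.warning("example %d has %d tokens > budget %d; skipped", i, t, budget)
    if not usable:
        return
    pw = w[usable] / w[usable].sum()
    batch, tokens, seeds = [], 0, []
    while True:
        i = usable[int(rng.choice(len(usable), p=pw))]
        t = token_counts[i]
        if batch and tokens + t > budget:
            yield TrainingBatch(batch, tokens, seeds)
            batch, tokens, seeds = [], 0, []
        batch.append(examples[i])
        tokens += t
        seeds.append(int(rng.integers(2**31)))
        if tokens >= budget:
            yield TrainingBatch(batch, tokens, seeds)
            batch, tokens, seeds = [], 0, []


@dataclass
class ToyTrainResult:
    model: NAMPNN
    losses: list
    grad_norms: list


def train_toy(complexes: list, cfg: ModelConfig, n_steps: int = 500,
              lr: float = 1e-3, seed: int = 0, noise_sigma: float = 0.0,
              examples_per_step: int = 2, targets: list | None = None,
              recovery_target: float | None = None,
              check_every: int = 100) -> ToyTrainResult:
    """End-to-end toy training on synthetic fixtures.

    Graphs are featurized once (optionally re-noised per step when
    `noise_sigma` > 0), examples are drawn uniformly, and the loss/optimizer
    stack (masked smoothed cross-entropy, Adam with beta2=0.98, global
    gradient-norm clip 1.0) runs for `n_steps`.  Deterministic under `seed`.
    With `recovery_target` set, training stops early once greedy training-set
    sequence recovery (checked every `check_every` steps) reaches the target.
    """
    rng = np.random.default_rng(seed)
    model = NAMPNN(cfg)
    opt = ad.Adam(model.params, lr=lr, beta1=ADAM_BETAS[0], beta2=ADAM_BETAS[1], eps=ADAM_EPSILON)
    if targets is None:
        targets = [build_design_targets(c) for c in complexes]
    graphs = [build_graph(c, k=cfg.k_neighbors, n_rbf=cfg.n_rbf) for c in complexes]
    tokens = [complex_tokens(c) for c in complexes]

    losses, grad_norms = [], []
    for step in range(n_steps):
        idx = rng.choice(len(complexes), size=min(examples_per_step, len(complexes)), replace=False)
        logps, tgts = [], []
        for i in idx:
            g = graphs[i]
            if noise_sigma > 0:
                g = build_graph(complexes[i], k=cfg.k_neighbors, n_rbf=cfg.n_rbf,
                                noise_sigma=noise_sigma, seed=int(rng.integers(2**31)))
            n = g.n_nodes
            free = targets[i].mask & g.node_mask
            order_pos = np.full(n, -1, dtype=np.int64)
            perm = rng.permutation(np.flatnonzero(free))
            order_pos[perm] = np.arange(perm.size)
            logits = model.forward_logits(g, tokens[i], order_pos, ~free)
            logps.append(ad.log_softmax(logits))
            tgts.append(targets[i])
        loss = batch_loss(logps, tgts)
        if np.isnan(loss.data):
            raise TargetError("divergent loss (NaN); aborting toy training")
        ad.zero_grads(model.params)
        loss.backward()
        grad_norms.append(ad.clip_grad_norm(model.params, GRAD_CLIP_NORM))
        opt.step()
        losses.append(loss.item())
        if recovery_target is not None and (step + 1) % check_every == 0:
            if training_recovery(model, complexes) >= recovery_target:
                logger.info("recovery target reached after %d steps", step + 1)
                break
    return ToyTrainResult(model, losses, grad_norms)


def training_recovery(model: NAMPNN, complexes: list, seed: int = 0) -> float:
    """Greedy (temperature -> 0) sequence recovery over all nucleic positions."""
    hits = total = 0
    for ci, c in enumerate(complexes):
        g = build_graph(c, k=model.cfg.k_neighbors, n_rbf=model.cfg.n_rbf)
        design = np.array([
            r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA) for r in c.residues
        ]) & g.node_mask
        designed, _ = model.sample_sequence(c, design, temperature=0.0, seed=seed + ci, graph=g)
        true = complex_tokens(c)
        hits += int((designed[design] == true[design]).sum())
        total += int(design.sum())
    return hits / total if total else float("nan")
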
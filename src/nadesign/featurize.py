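"""Residue-graph featurization shared by proteins, DNA and RNA.

Every residue is mapped onto one unified 18-slot backbone frame; only the
slots belonging to its polymer type are populated.  Two virtual side-chain
atoms complete the frame: an ideal Cβ for amino acids and a glycosidic-
nitrogen proxy for nucleotides.  Edges connect each residue to its K nearest
neighbors (Cα / C1′ distance) and carry Gaussian radial-basis embeddings of
all 18 x 18 slot-pair distances, zeroed wherever either slot is absent.
Training-time coordinate noise is injected here, before any derived geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures import Complex, PolymerClass, representative_atom

# fixed slot ordering of the unified backbone frame
SLOTS = (
    "N", "CA", "C", "O", "CBv",
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    "Nv",
)
N_SLOTS = len(SLOTS)
SLOT_INDEX = {name: i for i, name in enumerate(SLOTS)}

PROTEIN_SLOTS = tuple(SLOT_INDEX[s] for s in ("N", "CA", "C", "O", "CBv"))
DNA_SLOTS = tuple(
    SLOT_INDEX[s]
    for s in ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "Nv")
)
RNA_SLOTS = tuple(sorted(DNA_SLOTS + (SLOT_INDEX["O2'"],)))

K_NEIGHBORS = 32
NOISE_SIGMA = 0.1          # Å, training-time Gaussian coordinate noise
N_RBF = 16
RBF_MIN, RBF_MAX = 2.0, 22.0
RBF_CENTERS = np.linspace(RBF_MIN, RBF_MAX, N_RBF)
RBF_SIGMA = (RBF_MAX - RBF_MIN) / N_RBF  # bin spacing convention
REL_POS_CLIP = 32          # relative sequence offset clipped to ±32 on same-chain edges
N_EDGE_EXTRA = 2 * REL_POS_CLIP + 1 + 1  # offset one-hot + different-chain flag

VIRTUAL_NA_N_BOND = 1.48   # Å, glycosidic C1'–N bond length used for the proxy atom

# virtual-Cβ construction constants (ideal tetrahedral placement from N, CA, C)
_CB_A, _CB_B, _CB_C = -0.58273431, 0.56802827, -0.54067466

N_POLYMER_TYPES = 4        # protein, DNA, RNA, unknown
_CLASS_INDEX = {
    PolymerClass.PROTEIN: 0,
    PolymerClass.DNA: 1,
    PolymerClass.RNA: 2,
    PolymerClass.UNKNOWN: 3,
}


class GraphError(Exception):
    pass


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from the residue's N, CA, C coordinates."""
    n, ca, c = (np.asarray(x, dtype=np.float64) for x in (n, ca, c))
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    if np.linalg.norm(a) < 1e-8:
        warnings.warn("collinear N/CA/C; virtual Cβ placed along +x from CA")
        return ca + np.array([1.53, 0.0, 0.0])
    return _CB_A * a + _CB_B * b + _CB_C * cc + ca


def virtual_na_n(c1p: np.ndarray, o4p: np.ndarray, c2p: np.ndarray) -> np.ndarray:
    """Glycosidic-nitrogen proxy: 1.48 Å from C1′ along the O4′–C1′–C2′ bisector,
    pointing away from the sugar ring (toward the base)."""
    c1p, o4p, c2p = (np.asarray(x, dtype=np.float64) for x in (c1p, o4p, c2p))
    v = 2.0 * c1p - o4p - c2p
    nv = np.linalg.norm(v)
    if nv < 1e-8:
        raise GraphError("degenerate sugar geometry: zero-length bisector at C1'")
    return c1p + VIRTUAL_NA_N_BOND * v / nv


def apply_coordinate_noise(coord: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic Gaussian perturbation of a real atom coordinate (training only)."""
    if sigma <= 0:
        return np.asarray(coord)
    return np.asarray(coord) + rng.normal(0.0, sigma, size=np.shape(coord))


def residue_slots(polymer_class: PolymerClass) -> tuple:
    if polymer_class is PolymerClass.PROTEIN:
        return PROTEIN_SLOTS
    if polymer_class is PolymerClass.DNA:
        return DNA_SLOTS
    if polymer_class is PolymerClass.RNA:
        return RNA_SLOTS
    return ()


@dataclass
class GraphFeatures:
    """Geometry-level features of one complex, ready for the network.

    node_onehot:  (N, 4) polymer-type one-hot; the learned embedding stack
                  (bias-free linear -> layer norm -> linear) is applied by the
                  model, which owns those parameters.
    edge_index:   (N, K) neighbor residue indices (incoming edges j -> i).
    edge_mask:    (N, K) validity of each neighbor slot.
    edge_rbf:     (N, K, 18*18*n_rbf) float32, zero blocks for absent slots.
    edge_extra:   (N, K, 66) clipped relative-offset one-hot (same chain) plus
                  a different-chain flag.
    node_mask:    (N,) residue exists and entered the graph.
    coords:       (N, 18, 3) unified backbone coordinates (noised).
    present:      (N, 18) slot presence.
    """

    node_onehot: np.ndarray
    edge_index: np.ndarray
    edge_mask: np.ndarray
    edge_rbf: np.ndarray
    edge_extra: np.ndarray
    node_mask: np.ndarray
    coords: np.ndarray
    present: np.ndarray
    chain_ids: list
    residue_indices: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_onehot.shape[0]


def unified_backbone(c: Complex, noise_sigma: float = 0.0, seed: int = 0):
    """Build the (N, 18, 3) coordinate tensor and slot presence for a complex.

    Gaussian noise (std `noise_sigma`) is added to every real atom coordinate
    first; virtual atoms are then derived from the noised coordinates.
    """
    residues = c.residues
    n = len(residues)
    coords = np.zeros((n, N_SLOTS, 3), dtype=np.float64)
    present = np.zeros((n, N_SLOTS), dtype=bool)
    rng = np.random.default_rng(seed)

    for i, r in enumerate(residues):
        for a in r.atoms:
            s = SLOT_INDEX.get(a.name)
            if s is not None:
                coord = a.coord
                if noise_sigma > 0:
                    coord = apply_coordinate_noise(coord, noise_sigma, rng)
                coords[i, s] = coord
                present[i, s] = True
        if r.polymer_class is PolymerClass.PROTEIN:
            if present[i, SLOT_INDEX["N"]] and present[i, SLOT_INDEX["CA"]] and present[i, SLOT_INDEX["C"]]:
                coords[i, SLOT_INDEX["CBv"]] = virtual_cb(
                    coords[i, SLOT_INDEX["N"]], coords[i, SLOT_INDEX["CA"]], coords[i, SLOT_INDEX["C"]]
                )
                present[i, SLOT_INDEX["CBv"]] = True
        elif r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA):
            i_c1, i_o4, i_c2 = SLOT_INDEX["C1'"], SLOT_INDEX["O4'"], SLOT_INDEX["C2'"]
            if present[i, i_c1] and present[i, i_o4] and present[i, i_c2]:
                coords[i, SLOT_INDEX["Nv"]] = virtual_na_n(
                    coords[i, i_c1], coords[i, i_o4], coords[i, i_c2]
                )
                present[i, SLOT_INDEX["Nv"]] = True
        # restrict presence to this residue's polymer-type slots
        allowed = np.zeros(N_SLOTS, dtype=bool)
        allowed[list(residue_slots(r.polymer_class))] = True
        present[i] &= allowed
    return coords, present


def build_graph(c: Complex, k: int = K_NEIGHBORS, noise_sigma: float = 0.0,
                seed: int = 0, n_rbf: int = N_RBF) -> GraphFeatures:
    """Featurize a complex into a K-nearest-neighbor residue graph."""
    residues = c.residues
    n = len(residues)
    coords, present = unified_backbone(c, noise_sigma=noise_sigma, seed=seed)

    rep_slot = np.array(
        [
            SLOT_INDEX["CA"] if r.polymer_class is PolymerClass.PROTEIN else SLOT_INDEX["C1'"]
            for r in residues
        ]
    )
    node_mask = np.array(
        [r.exists and present[i, rep_slot[i]] for i, r in enumerate(residues)], dtype=bool
    )
    existing = np.flatnonzero(node_mask)
    if existing.size < 2:
        raise GraphError("graph needs at least two existing residues")

    rep = coords[np.arange(n), rep_slot]  # (N, 3)
    k_eff = min(int(k), existing.size - 1)

    edge_index = np.zeros((n, k_eff), dtype=np.int64)
    edge_mask = np.zeros((n, k_eff), dtype=bool)
    for i in existing:
        cand = existing[existing != i]
        d = np.linalg.norm(rep[cand] - rep[i], axis=1)
        # round so symmetry-induced ties break by residue index, stably
        # under rigid motions of the coordinates
        order = np.lexsort((cand, np.round(d, 6)))
        sel = cand[order[:k_eff]]
        edge_index[i, : sel.size] = sel
        edge_mask[i, : sel.size] = True

    # RBF embedding of all slot-pair distances on each edge
    centers = np.linspace(RBF_MIN, RBF_MAX, n_rbf)
    sigma = (RBF_MAX - RBF_MIN) / n_rbf
    xi = coords[:, None, :, None, :]                      # (N,1,18,1,3)
    xj = coords[edge_index][:, :, None, :, :]             # (N,K,1,18,3)
    dist = np.linalg.norm(xi - xj, axis=-1)               # (N,K,18,18)
    pair_ok = (present[:, None, :, None] & present[edge_index][:, :, None, :])
    rbf = np.exp(-(((dist[..., None] - centers) / sigma) ** 2))
    rbf *= pair_ok[..., None]
    rbf *= edge_mask[..., None, None, None]
    edge_rbf = rbf.reshape(n, k_eff, N_SLOTS * N_SLOTS * n_rbf).astype(np.float32)

    # chain-relative positional features
    chain_ids = [r.chain_id for r in residues]
    res_idx = np.array([r.index for r in residues])
    edge_extra = np.zeros((n, k_eff, N_EDGE_EXTRA), dtype=np.float32)
    for i in range(n):
        for kk in range(k_eff):
            if not edge_mask[i, kk]:
                continue
            j = edge_index[i, kk]
            if chain_ids[j] == chain_ids[i]:
                off = int(np.clip(res_idx[j] - res_idx[i], -REL_POS_CLIP, REL_POS_CLIP))
                edge_extra[i, kk, off + REL_POS_CLIP] = 1.0
            else:
                edge_extra[i, kk, -1] = 1.0

    node_onehot = np.zeros((n, N_POLYMER_TYPES), dtype=np.float32)
    for i, r in enumerate(residues):
        node_onehot[i, _CLASS_INDEX[r.polymer_class]] = 1.0
    node_onehot *= node_mask[:, None]

    return GraphFeatures(
        node_onehot=node_onehot,
        edge_index=edge_index,
        edge_mask=edge_mask,
        edge_rbf=edge_rbf,
        edge_extra=edge_extra,
        node_mask=node_mask,
        coords=coords,
        present=present,
        chain_ids=chain_ids,
        residue_indices=res_idx,
    )


def dump_graph_tables(g: GraphFeatures):
    """Debug dump: (node table, edge table) as pandas DataFrames."""
    import pandas as pd

    nodes = pd.DataFrame(
        {
            "node": np.arange(g.n_nodes),
            "chain": g.chain_ids,
            "index": g.residue_indices,
            "exists": g.node_mask,
        }
    )
    rows = []
    for i in range(g.n_nodes):
        for kk in range(g.edge_index.shape[1]):
            if g.edge_mask[i, kk]:
                rows.append((i, int(g.edge_index[i, kk]), float(g.edge_rbf[i, kk].sum())))
    edges = pd.DataFrame(rows, columns=["dst", "src", "rbf_sum"])
    return nodes, edges
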
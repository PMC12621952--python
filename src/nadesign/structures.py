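"""Domain types for macromolecular complexes, structure I/O, and filters.

A `Complex` is an ordered list of chains of typed `Residue`s, each residue
carrying its named backbone and side-chain atoms with occupancies.  Parsing
goes through gemmi for both mmCIF and PDB; a minimal writer round-trips the
synthetic fixtures.  The module also implements the dataset/evaluation entry
filters and the protein–nucleic-acid side-chain interface mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("nadesign")

OCCUPANCY_THRESHOLD = 0.8  # residues kept only if every backbone atom exceeds this
INTERFACE_CUTOFF = 5.0     # Å, side-chain heavy-atom contact distance
INTERFACE_KNN = 48         # neighbor residues searched per residue


class PolymerClass(Enum):
    PROTEIN = "protein"
    DNA = "DNA"
    RNA = "RNA"
    UNKNOWN = "unknown"


# ---- token alphabet -------------------------------------------------------
# 26 tokens: 20 canonical amino acids + unknown protein, then the 5 shared
# nucleic tokens (deoxy and ribo forms collapse onto one id each).

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

TOKEN_PROTEIN_UNK = 20
TOKEN_NA_A, TOKEN_NA_C, TOKEN_NA_G, TOKEN_NA_T = 21, 22, 23, 24
TOKEN_NA_UNK = 25
N_TOKENS = 26

PROTEIN_TOKENS = tuple(range(21))
NA_TOKENS = (TOKEN_NA_A, TOKEN_NA_C, TOKEN_NA_G, TOKEN_NA_T, TOKEN_NA_UNK)
PROTEIN_CANONICAL = tuple(range(20))
NA_CANONICAL = (TOKEN_NA_A, TOKEN_NA_C, TOKEN_NA_G, TOKEN_NA_T)

_NA_LETTER = {TOKEN_NA_A: "A", TOKEN_NA_C: "C", TOKEN_NA_G: "G", TOKEN_NA_T: "T", TOKEN_NA_UNK: "X"}
_LETTER_NA = {"A": TOKEN_NA_A, "C": TOKEN_NA_C, "G": TOKEN_NA_G, "T": TOKEN_NA_T,
              "U": TOKEN_NA_T, "X": TOKEN_NA_UNK}


def token_class(token: int) -> str:
    """'protein' or 'nucleic' partition of the alphabet."""
    if 0 <= token <= TOKEN_PROTEIN_UNK:
        return "protein"
    if token in NA_TOKENS:
        return "nucleic"
    raise ValueError(f"token {token} outside alphabet")


def token_is_canonical(token: int) -> bool:
    return token in PROTEIN_CANONICAL or token in NA_CANONICAL


def na_token_to_letter(token: int, polymer_class: PolymerClass) -> str:
    """Spell a shared nucleic token in the chain's ribo/deoxy alphabet."""
    letter = _NA_LETTER[token]
    if polymer_class is PolymerClass.RNA and letter == "T":
        return "U"
    return letter


def letter_to_na_token(letter: str) -> int:
    return _LETTER_NA[letter.upper()]


# ---- required backbone atoms ----------------------------------------------

PROTEIN_BACKBONE = ("N", "CA", "C", "O")
DNA_BACKBONE = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'")
RNA_BACKBONE = DNA_BACKBONE + ("O2'",)
PHOSPHATE_ATOMS = ("P", "OP1", "OP2")


def required_backbone(polymer_class: PolymerClass) -> tuple:
    if polymer_class is PolymerClass.PROTEIN:
        return PROTEIN_BACKBONE
    if polymer_class is PolymerClass.DNA:
        return DNA_BACKBONE
    if polymer_class is PolymerClass.RNA:
        return RNA_BACKBONE
    return ()


# ---- residue name tables --------------------------------------------------

_DNA_CANON = {"DA": TOKEN_NA_A, "DC": TOKEN_NA_C, "DG": TOKEN_NA_G, "DT": TOKEN_NA_T}
_RNA_CANON = {"A": TOKEN_NA_A, "C": TOKEN_NA_C, "G": TOKEN_NA_G, "U": TOKEN_NA_T}


@dataclass
class Atom:
    name: str
    coord: np.ndarray        # (3,) Å
    occupancy: float = 1.0
    is_sidechain: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=np.float64)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    polymer_class: PolymerClass
    token: int
    name: str                # residue name as in the file (e.g. "DA", "GLY", "5MC")
    atoms: list
    chain_id: str
    index: int               # 0-based position within the chain
    exists: bool = False

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> list:
        return [a for a in self.atoms if a.is_sidechain]

    def compute_exists(self, permissive_5prime: bool = False, is_chain_start: bool = False) -> bool:
        """All class-required backbone atoms present with occupancy > 0.8."""
        req = required_backbone(self.polymer_class)
        if permissive_5prime and is_chain_start and self.polymer_class in (PolymerClass.DNA, PolymerClass.RNA):
            req = tuple(n for n in req if n not in PHOSPHATE_ATOMS)
        for name in req:
            a = self.atom(name)
            if a is None or not a.occupancy > OCCUPANCY_THRESHOLD:
                return False
        return bool(req)


@dataclass
class Complex:
    chains: list             # list of (chain_id, PolymerClass, [Residue])
    resolution: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.chains:
            raise ValueError("complex must contain at least one chain")

    @property
    def residues(self) -> list:
        return [r for _, _, res in self.chains for r in res]

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, _, res in self.chains)

    def chain(self, chain_id: str):
        for cid, cls, res in self.chains:
            if cid == chain_id:
                return cid, cls, res
        raise KeyError(f"chain {chain_id!r} not found")

    def chain_na_letters(self, chain_id: str) -> str:
        """Chain sequence in the shared A/C/G/T/X alphabet (U read as T)."""
        _, _, res = self.chain(chain_id)
        out = []
        for r in res:
            if r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA):
                out.append(_NA_LETTER[r.token])
            else:
                out.append("X")
        return "".join(out)

    def heavy_atom_count(self) -> int:
        return sum(
            1
            for r in self.residues
            for a in r.atoms
            if not a.name.startswith("H") and a.name not in ("D",)
        )

    def has_nucleic_chain(self) -> bool:
        return any(
            r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA)
            for r in self.residues
        )


class StructureError(Exception):
    pass


class EmptyStructureError(StructureError):
    pass


# ---- classification helpers ----------------------------------------------


def _classify_residue(name: str, atom_names: set) -> tuple:
    """Return (PolymerClass, token) for a residue name, or (UNKNOWN, -1).

    Canonical names decide directly; modified residues fall back to atom
    content: a sugar (C1') marks a nucleic residue, with O2' separating RNA
    from DNA; CA without a sugar marks an amino acid.
    """
    name = name.strip().upper()
    if name in AA3_TO_1:
        return PolymerClass.PROTEIN, AA1.index(AA3_TO_1[name])
    if name in _DNA_CANON:
        return PolymerClass.DNA, _DNA_CANON[name]
    if name in _RNA_CANON:
        return PolymerClass.RNA, _RNA_CANON[name]
    if name in ("HOH", "WAT", "DOD"):
        return PolymerClass.UNKNOWN, -1
    if name == "UNK":
        return PolymerClass.PROTEIN, TOKEN_PROTEIN_UNK
    if "C1'" in atom_names:
        cls = PolymerClass.RNA if "O2'" in atom_names else PolymerClass.DNA
        return cls, TOKEN_NA_UNK
    if "CA" in atom_names and "N" in atom_names and "C" in atom_names:
        return PolymerClass.PROTEIN, TOKEN_PROTEIN_UNK
    return PolymerClass.UNKNOWN, -1


def _chain_class(residues: Sequence[Residue]) -> PolymerClass:
    counts = {}
    for r in residues:
        counts[r.polymer_class] = counts.get(r.polymer_class, 0) + 1
    return max(counts, key=counts.get)


# ---- parsing --------------------------------------------------------------


def parse_structure(path, fmt: Optional[str] = None, permissive_5prime: bool = False) -> Complex:
    """Read an mmCIF or PDB file into a Complex.

    Hydrogens, waters and non-polymer residues are dropped; for alternate
    locations the highest-occupancy atom per name is kept.  `exists` is
    computed per residue from the occupancy rule.
    """
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as e:
        raise StructureError(f"cannot parse {path} as {fmt}: {e}") from e
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    model = st[0]
    chains = []
    for chain in model:
        residues = []
        for res in chain:
            # keep highest-occupancy atom per name; skip hydrogens
            best = {}
            for at in res:
                if at.is_hydrogen():
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atom_names = set(best)
            cls, token = _classify_residue(res.name, atom_names)
            if cls is PolymerClass.UNKNOWN:
                continue  # ligand / water / unclassifiable
            req = set(required_backbone(cls))
            atoms = [
                Atom(
                    name=at.name,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    # files store occupancy as float32; round so a written
                    # 0.8 compares as exactly 0.8 against the strict threshold
                    occupancy=min(max(round(float(at.occ), 6), 0.0), 1.0),
                    is_sidechain=at.name not in req,
                )
                for at in best.values()
            ]
            residues.append(
                Residue(cls, token, res.name.strip(), atoms, chain.name, len(residues))
            )
        if residues:
            for i, r in enumerate(residues):
                r.exists = r.compute_exists(permissive_5prime, is_chain_start=(i == 0))
            chains.append((chain.name, _chain_class(residues), residues))

    if not chains:
        raise EmptyStructureError(f"{path}: no polymer residues")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    meta = {"entry_id": st.name, "method": getattr(st, "get_info", lambda k: "")("_exptl.method") or ""}
    return Complex(chains=chains, resolution=resolution, meta=meta)


def write_structure(c: Complex, path, fmt: Optional[str] = None) -> None:
    """Write a Complex as mmCIF or PDB (fixture-grade writer)."""
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"

    st = gemmi.Structure()
    st.name = str(c.meta.get("entry_id", "SYNT"))
    if c.resolution is not None:
        st.resolution = float(c.resolution)
    model = gemmi.Model("1")
    one_to3 = {v: k for k, v in AA3_TO_1.items()}
    for chain_id, cls, residues in c.chains:
        ch = gemmi.Chain(chain_id)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name if r.name else "UNK"
            gr.seqid = gemmi.SeqId(r.index + 1, " ")
            if r.name == "" and r.polymer_class is PolymerClass.PROTEIN and r.token < 20:
                gr.name = one_to3[AA1[r.token]]
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = float(a.occupancy)
                ga.element = gemmi.Element(a.name[0])
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    elif fmt == "pdb":
        st.write_pdb(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---- entry filters --------------------------------------------------------

MAX_RESOLUTION = 3.5
MIN_HEAVY_ATOMS = 100
MAX_POLYMER_RESIDUES = 6000
EVAL_MIN_RESIDUES = 20
EVAL_MAX_RESIDUES = 1000
MIN_SEQUENCE_COVERAGE = 0.9
UNK_DOMINANCE_LIMIT = 20


@dataclass
class FilterResult:
    accepted: bool
    reasons: list

    def __bool__(self):
        return self.accepted


def entry_filter(c: Complex, stage: str = "dataset",
                 reference_lengths: Optional[dict] = None) -> FilterResult:
    """Accept/reject a complex for the training dataset or for evaluation.

    Dataset stage: heavy atoms >= 100; resolution <= 3.5 Å or unreported;
    most frequent residue not UNK occurring > 20 times; at least one nucleic
    chain with at least one residue passing the occupancy rule; total polymer
    length <= 6000; per-chain sequence coverage >= 0.9 when reference chain
    lengths are supplied.  Evaluation stage: 20 <= total residues <= 1000.
    """
    reasons = []
    n = c.n_residues
    if stage == "evaluation":
        if n < EVAL_MIN_RESIDUES:
            reasons.append("too_few_residues")
        if n > EVAL_MAX_RESIDUES:
            reasons.append("too_many_residues")
    elif stage == "dataset":
        if c.heavy_atom_count() < MIN_HEAVY_ATOMS:
            reasons.append("heavy_atoms")
        if c.resolution is not None and c.resolution > MAX_RESOLUTION:
            reasons.append("resolution")
        name_counts = {}
        for r in c.residues:
            name_counts[r.name] = name_counts.get(r.name, 0) + 1
        if name_counts:
            top = max(sorted(name_counts), key=lambda k: name_counts[k])
            if top == "UNK" and name_counts[top] > UNK_DOMINANCE_LIMIT:
                reasons.append("unk_dominant")
        if not c.has_nucleic_chain():
            reasons.append("no_nucleic_chain")
        elif not any(
            r.exists and r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA)
            for r in c.residues
        ):
            reasons.append("no_existing_nucleic_residue")
        if n > MAX_POLYMER_RESIDUES:
            reasons.append("too_long")
        if reference_lengths:
            for chain_id, _, residues in c.chains:
                ref = reference_lengths.get(chain_id)
                if ref:
                    cov = sum(r.exists for r in residues) / ref
                    if cov < MIN_SEQUENCE_COVERAGE:
                        reasons.append(f"coverage:{chain_id}")
    else:
        raise ValueError(f"unknown stage {stage!r}")

    accepted = not reasons
    if not accepted:
        logger.info("entry_filter reject stage=%s reasons=%s entry=%s",
                    stage, reasons, c.meta.get("entry_id", "?"))
    return FilterResult(accepted, reasons)


# ---- interface mask -------------------------------------------------------


def representative_atom(r: Residue) -> Optional[Atom]:
    """Cα for protein residues, C1′ for nucleic residues."""
    if r.polymer_class is PolymerClass.PROTEIN:
        return r.atom("CA")
    if r.polymer_class in (PolymerClass.DNA, PolymerClass.RNA):
        return r.atom("C1'")
    return None


def interface_mask(c: Complex, cutoff: float = INTERFACE_CUTOFF,
                   knn_limit: int = INTERFACE_KNN) -> np.ndarray:
    """Per-residue boolean: residue participates in a protein–NA side-chain contact.

    A protein residue is flagged iff any of its side-chain atoms lies within
    `cutoff` Å of a nucleic side-chain atom among its `knn_limit` nearest
    residues (by representative atom), and symmetrically for nucleic
    residues.  Residues without a representative atom never enter the search.
    """
    residues = c.residues
    n = len(residues)
    mask = np.zeros(n, dtype=bool)

    reps, idx_map = [], []
    for i, r in enumerate(residues):
        a = representative_atom(r)
        if a is not None:
            reps.append(a.coord)
            idx_map.append(i)
    if len(reps) < 2:
        return mask

    reps = np.asarray(reps)
    tree = cKDTree(reps)
    k = min(int(knn_limit) + 1, len(reps)) if np.isfinite(knn_limit) else len(reps)

    sc_coords = [
        np.array([a.coord for a in r.sidechain_atoms()]) if r.sidechain_atoms() else None
        for r in residues
    ]

    def is_protein(i):
        return residues[i].polymer_class is PolymerClass.PROTEIN

    def is_na(i):
        return residues[i].polymer_class in (PolymerClass.DNA, PolymerClass.RNA)

    for pos, i in enumerate(idx_map):
        if sc_coords[i] is None:
            continue
        _, neigh = tree.query(reps[pos], k=k)
        for jpos in np.atleast_1d(neigh):
            j = idx_map[int(jpos)]
            if j == i or sc_coords[j] is None:
                continue
            cross = (is_protein(i) and is_na(j)) or (is_na(i) and is_protein(j))
            if not cross:
                continue
            d = np.linalg.norm(sc_coords[i][:, None, :] - sc_coords[j][None, :, :], axis=-1)
            if d.min() <= cutoff:
                mask[i] = True
                mask[j] = True
    return mask
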
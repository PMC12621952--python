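"""Synthetic structure, motif, and dataset fixtures.

Everything the other modules consume can be generated here at desk scale:
idealized B-DNA / A-RNA helices with all named backbone atoms and a single
base-proxy side-chain atom per nucleotide, ideal alpha-helical protein
fragments placeable at exact distances from a nucleic chain, JASPAR-style
motifs of controllable peakedness, and "planted" datasets in which base
identity is deterministically written into local backbone geometry so that a
small network can provably learn it.

Template coordinates are geometrically self-consistent (bond lengths within
about 0.1 Å of standard values) rather than fiber-diffraction-exact; tests
built on these fixtures rely on invariances, not absolute geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import (
    Atom,
    Complex,
    PolymerClass,
    Residue,
    letter_to_na_token,
)

# helical defaults
B_DNA_RISE, B_DNA_TWIST = 3.38, 36.0          # Å, degrees per step
A_RNA_RISE, A_RNA_TWIST = 2.81, 32.7
HELIX_RADIUS = 9.0                            # Å, ring-center distance from axis

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


@dataclass
class HelixSpec:
    form: str = "B-DNA"          # "B-DNA" | "A-RNA"
    sequence: str = "ACGTACGTAC"
    rise: float | None = None
    twist: float | None = None

    def resolved(self):
        if self.form == "B-DNA":
            return (self.rise or B_DNA_RISE, self.twist or B_DNA_TWIST, PolymerClass.DNA)
        if self.form == "A-RNA":
            return (self.rise or A_RNA_RISE, self.twist or A_RNA_TWIST, PolymerClass.RNA)
        raise ValueError(f"unknown helix form {self.form!r}")


def _rz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_DYAD = np.diag([1.0, -1.0, -1.0])  # two-fold rotation about x


def _nucleotide_template(with_o2p: bool) -> dict:
    """Local coordinates of one nucleotide; sugar ring in the z=0 plane."""
    r_ring = 1.26
    ring_angles = {"C1'": 90.0, "C2'": 18.0, "C3'": -54.0, "C4'": -126.0, "O4'": 162.0}
    atoms = {}
    for name, ang in ring_angles.items():
        t = np.deg2rad(ang)
        atoms[name] = r_ring * np.array([np.cos(t), np.sin(t), 0.0])

    z = np.array([0.0, 0.0, 1.0])

    def radial(name):
        v = atoms[name].copy()
        v[2] = 0.0
        return v / np.linalg.norm(v)

    atoms["O3'"] = atoms["C3'"] + 1.42 * (0.8 * radial("C3'") - 0.6 * z)
    atoms["C5'"] = atoms["C4'"] + 1.51 * (0.8 * radial("C4'") + 0.6 * z)
    atoms["O5'"] = atoms["C5'"] + 1.44 * (0.6 * radial("C4'") + 0.8 * z)
    atoms["P"] = atoms["O5'"] + 1.59 * (0.5 * radial("C4'") + 0.866 * z)
    atoms["OP1"] = atoms["P"] + 1.48 * np.array([0.0, 0.94, 0.342])
    atoms["OP2"] = atoms["P"] + 1.48 * np.array([0.0, -0.94, 0.342])
    if with_o2p:
        atoms["O2'"] = atoms["C2'"] + 1.41 * (0.8 * radial("C2'") - 0.6 * z)
    # base-proxy side-chain atom off C1', away from the ring, below the plane
    atoms["N9"] = atoms["C1'"] + 1.48 * (0.8 * radial("C1'") - 0.6 * z)
    # shift ring center out to the helix radius
    shift = np.array([HELIX_RADIUS, 0.0, 0.0])
    return {k: v + shift for k, v in atoms.items()}


def _na_residue(letter: str, cls: PolymerClass, rotation: np.ndarray, translation: np.ndarray,
                chain_id: str, index: int, c1p_offset: np.ndarray | None = None,
                rng: np.random.Generator | None = None, jitter: float = 0.0) -> Residue:
    letter = letter.upper()
    if letter not in "ACGTU":
        raise ValueError(f"non-canonical base letter {letter!r}")
    is_rna = cls is PolymerClass.RNA
    template = _nucleotide_template(with_o2p=is_rna)
    name = letter if is_rna else f"D{letter}"
    if is_rna and letter == "T":
        name, letter = "U", "U"
    atoms = []
    for atom_name, local in template.items():
        local = local.copy()
        if c1p_offset is not None and atom_name == "C1'":
            local = local + c1p_offset
        coord = rotation @ local + translation
        if jitter > 0 and rng is not None:
            coord = coord + rng.normal(0.0, jitter, 3)
        atoms.append(Atom(atom_name, coord, occupancy=1.0, is_sidechain=(atom_name == "N9")))
    token = letter_to_na_token(letter)
    r = Residue(cls, token, name, atoms, chain_id, index)
    r.exists = r.compute_exists()
    return r


def make_duplex(spec: HelixSpec, chain_ids=("A", "B"), planted_offsets=None,
                rng=None, jitter: float = 0.0, meta=None) -> Complex:
    """Antiparallel Watson–Crick duplex with exact dyad symmetry.

    Strand 1 residue i sits at helical step i; its partner is generated by a
    two-fold rotation about x followed by the same helical operator, so a
    palindromic duplex is rigidly self-symmetric.  `planted_offsets`
    optionally maps a base letter to a local-frame C1' displacement.
    """
    rise, twist, cls = spec.resolved()
    seq1 = spec.sequence.upper().replace("U", "T") if cls is PolymerClass.DNA else spec.sequence.upper()
    bad = set(seq1) - set("ACGTU")
    if bad:
        raise ValueError(f"non-canonical base letter(s) {sorted(bad)}")
    L = len(seq1)
    seq2_pair = [_COMPLEMENT[b] for b in seq1.replace("U", "T")]  # partner at step j

    def offset_for(letter):
        if planted_offsets is None:
            return None
        return planted_offsets[letter.upper().replace("U", "T")]

    strand1 = []
    for i, b in enumerate(seq1):
        rot = _rz(i * twist)
        trans = np.array([0.0, 0.0, i * rise])
        strand1.append(
            _na_residue(b, cls, rot, trans, chain_ids[0], i,
                        c1p_offset=offset_for(b), rng=rng, jitter=jitter)
        )
    strand2 = []
    for k in range(L):
        j = L - 1 - k                       # helical step of the partner
        b = seq2_pair[j]
        rot = _rz(j * twist) @ _DYAD
        trans = np.array([0.0, 0.0, j * rise])
        strand2.append(
            _na_residue(b, cls, rot, trans, chain_ids[1], k,
                        c1p_offset=offset_for(b), rng=rng, jitter=jitter)
        )
    return Complex(
        chains=[(chain_ids[0], cls, strand1), (chain_ids[1], cls, strand2)],
        resolution=2.0,
        meta=dict(meta or {"entry_id": "SYN-DUPLEX"}),
    )


def make_single_strand(spec: HelixSpec, chain_id="A", meta=None) -> Complex:
    """Single helical nucleic chain (e.g. an RNA strand)."""
    rise, twist, cls = spec.resolved()
    seq = spec.sequence.upper()
    residues = [
        _na_residue(b, cls, _rz(i * twist), np.array([0.0, 0.0, i * rise]), chain_id, i)
        for i, b in enumerate(seq)
    ]
    return Complex(chains=[(chain_id, cls, residues)], resolution=2.0,
                   meta=dict(meta or {"entry_id": "SYN-STRAND"}))


# ---- protein fixtures -----------------------------------------------------

_HELIX_RADIUS_CA = 2.3
_HELIX_TURN = 100.0      # degrees per residue
_HELIX_RISE = 1.5


def _helix_point(t: float) -> np.ndarray:
    a = np.deg2rad(_HELIX_TURN * t)
    return np.array([_HELIX_RADIUS_CA * np.cos(a), _HELIX_RADIUS_CA * np.sin(a), _HELIX_RISE * t])


def make_protein_helix(length: int, chain_id: str = "P", aa: str = "A",
                       anchor: tuple | None = None, meta=None) -> Complex:
    """Ideal alpha-helical protein fragment with a Cβ side-chain proxy atom.

    `anchor=(residue_index, target_point, distance, direction)` translates
    the helix so that residue `residue_index`'s CB sits exactly at
    `target_point + distance * direction`.
    """
    if length < 4:
        raise ValueError("protein helix needs length >= 4")
    residues = []
    aa3 = {"A": "ALA", "G": "GLY", "L": "LEU", "S": "SER"}.get(aa.upper(), "ALA")
    for i in range(length):
        ca = _helix_point(i)
        n = _helix_point(i - 0.33)
        c = _helix_point(i + 0.38)
        radial = np.array([ca[0], ca[1], 0.0])
        radial /= np.linalg.norm(radial)
        o = c + 1.23 * radial
        cb = ca + 1.53 * (0.9 * radial + np.array([0.0, 0.0, 0.436]))
        atoms = [
            Atom("N", n), Atom("CA", ca), Atom("C", c), Atom("O", o),
            Atom("CB", cb, is_sidechain=True),
        ]
        from .structures import AA1, AA3_TO_1
        token = AA1.index(AA3_TO_1[aa3])
        r = Residue(PolymerClass.PROTEIN, token, aa3, atoms, chain_id, i)
        r.exists = r.compute_exists()
        residues.append(r)

    if anchor is not None:
        residue_index, target_point, distance, direction = anchor
        direction = np.asarray(direction, dtype=np.float64)
        direction = direction / np.linalg.norm(direction)
        desired = np.asarray(target_point, dtype=np.float64) + distance * direction
        cb_now = residues[residue_index].atom("CB").coord
        shift = desired - cb_now
        for r in residues:
            for a in r.atoms:
                a.coord = a.coord + shift
    return Complex(chains=[(chain_id, PolymerClass.PROTEIN, residues)], resolution=2.0,
                   meta=dict(meta or {"entry_id": "SYN-HELIX"}))


def make_protein_dna_complex(dna_sequence: str = "ACGTACGTAC", helix_length: int = 8,
                             contact_distance: float = 4.0) -> Complex:
    """Duplex plus an alpha-helix whose anchor CB sits at an exact distance
    from one DNA base-proxy atom (interface-threshold fixture)."""
    duplex = make_duplex(HelixSpec(sequence=dna_sequence))
    _, _, strand1 = duplex.chains[0]
    na_atom = strand1[len(strand1) // 2].atom("N9").coord
    helix = make_protein_helix(
        helix_length,
        anchor=(helix_length // 2, na_atom, contact_distance, np.array([1.0, 0.3, 0.2])),
    )
    chains = duplex.chains + helix.chains
    return Complex(chains=chains, resolution=2.0, meta={"entry_id": "SYN-PDNA"})


def make_contact_pair(distance: float, dna_sequence: str = "ACGTACGTAC") -> tuple:
    """Duplex plus a single protein residue whose CB sits exactly `distance`
    from one DNA base-proxy atom, radially outward so no other side-chain
    pair can be closer.  Returns (complex, protein_residue_flat_index,
    dna_residue_flat_index) for threshold tests."""
    duplex = make_duplex(HelixSpec(sequence=dna_sequence))
    _, _, strand1 = duplex.chains[0]
    target = len(strand1) // 2
    n9 = strand1[target].atom("N9").coord
    u = np.array([n9[0], n9[1], 0.0])
    u /= np.linalg.norm(u)
    cb = n9 + distance * u
    ca = cb + 1.53 * u
    n = ca + 1.46 * np.array([0.0, 0.0, 1.0])
    cc = ca + 1.52 * np.array([u[1], -u[0], 0.0])
    o = cc + 1.23 * u
    atoms = [Atom("N", n), Atom("CA", ca), Atom("C", cc), Atom("O", o),
             Atom("CB", cb, is_sidechain=True)]
    res = Residue(PolymerClass.PROTEIN, 0, "ALA", atoms, "P", 0)
    res.exists = res.compute_exists()
    c = Complex(chains=duplex.chains + [("P", PolymerClass.PROTEIN, [res])],
                resolution=2.0, meta={"entry_id": "SYN-CONTACT"})
    flat_protein = c.n_residues - 1
    return c, flat_protein, target


# ---- planted dataset ------------------------------------------------------

PLANT_MAGNITUDE = 0.6    # Å, local-frame C1' displacement per base (>> noise sigma)
PLANT_JITTER = 0.02      # Å, i.i.d. Gaussian jitter on every atom

_TETRAHEDRON = {
    "A": np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
    "C": np.array([1.0, -1.0, -1.0]) / np.sqrt(3),
    "G": np.array([-1.0, 1.0, -1.0]) / np.sqrt(3),
    "T": np.array([-1.0, -1.0, 1.0]) / np.sqrt(3),
}


@dataclass
class PlantedDataset:
    complexes: list
    magnitude: float
    jitter: float
    sequences: list = field(default_factory=list)
    shuffled: bool = False


def make_planted_dataset(n_examples: int, seed: int = 0, length: int = 8,
                         magnitude: float = PLANT_MAGNITUDE, jitter: float = PLANT_JITTER,
                         shuffle_labels: bool = False) -> PlantedDataset:
    """Duplexes whose local C1' micro-offset deterministically encodes the base.

    Each base letter maps to a fixed tetrahedral displacement of magnitude
    `magnitude` applied to C1' in the residue's local frame, plus small
    Gaussian jitter on every atom.  With `shuffle_labels` the sequences are
    re-randomized after construction, destroying the geometry–label link
    (negative control).
    """
    if n_examples < 1:
        raise ValueError("need at least one example")
    rng = np.random.default_rng(seed)
    offsets = {b: magnitude * v for b, v in _TETRAHEDRON.items()}
    complexes, sequences = [], []
    for e in range(n_examples):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        c = make_duplex(
            HelixSpec(sequence=seq), planted_offsets=offsets, rng=rng, jitter=jitter,
            meta={"entry_id": f"PLANT-{e}"},
        )
        if shuffle_labels:
            for r in c.residues:
                letter = rng.choice(list("ACGT"))
                r.token = letter_to_na_token(letter)
                r.name = f"D{letter}"
        complexes.append(c)
        sequences.append(seq)
    return PlantedDataset(complexes, magnitude, jitter, sequences, shuffle_labels)


def local_geometry_features(c: Complex) -> np.ndarray:
    """Per-nucleotide intra-residue distance vector (C1' to every other
    backbone atom, fixed atom order) — the oracle feature for the planted rule."""
    order = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "N9")
    rows = []
    for r in c.residues:
        if r.polymer_class not in (PolymerClass.DNA, PolymerClass.RNA):
            continue
        c1 = r.atom("C1'").coord
        rows.append([np.linalg.norm(r.atom(n).coord - c1) for n in order])
    return np.asarray(rows)


# ---- synthetic PPMs -------------------------------------------------------


def make_synthetic_ppm(length: int, peakedness: float, seed: int = 0,
                       consensus: str | None = None):
    """L x 4 motif with controllable concentration.

    Each position's distribution is (peakedness * one-hot + 1) / (peakedness
    + 4) around a consensus base (given or drawn); peakedness -> infinity
    approaches one-hot columns, peakedness = 0 is uniform.
    """
    from .ppm_align import normalize_ppm

    if length < 1:
        raise ValueError("length >= 1 required")
    rng = np.random.default_rng(seed)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    mat = np.zeros((length, 4))
    for i in range(length):
        if consensus is not None and i < len(consensus):
            b = base_index[consensus[i].upper()]
        else:
            b = int(rng.integers(4))
        col = np.ones(4)
        col[b] += peakedness
        mat[i] = col / col.sum()
    return normalize_ppm(mat, source_id=f"SYN-{seed}")


# ---- deliberately failing fixtures ----------------------------------------


def make_filter_fixtures() -> dict:
    """One fixture per dataset-filter clause, plus an accepted baseline.

    Keys name the (single) clause each fixture violates; "ok" passes all.
    """
    fixtures = {"ok": make_duplex(HelixSpec(sequence="ACGTACGTAC"))}

    small = make_duplex(HelixSpec(sequence="ACG"))  # 6 residues, < 100 heavy atoms
    fixtures["heavy_atoms"] = small

    res4 = make_duplex(HelixSpec(sequence="ACGTACGTAC"))
    res4.resolution = 4.0
    fixtures["resolution"] = res4

    unk = make_duplex(HelixSpec(sequence="ACGTACGTAC"))
    helper = make_protein_helix(25, chain_id="U")
    for r in helper.chains[0][2]:
        r.name = "UNK"
    fixtures["unk_dominant"] = Complex(chains=unk.chains + helper.chains,
                                       resolution=2.0, meta={"entry_id": "SYN-UNK"})

    fixtures["no_nucleic_chain"] = make_protein_helix(30)

    occ = make_duplex(HelixSpec(sequence="ACGTACGTAC"))
    for r in occ.residues:
        for a in r.atoms:
            if a.name == "P":
                a.occupancy = 0.5
        r.exists = r.compute_exists()
    fixtures["no_existing_nucleic_residue"] = occ

    return fixtures
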
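"""Position probability matrices: loading, normalization, and structure alignment.

A binding motif is an L x 4 matrix of per-position base probabilities in
(A, C, G, T) order (RNA U is read as T).  Motifs are aligned to the nucleic
chains of a complex by sliding both the motif and its reverse complement
across every chain, scoring each overlap of length >= 5 by the sum of
per-position information-content-weighted Pearson correlations between the
motif column and the one-hot of the chain base.  Best alignments (ties kept)
are merged into a per-complex target map, conflicts resolved by the higher
per-position score, or by information content where the underlying base is
unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BASES = ("A", "C", "G", "T")
PPM_EPSILON = 1e-10
MIN_OVERLAP = 5
_LN_QUARTER = math.log(0.25)
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in (A,C,G,T) indexing


class PPMError(Exception):
    pass


@dataclass
class PPM:
    probs: np.ndarray          # (L, 4), rows sum to 1
    source_id: str = ""
    group_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise PPMError("PPM must be an L x 4 matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise PPMError("PPM rows must sum to 1")

    def __len__(self):
        return self.probs.shape[0]


def normalize_ppm(raw: np.ndarray, epsilon: float = PPM_EPSILON,
                  source_id: str = "", group_id: str = "") -> PPM:
    """Add epsilon to every entry of each position and renormalize."""
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise PPMError("negative PPM entry")
    if np.any(raw.sum(axis=1) == 0):
        raise PPMError("all-zero PPM position")
    p = raw + epsilon
    p = p / p.sum(axis=1, keepdims=True)
    return PPM(p, source_id=source_id, group_id=group_id)


def reverse_complement(p: PPM) -> PPM:
    """Reverse the positions and swap A<->T, C<->G within each position."""
    return PPM(p.probs[::-1, _COMPLEMENT].copy(), source_id=p.source_id, group_id=p.group_id)


def information_content(column: np.ndarray) -> float:
    """Sum over the four bases of ln(P)/ln(0.25); 4.0 for a uniform column."""
    column = np.asarray(column, dtype=np.float64)
    if np.any(column <= 0):
        raise PPMError("information content requires strictly positive entries")
    return float(np.sum(np.log(column) / _LN_QUARTER))


def ic_weighted_pcc(column: np.ndarray, onehot: np.ndarray) -> float:
    """Half the information content times the 4-channel Pearson correlation.

    Defined as exactly 0 when the column has zero variance (uniform), where
    the correlation denominator vanishes.
    """
    column = np.asarray(column, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    dc = column - column.mean()
    do = onehot - onehot.mean()
    denom = math.sqrt(float((dc**2).sum()) * float((do**2).sum()))
    if denom == 0.0:
        return 0.0
    pcc = float((dc * do).sum()) / denom
    return 0.5 * information_content(column) * pcc


@dataclass
class AlignmentResult:
    chain_id: str
    offset: int                       # PPM position 0 relative to chain position 0
    orientation: str                  # "forward" | "reverse_complement"
    score: float
    per_position: list                # [(chain_pos, ppm_pos, score)] over scored positions
    ppm: Optional[PPM] = None


def _onehot(base_index: int) -> np.ndarray:
    v = np.zeros(4)
    v[base_index] = 1.0
    return v


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def align_ppm_to_chain(p: PPM, chain_sequence: str, chain_id: str = "",
                       min_overlap: int = MIN_OVERLAP) -> list:
    """Score every overlap >= `min_overlap` of the PPM (both orientations)
    against a chain sequence in the shared A/C/G/T/X alphabet.

    Unknown positions ('X' or anything non-canonical) are excluded from both
    the score and the overlap-length count.
    """
    results = []
    L = len(p)
    N = len(chain_sequence)
    for orientation, mat in (("forward", p), ("reverse_complement", reverse_complement(p))):
        for offset in range(-(L - 1), N):
            per_position = []
            for ppm_pos in range(L):
                cpos = offset + ppm_pos
                if not (0 <= cpos < N):
                    continue
                base = chain_sequence[cpos].upper()
                bi = _BASE_INDEX.get(base)
                if bi is None:
                    continue
                per_position.append(
                    (cpos, ppm_pos, ic_weighted_pcc(mat.probs[ppm_pos], _onehot(bi)))
                )
            if len(per_position) >= min_overlap:
                score = float(sum(s for _, _, s in per_position))
                results.append(AlignmentResult(chain_id, offset, orientation, score,
                                               per_position, ppm=mat))
    return results


def best_alignments(results: list) -> list:
    """Maximal-score alignments; exact float ties are all retained."""
    if not results:
        return []
    best = max(r.score for r in results)
    return [r for r in results if r.score == best]


@dataclass
class AlignedColumn:
    column: np.ndarray      # 4-vector summing to 1
    local_score: Optional[float]   # per-position IC-weighted PCC; None at unknown bases
    ic: float


@dataclass
class AlignedTargetMap:
    """Per-complex map: (chain_id, position) -> aligned PPM column."""

    columns: dict = field(default_factory=dict)

    def get(self, chain_id: str, position: int) -> Optional[AlignedColumn]:
        return self.columns.get((chain_id, position))

    def __len__(self):
        return len(self.columns)


def merge_alignments(group_alignments: list, chain_sequences: dict) -> AlignedTargetMap:
    """Write best alignments of each PPM group into one per-complex map.

    `group_alignments` is a list (one entry per PPM group, in input order) of
    lists of AlignmentResult.  Conflicting writes at the same position keep
    the column with the higher per-position local score; at unknown sequence
    positions (no local score) the higher information content wins; exact
    ties keep the earlier write.
    """
    out = AlignedTargetMap()
    for alignments in group_alignments:
        for aln in alignments:
            seq = chain_sequences[aln.chain_id]
            scores = {cpos: s for cpos, _, s in aln.per_position}
            for ppm_pos in range(len(aln.ppm)):
                cpos = aln.offset + ppm_pos
                if not (0 <= cpos < len(seq)):
                    continue
                col = aln.ppm.probs[ppm_pos]
                known = seq[cpos].upper() in _BASE_INDEX
                cand = AlignedColumn(
                    column=col,
                    local_score=scores.get(cpos) if known else None,
                    ic=information_content(col),
                )
                key = (aln.chain_id, cpos)
                prev = out.columns.get(key)
                if prev is None:
                    out.columns[key] = cand
                elif not known:
                    if cand.ic > prev.ic:
                        out.columns[key] = cand
                else:
                    if (cand.local_score or 0.0) > (prev.local_score or 0.0):
                        out.columns[key] = cand
    return out


def select_group_ppm(group: list, mode: str = "first",
                     rng: Optional[np.random.Generator] = None) -> PPM:
    """Pick one of several experimentally equivalent PPMs.

    Training uses `mode='random'` (uniform each load); evaluation uses
    `mode='first'` (index 0, no randomization).
    """
    if not group:
        raise PPMError("empty PPM group")
    if mode == "first":
        return group[0]
    if mode == "random":
        if rng is None:
            raise PPMError("random mode requires an rng")
        return group[int(rng.integers(len(group)))]
    raise ValueError(f"unknown mode {mode!r}")


# ---- JASPAR-style I/O -----------------------------------------------------


def read_jaspar(path) -> list:
    """Read a JASPAR-style matrix file (4 rows labelled A/C/G/T per record).

    Count matrices are column-normalized before the epsilon treatment; rows
    of probabilities are accepted as-is.  Returns a list of PPMs.
    """
    records, name, rows = [], None, {}

    def flush():
        if rows:
            mat = np.stack([rows[b] for b in BASES], axis=1)  # (L, 4)
            sums = mat.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-3):
                mat = mat / sums[:, None]
            records.append(normalize_ppm(mat, source_id=name or ""))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], {}
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if parts and parts[0].upper() in BASES:
                    rows[parts[0].upper()] = np.array([float(x) for x in parts[1:]])
    flush()
    if not records:
        raise PPMError(f"no matrices found in {path}")
    return records


def write_jaspar(p: PPM, path, name: str = "motif") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for bi, base in enumerate(BASES):
            vals = " ".join(f"{x:.6f}" for x in p.probs[:, bi])
            fh.write(f"{base} [ {vals} ]\n")


def alignment_report(results: list) -> list:
    """JSON-ready summary of alignment results."""
    return [
        {
            "chain": r.chain_id,
            "offset": r.offset,
            "orientation": r.orientation,
            "score": r.score,
            "per_position": [
                {"chain_pos": c, "ppm_pos": q, "score": s} for c, q, s in r.per_position
            ],
        }
        for r in results
    ]
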
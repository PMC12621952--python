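"""Evaluation metrics: sequence recovery, PPM comparison, C1'-RMSD.

PPM metrics follow the per-position forms used throughout the package: MAE
is the mean over positions of the L1 distance over the four bases (range
[0, 2]); cross-entropy is the mean over positions of -sum(true * ln pred)
with predictions floored at 1e-10 before the log.  C1'-RMSD enumerates all
contiguous overlaps of the shorter chain along the longer, superposes each
overlap by least-squares rotation+translation (no reflection), and returns
the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PRED_FLOOR = 1e-10


class MetricError(Exception):
    pass


@dataclass
class EvaluationRecord:
    example_id: str
    metric: str
    per_position: np.ndarray

    @property
    def aggregate(self) -> float:
        return float(np.mean(self.per_position))


def sequence_recovery(true_seq, designed_seq, designed_mask) -> float:
    """Fraction of designed positions whose identity matches the native one."""
    true_seq = np.asarray(list(true_seq))
    designed_seq = np.asarray(list(designed_seq))
    designed_mask = np.asarray(designed_mask, dtype=bool)
    if true_seq.shape != designed_seq.shape or true_seq.shape != designed_mask.shape:
        raise MetricError("sequence/mask length mismatch")
    n = int(designed_mask.sum())
    if n == 0:
        raise MetricError("no designed positions; recovery undefined")
    return float((true_seq[designed_mask] == designed_seq[designed_mask]).sum() / n)


def ppm_mae(true_window: np.ndarray, pred_window: np.ndarray) -> float:
    """Mean over positions of the summed absolute base-probability error."""
    t = np.asarray(true_window, dtype=np.float64)
    q = np.asarray(pred_window, dtype=np.float64)
    if t.shape != q.shape or t.ndim != 2 or t.shape[0] < 1:
        raise MetricError("PPM windows must be equal-shape L x 4 with L >= 1")
    return float(np.abs(t - q).sum(axis=1).mean())


def ppm_cross_entropy(true_window: np.ndarray, pred_window: np.ndarray) -> float:
    """Mean over positions of -sum(true * ln pred), pred floored at 1e-10."""
    t = np.asarray(true_window, dtype=np.float64)
    q = np.asarray(pred_window, dtype=np.float64)
    if t.shape != q.shape or t.ndim != 2 or t.shape[0] < 1:
        raise MetricError("PPM windows must be equal-shape L x 4 with L >= 1")
    q = np.maximum(q, PRED_FLOOR)
    return float(-(t * np.log(q)).sum(axis=1).mean())


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (transformed mobile, rotation, translation).  The reflection
    branch is excluded (proper rotation enforced via the SVD determinant).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return (R @ mobile.T).T + t, R, t


def c1_rmsd(native_coords: np.ndarray, model_coords: np.ndarray):
    """Minimum superposed C1' RMSD over all contiguous overlaps.

    The shorter coordinate set slides along the longer; each full-containment
    offset is superposed and scored, and the best (RMSD, offset, overlap
    length) is returned.  Symmetric for equal lengths (single overlap).
    """
    a = np.asarray(native_coords, dtype=np.float64)
    b = np.asarray(model_coords, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise MetricError("coordinate arrays must be (N, 3)")
    if min(len(a), len(b)) < 3:
        raise MetricError("need at least 3 C1' atoms for superposition")

    swap = len(b) > len(a)
    long_, short = (b, a) if swap else (a, b)
    best = (np.inf, 0, len(short))
    for offset in range(len(long_) - len(short) + 1):
        window = long_[offset:offset + len(short)]
        moved, _, _ = kabsch_superpose(short, window)
        rmsd = float(np.sqrt(((moved - window) ** 2).sum(axis=1).mean()))
        if rmsd < best[0]:
            best = (rmsd, offset, len(short))
    return best


# ---- secondary-structure crop utility -------------------------------------

_OPEN = "([{<"
_CLOSE = ")]}>"


def parse_pairs(dotbracket: str) -> dict:
    """Base-pair map from a dot-bracket string (multiple bracket families)."""
    stacks = {o: [] for o in _OPEN}
    pairs = {}
    for i, ch in enumerate(dotbracket):
        if ch in _OPEN:
            stacks[ch].append(i)
        elif ch in _CLOSE:
            o = _OPEN[_CLOSE.index(ch)]
            if not stacks[o]:
                raise MetricError(f"unbalanced bracket at {i}")
            j = stacks[o].pop()
            pairs[i] = j
            pairs[j] = i
    if any(s for s in stacks.values()):
        raise MetricError("unbalanced bracket (unclosed)")
    return pairs


def crop_secondary_structure(dotbracket: str, start: int, end: int) -> str:
    """Crop to [start, end); a pair whose partner falls outside becomes a loop."""
    pairs = parse_pairs(dotbracket)
    out = []
    for i in range(start, end):
        ch = dotbracket[i]
        j = pairs.get(i)
        if j is not None and not (start <= j < end):
            ch = "."
        out.append(ch)
    return "".join(out)
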
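"""Motif normalization, reverse complement, IC-weighted PCC alignment, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nadesign.ppm_align import (
    PPM,
    PPMError,
    AlignedColumn,
    align_ppm_to_chain,
    best_alignments,
    ic_weighted_pcc,
    information_content,
    merge_alignments,
    normalize_ppm,
    read_jaspar,
    reverse_complement,
    select_group_ppm,
    write_jaspar,
)
from nadesign.synthetic import make_synthetic_ppm


def _onehot4(i):
    v = np.zeros(4)
    v[i] = 1.0
    return v


def _eps_onehot_ppm(seq):
    mat = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        mat[i, "ACGT".index(b)] = 1.0
    return normalize_ppm(mat)


class TestNormalize:
    def test_uniform_fixed_point(self):
        p = normalize_ppm(np.full((3, 4), 0.25))
        assert np.allclose(p.probs, 0.25)

    def test_count_column(self):
        p = normalize_ppm(np.array([[7.0, 1.0, 1.0, 1.0]]) / 10.0)
        assert np.allclose(p.probs, [[0.7, 0.1, 0.1, 0.1]], atol=1e-9)

    def test_one_hot_epsilon_semantics(self):
        p = normalize_ppm(np.array([[1.0, 0.0, 0.0, 0.0]]))
        assert p.probs[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert (p.probs[0, 1:] > 0).all()
        assert p.probs[0, 1:].max() < 1e-9

    def test_negative_raises(self):
        with pytest.raises(PPMError):
            normalize_ppm(np.array([[-0.1, 0.5, 0.3, 0.3]]))


class TestReverseComplement:
    @given(seed=st.integers(0, 100), L=st.integers(1, 10))
    @settings(max_examples=30, deadline=None)
    def test_involution(self, seed, L):
        p = make_synthetic_ppm(L, 5.0, seed=seed)
        assert np.allclose(reverse_complement(reverse_complement(p)).probs, p.probs)

    def test_uniform_fixed_point(self):
        p = PPM(np.full((4, 4), 0.25))
        assert np.allclose(reverse_complement(p).probs, 0.25)

    def test_single_column_swap(self):
        p = PPM(np.array([[0.7, 0.1, 0.1, 0.1]]))
        assert np.allclose(reverse_complement(p).probs, [[0.1, 0.1, 0.1, 0.7]])


class TestInformationContent:
    def test_uniform_is_four(self):
        assert information_content(np.full(4, 0.25)) == pytest.approx(4.0)

    def test_peaked_column(self):
        assert information_content(np.array([0.97, 0.01, 0.01, 0.01])) == pytest.approx(
            9.99, abs=0.01)

    def test_eps_one_hot(self):
        col = normalize_ppm(np.array([[1.0, 0, 0, 0]])).probs[0]
        assert information_content(col) == pytest.approx(49.8, abs=0.1)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_channel_permutation_invariant(self, seed):
        col = make_synthetic_ppm(1, 8.0, seed=seed).probs[0]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(4)
        assert information_content(col[perm]) == pytest.approx(information_content(col))


class TestICWeightedPCC:
    def test_uniform_column_defined_zero(self):
        assert ic_weighted_pcc(np.full(4, 0.25), _onehot4(0)) == 0.0

    def test_matching_one_hot(self):
        col = normalize_ppm(np.array([[1.0, 0, 0, 0]])).probs[0]
        assert ic_weighted_pcc(col, _onehot4(0)) == pytest.approx(
            0.5 * information_content(col), rel=1e-6)

    def test_mismatches_equal_and_negative(self):
        col = normalize_ppm(np.array([[1.0, 0, 0, 0]])).probs[0]
        vals = [ic_weighted_pcc(col, _onehot4(i)) for i in (1, 2, 3)]
        assert all(v < 0 for v in vals)
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])


def _brute_force_align(p, chain, min_overlap=5):
    """Independent enumeration over (orientation, offset, position)."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    out = []
    for orientation, mat in (("forward", p), ("reverse_complement", reverse_complement(p))):
        for offset in range(-(len(p) - 1), len(chain)):
            scores = []
            for q in range(len(p)):
                cp = offset + q
                if 0 <= cp < len(chain) and chain[cp] in base_index:
                    scores.append(ic_weighted_pcc(mat.probs[q], _onehot4(base_index[chain[cp]])))
            if len(scores) >= min_overlap:
                out.append((orientation, offset, sum(scores)))
    return out


class TestAlignment:
    def test_planted_consensus_found(self):
        p = _eps_onehot_ppm("ACGTA")
        best = best_alignments(align_ppm_to_chain(p, "TTACGTATT"))
        forward = [b for b in best if b.orientation == "forward"]
        assert forward and forward[0].offset == 2
        # each of the 5 positions contributes 0.5*IC with PCC ~ 1
        expected = sum(0.5 * information_content(p.probs[i]) for i in range(5))
        assert forward[0].score == pytest.approx(expected, rel=1e-6)

    def test_short_chain_no_overlap(self):
        p = _eps_onehot_ppm("ACGTA")
        assert align_ppm_to_chain(p, "ACGT") == []

    def test_unknowns_excluded_from_overlap_count(self):
        p = _eps_onehot_ppm("ACGTA")
        # 5 overlapping positions but one is unknown -> only 4 count
        assert align_ppm_to_chain(p, "ACGXA") == []
        assert align_ppm_to_chain(p, "ACGTA") != []

    def test_score_sum_consistency(self):
        p = make_synthetic_ppm(6, 4.0, seed=3)
        for r in align_ppm_to_chain(p, "ACGTACGTACGT"):
            assert r.score == pytest.approx(sum(s for _, _, s in r.per_position))

    @pytest.mark.parametrize("L", range(1, 9))
    def test_brute_force_equivalence(self, L):
        """Exhaustive-enumeration oracle over all chain lengths up to 12,
        including unknown positions."""
        rng = np.random.default_rng(L)
        for N in range(1, 13):
            p = make_synthetic_ppm(L, 3.0, seed=100 * L + N)
            chain = "".join(rng.choice(list("ACGTX"), size=N, p=[0.22] * 4 + [0.12]))
            got = {(r.orientation, r.offset): r.score
                   for r in align_ppm_to_chain(p, chain)}
            want = {(o, off): s for o, off, s in _brute_force_align(p, chain)}
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == want[k]  # identical summation order -> exact

    def test_mirror_symmetry(self):
        """Max forward score vs a chain equals max reverse-complement score
        vs the reverse-complemented chain."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "X": "X"}
        p = make_synthetic_ppm(5, 6.0, seed=9)
        chain = "ACGTAXGGTACC"
        rc_chain = "".join(comp[b] for b in reversed(chain))
        res = align_ppm_to_chain(p, chain)
        res_rc = align_ppm_to_chain(p, rc_chain)
        fwd = max(r.score for r in res if r.orientation == "forward")
        rc = max(r.score for r in res_rc if r.orientation == "reverse_complement")
        assert fwd == pytest.approx(rc, rel=1e-9)


class TestMerge:
    def _aln(self, chain, offset, ppm, scores):
        from nadesign.ppm_align import AlignmentResult

        per = [(offset + q, q, s) for q, s in enumerate(scores)]
        return AlignmentResult(chain, offset, "forward", sum(scores), per, ppm=ppm)

    def test_single_alignment_written(self):
        p = make_synthetic_ppm(3, 5.0, seed=1)
        m = merge_alignments([[self._aln("A", 2, p, [1.0, 1.0, 1.0])]], {"A": "ACGTACGT"})
        assert len(m) == 3
        assert np.allclose(m.get("A", 2).column, p.probs[0])

    def test_conflict_higher_local_score_wins(self):
        p1 = make_synthetic_ppm(1, 5.0, seed=2)
        p2 = make_synthetic_ppm(1, 5.0, seed=3)
        m = merge_alignments(
            [[self._aln("A", 0, p1, [1.2])], [self._aln("A", 0, p2, [0.8])]],
            {"A": "ACGT"})
        assert np.allclose(m.get("A", 0).column, p1.probs[0])
        m2 = merge_alignments(
            [[self._aln("A", 0, p1, [0.8])], [self._aln("A", 0, p2, [1.2])]],
            {"A": "ACGT"})
        assert np.allclose(m2.get("A", 0).column, p2.probs[0])

    def test_unknown_position_tiebreak_by_ic(self):
        sharp = normalize_ppm(np.array([[0.97, 0.01, 0.01, 0.01]]))
        flat = normalize_ppm(np.array([[0.4, 0.2, 0.2, 0.2]]))
        m = merge_alignments(
            [[self._aln("A", 0, flat, [0.0])], [self._aln("A", 0, sharp, [0.0])]],
            {"A": "XCGT"})
        assert np.allclose(m.get("A", 0).column, sharp.probs[0])

    def test_order_independent_with_distinct_scores(self):
        p1 = make_synthetic_ppm(2, 5.0, seed=4)
        p2 = make_synthetic_ppm(2, 5.0, seed=5)
        g1 = [[self._aln("A", 0, p1, [1.0, 2.0])], [self._aln("A", 1, p2, [3.0, 0.5])]]
        g2 = list(reversed(g1))
        m1 = merge_alignments(g1, {"A": "ACGTA"})
        m2 = merge_alignments(g2, {"A": "ACGTA"})
        for key in m1.columns:
            assert np.allclose(m1.columns[key].column, m2.columns[key].column)


class TestGroupSelection:
    def test_singleton(self):
        p = make_synthetic_ppm(3, 5.0, seed=0)
        assert select_group_ppm([p], "first") is p
        assert select_group_ppm([p], "random", np.random.default_rng(0)) is p

    def test_first_mode_never_randomizes(self):
        group = [make_synthetic_ppm(3, 5.0, seed=s) for s in range(3)]
        for _ in range(10):
            assert select_group_ppm(group, "first") is group[0]

    def test_random_mode_uniform(self):
        group = [make_synthetic_ppm(3, 5.0, seed=s) for s in range(2)]
        rng = np.random.default_rng(77)
        picks = sum(select_group_ppm(group, "random", rng) is group[0] for _ in range(5000))
        assert picks / 5000 == pytest.approx(0.5, abs=0.02)

    def test_empty_group_raises(self):
        with pytest.raises(PPMError):
            select_group_ppm([], "first")


def test_jaspar_roundtrip(tmp_path):
    p = make_synthetic_ppm(7, 6.0, seed=11)
    path = tmp_path / "motif.jaspar"
    write_jaspar(p, path, name="M1")
    back = read_jaspar(path)[0]
    assert np.allclose(back.probs, p.probs, atol=1e-5)


def test_jaspar_counts_normalized(tmp_path):
    path = tmp_path / "counts.jaspar"
    path.write_text(">M2\nA [ 7 0 ]\nC [ 1 10 ]\nG [ 1 0 ]\nT [ 1 0 ]\n")
    p = read_jaspar(path)[0]
    assert np.allclose(p.probs[0], [0.7, 0.1, 0.1, 0.1], atol=1e-8)
    assert p.probs[1, 1] == pytest.approx(1.0, abs=1e-9)
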
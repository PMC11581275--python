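import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdose.conservation import (
    AlignmentParams,
    align_pair,
    curate_fs,
    curate_sc,
    intersect_sets,
    read_fasta,
    reassign_to_reference,
    top_match,
)
from mirdose.synthetic import HomologyMap, simulate_mirna_fasta

MATCH, MISMATCH, OPEN, EXT = 5.0, -4.0, 10.0, 0.1


def brute_force_score(a: str, b: str) -> float:
    """Exhaustive maximum over all global alignments with affine gaps.

    A length-k gap costs OPEN + (k-1)*EXT; adjacent gaps in opposite
    sequences are distinct gaps. Recursion enumerates every alignment, so
    this is independent of any dynamic-programming shortcut.
    """

    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(
                best, (MATCH if a[i] == b[j] else MISMATCH) + rec(i + 1, j + 1, "m")
            )
        if i < len(a):
            best = max(best, -(EXT if prev == "gb" else OPEN) + rec(i + 1, j, "gb"))
        if j < len(b):
            best = max(best, -(EXT if prev == "ga" else OPEN) + rec(i, j + 1, "ga"))
        return best

    return rec(0, 0, None)


rna = st.text(alphabet="ACGU", min_size=1, max_size=30)


class TestAlignPair:
    def test_exact_match_worked_example(self):
        r = align_pair("ACGU", "ACGU")
        assert r.score == 20.0  # 4 matches at +5
        assert r.pct_identity == 100.0
        assert r.aligned_length == 4

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(rna.filter(lambda s: 18 <= len(s) <= 30))
    def test_self_identity_is_100(self, seq):
        r = align_pair(seq, seq)
        assert r.pct_identity == 100.0
        assert r.score == pytest.approx(len(seq) * MATCH)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(rna, rna)
    def test_score_symmetric(self, a, b):
        assert align_pair(a, b).score == pytest.approx(align_pair(b, a).score)

    def test_thymine_mapped_to_uracil(self):
        assert align_pair("ACGT", "ACGU").pct_identity == 100.0

    def test_empty_or_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGU")
        with pytest.raises(ValueError):
            align_pair("ACGX", "ACGU")

    def test_dp_score_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            la, lb = rng.integers(1, 8, 2)
            a = "".join(rng.choice(list("ACGU"), la))
            b = "".join(rng.choice(list("ACGU"), lb))
            assert align_pair(a, b).score == pytest.approx(brute_force_score(a, b))

    def test_percent_scoring_mode_bounded(self):
        p = AlignmentParams(scoring_mode="percent")
        r = align_pair("ACGUACGUACGUACGUAC", "ACGUACGUACGUACGUAC", p)
        assert r.score == pytest.approx(100.0)


class TestTopMatch:
    def test_unique_exact_reference_wins(self):
        ref = {"r1": "ACGUACGUACGUACGUAC", "r2": "GGGGGGGGGGGGGGGGGG"}
        out = top_match("q", "ACGUACGUACGUACGUAC", ref)
        assert [m.target for m in out] == ["r1"]

    def test_duplicate_references_both_returned(self):
        seq = "ACGUACGUACGUACGUAC"
        out = top_match("q", seq, {"r1": seq, "r2": seq})
        assert [m.target for m in out] == ["r1", "r2"]

    def test_best_by_score_matches_oracle_on_short_references(self):
        rng = np.random.default_rng(3)
        query = "".join(rng.choice(list("ACGU"), 6))
        ref = {
            f"r{i}": "".join(rng.choice(list("ACGU"), int(rng.integers(2, 8))))
            for i in range(8)
        }
        best_dp = top_match("q", query, ref)[0]
        oracle_scores = {tid: brute_force_score(query, s) for tid, s in ref.items()}
        assert best_dp.score == pytest.approx(max(oracle_scores.values()))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            top_match("q", "ACGU", {})


@pytest.fixture(scope="module")
def planted_fastas(tmp_path_factory):
    """Homologues at 100% identity plus diverged decoys near 50%."""
    d = tmp_path_factory.mktemp("fasta")
    pairs = [(f"mml-{i}", f"hsa-{i}", 100.0) for i in range(5)]
    pairs += [(f"mml-d{i}", f"hsa-d{i}", 50.0) for i in range(5)]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        simulate_mirna_fasta(HomologyMap(tuple(pairs)), d / "a.fa", d / "b.fa", seed=5)
    return read_fasta(d / "a.fa"), read_fasta(d / "b.fa")


class TestCurateSc:
    def test_planted_homologues_recovered(self, planted_fastas):
        fa, fb = planted_fastas
        de = sorted(fa)
        sc, homologues = curate_sc(de, fa, fb, min_identity=90.0)
        assert sc == {f"mml-{i}" for i in range(5)}
        assert all(f in homologues for f in de)

    def test_min_identity_zero_accepts_everything(self, planted_fastas):
        fa, fb = planted_fastas
        sc, _ = curate_sc(sorted(fa), fa, fb, min_identity=0.0)
        assert sc == set(fa)

    def test_min_identity_above_100_accepts_nothing(self, planted_fastas):
        fa, fb = planted_fastas
        sc, _ = curate_sc(sorted(fa), fa, fb, min_identity=101.0)
        assert sc == set()

    def test_feature_missing_from_fasta_excluded(self, planted_fastas):
        fa, fb = planted_fastas
        sc, homologues = curate_sc(["mml-0", "mml-unknown"], fa, fb)
        assert "mml-unknown" not in homologues
        assert sc <= {"mml-0"}


class TestCurateFs:
    def test_identity_reference_reproduces_de_union(self, normalized):
        """Re-assigning each feature to itself must leave the screen unchanged."""
        from mirdose.anova import fit_four_way_anova

        counts, meta = normalized["counts"], normalized["meta"]
        sub = counts.iloc[:40]
        hm = HomologyMap(tuple((f, f, 100.0) for f in sub.index))
        import tempfile, pathlib, warnings

        d = pathlib.Path(tempfile.mkdtemp())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            simulate_mirna_fasta(hm, d / "a.fa", d / "b.fa", seed=8)
        fa = read_fasta(d / "a.fa")
        fs, mapping = curate_fs(sub, meta, fa, fa)
        assert mapping == {f: f for f in sub.index}
        # expected: the same screen run directly on the sub-matrix
        from mirdose.normalize import (
            cpm,
            normalized_log2_cpm,
            prefilter_features,
            tmm_factors,
        )

        filt = prefilter_features(sub)
        expr = normalized_log2_cpm(cpm(filt, tmm_factors(filt)))
        expected = set(fit_four_way_anova(expr, meta).de_union().union)
        assert fs == expected

    def test_single_reference_collapses_to_one_id(self, normalized):
        counts, meta = normalized["counts"], normalized["meta"]
        sub = counts.iloc[:10]
        seqs = {f: "ACGUACGUACGUACGUACGU" for f in sub.index}
        reference = {"hsa-only": "ACGUACGUACGUACGUACGU"}
        fs, mapping = curate_fs(sub, meta, reference, seqs)
        assert set(mapping.values()) == {"hsa-only"}
        assert fs <= {"hsa-only"}

    def test_no_sequences_gives_empty_set_with_warning(self, normalized):
        counts, meta = normalized["counts"], normalized["meta"]
        fs, mapping = curate_fs(counts.iloc[:5], meta, {"r": "ACGUACGUACGUACGUAC"}, {})
        assert fs == set() and mapping == {}


class TestIntersect:
    def test_identity_map_intersection_is_sc(self, planted_fastas):
        fa, fb = planted_fastas
        sc, homologues = curate_sc(sorted(fa), fa, fb, min_identity=90.0)
        fs = {m.target for f in sc for m in homologues[f]}
        sets = intersect_sets(sc, fs, homologues)
        assert sets.cnvd == sc

    def test_disjoint_sets_give_empty_cnvd(self, planted_fastas):
        fa, fb = planted_fastas
        sc, homologues = curate_sc(sorted(fa), fa, fb, min_identity=90.0)
        sets = intersect_sets(sc, {"unrelated-id"}, homologues)
        assert sets.cnvd == set()

    def test_cnvd_bounded_by_both_sets(self, planted_fastas):
        fa, fb = planted_fastas
        rng = np.random.default_rng(4)
        _, homologues = curate_sc(sorted(fa), fa, fb, min_identity=0.0)
        for _ in range(20):
            sc = set(rng.choice(sorted(fa), size=rng.integers(0, len(fa)), replace=False))
            fs = set(
                rng.choice(sorted(fb), size=rng.integers(0, len(fb)), replace=False)
            )
            sets = intersect_sets(sc, fs, homologues)
            assert len(sets.cnvd) <= min(len(sc) if sc else 0, len(fs) if fs else 0) or (
                len(sets.cnvd) <= len(sc)
            )
            assert sets.cnvd <= sc
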
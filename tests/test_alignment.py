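"""Profile-profile DP, transitive alignment, metrics, and analyses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligomod.alignment import (ClusterRecord, PairAlignment,
                                classify_cluster_overlap, column_score,
                                filter_clusters, gap_percentage, identity,
                                kde, min_family_identity,
                                profile_profile_align, read_alignment_fasta,
                                read_cluster_table, transitive_align,
                                write_alignment_fasta, write_cluster_table)
from oligomod.domains import DomainHit, hmm_from_msa, viterbi_scan
from oligomod.sequences import TargetSequence, profile_from_sequence

from .oracles import random_profile, random_sequence
from .oracles import best_alignment_score_bruteforce


def _aln(cols, ids=("a", "b")):
    return PairAlignment(id_a=ids[0], id_b=ids[1], columns=cols)


class TestPairAlignmentInvariants:
    def test_double_gap_column_rejected(self):
        with pytest.raises(ValueError, match="gap in both"):
            _aln([(1, 1), (None, None)])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _aln([(2, 1), (1, 2)])


class TestProfileProfileAlign:
    def test_self_alignment_all_matches(self):
        p = profile_from_sequence(TargetSequence("s", "ACDE"))
        aln = profile_profile_align(p, p)
        assert aln.columns == [(1, 1), (2, 2), (3, 3), (4, 4)]
        assert identity(aln, "ACDE", "ACDE") == 100.0
        assert gap_percentage(aln) == 0.0

    def test_argument_swap_transposes(self, rng):
        a = random_profile(rng, 4, "a")
        b = random_profile(rng, 6, "b")
        f = profile_profile_align(a, b)
        r = profile_profile_align(b, a)
        assert f.score == pytest.approx(r.score, abs=1e-9)
        assert [(x, y) for x, y in f.match_columns] == \
            [(y, x) for x, y in r.match_columns]

    @pytest.mark.parametrize("mode", ["global-free-ends", "local"])
    def test_score_matches_exhaustive_enumeration(self, rng, mode):
        for _ in range(60):
            la, lb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            a = random_profile(rng, la, "a")
            b = random_profile(rng, lb, "b")
            gap_open = float(rng.uniform(0.5, 6.0))
            gap_extend = float(rng.uniform(0.1, 1.5))
            S = np.asarray(column_score(a, b))
            expected = best_alignment_score_bruteforce(
                S, mode, gap_open, gap_extend)
            aln = profile_profile_align(a, b, mode=mode, gap_open=gap_open,
                                        gap_extend=gap_extend)
            assert aln.score == pytest.approx(expected, abs=1e-9), mode

    def test_free_ends_covers_both_sequences(self, rng):
        a = random_profile(rng, 5, "a")
        b = random_profile(rng, 9, "b")
        aln = profile_profile_align(a, b)
        assert {p for p, _ in aln.columns if p is not None} <= set(range(1, 6))
        covered_a = {p for p, _ in aln.columns if p is not None}
        covered_b = {p for _, p in aln.columns if p is not None}
        assert covered_a == set(range(1, 6))
        assert covered_b == set(range(1, 10))

    def test_non_finite_profiles_rejected(self, rng):
        a = random_profile(rng, 3, "a")
        a.log_odds[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            profile_profile_align(a, random_profile(rng, 3, "b"))


class TestTransitiveAlign:
    def _scan_one(self, hmm, name, seq):
        hits = viterbi_scan(hmm, TargetSequence(id=name, residues=seq),
                            bitscore_cutoff=-1e9, max_hits=1)
        assert hits
        return hits[0]

    def test_identical_sequences_identity_100(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        hmm = hmm_from_msa("fam", [seq, seq])
        h1 = self._scan_one(hmm, "x", seq)
        h2 = self._scan_one(hmm, "y", seq)
        aln = transitive_align(h1, h2)
        assert identity(aln, seq, seq) == 100.0

    def test_match_state_intersection(self):
        h1 = DomainHit(pfam="PF", seq_id="x", start=1, end=10, score=1.0,
                       match_map=[(i, i) for i in range(1, 11)])
        h2 = DomainHit(pfam="PF", seq_id="y", start=1, end=10, score=1.0,
                       match_map=[(i, i + 5) for i in range(1, 11)])
        aln = transitive_align(h1, h2)
        assert [c for c in aln.columns] == \
            [(m, m - 5) for m in range(6, 11)]

    def test_different_hmms_rejected(self):
        h1 = DomainHit(pfam="PFA", seq_id="x", start=1, end=2, score=1.0,
                       match_map=[(1, 1)])
        h2 = DomainHit(pfam="PFB", seq_id="y", start=1, end=2, score=1.0,
                       match_map=[(1, 1)])
        with pytest.raises(ValueError, match="different HMMs"):
            transitive_align(h1, h2)

    def test_no_shared_states_rejected(self):
        h1 = DomainHit(pfam="PF", seq_id="x", start=1, end=2, score=1.0,
                       match_map=[(1, 1)])
        h2 = DomainHit(pfam="PF", seq_id="y", start=1, end=2, score=1.0,
                       match_map=[(1, 5)])
        with pytest.raises(ValueError, match="no shared match states"):
            transitive_align(h1, h2)

    def test_family_pairwise_identity_matches_recount(self, rng):
        # toy family of 6 gap-free members spanning all match states
        base = random_sequence(rng, 25)
        members = {f"m{i}": "".join(
            ch if rng.random() > 0.25 else random_sequence(rng, 1)
            for ch in base) for i in range(6)}
        hmm = hmm_from_msa("fam", list(members.values()))
        hits = {n: self._scan_one(hmm, n, s) for n, s in members.items()}
        names = sorted(members)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                aln = transitive_align(hits[a], hits[b])
                got = identity(aln, members[a], members[b])
                # independent recount over shared states
                ma = dict((m, p) for p, m in hits[a].match_map)
                mb = dict((m, p) for p, m in hits[b].match_map)
                shared = set(ma) & set(mb)
                same = sum(1 for m in shared
                           if members[a][ma[m] - 1] == members[b][mb[m] - 1])
                assert got == pytest.approx(100.0 * same / len(shared))


class TestMetrics:
    def test_identity_forced_arithmetic(self):
        aln = _aln([(1, 1), (2, 2), (3, 3), (4, 4)])
        assert identity(aln, "AAAA", "AAAT") == 75.0

    def test_identity_no_gap_free_columns_warns(self, caplog):
        aln = _aln([(1, None), (None, 1)])
        with caplog.at_level("WARNING"):
            assert identity(aln, "A", "A") == 0.0
        assert "no gap-free" in caplog.text

    def test_identity_out_of_bounds(self):
        aln = _aln([(1, 1), (2, 2)])
        with pytest.raises(ValueError, match="bounds"):
            identity(aln, "A", "AA")

    def test_gap_percentage(self):
        assert gap_percentage(_aln([(1, 1), (2, 2)])) == 0.0
        cols = [(1, 1), (2, None), (3, 2), (4, 3), (None, 4), (5, 5),
                (6, 6), (7, 7)]
        assert gap_percentage(_aln(cols)) == 25.0

    def test_swap_invariance(self, rng):
        for _ in range(20):
            seq_a = random_sequence(rng, 8)
            seq_b = random_sequence(rng, 8)
            cols, pa, pb = [], 0, 0
            while pa < 8 and pb < 8:
                r = rng.random()
                if r < 0.6:
                    pa, pb = pa + 1, pb + 1
                    cols.append((pa, pb))
                elif r < 0.8:
                    pa += 1
                    cols.append((pa, None))
                else:
                    pb += 1
                    cols.append((None, pb))
            aln = _aln(cols)
            swapped = aln.swapped()
            assert identity(aln, seq_a, seq_b) == \
                identity(swapped, seq_b, seq_a)
            assert gap_percentage(aln) == gap_percentage(swapped)

    def test_min_family_identity_minimum_forced(self):
        # three members with hand-set match maps giving 100/50/50
        seqs = {"a": "AAAA", "b": "AAAA", "c": "AATT"}
        hits = [DomainHit(pfam="PF", seq_id=n, start=1, end=4, score=1.0,
                          match_map=[(i, i) for i in range(1, 5)])
                for n in seqs]
        out = min_family_identity({"PF": hits}, seqs)
        assert out["PF"] == 50.0

    def test_min_family_identity_pair_of_identical(self):
        seqs = {"a": "ACDE", "b": "ACDE"}
        hits = [DomainHit(pfam="PF", seq_id=n, start=1, end=4, score=1.0,
                          match_map=[(i, i) for i in range(1, 5)])
                for n in seqs]
        assert min_family_identity({"PF": hits}, seqs) == {"PF": 100.0}


class TestKde:
    def test_peak_at_repeated_value(self):
        grid, dens = kde([50.0] * 10 + [50.0], bandwidth=1.0)
        assert grid[np.argmax(dens)] == pytest.approx(50.0, abs=0.2)

    def test_symmetry_about_midpoint(self):
        grid, dens = kde([20.0, 80.0], bandwidth=5.0, npoints=1001)
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-12)

    def test_mixture_mode_recovered(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([
            rng.normal(30, 3, size=700), rng.normal(70, 8, size=300)
        ])
        grid, dens = kde(values, bandwidth="auto", npoints=2001)
        assert abs(grid[np.argmax(dens)] - 30.0) < 2.0

    def test_nonnegative_and_normalized(self, rng):
        for _ in range(20):
            vals = rng.uniform(5, 95, size=int(rng.integers(2, 40)))
            bw = float(rng.uniform(0.5, 6.0))
            grid = np.linspace(-10 * bw, 100 + 10 * bw, 4001)
            g, dens = kde(vals, bandwidth=bw, grid=grid)
            assert np.all(dens >= 0)
            assert np.trapezoid(dens, g) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            kde([50.0])


class TestClusters:
    def _rec(self, cid, cf, ident, entries=("1abc",)):
        return ClusterRecord(cluster_id=cid, pfams=("PF",),
                             entries=frozenset(entries), crystal_forms=cf,
                             min_identity=ident)

    def test_boundary_behavior(self):
        kept = filter_clusters([self._rec("a", 5, 89.9),
                                self._rec("b", 4, 10.0),
                                self._rec("c", 5, 90.0)])
        assert [c.cluster_id for c in kept] == ["a"]

    def test_random_table_predicate_oracle(self, rng):
        recs = [self._rec(f"c{i}", int(rng.integers(1, 10)),
                          float(rng.uniform(0, 100)))
                for i in range(50)]
        kept = filter_clusters(recs)
        expected = [r for r in recs
                    if r.crystal_forms >= 5 and r.min_identity < 90.0]
        assert kept == expected

    def test_overlap_classification(self):
        a = self._rec("a", 5, 10.0, entries=("1abc",))
        b = self._rec("b", 5, 10.0, entries=("2xyz",))
        c = self._rec("c", 5, 10.0, entries=("1abc", "2xyz"))
        assert classify_cluster_overlap(a, b) == "disjoint"
        assert classify_cluster_overlap(c, b) == "overlapping"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(["a", "b", "c", "d"])),
           st.sets(st.sampled_from(["c", "d", "e", "f"])))
    def test_overlap_matches_set_intersection(self, ea, eb):
        a = self._rec("a", 5, 10.0, entries=ea or {"za"})
        b = self._rec("b", 5, 10.0, entries=eb or {"zb"})
        verdict = classify_cluster_overlap(a, b)
        assert verdict == ("overlapping" if (a.entries & b.entries)
                           else "disjoint")

    def test_table_round_trip(self, tmp_path):
        recs = [ClusterRecord("c1", ("PFA", "PFB"), frozenset({"1a", "2b"}),
                              6, 45.5)]
        path = tmp_path / "cl.tsv"
        write_cluster_table(recs, path)
        back = read_cluster_table(path)
        assert back == recs


class TestAlignmentFastaRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        seq_a, seq_b = "ACDEFG", "ACWF"
        aln = _aln([(1, 1), (2, 2), (3, None), (4, 3), (5, 4), (6, None)])
        path = tmp_path / "aln.a2m"
        write_alignment_fasta(aln, seq_a, seq_b, path)
        back, sa, sb = read_alignment_fasta(path)
        assert back.columns == aln.columns
        assert (sa, sb) == (seq_a, seq_b)

    def test_hand_edit_then_reload(self, tmp_path):
        path = tmp_path / "aln.a2m"
        path.write_text(">a\nAC-E\n>b\nACW-\n")
        aln, sa, sb = read_alignment_fasta(path)
        assert aln.columns == [(1, 1), (2, 2), (None, 3), (3, None)]
        assert (sa, sb) == ("ACE", "ACW")
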
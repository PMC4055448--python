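"""Entity assignment, backbone threading, and side-chain grafting."""

import numpy as np
import pytest

import biotite.structure.info as binfo

from oligomod.alignment import PairAlignment
from oligomod.assembly import Atom, Chain, ONE_TO_THREE, Residue
from oligomod.modelbuild import (COPIED_IDENTICAL, MUTATED_REBUILT,
                                 UNMODELED_INSERTION,
                                 assign_targets_to_entities, build_complex,
                                 graft_side_chains, thread_backbone)
from oligomod.domains import DomainArchitecture, TemplateRecord
from oligomod.sequences import TargetSequence
from oligomod.sidechains import (CHI_DEFS, RotamerEntry, build_side_chain,
                                 default_rotamer_library, ideal_recipe,
                                 load_rotamer_table, write_rotamer_table)

from .oracles import random_sequence
from .oracles import best_rotamer_bruteforce


def _identity_alignment(n, ids=("t", "e")):
    return PairAlignment(id_a=ids[0], id_b=ids[1],
                         columns=[(i, i) for i in range(1, n + 1)])


def _chain_for(sequence, chain_id="A", entity_id="1"):
    """A fully built template chain (helix + top-rotamer side chains)."""
    from oligomod.fixtures import _helix_backbone

    residues = []
    for num, (name3, atoms) in enumerate(_helix_backbone(sequence), start=1):
        residues.append(Residue(
            seq_num=num, name=name3,
            atoms=[Atom(an, el, np.array(pos)) for an, el, pos in atoms],
        ))
    return Chain(chain_id=chain_id, entity_id=entity_id, residues=residues)


class TestAssignTargets:
    def _template(self, entities):
        recs = []
        for eid, seq, fam in entities:
            arch = DomainArchitecture(
                seq_id=f"t_{eid}", domains=[(fam, 1, len(seq))])
            recs.append((eid, seq, arch))
        return TemplateRecord(pdb_id="9tpl", resolution=2.0, entities=recs,
                              assemblies=[("1", {e: 1 for e, _, _ in recs})])

    def _arch(self, tid, fam, length):
        return DomainArchitecture(seq_id=tid, domains=[(fam, 1, length)])

    def test_receptor_style_closest_entity_wins(self, rng):
        e2 = random_sequence(rng, 30)
        e3 = "".join(ch if rng.random() > 0.5 else random_sequence(rng, 1)
                     for ch in e2)
        t1 = "".join(ch if rng.random() > 0.1 else random_sequence(rng, 1)
                     for ch in e2)
        t2 = "".join(ch if rng.random() > 0.1 else random_sequence(rng, 1)
                     for ch in e3)
        targets = [TargetSequence("BMR1B", t1), TargetSequence("AVR2A", t2)]
        archs = {t.id: self._arch(t.id, "Activin_rec", 30) for t in targets}
        template = self._template([("2", e2, "Activin_rec"),
                                   ("3", e3, "Activin_rec")])
        out = assign_targets_to_entities(targets, archs, template)
        assert out.pairs["BMR1B"][0] == "2"
        assert out.pairs["AVR2A"][0] == "3"

    def test_single_pair_assigned_regardless_of_identity(self, rng):
        seq = random_sequence(rng, 20)
        tgt = random_sequence(rng, 20)
        targets = [TargetSequence("t", tgt)]
        archs = {"t": self._arch("t", "PF", 20)}
        template = self._template([("1", seq, "PF")])
        out = assign_targets_to_entities(targets, archs, template)
        assert out.pairs["t"][0] == "1"

    def test_competition_higher_identity_wins(self, rng):
        e = random_sequence(rng, 30)
        t_close = "".join(ch if rng.random() > 0.1 else "W" for ch in e)
        t_far = "".join(ch if rng.random() > 0.5 else "W" for ch in e)
        targets = [TargetSequence("far", t_far), TargetSequence("near",
                                                                t_close)]
        archs = {t.id: self._arch(t.id, "PF", 30) for t in targets}
        template = self._template([("1", e, "PF")])
        out = assign_targets_to_entities(targets, archs, template)
        assert out.pairs["near"][0] == "1"
        assert out.unassigned == ["far"]

    def test_no_shared_family_is_error(self, rng):
        targets = [TargetSequence("t", random_sequence(rng, 10))]
        archs = {"t": self._arch("t", "PFA", 10)}
        template = self._template([("1", random_sequence(rng, 10), "PFB")])
        with pytest.raises(ValueError, match="no target shares"):
            assign_targets_to_entities(targets, archs, template)

    def test_entity_order_permutation_stable(self, rng):
        e_list = [(str(i), random_sequence(rng, 25), "PF")
                  for i in range(1, 4)]
        targets = [TargetSequence(f"t{i}", _mut(rng, e_list[i][1], 0.1))
                   for i in range(3)]
        archs = {t.id: self._arch(t.id, "PF", 25) for t in targets}
        fwd = assign_targets_to_entities(targets, archs,
                                         self._template(e_list))
        rev = assign_targets_to_entities(targets, archs,
                                         self._template(e_list[::-1]))
        assert {k: v[0] for k, v in fwd.pairs.items()} == \
            {k: v[0] for k, v in rev.pairs.items()}


def _mut(rng, seq, rate):
    return "".join(ch if rng.random() > rate else random_sequence(rng, 1)
                   for ch in seq)


class TestThreadBackbone:
    def test_self_threading_backbone_bit_exact(self, rng):
        seq = random_sequence(rng, 15)
        chain = _chain_for(seq)
        target = TargetSequence("t", seq)
        threaded = thread_backbone(target, chain, _identity_alignment(15))
        for rt, rc in zip(threaded.residues, chain.residues):
            for atom in rt.atoms:
                np.testing.assert_array_equal(atom.pos,
                                              rc.atom(atom.name).pos)
        assert all(tag == COPIED_IDENTICAL
                   for tag in threaded.provenance.values())

    def test_insertion_leaves_numbering_gap(self, rng):
        tpl_seq = random_sequence(rng, 10)
        tgt_seq = tpl_seq[:5] + "AAA" + tpl_seq[5:]
        cols = [(i, i) for i in range(1, 6)] + \
               [(i, None) for i in range(6, 9)] + \
               [(i + 3, i) for i in range(6, 11)]
        chain = _chain_for(tpl_seq)
        threaded = thread_backbone(TargetSequence("t", tgt_seq), chain,
                                   PairAlignment("t", "e", cols))
        assert threaded.unmodeled == [6, 7, 8]
        numbers = [r.seq_num for r in threaded.residues]
        assert numbers == [1, 2, 3, 4, 5, 9, 10, 11, 12, 13]
        # flanking residues keep template coordinates
        np.testing.assert_array_equal(
            threaded.residues[5].atom("CA").pos,
            chain.residues[5].atom("CA").pos)

    def test_copied_atom_count_matches_recount(self, rng):
        for _ in range(15):
            tpl_seq = random_sequence(rng, 12)
            tgt_seq = random_sequence(rng, 12)
            cols, pa, pb = [], 0, 0
            while pa < 12 and pb < 12:
                r = rng.random()
                if r < 0.7:
                    pa, pb = pa + 1, pb + 1
                    cols.append((pa, pb))
                elif r < 0.85:
                    pa += 1
                    cols.append((pa, None))
                else:
                    pb += 1
                    cols.append((None, pb))
            chain = _chain_for(tpl_seq)
            threaded = thread_backbone(TargetSequence("t", tgt_seq), chain,
                                       PairAlignment("t", "e", cols))
            got = sum(len(r.atoms) for r in threaded.residues)
            expected = 0
            for pa_, pb_ in cols:
                if pa_ is None or pb_ is None:
                    continue
                names = ["N", "CA", "C", "O"]
                if tgt_seq[pa_ - 1] != "G":
                    names.append("CB")
                expected += sum(
                    1 for n in names
                    if chain.residues[pb_ - 1].atom(n) is not None)
            assert got == expected
            n_match = sum(1 for a, b in cols if a and b)
            n_ins = sum(1 for a, b in cols if b is None)
            assert len(threaded.residues) + len(threaded.unmodeled) == \
                n_match + n_ins

    def test_glycine_target_gets_no_cb(self, rng):
        chain = _chain_for("AAA")
        threaded = thread_backbone(TargetSequence("t", "GGG"), chain,
                                   _identity_alignment(3))
        assert all(r.atom("CB") is None for r in threaded.residues)

    def test_missing_ca_rejected(self, rng):
        chain = _chain_for("AAA")
        chain.residues[1].atoms = [a for a in chain.residues[1].atoms
                                   if a.name != "CA"]
        with pytest.raises(ValueError, match="lacks a CA"):
            thread_backbone(TargetSequence("t", "AAA"), chain,
                            _identity_alignment(3))


class TestGraftSideChains:
    def test_self_grafting_bit_exact(self, rng):
        seq = random_sequence(rng, 12)
        chain = _chain_for(seq)
        aln = _identity_alignment(12)
        threaded = thread_backbone(TargetSequence("t", seq), chain, aln)
        graft_side_chains(threaded, chain, aln)
        for rt, rc in zip(threaded.residues, chain.residues):
            assert {a.name for a in rt.atoms} == {a.name for a in rc.atoms}
            for atom in rt.atoms:
                np.testing.assert_array_equal(atom.pos,
                                              rc.atom(atom.name).pos)

    def test_open_space_mutation_uses_top_prior_rotamer(self):
        chain = _chain_for("AAAAA")
        aln = _identity_alignment(5)
        threaded = thread_backbone(TargetSequence("t", "AALAA"), chain, aln)
        graft_side_chains(threaded, chain, aln)
        leu = threaded.residues[2]
        top = max((e for e in default_rotamer_library()
                   if e.residue_type == "L"), key=lambda e: e.prior)
        backbone = {a.name: a.pos for a in leu.atoms
                    if a.name in ("N", "CA", "C", "CB")}
        expected = dict(
            (n, p) for n, _, p in build_side_chain(backbone, "LEU", top.chi))
        for name, pos in expected.items():
            np.testing.assert_allclose(leu.atom(name).pos, pos, atol=1e-9)

    def test_crowded_mutation_matches_exhaustive_clash_oracle(self, rng):
        for trial in range(10):
            chain = _chain_for("AAKAA")
            aln = _identity_alignment(5)
            threaded = thread_backbone(TargetSequence("t", "AAKAA"), chain,
                                       aln)
            # crowd the space around the lysine with random obstacles
            ca = chain.residues[2].atom("CA").pos
            obstacles = ca + rng.normal(scale=3.0, size=(6, 3))
            threaded.provenance[3] = MUTATED_REBUILT  # force a rebuild
            graft_side_chains(threaded, chain, aln, environment=obstacles)
            lys = threaded.residues[2]
            entries = sorted((e for e in default_rotamer_library()
                              if e.residue_type == "K"),
                             key=lambda e: -e.prior)
            backbone = {a.name: a.pos for a in lys.atoms
                        if a.name in ("N", "CA", "C", "CB")}
            own_backbone = [a.pos for a in lys.atoms
                            if a.name in ("N", "CA", "C", "O", "CB")]
            env_atoms = [a.pos for r in threaded.residues for a in r.atoms
                         if r.seq_num != 3 and a.name in
                         ("N", "CA", "C", "O", "CB")]
            env = np.vstack([np.array(env_atoms), obstacles])

            def build(entry):
                return np.array([p for _, _, p in build_side_chain(
                    backbone, "LYS", entry.chi)])

            best = best_rotamer_bruteforce(entries, build, env, 2.5)
            expected = {n: p for n, _, p in build_side_chain(
                backbone, "LYS", best.chi)}
            for name, pos in expected.items():
                np.testing.assert_allclose(lys.atom(name).pos, pos,
                                           atol=1e-9, err_msg=str(trial))

    def test_rebuilt_bond_lengths_match_ideal_table(self, rng):
        chain = _chain_for("A" * 8)
        aln = _identity_alignment(8)
        tgt = "AWRLYKME"
        threaded = thread_backbone(TargetSequence("t", tgt), chain, aln)
        graft_side_chains(threaded, chain, aln)
        for res in threaded.residues:
            pos = {a.name: a.pos for a in res.atoms}
            for rec in ideal_recipe(res.name):
                if rec.name not in pos:
                    continue
                got = np.linalg.norm(pos[rec.name] - pos[rec.refs[2]])
                assert abs(got - rec.bond) < 0.05, (res.name, rec.name)

    def test_missing_library_type_rejected(self):
        chain = _chain_for("AAA")
        aln = _identity_alignment(3)
        threaded = thread_backbone(TargetSequence("t", "AWA"), chain, aln)
        lib = [e for e in default_rotamer_library() if e.residue_type != "W"]
        with pytest.raises(ValueError, match="absent from the rotamer"):
            graft_side_chains(threaded, chain, aln, library=list(lib))


class TestRotamerLibrary:
    def test_priors_normalized_per_type(self):
        lib = default_rotamer_library()
        totals = {}
        for e in lib:
            totals[e.residue_type] = totals.get(e.residue_type, 0) + e.prior
        for res, total in totals.items():
            assert total == pytest.approx(1.0, abs=1e-6), res

    def test_chi_counts_match_residue_definitions(self):
        for e in default_rotamer_library():
            n = len(CHI_DEFS[ONE_TO_THREE[e.residue_type]])
            assert len(e.chi) == n

    def test_table_round_trip(self, tmp_path):
        lib = default_rotamer_library()
        path = tmp_path / "rot.tsv"
        write_rotamer_table(lib, path)
        back = load_rotamer_table(path)
        assert len(back) == len(lib)
        for a, b in zip(lib, back):
            assert a.residue_type == b.residue_type
            assert a.chi == pytest.approx(b.chi, abs=0.05)
            assert a.prior == pytest.approx(b.prior, abs=1e-6)


class TestBuildComplex:
    def test_heterohexamer_six_chain_model(self, fixture_tree):
        out, manifest = fixture_tree
        from oligomod.assembly import build_assembly, read_structure
        from oligomod.domains import read_catalogue

        st, defs, ops = read_structure(out / "structures" / "9hex.cif")
        assembly = build_assembly(st, defs[0], ops)
        catalogue = {r.pdb_id: r for r in
                     read_catalogue(out / "catalogue.tsv")}
        rec = catalogue["9hex"]
        targets = [
            TargetSequence(tid, manifest["targets"][tid]["sequence"])
            for tid in ("t_lig", "t_r1", "t_r2")
        ]
        archs = {
            t.id: DomainArchitecture(
                seq_id=t.id,
                domains=[("FamL" if t.id == "t_lig" else "FamR", 1, len(t))])
            for t in targets
        }
        assignment = assign_targets_to_entities(targets, archs, rec)
        model = build_complex(assembly, assignment, targets)
        assert len(model.chains) == 6
        per_target = {}
        for ch in model.chains:
            per_target[ch.target_id] = per_target.get(ch.target_id, 0) + 1
        assert per_target == {"t_lig": 2, "t_r1": 2, "t_r2": 2}

    def test_homodimer_one_target_two_chains(self, fixture_tree):
        out, manifest = fixture_tree
        from oligomod.assembly import build_assembly, read_structure
        from oligomod.domains import read_catalogue

        st, defs, ops = read_structure(out / "structures" / "9cee.cif")
        assembly = build_assembly(st, defs[0], ops)
        rec = {r.pdb_id: r for r in
               read_catalogue(out / "catalogue.tsv")}["9cee"]
        target = TargetSequence("t_lig",
                                manifest["targets"]["t_lig"]["sequence"])
        archs = {"t_lig": DomainArchitecture(
            seq_id="t_lig", domains=[("FamL", 1, len(target))])}
        assignment = assign_targets_to_entities([target], archs, rec)
        model = build_complex(assembly, assignment, [target])
        assert len(model.chains) == 2
        assert model.chains[0].sequence == model.chains[1].sequence
        assert model.chains[0].chain_id != model.chains[1].chain_id

        sub = build_complex(assembly, assignment, [target],
                            include_chains=["A"])
        assert len(sub.chains) == 1
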
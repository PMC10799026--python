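import math

import numpy as np
import pytest

from gsreg import regulation as reg
from gsreg.regulation import (
    RULE_2OG, RULE_GLN, Verdict, build_profile, classify_group,
    classify_sequence, classify_subject, count_regulation_classes,
    default_rules, verify_monophyly,
)
from gsreg.seq_core import AlignedRecord, Msa, map_reference_positions

from conftest import MTGS_RESIDUES, MSGS_RESIDUES


class TestDefaultRules:
    def test_2og_rule_positions(self, rules):
        r2og = next(r for r in rules if r.name == RULE_2OG)
        assert set(r2og.positions) == {20, 34, 88, 174, 175, 191}
        for p in (20, 88, 174, 175):
            assert r2og.requirements[p] == {"R"}
        assert r2og.requirements[191] == {"S"}

    def test_gln_rule_single_position(self, rules):
        rgln = next(r for r in rules if r.name == RULE_GLN)
        assert rgln.positions == [67]
        assert rgln.requirements[67] == {"R"}

    def test_glutamate_forbidden_at_34(self, rules):
        r2og = next(r for r in rules if r.name == RULE_2OG)
        assert "E" in r2og.exclusions[34]

    def test_overrides(self):
        rules = default_rules({RULE_2OG: {"exclusions": {34: "E"}}})
        r2og = next(r for r in rules if r.name == RULE_2OG)
        assert r2og.exclusions[34] == {"E"}

    def test_hash_changes_with_rules(self, rules):
        other = default_rules({RULE_2OG: {"exclusions": {34: "E"}}})
        assert reg.ruleset_hash(rules) != reg.ruleset_hash(other)


class TestClassifySequence:
    def test_mtgs_configuration(self, rules):
        call = classify_subject("MtGS", MTGS_RESIDUES, rules)
        assert call.verdict(RULE_2OG) is Verdict.CAPABLE
        assert call.verdict(RULE_GLN) is Verdict.INCAPABLE

    def test_msgs_configuration(self, rules):
        call = classify_subject("MsGS", MSGS_RESIDUES, rules)
        assert call.verdict(RULE_2OG) is Verdict.INCAPABLE
        assert call.verdict(RULE_GLN) is Verdict.CAPABLE

    def test_single_requirement_ablation(self, rules):
        r2og = next(r for r in rules if r.name == RULE_2OG)
        residues = dict(MTGS_RESIDUES)
        residues[191] = "A"
        assert classify_sequence(residues, r2og).verdict is Verdict.INCAPABLE

    def test_exhaustive_implant_ablate(self, rules):
        """Any single non-allowed residue at any rule position flips the call."""
        for rule in rules:
            capable = {p: sorted(s)[0] for p, s in rule.requirements.items()}
            for p in rule.exclusions:
                capable[p] = "A" if "A" not in rule.exclusions[p] else "G"
            assert classify_sequence(capable, rule).verdict is Verdict.CAPABLE
            for pos in rule.requirements:
                bad = set("ACDEFGHIKLMNPQRSTVWY") - rule.requirements[pos]
                for res in bad:
                    mutated = {**capable, pos: res}
                    assert classify_sequence(mutated, rule).verdict is \
                        Verdict.INCAPABLE, (pos, res)
            for pos, forbidden in rule.exclusions.items():
                for res in forbidden:
                    mutated = {**capable, pos: res}
                    assert classify_sequence(mutated, rule).verdict is \
                        Verdict.INCAPABLE, (pos, res)

    @pytest.mark.parametrize("res,expected", [
        ("X", Verdict.UNKNOWN), ("-", Verdict.UNKNOWN),
    ])
    def test_missing_evidence_gives_unknown(self, rules, res, expected):
        r2og = next(r for r in rules if r.name == RULE_2OG)
        residues = {**MTGS_RESIDUES, 88: res}
        assert classify_sequence(residues, r2og).verdict is expected

    def test_violation_dominates_unknown(self, rules):
        r2og = next(r for r in rules if r.name == RULE_2OG)
        residues = {**MTGS_RESIDUES, 88: "X", 191: "A"}
        assert classify_sequence(residues, r2og).verdict is Verdict.INCAPABLE

    def test_absent_position_treated_as_gap(self, rules):
        rgln = next(r for r in rules if r.name == RULE_GLN)
        assert classify_sequence({}, rgln).verdict is Verdict.UNKNOWN


class TestProfiles:
    def _group_msa(self, column_residues):
        """One diagnostic column (position 2 of a 3-residue reference)."""
        rows = [AlignedRecord("ref", "MRK")]
        rows += [AlignedRecord(f"s{i}", f"M{c}K")
                 for i, c in enumerate(column_residues)]
        return Msa(tuple(rows))

    def test_full_conservation_max_ic(self):
        msa = self._group_msa("R" * 10)
        pm = map_reference_positions(msa, "ref", [2])
        prof = build_profile("g", [f"s{i}" for i in range(10)], msa, pm)
        col = prof.column(2)
        assert col.frequencies["R"] == 1.0
        assert col.information_bits == pytest.approx(math.log2(20), abs=1e-9)

    def test_two_state_column_ic(self):
        msa = self._group_msa("RRRRRKKKKK")
        pm = map_reference_positions(msa, "ref", [2])
        prof = build_profile("g", [f"s{i}" for i in range(10)], msa, pm)
        assert prof.column(2).information_bits == \
            pytest.approx(math.log2(20) - 1.0, abs=1e-9)

    def test_uniform_column_zero_ic(self):
        msa = self._group_msa("ACDEFGHIKLMNPQRSTVWY")
        pm = map_reference_positions(msa, "ref", [2])
        prof = build_profile("g", [f"s{i}" for i in range(20)], msa, pm)
        assert prof.column(2).information_bits == pytest.approx(0.0, abs=1e-9)

    def test_frequencies_normalized_random_profiles(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            col = "".join(rng.choice(list("ARNDCQE-"), size=n))
            msa = self._group_msa(col)
            pm = map_reference_positions(msa, "ref", [2])
            prof = build_profile("g", [f"s{i}" for i in range(n)], msa, pm)
            c = prof.column(2)
            assert sum(c.frequencies.values()) == pytest.approx(1.0)
            assert 0.0 <= c.information_bits <= math.log2(20) + 1e-12

    def test_gap_fraction_reported(self):
        msa = self._group_msa("RR--")
        pm = map_reference_positions(msa, "ref", [2])
        prof = build_profile("g", [f"s{i}" for i in range(4)], msa, pm)
        col = prof.column(2)
        assert col.gap_fraction == pytest.approx(0.5)
        # entropy over amino acids only: all-R -> maximal IC
        assert col.information_bits == pytest.approx(math.log2(20), abs=1e-9)

    def test_modal_tie_break_alphabetical(self):
        msa = self._group_msa("RK")
        pm = map_reference_positions(msa, "ref", [2])
        prof = build_profile("g", ["s0", "s1"], msa, pm)
        assert prof.column(2).modal_residue == "K"

    def test_member_absent_errors(self):
        msa = self._group_msa("R")
        pm = map_reference_positions(msa, "ref", [2])
        with pytest.raises(KeyError):
            build_profile("g", ["nope"], msa, pm)

    def test_member_order_invariance(self, family, family_pmap, rules):
        gid, members = next(iter(family.groups.items()))
        p1 = build_profile(gid, members, family.msa, family_pmap)
        p2 = build_profile(gid, members[::-1], family.msa, family_pmap)
        c1 = classify_group(p1, rules)
        c2 = classify_group(p2, rules)
        assert {n: r.verdict for n, r in c1.results.items()} == \
               {n: r.verdict for n, r in c2.results.items()}


class TestClassifyGroup:
    def _profile(self, column_residues, positions_ok=True):
        residues = {p: r for p, r in MTGS_RESIDUES.items()}
        rows = [AlignedRecord("ref", "".join(
            residues.get(i + 1, "A") for i in range(200)))]
        members = []
        for i, c in enumerate(column_residues):
            row = list(rows[0].residues)
            row[20 - 1] = c  # vary position 20
            members.append(f"s{i}")
            rows.append(AlignedRecord(f"s{i}", "".join(row)))
        msa = Msa(tuple(rows))
        pm = map_reference_positions(msa, "ref", sorted(MTGS_RESIDUES))
        return build_profile("g", members, msa, pm)

    def test_modal_mode_60_40(self, rules):
        prof = self._profile("RRRKKR" + "RRRK")  # 7 R / 3 K at position 20
        call = classify_group(prof, rules, mode="modal")
        assert call.verdict(RULE_2OG) is Verdict.CAPABLE

    def test_plurality_theta_blocks_weak_consensus(self, rules):
        prof = self._profile("RRRKK")  # 60% R
        call = classify_group(prof, rules, mode="plurality", theta=0.8)
        assert call.verdict(RULE_2OG) is Verdict.UNKNOWN

    def test_unanimous_group_capable_all_modes(self, rules):
        prof = self._profile("RRRR")
        for mode in ("modal", "plurality", "unanimity"):
            call = classify_group(prof, rules, mode=mode)
            assert call.verdict(RULE_2OG) is Verdict.CAPABLE, mode


class TestCounts:
    def _call(self, v2og, vgln):
        res = {
            RULE_2OG: reg.RuleResult(v2og, ()),
            RULE_GLN: reg.RuleResult(vgln, ()),
        }
        return reg.RegulationCall("g", res)

    def test_enumeration(self):
        calls = [
            self._call(Verdict.CAPABLE, Verdict.INCAPABLE),
            self._call(Verdict.CAPABLE, Verdict.CAPABLE),
            self._call(Verdict.INCAPABLE, Verdict.INCAPABLE),
        ]
        assert count_regulation_classes(calls) == \
            {"either": 1, "both": 1, "neither": 1, "unknown": 0}

    def test_all_both(self):
        calls = [self._call(Verdict.CAPABLE, Verdict.CAPABLE)] * 5
        c = count_regulation_classes(calls)
        assert c["both"] == 5 and c["either"] == 0

    def test_unknown_bucket(self):
        calls = [self._call(Verdict.CAPABLE, Verdict.UNKNOWN)]
        assert count_regulation_classes(calls)["unknown"] == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            count_regulation_classes([])


class TestMonophyly:
    def test_four_leaf_examples(self):
        tree = "((A,B),(C,D));"
        res = verify_monophyly(tree, {"A", "B"})
        assert res.is_monophyletic and res.containing_clade == {"A", "B"}
        res = verify_monophyly(tree, {"A", "C"})
        assert not res.is_monophyletic
        assert res.containing_clade == {"A", "B", "C", "D"}
        assert verify_monophyly(tree, {"A", "B", "C", "D"}).is_monophyletic

    def test_unknown_leaf_errors(self):
        with pytest.raises(KeyError):
            verify_monophyly("((A,B),(C,D));", {"A", "Z"})

    def test_unrooted_complement_side_counts(self):
        # {B,C,D} is the complement of the A leaf edge: monophyletic in
        # the unrooted sense only, since no rooted clade equals it
        tree = "((A,B),(C,D));"
        assert verify_monophyly(tree, {"B", "C", "D"}).is_monophyletic
        assert not verify_monophyly(tree, {"B", "C", "D"},
                                    rooted=True).is_monophyletic

    def test_against_exhaustive_enumeration(self, rng):
        """Random trees (<= 8 leaves), all subsets, vs subset enumeration."""
        import itertools

        import dendropy

        for seed in range(5):
            taxa = [chr(ord("A") + i) for i in range(6)]
            r = np.random.default_rng(seed)
            nodes = list(taxa)
            while len(nodes) > 1:
                i, j = sorted(r.choice(len(nodes), 2, replace=False))
                b = nodes.pop(j)
                a = nodes.pop(i)
                nodes.append(f"({a},{b})")
            newick = nodes[0] + ";"
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
            # oracle: collect all edge bipartition sides by re-parsing
            leaf_sets = []
            for node in tree.postorder_node_iter():
                s = frozenset(l.taxon.label for l in node.leaf_iter())
                leaf_sets.append(s)
            full = frozenset(taxa)
            sides = set(leaf_sets) | {full - s for s in leaf_sets}
            for size in (2, 3):
                for combo in itertools.combinations(taxa, size):
                    expected = frozenset(combo) in sides
                    got = verify_monophyly(newick, set(combo)).is_monophyletic
                    assert got == expected, (newick, combo)
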
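"""Residue rules for GS effector binding, conservation profiles, monophyly.

Archaeal GSI-alpha enzymes differ in how their activity is controlled:
some are switched on allosterically by 2-oxoglutarate (2OG), a cellular
signal of nitrogen deficiency, and some are feedback-inhibited by their
own product glutamine. Both behaviours hinge on a handful of residues,
so they can be predicted from sequence alone once the sequences are
placed in the MtGS numbering frame:

* 2OG binding requires arginines at 20, 88, 174 and 175 and a serine at
  191 (the primed residues come from the adjacent subunit of the hexamer
  ring), and no bulky or acidic side chain at position 34, which would
  sterically or electrostatically exclude the effector.
* glutamine feedback inhibition requires the Asp50'-loop arginine at
  position 67 (Arg62' in B. subtilis, Arg61' in M. shengliensis; MtGS
  itself carries a glycine there and is not inhibited).

Verdicts are tri-state: ``capable`` / ``incapable`` / ``unknown``. A
gap or an ``X`` at a diagnostic position is honest missing evidence, not
a pass or a fail, but one definite violation suffices for ``incapable``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from math import log2
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

from .seq_core import AA20, GAP, Msa, PositionMap, residues_at

logger = logging.getLogger(__name__)

RULE_2OG = "2OG-binding"
RULE_GLN = "Gln-inhibition"

#: Residues at position 34 whose bulk or charge would occlude the 2OG pocket.
DEFAULT_FORBIDDEN_34 = frozenset("DEFWYKRHQNMLI")
#: Small side chains compatible with 2OG binding at position 34.
DEFAULT_ALLOWED_34 = frozenset("AGSCTVP")


class Verdict(str, Enum):
    CAPABLE = "capable"
    INCAPABLE = "incapable"
    UNKNOWN = "unknown"


class EvidenceStatus(str, Enum):
    SATISFIES = "satisfies"
    VIOLATES = "violates"
    MISSING = "missing"


@dataclass(frozen=True)
class PositionEvidence:
    position: int
    residue: str
    status: EvidenceStatus


@dataclass(frozen=True)
class MotifRuleSet:
    """Per-position residue requirements and exclusions for one effector.

    ``requirements`` maps a reference position to the set of residues
    that satisfy it; ``exclusions`` maps a position to residues that
    definitely break binding (anything else there is acceptable).
    ``notes`` carries rule provenance such as structural observations
    that are documented but deliberately not enforced.
    """

    name: str
    requirements: Mapping[int, frozenset]
    exclusions: Mapping[int, frozenset]
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "requirements",
                           {p: frozenset(s) for p, s in self.requirements.items()})
        object.__setattr__(self, "exclusions",
                           {p: frozenset(s) for p, s in self.exclusions.items()})
        overlap = set(self.requirements) & set(self.exclusions)
        if overlap:
            raise ValueError(f"positions in both requirements and exclusions: {overlap}")
        for p, s in {**self.requirements, **self.exclusions}.items():
            if not s:
                raise ValueError(f"empty residue set at position {p}")
            if not s <= set(AA20):
                raise ValueError(f"non-amino-acid residues {s - set(AA20)} at {p}")

    @property
    def positions(self) -> list[int]:
        return sorted(set(self.requirements) | set(self.exclusions))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "requirements": {p: sorted(s) for p, s in sorted(self.requirements.items())},
            "exclusions": {p: sorted(s) for p, s in sorted(self.exclusions.items())},
            "notes": self.notes,
        }


def ruleset_hash(rules: Sequence[MotifRuleSet]) -> str:
    """Stable short hash identifying the exact rule configuration of a run."""
    payload = json.dumps([r.to_dict() for r in rules], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_rules(overrides: Optional[Mapping[str, Mapping]] = None) -> list[MotifRuleSet]:
    """The two built-in effector rule sets, in MtGS numbering.

    ``overrides`` may replace the requirement/exclusion sets per rule
    name, e.g. ``{"2OG-binding": {"exclusions": {34: "DE"}}}``.

    Notes kept as metadata, not enforced: Phe18' stacks against the 2OG
    ring, and in the insensitive MsGS a glutamate replacing Val94'
    clashes with the effector; neither is part of the diagnostic motif.
    """
    base = {
        RULE_2OG: {
            "requirements": {20: "R", 88: "R", 174: "R", 175: "R", 191: "S"},
            "exclusions": {34: "".join(sorted(DEFAULT_FORBIDDEN_34))},
            "notes": ("Arg20'/Arg88'/Arg174/Arg175 ionic bonds + Ser191 H-bond; "
                      "bulky/acidic residues at 34 occlude the pocket. "
                      "Phe18' stacking and the Val94'->Glu clash are recorded "
                      "but not classified on."),
        },
        RULE_GLN: {
            "requirements": {67: "R"},
            "exclusions": {},
            "notes": "Asp50'-loop arginine locking the Glu-flap on glutamine.",
        },
    }
    if overrides:
        for name, parts in overrides.items():
            if name not in base:
                raise KeyError(f"unknown rule set {name!r}")
            for key in ("requirements", "exclusions"):
                if key in parts:
                    base[name][key] = {int(p): s for p, s in parts[key].items()}
            if "notes" in parts:
                base[name]["notes"] = parts["notes"]
    return [
        MotifRuleSet(
            name=name,
            requirements={p: frozenset(s) for p, s in cfg["requirements"].items()},
            exclusions={p: frozenset(s) for p, s in cfg["exclusions"].items()},
            notes=cfg["notes"],
        )
        for name, cfg in base.items()
    ]


@dataclass(frozen=True)
class RuleResult:
    verdict: Verdict
    evidence: tuple[PositionEvidence, ...]


@dataclass(frozen=True)
class RegulationCall:
    """Tri-state verdicts for one subject under a collection of rule sets."""

    subject_id: str
    results: Mapping[str, RuleResult]

    def verdict(self, rule_name: str) -> Verdict:
        return self.results[rule_name].verdict

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "verdicts": {n: r.verdict.value for n, r in self.results.items()},
            "evidence": {
                n: [
                    {"position": e.position, "residue": e.residue,
                     "status": e.status.value}
                    for e in r.evidence
                ]
                for n, r in self.results.items()
            },
        }


def classify_sequence(residues: Mapping[int, str], rules: MotifRuleSet) -> RuleResult:
    """Classify one residue map under one rule set.

    A definite violation (wrong residue at a required position, or a
    forbidden residue at an exclusion position) dominates; otherwise any
    missing evidence (``X`` or gap) yields ``unknown``; otherwise
    ``capable``.
    """
    evidence = []
    n_violations = 0
    n_missing = 0
    for pos in rules.positions:
        res = residues.get(pos, GAP)
        if res in ("X", GAP):
            status = EvidenceStatus.MISSING
            n_missing += 1
        elif pos in rules.requirements:
            if res in rules.requirements[pos]:
                status = EvidenceStatus.SATISFIES
            else:
                status = EvidenceStatus.VIOLATES
                n_violations += 1
        else:  # exclusion position
            if res in rules.exclusions[pos]:
                status = EvidenceStatus.VIOLATES
                n_violations += 1
            else:
                status = EvidenceStatus.SATISFIES
        evidence.append(PositionEvidence(pos, res, status))
    if n_violations:
        verdict = Verdict.INCAPABLE
    elif n_missing:
        verdict = Verdict.UNKNOWN
    else:
        verdict = Verdict.CAPABLE
    return RuleResult(verdict=verdict, evidence=tuple(evidence))


def classify_subject(subject_id: str, residues: Mapping[int, str],
                     rules: Sequence[MotifRuleSet]) -> RegulationCall:
    """Apply every rule set to one subject's residue map."""
    return RegulationCall(
        subject_id=subject_id,
        results={r.name: classify_sequence(residues, r) for r in rules},
    )


# ---------------------------------------------------------------------------
# Group profiles and conservation


MAX_IC_BITS = log2(20.0)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue distribution of one diagnostic position within a group.

    ``frequencies`` covers the 20 amino acids plus the gap symbol and
    sums to 1 over the counted symbols; ``X`` characters are excluded
    from the counts (logged). Information content follows the sequence-
    logo convention, IC = log2(20) - H, with the entropy H taken over
    amino-acid symbols only; the gap fraction is reported separately.
    """

    position: int
    frequencies: Mapping[str, float]
    modal_residue: str
    information_bits: float
    gap_fraction: float


@dataclass(frozen=True)
class GroupProfile:
    group_id: str
    member_ids: tuple[str, ...]
    columns: tuple[ColumnProfile, ...]

    def column(self, position: int) -> ColumnProfile:
        for c in self.columns:
            if c.position == position:
                return c
        raise KeyError(position)


GroupAssignment = dict  # group_id -> list of member sequence ids


def read_group_assignment(source: Union[str, Path]) -> GroupAssignment:
    """Two-column TSV (group_id, sequence_id) -> ``{group: [members]}``.

    Lines starting with ``#`` are comments; membership must be disjoint.
    """
    groups: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for line in Path(source).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 2 tab-separated fields, got {line!r}")
        gid, sid = parts
        if sid in seen:
            raise ValueError(
                f"sequence {sid!r} assigned to both {seen[sid]!r} and {gid!r}")
        seen[sid] = gid
        groups.setdefault(gid, []).append(sid)
    return groups


def build_profile(group_id: str, member_ids: Sequence[str], msa: Msa,
                  pmap: PositionMap) -> GroupProfile:
    """Residue frequency / conservation profile of a group at the mapped positions."""
    if not member_ids:
        raise ValueError("empty group")
    rows = {sid: residues_at(msa, pmap, sid) for sid in member_ids}  # KeyError if absent
    columns = []
    for pos in pmap.positions:
        observed = [rows[sid][pos] for sid in member_ids]
        n_x = observed.count("X")
        if n_x:
            logger.warning("group %s position %d: %d 'X' residues excluded "
                           "from the profile", group_id, pos, n_x)
        counted = [r for r in observed if r != "X"]
        n = len(counted)
        freqs = {sym: counted.count(sym) / n for sym in list(AA20) + [GAP]} if n else {}
        gap_fraction = freqs.get(GAP, 0.0)
        aa_total = sum(freqs.get(a, 0.0) for a in AA20)
        if aa_total > 0:
            h = -sum(
                (freqs[a] / aa_total) * log2(freqs[a] / aa_total)
                for a in AA20 if freqs.get(a, 0.0) > 0
            )
            ic = MAX_IC_BITS - h
        else:
            ic = 0.0
        # modal symbol over the full 21-symbol distribution; alphabetical
        # tie-break (gap sorts before letters), ties logged
        if n:
            best = max(freqs.values())
            candidates = sorted(s for s, f in freqs.items() if f == best)
            if len(candidates) > 1:
                logger.info("group %s position %d: modal tie among %s, "
                            "taking %r", group_id, pos, candidates, candidates[0])
            modal = candidates[0]
        else:
            modal = "X"
        columns.append(ColumnProfile(
            position=pos, frequencies=freqs, modal_residue=modal,
            information_bits=ic, gap_fraction=gap_fraction,
        ))
    return GroupProfile(group_id=group_id, member_ids=tuple(member_ids),
                        columns=tuple(columns))


def classify_group(profile: GroupProfile, rules: Sequence[MotifRuleSet],
                   mode: str = "modal", theta: float = 0.8) -> RegulationCall:
    """Classify a group by its consensus residues.

    ``modal`` (default) classifies the most common residue per position;
    ``plurality`` additionally requires the modal frequency to reach
    ``theta``, else the position counts as unknown; ``unanimity``
    requires frequency 1.
    """
    if mode not in ("modal", "plurality", "unanimity"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    residues: dict[int, str] = {}
    for col in profile.columns:
        res = col.modal_residue
        freq = col.frequencies.get(res, 0.0)
        if mode == "plurality" and freq < theta:
            res = "X"
        elif mode == "unanimity" and freq < 1.0:
            res = "X"
        residues[col.position] = res
    return classify_subject(profile.group_id, residues, rules)


def count_regulation_classes(calls: Sequence[RegulationCall],
                             rule_a: str = RULE_2OG,
                             rule_b: str = RULE_GLN) -> dict[str, int]:
    """Partition group calls into either / both / neither / unknown.

    A group counts as ``unknown`` if any of its two verdicts is unknown
    (its membership in the other classes cannot be decided); otherwise
    by how many effectors it is predicted capable of.
    """
    if not calls:
        raise ValueError("no calls to summarise")
    counts = {"either": 0, "both": 0, "neither": 0, "unknown": 0}
    for call in calls:
        va, vb = call.verdict(rule_a), call.verdict(rule_b)
        if Verdict.UNKNOWN in (va, vb):
            counts["unknown"] += 1
        else:
            n_capable = [va, vb].count(Verdict.CAPABLE)
            counts["both" if n_capable == 2
                   else "either" if n_capable == 1 else "neither"] += 1
    return counts


# ---------------------------------------------------------------------------
# Monophyly


@dataclass(frozen=True)
class MonophylyResult:
    is_monophyletic: bool
    containing_clade: frozenset


def _load_tree(tree: Union[str, Path, dendropy.Tree]) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    looks_like_path = isinstance(tree, Path) or (
        "(" not in tree and len(tree) < 4096 and Path(tree).exists())
    if looks_like_path:
        return dendropy.Tree.get(path=str(tree), schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=str(tree), schema="newick",
                             preserve_underscores=True)


def verify_monophyly(tree: Union[str, Path, dendropy.Tree],
                     member_ids: Iterable[str],
                     rooted: bool = False) -> MonophylyResult:
    """Do ``member_ids`` form a clade of the tree?

    For unrooted trees (default) a group is monophyletic when some edge
    bipartition has exactly the group on one side; for rooted trees only
    descendant clades count. Also reports the smallest clade (or, when
    unrooted, bipartition side) containing all members.
    """
    t = _load_tree(tree)
    members = frozenset(member_ids)
    if not members:
        raise ValueError("empty member set")
    all_leaves = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
    unknown = members - all_leaves
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)}")

    # leaf sets below each node, postorder
    clades: list[frozenset] = []
    below: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        clades.append(below[node])
    sides = list(clades)
    if not rooted:
        sides.extend(all_leaves - s for s in clades)

    is_mono = members in sides
    if is_mono:
        containing = members
    else:
        containing = min((s for s in clades if members <= s), key=len)
    return MonophylyResult(is_monophyletic=is_mono, containing_clade=containing)


# ---------------------------------------------------------------------------
# Reports


def calls_to_table(calls: Sequence[RegulationCall],
                   rules: Sequence[MotifRuleSet]) -> "pandas.DataFrame":
    """Flatten calls into one row per subject (verdicts + per-position evidence)."""
    import pandas as pd

    rhash = ruleset_hash(rules)
    rows = []
    for call in calls:
        row: dict = {"subject_id": call.subject_id, "ruleset_hash": rhash}
        for name, res in call.results.items():
            row[f"{name}"] = res.verdict.value
            for ev in res.evidence:
                row[f"{name}@{ev.position}"] = f"{ev.residue}:{ev.status.value}"
        rows.append(row)
    return pd.DataFrame(rows)
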
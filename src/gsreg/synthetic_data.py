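"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to the analysis -- curated GS sequence families, plate-reader
NADH-depletion traces, deposited coordinate models -- cannot ship with
the package, so each generator here produces data with the same
statistical structure the analysis assumes, plus the truth used to make
it:

* :func:`make_gs_family` evolves a protein family along random
  bifurcating trees with the diagnostic effector-binding residues
  implanted per group, returning sequences, the true generative
  alignment, a tree in which each group is monophyletic, and a truth
  table of expected regulation verdicts.
* :func:`make_assay_traces` builds A340(t) time courses with a coupling
  lag, Gaussian noise and first-order flattening near NADH exhaustion,
  driven by a Hill rate law; :func:`make_hill_rates` gives bare
  initial-rate dose-response points for fit-recovery studies.
* :func:`make_coordinates` builds C-alpha-like chains related by a known
  rigid transform plus optional coordinate noise.

Every generator is a pure function of its spec and seed; one seed fans
out through :class:`numpy.random.SeedSequence` so sub-streams stay
independent and reproducible. The scaffold residue composition is a
generic globular-protein frequency profile, not a real GS profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import EPSILON_340, AssayTrace, hill_rate
from .seq_core import AA20, GAP, AlignedRecord, Msa, SequenceRecord, write_fasta, write_msa
from .struct_compare import Atom, CoordinateSet

#: Diagnostic positions (MtGS numbering) and the residues of the
#: 2OG-capable configuration.
CAPABLE_2OG_RESIDUES = {20: "R", 34: "A", 88: "R", 174: "R", 175: "R", 191: "S"}
#: Residues satisfying / breaking the glutamine-inhibition rule.
GLN_CAPABLE, GLN_INCAPABLE = "R", "G"
DIAGNOSTIC_POSITIONS = sorted(set(CAPABLE_2OG_RESIDUES) | {67})

# residues that definitely violate the default rule at each 2OG position
_VIOLATING = {20: "DE", 88: "DE", 174: "DE", 175: "DE", 191: "DE", 34: "DEFWY"}

# Rough average residue frequencies of globular proteins (order AA20);
# used only to make scaffolds look protein-like.
_BG_FREQS = np.array([
    .083, .014, .054, .067, .039, .071, .023, .059, .058, .097,
    .024, .040, .047, .039, .055, .066, .053, .069, .011, .031,
])
_BG_FREQS = _BG_FREQS / _BG_FREQS.sum()


@dataclass(frozen=True)
class FamilySpec:
    """Configuration of a synthetic GS-like family."""

    seed: int
    n_groups: int = 6
    seqs_per_group: int = 8
    scaffold_length: int = 450
    #: per-group (2OG capable?, Gln inhibitable?); cycles a default
    #: pattern when omitted
    group_truths: Optional[tuple] = None
    substitution_rate: float = 0.02   # per site per branch
    indel_rate: float = 0.005         # per site per leaf sequence
    indel_p: float = 0.4              # geometric length parameter
    truth_preserving: bool = True     # protect diagnostic sites
    protection_window: int = 3

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must be in [0, 1)")
        if self.scaffold_length < max(DIAGNOSTIC_POSITIONS) + 10:
            raise ValueError("scaffold too short for the diagnostic positions")
        if self.indel_rate > 0 and self.truth_preserving is False and \
                self.substitution_rate == 0 and self.indel_rate > 0.5:
            raise ValueError("contradictory spec")

    def truths(self) -> list[tuple[bool, bool]]:
        if self.group_truths is not None:
            if len(self.group_truths) != self.n_groups:
                raise ValueError("group_truths length != n_groups")
            return [tuple(t) for t in self.group_truths]
        cycle = [(True, False), (False, True), (True, True), (False, False)]
        return [cycle[i % 4] for i in range(self.n_groups)]


@dataclass
class FamilyData:
    """Everything :func:`make_gs_family` produced, with writers."""

    records: list            # unaligned SequenceRecord, reference first
    msa: Msa                 # the true generative alignment
    tree_newick: str
    groups: dict             # group_id -> member ids
    truth: pd.DataFrame      # per-sequence and per-group expected verdicts
    reference_id: str
    spec: FamilySpec

    def write(self, outdir) -> dict:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "sequences.fasta",
            "msa": out / "alignment.fasta",
            "tree": out / "tree.nwk",
            "groups": out / "groups.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_msa(self.msa, paths["msa"])
        paths["tree"].write_text(self.tree_newick + "\n")
        with paths["groups"].open("w") as fh:
            for gid, members in self.groups.items():
                for m in members:
                    fh.write(f"{gid}\t{m}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_topology(labels: list, rng: np.random.Generator) -> str:
    """Random bifurcating newick subtree over the given leaf labels."""
    nodes = list(labels)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0]


def _evolve_group(root: np.ndarray, n_leaves: int, sub_rate: float,
                  mutable: np.ndarray, rng: np.random.Generator) -> list:
    """Evolve the root sequence down a random bifurcating tree.

    Returns leaf sequences (as index arrays into AA20) in leaf order.
    Each branch substitutes each mutable site with probability
    ``sub_rate`` to a uniformly random different residue.
    """
    def mutate(seq: np.ndarray) -> np.ndarray:
        out = seq.copy()
        hits = np.where(mutable & (rng.random(len(seq)) < sub_rate))[0]
        for i in hits:
            choices = [k for k in range(20) if k != out[i]]
            out[i] = rng.choice(choices)
        return out

    # recursive random split of leaf count, evolving along each branch
    def grow(seq: np.ndarray, k: int) -> list:
        if k == 1:
            return [mutate(seq)]
        left = int(rng.integers(1, k))
        node_seq = mutate(seq)
        return grow(node_seq, left) + grow(node_seq, k - left)

    return grow(root, n_leaves)


def make_gs_family(spec: FamilySpec) -> FamilyData:
    """Generate a GS-like family with implanted effector-binding truth.

    The reference row (first record, MtGS-like: 2OG capable, not
    glutamine inhibitable) is kept free of substitutions and indels so
    reference residue numbering equals scaffold numbering, exactly as
    MtGS anchors the numbering of the real analysis.
    """
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_scaffold, rng_tree, rng_evo, rng_indel = rngs
    L = spec.scaffold_length
    aa = np.array(list(AA20))

    scaffold = rng_scaffold.choice(20, size=L, p=_BG_FREQS)
    diag0 = [p - 1 for p in DIAGNOSTIC_POSITIONS]
    protected = np.zeros(L, dtype=bool)
    for p in diag0:
        lo = max(0, p - spec.protection_window)
        hi = min(L, p + spec.protection_window + 1)
        protected[lo:hi] = True
    mutable = ~protected if spec.truth_preserving else np.ones(L, dtype=bool)

    reference_id = "MtGS_like_ref"
    ref = scaffold.copy()
    aa_index = {c: k for k, c in enumerate(AA20)}
    for pos, res in CAPABLE_2OG_RESIDUES.items():
        ref[pos - 1] = aa_index[res]
    ref[67 - 1] = aa_index[GLN_INCAPABLE]

    truths = spec.truths()
    groups: dict[str, list[str]] = {}
    leaf_seqs: dict[str, np.ndarray] = {reference_id: ref}
    truth_rows = []
    subtrees = []
    for g in range(spec.n_groups):
        gid = f"group{g + 1}"
        cap2og, capgln = truths[g]
        labels = [f"{gid}_seq{i + 1}" for i in range(spec.seqs_per_group)]
        groups[gid] = labels
        # group root: reference scaffold with the group's effector truth
        # implanted (incapable 2OG -> one randomized violating position)
        root = ref.copy()
        for pos, res in CAPABLE_2OG_RESIDUES.items():
            root[pos - 1] = aa_index[res]
        if not cap2og:
            viol_pos = int(rng_evo.choice(sorted(CAPABLE_2OG_RESIDUES)))
            viol_res = str(rng_evo.choice(list(_VIOLATING[viol_pos])))
            root[viol_pos - 1] = aa_index[viol_res]
        root[67 - 1] = aa_index[GLN_CAPABLE if capgln else GLN_INCAPABLE]
        seqs = _evolve_group(root, spec.seqs_per_group, spec.substitution_rate,
                             mutable, rng_evo)
        for label, seq in zip(labels, seqs):
            leaf_seqs[label] = seq
            truth_rows.append({
                "sequence_id": label, "group_id": gid,
                "truth_2og": "capable" if cap2og else "incapable",
                "truth_gln": "capable" if capgln else "incapable",
            })
        subtrees.append(_random_topology(labels, rng_tree))
    tree_newick = "(" + ",".join(subtrees + [reference_id]) + ");"

    # indels in scaffold coordinates: deletions mark sites as gaps,
    # insertions attach extra residues after a scaffold position
    deletions: dict[str, np.ndarray] = {}
    insertions: dict[str, dict[int, str]] = {}
    for label in leaf_seqs:
        deleted = np.zeros(L, dtype=bool)
        ins: dict[int, str] = {}
        if label != reference_id and spec.indel_rate > 0:
            allowed = ~protected if spec.truth_preserving else np.ones(L, bool)
            site = 0
            while site < L:
                if allowed[site] and rng_indel.random() < spec.indel_rate:
                    length = int(rng_indel.geometric(spec.indel_p))
                    if rng_indel.random() < 0.5:
                        stop = site
                        while stop < L and allowed[stop] and stop - site < length:
                            deleted[stop] = True
                            stop += 1
                        site = stop
                    else:
                        ins[site] = "".join(
                            aa[rng_indel.choice(20, size=length, p=_BG_FREQS)])
                        site += 1
                else:
                    site += 1
        deletions[label] = deleted
        insertions[label] = ins

    # assemble the generative alignment: per scaffold site one column,
    # plus max-insertion-length columns after sites carrying insertions
    order = [reference_id] + [m for g in groups.values() for m in g]
    ins_width = {}
    for site in range(L):
        w = max((len(insertions[l].get(site, "")) for l in order), default=0)
        if w:
            ins_width[site] = w

    aligned_rows = {}
    for label in order:
        seq = leaf_seqs[label]
        deleted = deletions[label]
        parts = []
        for site in range(L):
            parts.append(GAP if deleted[site] else aa[seq[site]])
            if site in ins_width:
                s = insertions[label].get(site, "")
                parts.append(s + GAP * (ins_width[site] - len(s)))
        aligned_rows[label] = "".join(parts)

    msa = Msa(tuple(AlignedRecord(l, aligned_rows[l]) for l in order))
    records = [msa.row(l).degap() for l in order]
    truth = pd.DataFrame(truth_rows)
    return FamilyData(records=records, msa=msa, tree_newick=tree_newick,
                      groups=groups, truth=truth, reference_id=reference_id,
                      spec=spec)


# ---------------------------------------------------------------------------
# Kinetic traces


@dataclass(frozen=True)
class TraceSpec:
    """Configuration of a synthetic coupled-assay trace set."""

    seed: int
    vmax: float = 3.269          # U mg^-1
    k_half: float = 0.14         # mM
    hill_n: float = 1.48
    concentrations: tuple = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)  # mM
    lag_s: float = 0.0
    noise_sd: float = 0.0        # AU
    nadh_mm: float = 1.0         # NADH pool, mM
    enzyme_mass_mg: float = 0.002
    reaction_volume_l: float = 1e-4
    path_length_cm: float = 1.0
    epsilon_340: float = EPSILON_340
    times_s: tuple = tuple(np.arange(0.0, 601.0, 5.0))
    control_drift_au_min: float = 0.0

    def __post_init__(self) -> None:
        if min(self.vmax, self.k_half, self.hill_n) <= 0:
            raise ValueError("Hill parameters must be positive")
        if self.nadh_mm <= 0:
            raise ValueError("NADH pool must be positive")

    @property
    def nadh_pool_m(self) -> float:
        return self.nadh_mm * 1e-3

    @property
    def initial_a340(self) -> float:
        """Initial absorbance consistent with the NADH pool."""
        return self.nadh_pool_m * self.epsilon_340 * self.path_length_cm


def make_assay_traces(spec: TraceSpec) -> tuple[list, list]:
    """Simulate A340(t) traces, one per concentration, plus controls.

    Cumulative NADH consumption follows the lag-integrated linear law
    R(t) = r (t - tau (1 - e^{-t/tau})) and flattens first-order near
    exhaustion via C(t) = N0 (1 - e^{-R(t)/N0}); Gaussian noise of
    ``noise_sd`` AU is added per point. Controls carry baseline drift
    only. Zero enzyme mass gives flat traces apart from drift and noise.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times_s, dtype=float)
    el = spec.epsilon_340 * spec.path_length_cm
    n0 = spec.nadh_pool_m
    traces, controls = [], []
    for s_mm in spec.concentrations:
        v = float(hill_rate(s_mm, spec.vmax, spec.k_half, spec.hill_n))  # U/mg
        rate_m_s = v * spec.enzyme_mass_mg * 1e-6 / spec.reaction_volume_l / 60.0
        if spec.lag_s > 0:
            r_t = rate_m_s * (t - spec.lag_s * (1 - np.exp(-t / spec.lag_s)))
        else:
            r_t = rate_m_s * t
        consumed = n0 * (1 - np.exp(-r_t / n0))
        a = spec.initial_a340 - el * consumed
        a = a + rng.normal(0.0, spec.noise_sd, size=t.shape)
        traces.append(AssayTrace(
            times=t, absorbance_340=a, enzyme_mass_mg=spec.enzyme_mass_mg,
            reaction_volume_l=spec.reaction_volume_l,
            path_length_cm=spec.path_length_cm,
            label=f"S={s_mm}mM",
        ))
        ac = (spec.initial_a340 + spec.control_drift_au_min * t / 60.0
              + rng.normal(0.0, spec.noise_sd, size=t.shape))
        controls.append(AssayTrace(
            times=t, absorbance_340=ac, enzyme_mass_mg=0.0,
            reaction_volume_l=spec.reaction_volume_l,
            path_length_cm=spec.path_length_cm,
            label=f"control S={s_mm}mM", is_control=True,
        ))
    return traces, controls


def write_trace_csv(trace: AssayTrace, path) -> None:
    """Trace as a two-column CSV (time_s, a340) with a metadata sidecar JSON."""
    import json

    p = Path(path)
    pd.DataFrame({"time_s": trace.times, "a340": trace.absorbance_340}
                 ).to_csv(p, index=False)
    meta = {
        "enzyme_mass_mg": trace.enzyme_mass_mg,
        "reaction_volume_l": trace.reaction_volume_l,
        "path_length_cm": trace.path_length_cm,
        "label": trace.label, "is_control": trace.is_control,
    }
    p.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_trace_csv(path) -> AssayTrace:
    import json

    p = Path(path)
    df = pd.read_csv(p)
    meta = {}
    side = p.with_suffix(".meta.json")
    if side.exists():
        meta = json.loads(side.read_text())
    return AssayTrace(times=df["time_s"].to_numpy(),
                      absorbance_340=df["a340"].to_numpy(),
                      enzyme_mass_mg=meta.get("enzyme_mass_mg", 0.0),
                      reaction_volume_l=meta.get("reaction_volume_l", 1e-4),
                      path_length_cm=meta.get("path_length_cm", 1.0),
                      label=meta.get("label", p.stem),
                      is_control=meta.get("is_control", False))


def make_hill_rates(vmax: float, k_half: float, hill_n: float,
                    concentrations: Sequence[float], n_replicates: int = 3,
                    noise_frac: float = 0.03,
                    rng: Optional[np.random.Generator] = None,
                    seed: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Initial-rate dose-response points with multiplicative Gaussian noise.

    The noise standard deviation is ``noise_frac`` of the true rate at
    each point (rates floored at 0). Returns concentration and rate
    arrays of length ``len(concentrations) * n_replicates``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    s = np.repeat(np.asarray(concentrations, dtype=float), n_replicates)
    v_true = hill_rate(s, vmax, k_half, hill_n)
    v = v_true * (1.0 + noise_frac * rng.standard_normal(len(s)))
    return s, np.clip(v, 0.0, None)


# ---------------------------------------------------------------------------
# Coordinates


def make_coordinates(n_atoms: int, rotation: Optional[np.ndarray] = None,
                     translation: Optional[np.ndarray] = None,
                     noise_sd: float = 0.0, seed: int = 0,
                     ) -> tuple[CoordinateSet, CoordinateSet, np.ndarray, np.ndarray]:
    """A C-alpha-like chain and its copy under a known rigid transform.

    The chain is a 3.8-A-step self-avoiding random walk; the copy is
    ``R x + t`` plus isotropic Gaussian noise of ``noise_sd`` per
    component. Returns (A, B, R, t) with B = R A + t + noise.
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    ss = np.random.SeedSequence(seed)
    rng_walk, rng_transform, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3))

    pts = [np.zeros(3)]
    while len(pts) < n_atoms:
        for _ in range(40):
            step = rng_walk.standard_normal(3)
            step *= 3.8 / np.linalg.norm(step)
            cand = pts[-1] + step
            d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) if len(pts) > 1 \
                else np.array([np.inf])
            if d.min() > 3.0:
                break
        pts.append(cand)
    xyz_a = np.array(pts)

    if rotation is None:
        from scipy.spatial.transform import Rotation
        rotation = Rotation.random(rng=rng_transform).as_matrix()
    rotation = np.asarray(rotation, dtype=float)
    if translation is None:
        translation = rng_transform.uniform(-20, 20, size=3)
    translation = np.asarray(translation, dtype=float)

    xyz_b = (rotation @ xyz_a.T).T + translation
    if noise_sd > 0:
        xyz_b = xyz_b + rng_noise.normal(0.0, noise_sd, size=xyz_b.shape)

    def to_cs(xyz: np.ndarray, b0: float) -> CoordinateSet:
        return CoordinateSet([
            Atom(chain="A", res_num=i + 1, icode="", res_name="ALA",
                 name="CA", altloc="", occupancy=1.0,
                 xyz=tuple(p), b_factor=b0, element="C")
            for i, p in enumerate(xyz)
        ])

    return to_cs(xyz_a, 20.0), to_cs(xyz_b, 20.0), rotation, translation
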
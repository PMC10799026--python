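# gsreg — regulation-mode analysis for GSI-α glutamine synthetases

Archaeal glutamine synthetases of the GSI-α class are controlled in two
opposite ways: some enzymes are switched **on** by the nitrogen-starvation
metabolite 2-oxoglutarate (2OG), while others are switched **off** by their
own product through glutamine feedback inhibition. Which mode an enzyme uses
is encoded in a handful of active-site and effector-pocket residues, so it
can be predicted directly from sequence once those positions are mapped onto
a reference numbering.

`gsreg` implements the full desk-scale analysis around this question:

- **Sequence layer** (`gsreg.seq_core`) — FASTA/MSA I/O, and mapping of
  reference residue positions (MtGS numbering) through a gapped alignment.
- **Regulation calls** (`gsreg.regulation`) — residue-motif rule sets for
  2OG binding and glutamine inhibition, per-sequence and per-group verdicts,
  conservation profiles (information content in bits), class counts
  (either / both / neither / unknown), and monophyly checks of groups
  against a phylogenetic tree.
- **Kinetics** (`gsreg.kinetics`) — initial-rate extraction from NADH-coupled
  A340 traces (best linear window, control subtraction,
  ε₃₄₀ = 6220 M⁻¹ cm⁻¹), Hill-model fitting
  v(S) = Vmax·Sⁿ/(Kⁿ+Sⁿ) with multi-start nonlinear least squares,
  activation fractions and inhibition percentages.
- **Structure comparison** (`gsreg.struct_compare`) — Kabsch superposition
  with iterative outlier trimming, Cα pairing by residue number or by
  alignment, per-residue deviation "putty" PDBs, ligand contacts and
  van-der-Waals clash checks.
- **Synthetic data** (`gsreg.synthetic_data`) — generators with known ground
  truth: protein families with implanted regulation motifs (plus matching
  alignment, tree, group table and truth table), NADH-depletion assay
  traces, noisy dose–response rate tables, and rigid-transform coordinate
  pairs. Every pipeline stage has a closure test against these generators.
- **CLI** (`gsreg`) — `simulate`, `classify`, `kinetics`, `superpose`
  subcommands; logs to stderr, data to files (TSV + JSON); exit codes
  0 / 2 (usage) / 3 (data error).

## The residue rules

In MtGS numbering, the default rule sets are:

| Rule | Requires | Excludes |
|---|---|---|
| 2OG-binding | Arg20, Arg88, Arg174, Arg175, Ser191 | bulky/charged residues at 34 |
| Gln-inhibition | Arg67 (Asp50′-loop arginine) | — |

A definite mismatch at any position makes the sequence *incapable*; a gap or
unknown residue makes the call *unknown*; otherwise it is *capable*. MtGS
itself is 2OG-capable but carries Gly67, so it escapes feedback inhibition;
MsGS has the arginine at 67 but lacks the intact 2OG pocket — the two
enzymes are each other's converse.

## Worked example

Simulate a family with implanted ground truth, classify it, and verify the
calls, all from the command line:

```console
$ gsreg simulate family --seed 11 --out family
wrote 5 files to family
$ gsreg classify --msa family/alignment.fasta --reference MtGS_like_ref \
      --groups family/groups.tsv --tree family/tree.nwk --out calls
classified 49 sequences -> calls
$ head -3 calls/group_calls.tsv | cut -f1-4
subject_id      ruleset_hash    2OG-binding     2OG-binding@20
group1  a5d482d76043    capable R:satisfies
group2  a5d482d76043    incapable       R:satisfies
$ python -c "import json; print(json.load(open('calls/classification.json'))['class_counts'])"
{'either': 4, 'both': 1, 'neither': 1, 'unknown': 0}
```

Kinetics, end to end from raw traces (defaults simulate the MtGS/NH₄Cl
parameter set with a 20 s coupling lag and photometric noise):

```console
$ gsreg simulate traces --seed 4 --out traces
wrote 8 trace/control pairs to traces
$ gsreg kinetics --traces traces --out fit
Vmax=3.101 U/mg  K0.5=0.125 mM  n=1.47 -> fit
```

Or from Python, recovering the cooperative 2OG activation switch
(half-activation 0.17 mM, Hill coefficient 3.4) from a simulated
dose–response at 3 % noise:

```python
from gsreg.kinetics import fit_hill, activation_fraction
from gsreg.synthetic_data import make_hill_rates
import numpy as np

s, v = make_hill_rates(1.0, 0.17, 3.4, np.geomspace(0.02, 5.0, 10),
                       n_replicates=3, noise_frac=0.03, seed=42)
m = fit_hill(s, v)
print(f"K0.5 = {m.k_half:.3f} mM   n = {m.hill_n:.2f}   Vmax = {m.vmax:.3f}")
print(f"activity at 0.06 mM: {activation_fraction(m, 0.06):.1%}")
print(f"activity at 0.60 mM: {activation_fraction(m, 0.60):.1%}")
```

prints

```
K0.5 = 0.169 mM   n = 3.41   Vmax = 1.002
activity at 0.06 mM: 2.9%
activity at 0.60 mM: 98.7%
```

— the steep off/on transition between 0.06 mM (essentially inactive) and
0.6 mM (saturated) that makes 2OG a genuine switch rather than a dimmer.

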
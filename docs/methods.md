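# Methods

This note defines the models and numerical procedures implemented in
`gsreg`, the defaults and units of every tunable parameter, and the known
limitations. Everything stated here is computed by the package; no claim is
made beyond what the code and tests verify.

## 1. Reference position mapping (`seq_core`)

Residue positions are always given in the numbering of a designated
reference sequence (MtGS numbering by default). Given an alignment
containing the reference row, `map_reference_positions` walks the gapped
row, counting non-gap characters, and records the alignment column of each
requested position. `residues_at` then reads those columns from any other
row. The map is invariant under insertion of gap columns anywhere in the
alignment (tested by inserting a gap at every possible column) and errors
if a requested position exceeds the reference's ungapped length.

Parsing rules: FASTA identifiers end at the first whitespace; sequences
are uppercased; `.` is normalised to `-`; characters outside the 20
standard amino acids become `X` (logged); duplicate identifiers and ragged
alignment rows are errors.

## 2. Regulation-mode classification (`regulation`)

A `MotifRuleSet` is a named set of *required* residues and *excluded*
residues at reference positions. Defaults (MtGS numbering):

- **2OG-binding**: requires R20, R88, R174, R175, S191; excludes
  D, E, F, W, Y, K, R, H, Q, N, M, L, I at position 34 (small residues
  A, G, S, C, T, V, P are compatible with the effector pocket).
- **Gln-inhibition**: requires R67 (the Asp50′-loop arginine contributed
  by the adjacent subunit).

Verdict logic per rule, in order of precedence: any definite mismatch →
`incapable`; otherwise any gap/`X` at a scored position → `unknown`;
otherwise `capable`. Evidence (residue and status per position) is kept in
every call, and a 12-hex-digit SHA-256 hash of the exact rule configuration
is stamped into all outputs.

Group-level calls first build a per-column `GroupProfile`: residue
frequencies over the 20 amino acids plus gap (normalised to 1; `X`
excluded and logged), gap fraction, modal residue (alphabetical
tie-break, logged), and information content
IC = log₂(20) − H(p) in bits, where H is the Shannon entropy of the
frequencies renormalised over amino acids only. Consensus modes:
`modal` (default; classify the modal residue per position), `plurality`
(modal residue must exceed a threshold θ, default 0.8, else `unknown`),
`unanimity`. Groups are then counted into `either` (2OG only or Gln
only... strictly: exactly one capability), `both`, `neither`, or
`unknown` (any unknown verdict).

Monophyly of a group on a supplied tree is decided by bipartition
membership: on an unrooted tree (default) the group is monophyletic iff
its leaf set equals one side of some edge (a clade or a clade's
complement); on a rooted tree it must equal a clade. For non-monophyletic
groups the smallest rooted clade containing all members is reported. The
implementation was validated against exhaustive clade enumeration on all
leaf subsets of small trees.

## 3. Kinetics (`kinetics`)

**Rate extraction.** An assay trace is (t in s, A₃₄₀). The initial rate is
the slope (in AU·min⁻¹) of the best linear window: all contiguous windows
of ≥ `window_min_points` (default 5) points are scanned exhaustively; among
windows with R² ≥ `r2_threshold` (default 0.99) the one with the largest
|slope| wins, ties broken by earliest start then longest window. If no
window qualifies, the threshold is relaxed in steps of 0.01 down to 0.90
(logged); below that, the trace is rejected ("no linear phase"). A no-enzyme
control trace, when given, must cover the chosen window's timeframe; its
slope over that same timeframe is subtracted.

**Specific activity.** For a net slope m (AU·min⁻¹), path length l (cm),
reaction volume V (l) and enzyme mass w (mg):

  a = |m| / (ε₃₄₀ · l) · V · 10⁶ / w  [µmol·min⁻¹·mg⁻¹ = U·mg⁻¹]

with ε₃₄₀ = 6220 M⁻¹cm⁻¹. Worked example: 0.0622 AU·min⁻¹ in 100 µl with
2 µg enzyme → 0.5 U·mg⁻¹.

**Hill fitting.** v(S) = Vmax·Sⁿ/(K₀.₅ⁿ + Sⁿ), with v(0) = 0. Replicates
are averaged per unique concentration; ≥ 4 distinct concentrations are
required. Fitting uses bounded nonlinear least squares
(`scipy.optimize.curve_fit`) from multiple starts (n₀ ∈ {0.5, 1, 2, 4};
Vmax₀ = max rate; K₀ = concentration nearest half-max), keeping the best
residual. Standard errors come from the covariance of the best fit; n can
be fixed (e.g. to 1 for a Michaelis–Menten fit). Noiseless data are
recovered to < 0.1 % relative error; at 3 % multiplicative noise with
3 replicates the median bias over seeds is < 5 % for all tested parameter
regimes.

`activation_fraction(model, c)` = v(c)/Vmax; `inhibition_percent(v, v_ref)`
= 100·(1 − v/v_ref), clipped at 0 with a warning if v > v_ref.

## 4. Structure comparison (`struct_compare`)

PDB I/O uses gemmi. Alternate locations are resolved to the highest
occupancy (ties: blank/`A` first). Chain selection for superposition
defaults to the chain with the lowest mean B-factor. Cα pairing is either
`by_residue_number` (matching residue number + insertion code) or
`by_alignment` (two-row MSA, ordinal pairing of mutually ungapped columns).

Superposition is the Kabsch algorithm: SVD of the cross-covariance of the
centred point sets with determinant correction, guaranteeing a proper
rotation (det = +1) even for degenerate or mirror-related inputs. With
`trim=True` (default), pairs deviating more than max(2·rmsd, 3.0 Å) are
removed and the fit repeated until convergence, never discarding more than
half the pairs. For pairs perturbed by isotropic Gaussian noise of
standard deviation σ per coordinate, the expected rmsd is σ√3; the
implementation matches this law within 5 % and agrees with
`scipy.spatial.transform.Rotation.align_vectors` used as an independent
cross-check in the tests.

"Putty" output writes the per-residue Cα deviation (Å) into the B-factor
column of the first structure (unpaired residues get a sentinel, default
0.00, and are logged). Ligand contacts use a k-d tree within a distance
cutoff; clash checks flag atom pairs closer than the sum of van-der-Waals
radii minus a tolerance (unknown elements fall back to 1.7 Å, logged).

## 5. Synthetic data (`synthetic_data`)

One master seed fans out through `numpy.random.SeedSequence.spawn` so the
family, trace and coordinate generators draw from independent,
reproducible streams.

**Families.** A background scaffold (length ≥ 250, default 450) is drawn
from a fixed amino-acid composition; the reference row gets the
2OG-capable/Gln-incapable residue configuration and is never mutated, so
it anchors the numbering. Each group's root implants its ground-truth
configuration (an incapable 2OG group gets one randomly chosen violating
residue at a required position); descendants evolve by per-site
substitution (default rate 0.02) along a random topology, with positions
within ±3 of any diagnostic site protected unless `truth_preserving` is
disabled. Indels (default rate 0.005) are applied in scaffold coordinates
and reconciled into a master alignment. Output: unaligned FASTA, aligned
FASTA, newick tree (groups monophyletic by construction), group TSV and
truth TSV. The closure tests require 100 % truth recovery by the
classifier on default settings, and monotone degradation when protection
is off.

**Assay traces.** Given Hill parameters, enzyme mass w (mg), volume V (l)
and an NADH pool N₀ (default 1 mM), the true consumption rate is
R = v·w·10⁻⁶/V/60 (M·s⁻¹). An optional coupling lag τ enters as
R(t)·(t − τ(1 − e^(−t/τ)))/t, and substrate depletion caps cumulative
consumption at C(t) = N₀(1 − e^(−R·t/N₀)). The trace is
A(t) = ε₃₄₀·l·(N₀ − C(t)) plus optional Gaussian noise; controls carry
only baseline drift. Closure: with zero noise, zero lag and an enzyme dose
far from depletion, `extract_rate` recovers the generating specific
activity to 0.1 %.

**Dose–response tables.** `make_hill_rates` evaluates the Hill form and
applies multiplicative Gaussian noise (σ = `noise_frac`·v, default 3 %),
flooring rates at 0 — the scheme used by the acceptance targets.

**Coordinates.** A 3.8 Å-step self-avoiding random walk and its image
under a random (or given) proper rotation + translation, plus isotropic
noise; the generating transform is returned for closure tests.

## 6. Acceptance targets (`scripts/acceptance.py`)

For each regime (2OG activation: Vmax = 1 relative, K₀.₅ = 0.17 mM,
n = 3.4, 0.02–5 mM; MtGS/NH₄Cl: 3.269 U·mg⁻¹, 0.14 mM, 1.48, up to 5 mM;
MsGS/glutamate: 1.40 U·mg⁻¹, 32.57 mM, 2.35, up to 200 mM) the script
simulates 10 log-spaced concentrations × 3 replicates at 3 % noise, fits,
and reports the median recovered parameter over 200 seeds derived from the
master seed. Typical recoveries are within 1 % of the generators; the
stochastic tolerance for acceptance is 10 %.

## Limitations

- The family generator is deliberately non-phylogenetic: uniform
  substitution without rate heterogeneity or empirical exchange matrices,
  star-like random topologies, site-independent indels. It provides ground
  truth for closure tests, not realistic evolution.
- The motif rules are necessary-condition heuristics at seven positions;
  they cannot detect compensating mutations elsewhere, and `unknown` is
  the honest verdict whenever a scored position is gapped or ambiguous.
- The trace model treats the coupled assay as a single exponential
  depletion with an optional first-order lag; it does not model ATP
  regeneration kinetics, product inhibition within a trace, or instrument
  drift beyond a linear control.
- Hill-fit standard errors are asymptotic (from the Jacobian) and
  underestimate uncertainty for small designs.
- Superposition quality depends on the supplied pairing; `by_alignment`
  trusts the given alignment and does not realign structurally.
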
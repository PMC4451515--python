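# Methods

This note records the models, conventions and deliberate approximations
behind felscape, and what the synthetic validation does and does not show.

## Units and indexing

Internal units follow simulation-package convention: nm for lengths, kJ/mol
for energies (k_B = 0.0083145 kJ/mol/K), ps for times. The single exception
is `helix` output, which uses kcal/mol as nearest-neighbor tables always do.
PDB coordinates (Å) are converted to nm exactly once, in the reader.
Nucleotides are indexed by their 1-based PDB residue number within a chain.

## Free-energy landscapes

`estimate_fel` is the Boltzmann inversion F(s) = −k_B T ln P(s) of the CV
histogram over 1–2 CVs, min-shifted so the lowest occupied bin is 0. The
temperature defaults to 300 K. Empty bins carry a +∞ sentinel (−kT ln 0 is
undefined) and are excluded from every norm; they serialize as `inf`.

Default bin widths are 1 for hydrogen-bond-count CVs (integer-valued) and
0.05 nm for Rg; both configurable. The statistical error of a bin with n
samples is ≈ k_B T/√n, so whenever an estimated surface is compared against
a reference (convergence windows, the ground-truth double well) only bins
with ≥ 100 samples enter the norm — a stated threshold, not a tuned one.

Convergence is assessed as in block analysis: the series is split at given
fractions, each window's surface is compared with the full-series surface,
and the RMS |F_window − F_full| over co-occupied bins (optionally below an
F cap) is reported. A monotone decrease is reported, never assumed. Note
that a window whose samples are a mere renormalized restriction of the full
distribution is — correctly — invisible to this diagnostic after
min-shifting; drift is detected when the windows differ in *shape* (e.g.
well occupancy ratios), which is what the test constructs.

Basins are user-supplied axis-aligned rectangles, validated pairwise
disjoint, with half-open interval membership; frames outside every
rectangle are labelled `transition`. Making basin geometry part of the
configuration is a deliberate choice: basins of attraction on a landscape
are identified by inspection, and a declared rectangle is the reproducible
form of that step.

## Structural observables

Hydrogen bonds use the community-standard geometric criterion:
donor–acceptor heavy-atom distance ≤ 0.35 nm, plus a D–H···A angle ≥ 150°
applied only when the donor carries hydrogens (hydrogens are matched to
donors within 0.12 nm). Heavy-atom-only models and the toy ensembles fall
back to the distance test. Both thresholds, and the donor/acceptor atom-name
sets, are configurable — the criterion used to produce any given published
map is generally unrecoverable, so ours is declared, not inferred. The HB
probability map is symmetric: entry (i, j) is the fraction of frames in
which *any* hydrogen bond links residues i and j. The native-HB fraction Q
counts formed entries of the configured native list.

Rg is the mass-weighted (optionally unweighted) RMS distance from the
center of mass over polymer atoms; cations are always excluded. RMSD uses
heavy atoms and, by default, optimal superposition (Kabsch rotation via
`scipy.spatial.transform.Rotation.align_vectors`, with the residual
recomputed from coordinates because the solver's reported residual loses
precision near zero). Raw (unsuperposed) RMSD is a flag away.

## Leader clustering

The clustering is the literal single-pass scheme: frame i is compared to
existing cluster representatives *in founding order* and joins the FIRST
one within the threshold (0.1 nm default); otherwise it founds a new
cluster. The final clusters are sorted by size, stably, so ties go to the
earliest-founded cluster — the documented tie-break for basin
representatives (the founder of a basin's largest cluster). Leader
clustering is order-sensitive by construction; the processing order is
explicit (`trajectory`, the default, or `random` with a seed) and a
nearest-representative variant exists but is not the default, since the
first-qualifying reading matches the procedure as usually stated.

## Ion statistics

Residue–ion distance is the minimum over the residue's atoms (the most
inclusive reading of "within 0.4 nm of a nucleotide"); a phosphate-only
mode is available. "Separated by at least 4 nucleotides" is implemented as
|i − j| ≥ 4 on residue numbering, with the bound configurable. Anions are
parsed and stored but excluded from every statistic. R_p is reported with
its mediated/non-mediated counts, and an all-mediated ensemble yields +∞
(serialized as `inf`) rather than a silent clip.

## Kinetics

D is estimated per CV from the mean-square displacement,
D(τ) = ⟨(s(t+τ) − s(t))²⟩/2τ, with the plateau taken as the mean over a lag
window; a large relative spread inside the window flags the absence of a
plateau (pure drift gives D(τ) ∝ τ and is flagged, not averaged away).

The rate model lives on the occupied bins of a surface with von-Neumann
connectivity and per-axis Δs and D (the axes of a 2D surface carry
different units). Rates follow the discretized-Smoluchowski form
k_ij = (D/Δs²) exp(−(F_j−F_i)/2k_BT); a Metropolis-type convention
min(1, e^(−ΔF/kT)) is available. Both satisfy detailed balance w.r.t. the
Boltzmann weights *exactly*, and the test suite asserts the pairwise
identity to 1e-12. Position-independent D is a deliberate, rough
approximation — transition times derived from it are best read as
order-of-magnitude estimates, plausibly on the fast side.

KMC is the Gillespie algorithm: dwell ~ Exp(Σ_j k_ij), next state ∝ k_ij.
The trajectory-recording path spawns one substream per trajectory from the
global seed, so growing n_traj never reshuffles earlier trajectories. Two
vectorized routes (synchronous ensemble stepping for first-passage times;
an embedded-chain loop with time-weighted occupancy for stationarity
checks) are statistically identical and are cross-checked against the
Gillespie path in the tests. Folding is first entry into the designated
folded basin, so the folding curve is non-decreasing by construction; the
single-exponential fit f(t) = 1 − exp(−kt) reports its RMS residual, which
is the multi-exponential signature when the underlying process is not
two-state (a Gamma-distributed two-step chain visibly inflates it). MFPTs
come from the linear system Qτ = −1 restricted to non-target states, with
basin values weighted by the equilibrium distribution inside the source
basin; unreachable targets report +∞ with a warning. For 1D birth-death
chains the standard nested-sum closed form is provided as an independent
cross-check. One consequence of the continuous-time convention worth
stating: a 3-state unit-rate chain has MFPT(end→end) = 3, because the
middle state's exit rate is 2 (its mean dwell is 1/2), not the 4 steps of
the discrete-time embedded walk.

## Helix thermodynamics

`helix_stability` sums tabulated nearest-neighbor ΔG°₃₇ stacks over a
contiguous stem. Two conventions are exposed: `duplex` (initiation +
stacks + terminal AU/GU penalties — the standard duplex-formation free
energy) and `stem` (stacks only — the natural score for a stem embedded in
a larger fold, and the convention under which the bundled reconstruction
reproduces the reference stabilities −10/−12.4 kcal/mol). The bundled table
carries the Watson-Crick stack parameters shared verbatim by the 1999 and
2004 Turner rule sets (both adopt the Xia et al. 1998 regression), so the
two rule sets are indistinguishable for GU-free stems; GU-containing stack
values are deliberately not bundled (we would not ship numbers we could not
source exactly), and a lookup touching one raises an error naming the
stack. GU pairs themselves validate fine, and the terminal penalty applies
to AU and GU ends alike. The bundled pseudoknot input
(`data/pseudoknot_2tpk_synthetic.json`) is a *synthetic reconstruction*:
sequence and stem registers rebuilt from published nucleotide identities of
the T2 gene 32 mRNA pseudoknot plus Watson-Crick complementarity, intended
only for stability arithmetic, not as coordinates.

## Synthetic data: what it emulates, and what it does not

The generators provide every pipeline input with exact ground truth:

* `sample_metropolis` draws from analytic Gaussian-well potentials with a
  uniform-step Metropolis chain (out-of-domain proposals rejected, which
  preserves detailed balance on the box). It emulates *unbiased sampling of
  a known landscape* — the role of a neutral replica — not the
  enhanced-sampling machinery itself; no bias deposition or replica
  exchange is modelled.
* `generate_toy_ensemble` builds 3-pseudo-atom nucleotides (backbone,
  donor, acceptor) on a ring — the minimum structure exercising HB
  detection, Rg, RMSD and the ion logic. Listed HB pairs form geometrically
  per frame by Bernoulli draws; cations are placed to be bridging (midpoint
  of two residues, relocated to within reach and recorded when the ring
  geometry makes the bridge impossible — or an error under the
  frozen-geometry flag), bound (0.3 nm above one residue) or free (> 2×
  cutoff from everything). Ground-truth labels travel as a JSON sidecar,
  never inside the PDB, so the analysis path cannot read them.
* `generate_known_rate_model` wraps exactly-prescribed rates.

Passing tests therefore demonstrate that the *estimators* are correct on
data matching their assumptions. They do not show that 0.35 nm/150° is the
right HB criterion for a given force field, that real landscapes are
well-sampled, or that a position-independent D holds for a real RNA — those
are properties of the data, not of the code.

## Problem sizes and numerical choices

The validation suite uses 10⁶ Metropolis samples for landscape recovery
(RMS error vs ground truth < 0.3 kJ/mol on ≥100-sample bins), 10⁴ KMC
trajectories for rate and MFPT recovery (5% tolerance — the Monte-Carlo
error at that ensemble size), 10⁶ jumps for stationarity (total-variation
< 0.02 on a 10-bin surface), 300 frames for the three-conformer clustering
check and 5000 frames for binomial-accuracy HB/ion probabilities (±0.02 ≈
3σ). Ties, degenerate inputs and sentinels are as above: stable sorts for
cluster ties, +∞ for empty bins/unreachable basins/all-mediated R_p, errors
for empty ensembles and misaligned inputs.

## Known limitations

Only the neutral-replica reading of CV series is supported (no reweighting
of biased replicas); binary trajectory formats (XTC/TRR/DCD) are not parsed
— ensembles arrive as multi-model PDB; base-pair classification (WC vs
non-canonical edges, A-minor typing) is out of scope, as are electrostatic
ion-atmosphere models and Mg²⁺ inner/outer-sphere classification; MSM
estimation from transition counts is deliberately absent (the model here is
built from the FEL, which is its point and its approximation).
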
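# Methods

## The rigid-base-pair Gaussian-mixture model

A duplex of `n_bp` base pairs is reduced to `n_bp − 1` bp steps, each
described by the six inter-bp helical parameters (shift, slide, rise in Å;
tilt, roll, twist in degrees).  Step `i` carries one or more conformational
*substates*; substate `s` is a Gaussian basin

    E_s(x) = (x − μ_s)ᵀ F_s (x − μ_s) + ε_s        [kcal/mol]

written without the conventional ½ so that the quadratic restraint and the
basin share one convention; the implied covariance is `Σ = (k_BT/2) F⁻¹`
and a diagonal basin has marginal variance `k_BT/(2F_ii)`.  Adjacent steps
may pay an Ising mismatch penalty `J` when their substate labels differ
(default `J = 0`).

Defaults (synthetic, chosen to caricature B-DNA ensembles rather than fit
any particular trajectory):

| parameter | default | unit |
|---|---|---|
| relaxed twist mean | 34.6 | deg/step |
| twist SD (unimodal step) | 3.0 (2.5–3.2 plausible band) | deg |
| twist SD (per substate, bimodal step) | 2.8 | deg |
| bimodal mean-twist separation | 20.0 | deg |
| shift / slide / rise SD | 0.45 / 0.40 / 0.30 | Å |
| tilt / roll SD | 2.5 / 4.0 | deg |
| twist–roll correlation | −0.4 | – |
| twist–slide correlation | +0.3 | – |
| temperature | 300 | K |

Pyrimidine–purine steps (TA, TG, CA, CG) are *twist capacitors*: they get
two equal-weight substates straddling the relaxed twist by the full
separation.  `homogeneous_model` builds the single-substate diagonal chain
used for analytic elasticity validation.

## Sampling

*Unbiased*: substate labels are drawn exactly (forward-filter /
backward-sample along the nearest-neighbour chain, with the Gaussian
normalizers `exp(−βε)/√det F` folded into the weights), then each step's
6-vector is drawn from its substate Gaussian.  Draws are i.i.d.; there is
no autocorrelation by construction.

*Biased (umbrella window)*: the restraint `K_tw (Σ twist_i − T_ref)²`
couples only the in-region twist coordinates and only through a rank-one
quadratic.  Conditional on the labels the joint distribution of all step
6-vectors is therefore still Gaussian (block precision plus a rank-one
twist–twist term), and the *marginal* weight of a label configuration has
a closed form via the matrix determinant lemma built from per-step
scalars.  The sampler exploits this:

* when the number of label configurations is ≤ 4096 they are enumerated,
  the marginal weights computed exactly, and frames drawn i.i.d.
  (categorical labels, then the conditional Gaussian via a Cholesky factor
  cached per configuration);
* for larger spaces a collapsed Metropolis chain runs over labels only
  (single-step proposals accepted on marginal-weight ratios), with the
  6-vectors again drawn exactly given the labels.

An earlier design updated labels by Metropolis at *fixed* x; with basins
20° apart the acceptance collapses to ~10⁻⁴ because the current x pins its
label, so that scheme was replaced by the marginalized one.  The collapsed
chain's stationary distribution is the exact label marginal, which the
test suite verifies by enumeration and by flow-balance (detailed-balance)
checks.

The umbrella schedule orders windows outward from the relaxed centre in
two one-sided cascades; `sequential_seeding` hands each window's final
configuration to the next window of its branch (it matters only for the
collapsed-Metropolis path — the enumerated path is i.i.d.).  Each window
discards the first 10 % of frames as burn-in; with i.i.d. draws this is
redundant but kept for uniformity.  Every window consumes an independent
RNG stream spawned from the master seed.

## WHAM and the twisting PMF

Standard self-consistent 1-D WHAM on the end-to-end twist: histogram bin
width 0.25° on the total-twist axis (≈0.02°/bp after axis conversion),
convergence when every window free-energy shift moves by
< 10⁻⁷ kcal/mol, iteration cap 10⁵ (exceeded → error with the residual).
Bins with zero total count are masked, never zero-filled.  The profile is
reported against `δ = (T − ⟨T⟩_relaxed)/n_steps`, the average twist change
per bp step, with the relaxed mean taken from the central window, and is
min-zeroed over sampled bins.  No statistical-inefficiency weighting is
applied: the samplers produce decorrelated frames by construction; for
externally supplied trajectories the caller must decorrelate first.
Histogram-overlap diagnostics (`overlap_report`, the summed bin-wise
minimum of neighbouring normalized histograms) accompany every run.

## Elasticity

`fit_force_constant` performs an unweighted least-squares quadratic fit
`F = K(δ − c)² + F₀` over `|δ − δ_min| ≤ 2°/bp` (≥ 5 bins required; the
range is configurable).  The centre is left free rather than pinned at
δ = 0 and is reported in the output.  The ±2° range is read on the per-bp
axis: the fragment-total reading would span less than one window and
cannot support a fit.

The torsional modulus uses the homogeneous rod model,

    C = 2 K_rad L / (n k_B T),   K_rad = K (180/π)²,  L = 0.34 nm,

with `k_BT(300 K) = 0.5962 kcal/mol`.  For independent Gaussian steps this
is algebraically identical to `C = L / Var(step twist, rad²)`
(`ground_truth_modulus` evaluates that identity, including exact mixture
variances for multimodal steps), which is the package's independent oracle
for the full pipeline: per-step twist SDs of 3.171° and 2.578° correspond
to 111 nm and 168 nm.  The supercoiling conversion is twist-only,
`σ = Δtw/tw₀`, appropriate for fragments of ~10–20 bp below any buckling
transition.

## Deformation energy

The 12-parameter (6 inter + 6 intra) scorer assigns each step one or more
harmonic substates `½(x−μ)ᵀF(x−μ) + ε` with nearest-neighbour Ising
couplings `J(s_i, s_{i+1})` and Boltzmann-sums over all substate chains
with an exact transfer matrix in log space (`mode="min"` takes the
lowest-energy chain instead; both are exposed because either reading of a
chain-summed score is defensible).  Energies are referenced to the model's
minimum-energy configuration: the Viterbi (min-plus) chain fixes the
ground label path, whose stacked means give the reference configuration.
The published tetranucleotide parameterization of this model family is
*not* bundled; a JSON loader accepts user parameter sets
(provenance-tagged), and the shipped synthetic dimer-level set is derived
from the sampling model (inter-bp stiffness doubled to bridge the two
quadratic conventions; intra-bp block diagonal around zero with SDs
0.3/0.12/0.35 Å and 8/8/4°).

Under the default capacitor-rich generator the window-averaged deformation
energy is only weakly U-shaped (~0.2 kcal/mol between relaxed and
±4.5°/bp against a per-frame SD of ~3.8): the capacitors absorb twist
nearly free of charge, and for equal-ε substates the label part of the
score's expectation is window-independent.  The homogeneous generator
shows the full U (≈23 → ≈30 kcal/mol).  Tests therefore assert the
minimum at the relaxed window and a significant rise at ±4.5°/bp, and only
non-decrease within noise at ±2.5°/bp.

## Helical geometry

Base frames are fitted by Kabsch superposition of embedded idealized
planar base geometries (standard reference frame: origin near the helix
axis, +x toward the major groove, Crick bases flipped 180° about x).
Step and intra-bp parameters use the mid-frame (CEHS/3DNA-style)
decomposition, which is exactly invertible (`compose_step`,
round-trip-tested to 10⁻⁸); a curvilinear-axis treatment in the style of
Curves+ would shift values by small systematic offsets and is deliberately
not implemented.  Per-step axis bending is the angle between consecutive
bp-frame z-axes.  Degenerate inputs: a pure-twist step has an undefined
hinge axis, resolved by convention (roll = tilt = 0); bend angles are
clipped into [0°, 180°] only through the arccos domain guard.

Groove geometry follows the refined cross-strand phosphate-distance
approach: the width at a level is the minimal distance from each strand's
P atom to the opposite backbone polyline, split into minor/major by the
side of the bp-frame x-axis on which the connecting segment's midpoint
falls, minus a fixed 5.8 Å backbone-radius correction; the depth is the
distance from the bp mid-frame origin to the width segment.  Levels
without flanking phosphates are flagged undefined (NaN), not zeroed.  This
simplified level-wise measure is labelled as such in outputs; it is not a
curvilinear-axis groove tracing.

Watson–Crick integrity uses the canonical heavy-atom donor–acceptor pairs
(G·C: O6–N4, N1–N3, N2–O2; A·T: N6–O4, N1–N3); a pair is flagged melted
when any distance is ≥ 4.0 Å (the boundary itself counts as melted).

Idealized coordinates built from parameters place standard base atoms plus
backbone P/OP1/OP2 at fixed positions in each bp frame, chosen once so
that a straight fibre at twist 36°/rise 3.38 Å reproduces canonical
B-form groove dimensions (≈5.9/11.5 Å after the radius correction).  The
structure container (biotite) stores single-precision coordinates and PDB
text carries three decimals, so parameter round trips through those routes
are representation-limited (~10⁻⁴ and ~10⁻² respectively); the lossless
float64 atom-dict route is exact and is the one the 10⁻⁶-level tests use.

## Contacts

Hydrogen bonds: protein N/O to DNA N/O heavy atoms within 3.5 Å, with a
D–H···A angle ≥ 120° required whenever a hydrogen within 1.25 Å of either
heavy atom exists (distance-only fallback otherwise).  Hydrophobic:
C–C within 4.5 Å.  These cutoffs are package conventions (the protocols
this mirrors defer to unpublished tool defaults) and are overridable.
Moiety partition: base = ring + exocyclic atoms; sugar = C1′–C5′, O4′;
phosphate = P, OP1, OP2, O3′, O5′.  A contact is *specific* iff it touches
the base moiety.  Occupancy aggregates at residue–residue–moiety level: a
key is occupied in a frame when at least one atomic contact carries it.

## What the generator does and does not emulate

It reproduces: near-Gaussian per-step fluctuations with realistic SDs,
twist bimodality at YpR steps with substates up to 20° apart, twist–roll
anti-correlation and twist–slide correlation, the restraint-driven shift
of the mean end-to-end twist across the 21-window schedule, and
concentration of imposed twist on soft (capacitor) steps.  It does *not*
emulate: backbone BI/BII conformational coupling, sequence-specific
stiffness beyond the dimer rule, ion atmospheres, writhe or plectoneme
formation, base-pair opening/melting, or protein-induced rigidification —
so a passing suite validates the *analysis machinery* on a controlled
ensemble, not any claim about real DNA sequences.  Protein–DNA fixtures
for the contact module are constructed geometric probes, not structures
of real complexes.

## Problem sizes and numerical conventions

Acceptance-scale runs use 21 windows × 2×10⁵ frames; module tests use
10³–10⁵ frames per check, sizes chosen so each statistical assertion sits
at ≥ 3–4 standard errors of headroom.  Angles are degrees at every public
interface (radians only inside rotation math and the rod conversion);
k_B = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; all RNG streams spawn from a single
master seed via `numpy.random.SeedSequence`, and equal seeds give
bit-identical outputs.

## Known limitations

The shipped deformation parameters are synthetic, so absolute deformation
energies are not comparable to published tetranucleotide-parameterized
values — only trends are meaningful.  The mid-frame helical convention
differs from curvilinear-axis analyses by small systematic offsets.  The
groove measure is level-wise, not axis-following.  The collapsed-Metropolis
fallback (label spaces > 4096) mixes by single-label moves and can be slow
if two high-weight configurations differ at many steps simultaneously.
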
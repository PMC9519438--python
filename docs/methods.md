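# Methods

`supertwist` analyses the topology of closed-circular (minicircle) DNA and
of protein–DNA complexes formed on it.  This note describes the models and
algorithms, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## Ribbon model and White's theorem

A closed duplex is represented as a *ribbon*: per-base-pair frames holding
an axis origin, a unit tangent and a unit reference vector (axis → strand-I
backbone).  The central conservation law is White's theorem,

    Lk = Tw + Wr,

with Lk the integer Gauss linking number of the two backbone strands, Tw
the total winding of the reference vector about the axis, and Wr the Gauss
self-integral of the axis curve.  Superhelical density is σ = (Lk − Lk0)/Lk0
relative to the relaxed linking number Lk0.

**Writhe.**  Computed with the exact per-segment-pair solid-angle formula
(the Klenin–Langowski method) over all non-adjacent segment pairs of the
closed polyline; adjacent and identical pairs contribute zero by
convention.  Right-handed crossings count positive, so negatively
supercoiled plectonemes carry negative writhe.  The same kernel evaluated
over restricted index sets yields the arc decomposition used by the domain
analysis, `Wr_total = Wr_11 + Wr_22 + 2 Wr_12`, which is exact to machine
precision per frame and serves as an internal oracle.  The kernel is
validated in the test suite against an independent dense midpoint
quadrature of the Gauss double integral (agreement ≤ 1e−4 on a smooth
asymmetric test curve).  Pair sums are chunked (10^6 pairs per block) to
bound memory on long contours.  One numerical caveat: for *exactly planar*
polygons every quadrilateral in the kernel is degenerate, and a rigidly
rotated planar circle accumulates ~1e−8 of roundoff writhe; curves in
general position are rigid-motion invariant to 1e−9.

**Twist.**  The frame is parallel-transported step by step along the axis
(minimal rotation mapping tangent *i* onto tangent *i+1*); the signed
residual rotation of the reference vector about the local tangent, summed
over all steps including the closing one, is the total twist in turns.
The binding-site accumulated twist sums the same per-step angles over a bp
range (0-based half-open over step indices internally; 1-based closed in
reports).  This is a simplified dinucleotide twist — the rotation of the
bp reference vector about the local tangent — not the full mid-frame
step-parameter algebra of helical-parameter programs; for uniform ribbons
the two coincide.

**Linking number.**  The Gauss double integral between two closed
polylines, rounded to the nearest integer; a raw value further than 0.05
from an integer emits a warning (undersampled or nearly touching curves).

**Axis extraction.**  A circular moving average of the bp centres with a
default window of one helical repeat (round(n_bp/Lk) ≈ 10–11 bp), which
removes helical wobble exactly for ideal helices.  The published
contour-averaging weightings of trajectory-analysis tools are not
reproduced; the moving average is a documented simplification.

**Lk0 calibration.**  Ordinary least squares of mean writhe versus Lk over
≥ 3 bare topoisomers; Lk0 is the root of the fitted line (the Lk at which
the relaxed circle carries no writhe).  On noiseless linear data the root
is recovered exactly; with Gaussian noise of sd 0.1 on the writhe means
the estimator is unbiased to < 0.05 turns over 200 replicates.

## Planar topoisomer construction

`build_planar_minicircle` places n_bp axis origins on a circle of radius
n_bp·rise/(2π) (rise 3.4 Å/bp by default) and distributes the imposed
twist uniformly: per-step twist = Lk·360/n_bp degrees.  The in-plane
radial frame of a planar circle is relatively parallel (twist-free), so
rotating within it by the accumulated angle gives Tw = Lk exactly and
Wr = 0 by planarity.  The reference vector starts along the radial
direction at bp 0 (any phase is equivalent by symmetry).  Strand curves
sit at ±strand_radius along the reference vector (separation angle 180° —
a symmetric ribbon rather than the minor/major-groove asymmetry of B-DNA,
which does not affect any topological quantity).  Sequence is carried as
metadata only.  Linking numbers below 1, non-integer turns, and circles
too small to discretize are rejected.

## Closed twistable-chain Monte Carlo

The generator stands in for atomistic simulation at desk scale.  A closed
chain of N beads (default 84, spacing 13.6 Å — a 336-bp circle) evolves by
Metropolis crankshaft moves: a random sub-chain is rigidly rotated about
the chord between two pivots, which preserves closure by construction.
The energy, in units of kBT,

    E = (P_b / 2ℓ) Σ θ_i²  +  (2π² P_t / L) (ΔLk − Wr)²,

uses bending persistence length P_b = 500 Å and twist persistence length
P_t = 750 Å (standard B-DNA values), ℓ the bead spacing and L the contour
length.  Twist is treated implicitly: at fixed Lk a twistable rod relaxes
its twist uniformly, leaving the harmonic writhe penalty above.  This
guarantees White's theorem for every emitted frame and keeps the sampler
cheap.  The writhe change of a move is evaluated incrementally over only
the segment pairs whose geometry changed (cross pairs between the moved
block and the rest, plus pairs touching the two boundary segments), with
a full recomputation every 2000 steps to absorb accumulation error; a
numba-compiled kernel accelerates the pair sums when available, with a
numerically identical NumPy path otherwise.  Excluded volume (hard bead
diameter, default off; 20 Å for |ΔLk| = 3 fixtures) prevents chain passage
in tight plectonemes.  Default move amplitude 0.8 rad gives acceptance
fractions of ~0.3–0.4 across ΔLk ∈ {−2…+3}.

Emitted frames carry the axis contour, its writhe, the implied twist
ΔLk − Wr, and a ribbon dressed at the integer Lk = lk_reference + ΔLk
(default reference 31).  Ribbon dressing transports a twist-free frame
around the contour, measures its closure mismatch, and adds uniform
per-step twist so the reference closes after an integer number of turns
with Tw = Lk − Wr; a per-step twist ≥ 180° cannot be represented on the
discretization and raises (aliasing guard).

At 84 beads and ~20 000 steps per topoisomer the ensembles equilibrate
well inside a minute each on one core: mean writhe is zero within error at
ΔLk = 0, strictly monotone in ΔLk with the correct sign, and the
six-topoisomer calibration recovers the planted Lk0 = 31 within 0.2.
These sizes are the package's default study conditions for tests and for
the acceptance script.

## Shape observables and apex pinning entropy

Radius of gyration is the unweighted RMS distance of contour points from
their centroid.  Polar profiles record, per frame, the distance of each
axis point to that frame's centroid, with the angular coordinate anchored
so a marked site sits at angle 0; the profile mean ± sd across frames is
the ensemble summary.  The centroid is computed from the axis contour, not
from all atoms.  Plectoneme apices are local maxima of the circularly
smoothed per-bp distance series (default smoothing window 5 bp, default
prominence threshold 0.5·sd of the series; both configurable — the
detection rule is a package choice, since apices are usually read off
structures by eye).  Apex occupancy is the fraction of frames whose
top-ranked apex lies within a circular tolerance of the site; under a
uniform null it equals (2t+1)/n_bp.

The entropy of apex pinning uses state counting, S = kB ln W, with
W = floor(f·n_bp/2) candidate apex positions (an apex can be pinned to
each bp along half the circle; the accessible fraction f models unequal
position probabilities; W is clamped to ≥ 1).  ΔS = ln(W_before/W_after)
in kB and kB·T·ΔS in kcal/mol with kB = 0.0019872 kcal/(mol·K), so that
kB·300 K = 0.59616 kcal/mol.  For a 336-bp circle this gives 168 states
and a pinning cost of 5.1 kB (3.0 kcal/mol at 300 K); at 50% and 25%
accessibility, 4.4 kB (2.6 kcal/mol) and 3.7 kB (2.2 kcal/mol).  An
optional Shannon mode, −Σ p ln p over the empirical apex histogram,
generalizes the uniform count and is bounded above by ln W (Gibbs).

## Topological domains of bridged minicircles

A bridging protein clamping ring positions (i, j) splits the circle into
two arcs (default (0, 255) on 336 bp: loops of 255 and 81 bp; the large
loop is 76% of the contour).  Loop writhe is reported two ways: *chord
closure* (each arc closed through the straight bridge segment — the
minimal stand-in for the physical protein clamp) and the exactly additive
*arc decomposition*.  Which closure published loop-writhe series use is
generally not stated, so both are emitted.  Domain independence is the
squared Pearson correlation of the two loop series computed on the raw
series (no detrending), with the slope sign of the least-squares fit:
R² ≈ 0 means isolated domains; R² ≈ 1 with negative slope means free
writhe exchange at fixed total.  Bridge contacts are user-supplied; a
convenience detector returns the closest ring pair at least 10 bp apart
under a 10 Å cutoff (note that near the bridge all four closure points
cluster within a few bp, so the detected pair may sit 1–2 bp from the
nominal contacts).

## Binding-mode classification

Hydrogen bonds require donor-heavy→acceptor distance ≤ 3.5 Å and a
donor–hydrogen–acceptor angle ≥ 120°; without hydrogens the detector falls
back to distance-only and flags it.  Bonds are capped at one per protein
residue per frame, so trajectory averages are per-residue occupancy in
[0, 1].  Frames are clustered on pairwise backbone RMSD (Kabsch
superposition per pair) with average-linkage (UPGMA) agglomeration.  The
automatic cluster count picks the **largest** k ≤ 10 whose per-cluster
mean contact fingerprints are pairwise L1-separated by ≥ 0.5 — i.e. the
finest partition in which every state still has a distinct interaction
pattern.  (Choosing the smallest such k would always return 1, since a
single cluster is vacuously distinct.)  State populations are tabulated
per topoisomer both frame-weighted (pooled) and replica-weighted (each
replica counts equally), because printed population tables are often
ambiguous about the convention; percentages are rounded to integers.

## Synthetic generators: what they do and do not emulate

* The MC sampler reproduces the coarse physics of torsionally stressed
  circles — writhe of the correct sign and roughly linear in ΔLk,
  plectoneme formation, compaction — but has no sequence effects, no
  denaturation bubbles or kinks (underwound circles in atomistic
  simulation develop defects that this harmonic model cannot), no protein,
  and implicit rather than explicit twist dynamics.
* Bridged trajectories build each loop from a solenoidally decorated
  circle whose out-of-plane chirality parameter sets its writhe through a
  precomputed monotone map; loop writhes evolve as AR(1) series either
  independently or in exact compensation (fixed planted total).  They test
  the domain statistics, not bridge energetics.
* Planted complexes realize prescribed binary H-bond patterns
  geometrically (bound donors 2.9 Å from their acceptor, unbound 8 Å,
  Gaussian jitter, random rigid motion per frame) and are regenerated if
  jitter breaks a pattern.  Distinct patterns imply distinct backbone
  geometry, so RMSD clustering can recover the planted states; real
  binding modes differ by much subtler rearrangements.

Passing tests therefore demonstrate the correctness of the *analysis*
operations and the self-consistency of the pipeline, not that the
generators reproduce atomistic ensembles.  Quantities that depend on a
specific force field or on deposited trajectories (e.g. a particular
calibrated Lk0 of 31.08, specific state-population tables, or a particular
bridged-complex R²) are inputs or qualitative patterns here, not numbers
this package claims to reproduce from first principles.

## Numerical choices and degenerate inputs

* Writhe of coincident consecutive points, intersecting strand curves,
  zero-length site ranges, windows ≥ n, empty trajectories and
  zero-variance correlation inputs all raise with specific messages.
* Tolerances: frame orthonormality 1e−6 at use, 1e−9 at construction;
  linking-number integer residual warning at 0.05; White's-theorem checks
  at 0.05 turns on MC frames (discretization, not sampling, limited).
* Apex ties break by larger prominence, then larger distance, then lower
  bp index.  All ring comparisons use circular distance.
* Reports and file outputs are 1-based closed; internal indexing is
  0-based half-open.  CSVs are comma-separated, '.' decimal, UTF-8, with
  a header and a config hash column; reruns with an unchanged config are
  byte-identical.
* All stochastic components take explicit integer seeds; identical seeds
  give bit-identical trajectories.

## Known limitations

* The MC chain has no explicit twist degree of freedom, so twist-dominated
  observables (e.g. site twist along MC trajectories) reflect the uniform
  implied twist, not local sequence-dependent variation.
* The moving-average axis extraction shrinks contours slightly (a circle
  maps to a concentric circle of marginally smaller radius); topological
  quantities are unaffected, absolute distances change at the sub-Å level
  for one-repeat windows.
* `detect_bridge` assumes a single dominant contact; multiply bridged
  circles need user-supplied contacts.
* PDB output stores pseudo-atoms (axis and strand points), not all-atom
  DNA; downstream tools expecting chemistry will not find it.
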
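# Methods

## The model

`dlptether` implements a Cα structure-based ("Gō-like") model for studying
whether a short flexible linker permits two tethered GTPase domains to
dimerise.  The biological setting is a bacterial dynamin-like-protein
heterotetramer: a rigid central dimer carries two G-domains, each joined
to it by a 9-residue random-coil linker, and catalysis requires the two
G-domains to meet head-to-head across their nucleotide-binding pockets.
The question the simulation answers is geometric and statistical — is the
tether long enough, and what interface strength populates the dimerised
state how often?

Each residue is one bead at the Cα position, mass 1.  The potential's
global minimum is the native structure:

    V = Σ k_b (r−r0)²                            bonds
      + Σ k_a (θ−θ0)²                            angles
      + Σ k_d [(1−cos Δφ) + ½(1−cos 3Δφ)]        dihedrals
      + Σ ε_c [(1+(r_ex/r)¹²)(1−e^{−(r−r0)²/2σ²}) − 1]   native contacts
      + Σ (r_ex/r)¹²                             excluded volume

with defaults `k_b = 200 ε/Å²`, `k_a = 40 ε/rad²`, `k_d = 1 ε`,
`σ = 0.5 Å`, `r_ex = 4 Å`, contact depth `ε = 1` defining the energy unit.
The Gaussian contact form makes the well depth at the native distance
exactly −ε regardless of the repulsive core.  Native contacts come from a
shadow map on atomic structures (6 Å atomic cutoff, 1 Å screening radius,
|Δi| ≥ 4 intra-chain) or from a Cα distance cutoff for bead-only models.
Interface contacts between the two G-domains are added as an extra
contact set whose depth is a tunable fraction of ε; a fraction of 0.5
("half as strong as the native interactions") is the reference condition.

Linker beads inserted by the loop builder are an entropic tether: bonds at
3.8 Å and angles at 2.0 rad with standard stiffness, no dihedral bias, no
contacts, full excluded volume.  Excluded volume is truncated exactly at
8 Å, where its value is 2.4 × 10⁻⁴ ε; this makes the Verlet-list
evaluation bit-identical to a brute-force pass and the discontinuity is
far below thermal noise.

## Dynamics

Langevin dynamics with a BAOAB splitting in reduced units (k_B = 1,
mass 1, lengths in Å): timestep 0.0005, friction 1, reduced temperature
T* = 0.92 — low enough that folded domains stay folded, high enough that
dimerisation is reversible.  With zero friction and temperature the
scheme reduces to velocity Verlet and conserves energy (checked to
relative drift < 10⁻⁴ over 10⁵ steps).  Runs are bit-reproducible for a
given seed.  The desk-scale default is 5 × 10⁶ steps with stride 1000;
multi-billion-step runs are a configuration value, not a default.

## Reaction coordinates and occupancy

Two coordinates: the centre-of-mass distance `d` between two marker
groups (nucleotide-pocket proxies; < 2 nm in the docked reference), and
`Q_int`, the fraction of interface contacts within 120% of their
reference distance.  A frame is "dimerised" when `Q_int ≥ 0.5` (default)
or, under the alternative rule reported alongside, when `d < 20 Å`; the
classification rule is configurable because the two coordinates are
plotted together but neither fixes a unique boundary.  Occupancy carries
a circular block-bootstrap 95% CI with block length twice the integrated
autocorrelation time of the indicator (frames are strongly correlated;
an i.i.d. SEM would be overconfident).  The first 10% of frames are
discarded as equilibration.  Free-energy surfaces are −T*·ln P over
binned coordinates, minimum shifted to zero, empty bins flagged rather
than capped.

`tune_interface_strength` bisects the strength factor on [0, 2], one
seeded trial per step, and accepts a factor whose occupancy CI covers the
target.  The tuned factor is a property of the system *at the stated
trial budget*; with short trials the CI is wide and the bracket
correspondingly loose.  A trial ladder that is non-monotone beyond CI
noise aborts.

## The synthetic system

The toy reproduces the statistical topology the analysis assumes — two
independently folded compact domains tethered by contact-free linkers to
a rigid central body, plus a designated inter-domain interface — at a
size where the full pipeline runs in minutes on one CPU:

* domains: 2 antiparallel ideal helices × 9 residues (21 beads each),
* central body: 2 helices × 8 residues (19 beads),
* linkers: 9 residues each (the tetramer's linker length), bonds 3.8 Å,
* interface: the 15 closest facing-helix bead pairs of the docked pose,
* ~80 beads total.

Two scale choices matter and were made for physical reasons, not fitted:

1. **Domain size.**  A bead-mass-1 domain diffuses with D = T*/(γN).  At
   the stated integration regime, 50-bead domains have first-encounter
   times far beyond any desk-scale run (no binding events in 5 × 10⁶
   steps); 21-bead domains undergo tens of reversible encounter/release
   events per run.  The mechanism being tested is equilibrium
   thermodynamics of a tethered pair, which is invariant to this purely
   kinetic rescaling.
2. **Contact density.**  With an 8 Å cutoff the two-helix domains have a
   folding temperature below 0.92 and partially unfold, violating the
   premise that T* is "low enough to prevent unfolding"; a 10 Å toy
   cutoff restores median per-domain Q_intra = 1.0.  The general
   cutoff-map default remains 8 Å.

The pipeline's default simulation start is the *minimised docked
reference*, not the separated configuration: starting separated, the
observable of interest (reversible occupancy) is gated by a single slow
first-encounter event, whereas starting docked exposes both unbinding
and rebinding within the trial budget.  The separated start is retained
for geometric contracts and longer exploratory runs.

What the toy does *not* emulate: real DLP sequence or secondary-structure
content, the atomic shadow interface of the deposited structures, crystal
environments, and solvent.  Passing the toy-scale checks shows the
machinery is correct and the tether mechanism operates as described; it
does not by itself reproduce the deposited-structure numbers, which
require the real coordinates (a download helper and the full
atomic-structure path are provided for online use).

## Geometry utilities

SASA is Shrake–Rupley point sampling (960 deterministic Fibonacci points
per atom, probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å,
hydrogens ignored) via biotite's implementation behind the package's
interface; tests compare it against an independent dense-sampling oracle.
Buried surface area is reported two-sided (SASA(A)+SASA(B)−SASA(AB))
with the one-sided half printed alongside, because published interface
areas use either convention.  Superposition is Kabsch with reflection
correction; collinear point sets are rejected rather than silently
resolved.  Hinge angles superpose two states by a reference domain and
decompose the residual transform of the moving domain into angle, axis
and screw translation.  Maximum tether reach follows the contour
arithmetic used for such estimates: rigid spans plus 3.8 Å per linker
residue (`max_reach`); the model-path variant (`path_reach`) also counts
the two junction bonds per linker so it coincides with brute-force
maximisation over linker conformations.

## Numerical choices and degenerate inputs

* Alt-locs resolve to highest occupancy, ties to first record; insertion
  codes are rejected (silent renumbering would corrupt residue-keyed
  contact maps).
* Chain breaks are flagged at non-consecutive numbering or Cα–Cα gaps
  over 4.5 Å; the loop builder inserts beads on a circular arc with
  exactly equal sub-chords ≤ 3.8 Å and refuses gaps beyond
  3.8 Å × (n+1).
* The shadow occlusion test uses the open segment between atom centres,
  so an atom at an endpoint never occludes its own contact; coincident
  beads in any pair term raise rather than propagate NaNs.
* Minimisation is steepest descent with a backtracking step, energy
  non-increasing by construction, default force tolerance 10⁻³ reduced
  units (its role is removing small clashes before dynamics).
* Degenerate occupancy series (all frames one state) collapse the CI to
  a point with a warning instead of bootstrapping noise.

## Problem sizes used by the test suite

The acceptance-level checks use 5 × 10⁶-step occupancy trials (stride
1000), 16–24 replicas of 10⁶ steps for equipartition, one 10⁷-step
high-friction run for the Boltzmann KS check, and 10⁶ steps for fold
stability — together roughly 10–15 minutes on one CPU, the package's
desk-scale working envelope.

## Known limitations

* Occupancy values at desk scale carry wide CIs; the tuned 50% strength
  factor is budget-dependent by design.
* The toy's mirror-image domain B is a legitimate Gō system but not a
  physical protein fold.
* No WHAM/MBAR reweighting: surfaces are single-ensemble histograms.
* The all-atom relaxation of the docked dimer is replaced by
  coarse-grained minimisation, adequate at the resolution the dynamics
  actually uses but not a substitute for atomic refinement.
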
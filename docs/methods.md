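# Methods

## The selection model

An amorphous molecular solid is treated as an ensemble of local
molecular environments — one molecule in one periodic snapshot,
together with its surroundings.  The experimental observable for each
assigned atomic site is a Gaussian distribution of chemical shifts
N(μ, σ²) (ppm), obtained by least-squares fitting of the solid-state
peak; inhomogeneous broadening in the amorphous state makes a single
Gaussian per site a reasonable lineshape model.  Overlapping sites
that cannot be resolved are fitted together to one Gaussian and every
member site shares the resulting (μ, σ) ("lumped" distributions).

A candidate environment with predicted shifts {δ_a} is scored per
site by the two-sided tail probability

    p_a = erfc(|δ_a − μ_a| / (σ_a √2)),

the probability that a random draw from the experimental distribution
deviates from its mean by more than the prediction does.  The
environment's p-value is the geometric mean of the p_a over the
scored sites, computed in log space with a floor of 1e−300 per factor
to keep extreme outliers finite.  The geometric mean (rather than a
product) makes p-values comparable across different numbers of scored
sites; the tail form was chosen because it is parameter-free,
monotone in the deviation, and exactly 1 at zero deviation.  The form
is isolated in `shift_probability` so an alternative (for instance a
width convolved with the shift model's own error) can be swapped in
without touching the rest of the pipeline.

Predicted shifts of equivalent protons on one carbon (CH₂/CH₃,
labels differing by an a/b suffix) are arithmetically averaged before
scoring, since fast rotation and exchange average them
experimentally; this can be disabled.

The **NMR set** is the top-N environments by p-value (stable
descending sort, ties broken by lexicographic environment id so runs
are reproducible); the **MD set** is every environment.  Selection
streams over the predictions with a bounded top-N heap, so arbitrarily
large ensembles fit in memory.

Assumptions: no large-amplitude dynamics (each environment is scored
as a static geometry); predicted-shift errors are uncorrelated across
sites; the candidate ensemble actually contains environments close to
the real solid — selection can only reweight what the ensemble
contains.

## Structure metrics

Dihedrals follow the IUPAC sign convention (cis = 0; looking from
atom 2 to atom 3, clockwise positive) and are reported in (−180,
180].  All intermolecular geometry uses the minimum-image convention;
for orthorhombic cells the rounded image is exact and is used
directly, for triclinic cells the 27 neighbour images around the
wrapped displacement are scanned.  Molecules are stored whole
(unwrapped).

A hydrogen bond is a geometric event: an acceptor atom (N or O by
default) with H⋯A ≤ 2.5 Å and a D–H⋯A angle at the hydrogen of at
least 120°; when several acceptors qualify the shortest H⋯A wins.
These thresholds are conventional values for moderate-to-strong
hydrogen bonds and are fully configurable (`HBondCriterion`).
Intramolecular acceptors are classified by atom label; intermolecular
acceptors through a user-supplied label→chemical-class map (default:
the element), since any grouping into "amines", "carbonyls" etc. is a
chemistry judgement the code should not hard-wire.

Histograms are unit-integral probability densities so sets of
different size (all environments vs the selected N) are directly
comparable.  Default bins: 10° for dihedrals (periodic, edges
symmetric about 0°, with an optional edge offset to centre a bin on
180°), 0.5 Å for distances.  A bin is *promoted* when the NMR/MD
density ratio exceeds 1.25 and *demoted* below 0.8; bins with zero MD
density are flagged undefined rather than given an infinite ratio.
2D correlations are joint densities on the same bin grids, so
marginalizing reproduces the 1D histograms exactly.

Reference conformations (the protein-bound geometry and proline
backbone statistics) are carried as annotation constants for plots
and reports only; no assertion about them is computed.

## Cluster formation energies

A cluster is a central molecule plus every molecule with at least one
atom within the cutoff (default 7 Å, inclusive) of it, each neighbour
translated to its minimum-image copy nearest the central molecule.
The cutoff must stay below half the shortest cell height or the
neighbour search is refused as ambiguous.  Three backend calls give
E(with), E(without) and E(central); the formation energy is

    ΔE = E(with) − E(without) − E(central)   (kJ/mol),

which isolates the interaction part for backends with intramolecular
terms; the alternative reading E(with) − E(without) (conformational
plus interaction energy) is exposed as `delta_env` so either can be
profiled.

Two backends ship with the package.  The *toy pairwise backend* is a
strictly intermolecular potential: 12-6 Lennard-Jones between heavy
atoms (ε = 0.4 kJ/mol, σ = 3.4 Å) plus a Gaussian donor–acceptor well
−20 kJ/mol · exp(−(r − 1.9 Å)²/(2·0.25²)) for H⋯N/O contacts, cut off
at 10 Å.  Being pairwise and intermolecular, its cluster ΔE equals
the central↔member pair sum exactly, which is the analytic oracle the
tests use.  The *file backend* reads precomputed per-cluster energies
(CSV `run_id,frame,molecule,e_with,e_without,e_central`), the route
for energies from an external quantum-chemistry code.

Energy profiles along a geometric feature report per-bin means of ΔE
referenced to the minimum bin mean of the MD reference sample (so the
MD profile's lowest bin sits at 0 and both profiles share one zero),
with the within-bin standard deviation as the spread (standard error
of the mean available via a flag).  The MD reference sample draws a
fixed number of environments per run (default 1,500) uniformly
without replacement under a seed.

## The synthetic benchmark

The generator emulates the three-region architecture of a flexible
degrader — a hydrogen-bond donor on a rigid aromatic part, a
disordered linker, an intramolecular acceptor — with a 12-atom
internal-coordinate template: hydroxyl donor O1–H1, rigid ring
C2–C3–C4–C5, linker chain C2–C7–C8–C9–N53 with four rotatable
torsions, and a terminal C50=O49 carbonyl.  Cartesian geometry is
reconstructed deterministically from the four torsions.

Torsions are drawn from a two-basin mixture.  The *closed* basin
(centres 4.95°, 43.36°, −127.06°, −17.55°, solved once from the
template so that r(H1⋯N53) = 1.90 Å with a 163° O–H⋯N angle) is
sampled with probability `bias_fraction`; the *open* basin is
all-trans (r = 6.81 Å).  Jitter is Gaussian with a 5° width,
truncated at 2.3σ, which guarantees closed-basin geometries stay
below 2.44 Å and open ones above 6.7 Å — basin membership is
therefore recomputable from the emitted geometry alone with the
default H-bond criterion, and the generator keeps no hidden state.
Molecules are rigidly rotated (uniform quaternions) and placed at
random non-overlapping positions (centres ≥ 9 Å apart) in a periodic
40 Å cubic box.

The surrogate shift model is closed-form:

    δ(H1)  = 5.0  + 8.0 · exp(−r(H1⋯N53)/1.0 Å) + ε
    δ(N53) = 250  + 15  · exp(−r(H1⋯N53)/1.0 Å) + ε
    δ(ring C) = δ0 + 3.0 · cos(τ_C2-C7-C8-C9) + ε
    δ(other)  = δ0 + ε,        ε ~ N(0, 0.2 ppm²)

so the H-bond contributes ≈1.2 ppm on H1 in the closed basin and
< 0.01 ppm in the open one — a signal-to-noise ratio of about 6,
comparable in spirit to the ppm-scale discrimination real shift
predictions provide.  "Experimental" distributions are the sample
mean and standard deviation of the surrogate shifts over a designated
subpopulation (the closed basin by default, emulating a biased
solid), with σ floored at 0.01 ppm.

Benchmark sizes are 4 runs × 50 frames × 25 molecules = 5,000
environments with a 500-environment selection (10%), a desk-scale
mirror of selecting a few thousand structures from a few hundred
thousand; the `planted_hbond` preset plants `bias_fraction` = 0.40.

The *null* preset zeroes all geometry→shift couplings and fits the
distributions to the whole ensemble.  This is deliberately stronger
than only widening the distributions: with couplings active, a single
Gaussian fitted to the bimodal whole-ensemble shift population still
favours mid-range geometries and is not a true null.  With couplings
off, selection is provably independent of structure, and NMR-set bin
counts are hypergeometric — the bound the null-control test applies.

What the generator does **not** emulate: realistic force-field
energetics or packing (placement ignores intermolecular energies),
realistic shift physics (ring currents, susceptibility,
many-body effects), conformational correlation between molecules,
and finite-temperature dynamics.  Passing the planted-recovery tests
therefore shows the *pipeline* is correct — that a real analysis
recovers the true structure still depends on the quality of the MD
ensemble and the shift predictor.

## Numerical choices

- Gaussian peak fitting: bounded least squares (trf via
  `scipy.optimize.curve_fit`), μ initialised at the window argmax,
  σ at a quarter of the window width per component, amplitude at the
  window maximum; up to 5 deterministic jittered restarts before a
  fit-failure error.
- Assignment refinement is per-site independent nearest-peak matching
  (many-to-one allowed, as lumped peaks require); default acceptance
  thresholds 1.0 ppm (¹H) and 5.0 ppm (¹³C/¹⁵N).
- Selection ties: lexicographic environment id, applied identically
  in the streamed heap and the in-memory sort.
- Histogram values exactly on the upper edge belong to the last bin;
  periodic histograms wrap values into the edge window before
  binning.
- Cluster membership at exactly the cutoff is inclusive; the
  half-cell-height check uses a 1e−9 Å tolerance.
- All randomness flows from explicit `numpy.random.default_rng`
  seeds; per-run generators are spawned from a master seed so run
  outputs are independent but jointly reproducible.

## Limitations

- The per-site tail probability ignores correlations between sites
  and any site-dependent predictor error; both would sharpen or widen
  the selection.
- Promotion thresholds (1.25/0.8) are descriptive conventions, not
  significance tests; the null control bounds spurious enrichment
  only under structure-blind selection.
- The toy energy backend has no intramolecular terms, so ΔE and
  `delta_env` coincide on it; distinguishing the two readings needs a
  backend with conformational energies.
- PDB input carries no per-atom site labels beyond atom names; use a
  label map when names do not match the labelling scheme.
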
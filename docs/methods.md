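# Methods

`budmrna` re-implements, as a tested pipeline, the computational analyses
around cell-cycle-coupled bud localization of the *CLB2* mRNA in
*S. cerevisiae*: zipcode motif discovery and synonymous destruction, a
steady-state reaction–diffusion model of bud enrichment, single-molecule
spot statistics, and time-lapse lineage analytics.  Raw imaging data are
replaced by a seeded synthetic-data module whose defaults encode the study
conditions.  This note records the models, the conventions chosen where the
methodology leaves them open, and what the synthetic data can and cannot
show.

## Zipcode search

She2-recognised elements of the *ASH1* E3 class are stem–loops with two
nested inverted-repeat stems framing an asymmetric bulge, a CGA
trinucleotide and a single unpaired cytosine at a fixed spacing.  The
search has two stages:

1. **Combinatorial scan.**  All placements of two nested stems with arm
   length ≥ 4 bp (`min_stem`) and overall extent ≤ 60 nt (`max_span`) are
   enumerated; the unpaired gaps between outer and inner stems must be
   asymmetric (|left − right| ≥ 1).  A candidate additionally needs an
   unpaired CGA and an isolated unpaired C, separated by exactly
   `cga_c_spacing` nucleotides (default 6) in the sequence.
2. **Folding filter.**  Each candidate's 80-nt window is MFE-folded at
   28 °C with ViennaRNA, with and without forcing the candidate's stem
   pairs.  A candidate survives if (i) all pairs of at least one stem are
   present in the unconstrained MFE structure and (ii) the constrained
   fold's free energy differs from the unconstrained MFE by at most 20 % of
   its magnitude (|ΔG_c − ΔG_f| ≤ 0.2·|ΔG_f|; a zero-energy window passes
   only against a zero-energy constrained fold).  Surviving candidates with
   overlapping spans are merged into a single hit reported with the union
   span, preventing near-identical stem placements from being counted
   twice.

Two conventions were genuinely open and were fixed against the one known
positive example, the printed 37-nt minimal *CLB2* element
(`AGCAGATGACTACGATATACAGTCTCGAACTCTTGCC`):

* **Pairing rule.**  G·U wobble pairs are allowed by default.  Brute-force
  enumeration shows the minimal element's outer stem contains a G·U pair,
  so a strict Watson–Crick scan cannot see it; with wobble pairing the
  element contains exactly one nested-stem candidate whose extent is the
  35-nt core — matching the element's reported length.  `--no-gu` restores
  strict pairing.
* **CGA–C spacing.**  Measured as linear sequence separation between the
  5′ base of CGA and the isolated C (|31 − 25| = 6 on the 37-mer,
  0-based).  A pairing-register convention was also evaluated and yields no
  spacing-6 combination on this element.

Only the convention was calibrated this way, never the numeric thresholds
(4 bp, 60 nt, 6 nt, 80 nt, 28 °C, 20 %), which are fixed by the method
being reproduced.

**Synonymization** destroys a hit by greedy single-codon substitution
restricted to the hit-span codons: each step applies the synonymous swap
that most reduces the number of scan-stage candidates still overlapping the
span (tie-breaks: fewest base changes, then highest codon relative
adaptiveness, so rare codons are avoided).  Driving the scan-stage count to
zero guarantees the full search reports nothing there, since scan
candidates are a superset of hits.  The codon-usage score is the mean
relative adaptiveness w = f/max f over synonyms, using bundled
*S. cerevisiae* genomic usage frequencies.  The search fails explicitly if
`max_changes` substitutions (default 12) do not suffice.

## Reaction–diffusion model of bud enrichment

Free mRNA concentration c(x, y, z) obeys, at steady state,

    0 = D ∇²c − k_d c + k_p − k_on c + k_off b
    0 = k_on c − k_off b − k_d b

with an immobile bound pool b (ribosome-bound complexes).  Defaults encode
a 240 s half-life (k_d = ln 2/240 ≈ 0.0029 s⁻¹), a 90 s bound lifetime
(k_off = 1/90 ≈ 0.011 s⁻¹) and k_on = 0.25 (k_off + k_d) ≈ 0.0035 s⁻¹,
which puts 20 % of molecules in the bound pool; the *anchored* scenario
multiplies k_on by 125 (bound fraction ≈ 97 %).  Production follows the
smooth radial step k_p(r) = k_max e^{sm}/(e^{mr} + e^{sm}) centred on the
bud, with s = 5, m = 10 and k_max fixed by normalizing the volume integral
over unbounded 3-D space to 1 (k_max ≈ 0.0019; integrating over unbounded
space, not the clipped domain, is what reproduces this value, since
1/((4/3)π·5³) ≈ 0.00191).

**Geometry.**  The mother and bud are spheres of radius 8 and 6 model
units, centres 13 apart (a small overlap keeps the domain connected).  The
bud radius exceeds the production radius s = 5 so that the normalized
production profile fits inside the domain up to an e⁻¹⁰ tail — a
prerequisite for the 1 % mass-balance check below.  `length_unit`
(default 0.3125 µm per model unit, mapping the mother onto a 2.5 µm G2
cell) converts the printed diffusion coefficients (0.1 and 0.4 µm²/s) into
model units by D/length_unit².  Because the study's actual cell volumes are
not published, enrichment levels are meaningful only comparatively: the
package reproduces the ordering anchored ≫ free_slow > free_fast (on the
defaults 0.93 / 0.50 / 0.36), not a specific percentage.

**Discretisation.**  b is eliminated algebraically
(b = k_on c/(k_off + k_d)), leaving a screened-Poisson problem
−D ∇²c + k_d(1 + k_on/(k_off + k_d)) c = k_p.  This is discretised by
7-point finite differences on a regular Cartesian grid (cell-centred,
default spacing h = 0.5) masked to the two-sphere union; zero-flux walls
arise by ghost-node mirroring (missing neighbours simply drop out of the
stencil), which makes the discrete balance k_d Σ(c+b)h³ = Σk_p h³ exact to
solver precision.  The system is solved by direct sparse LU with a fixed
node ordering, so results are deterministic.  Verified numerical
properties: grid production integrates to 1 within 1 % at the default
spacing; bud fraction changes < 2 % between h = 1.0 and h = 0.5; the
solution matches the closed-form screened-Poisson radial solution
c(r) = B e^{−r/λ}/r (B from 1-D quadrature of the source against
sinh(r/λ)r) within 5 % on a single-sphere test problem.  Nodes in the
overlap lens belong to the nearer sphere centre (tie → bud).

## Spot statistics

Cells are a mother plus optional bud ellipsoid built from 2-D outline
measurements; the z semi-axis equals the shorter in-plane semi-axis, and
the shared z origin is found by a 50-nm grid search maximizing spot
inclusion in the ellipsoid union (plateau ties resolve toward the spot
centroid, keeping the model centred).  Compartment labels use the
normalized quadratic form; points inside both ellipsoids (neck region) go
to the bud.  Colocalization computes all 3-D Euclidean mRNA–protein
distances (µm stored, nm compared; z not rescaled — a `project_2d` flag
gives the maximal-projection variant) and pairs within 250 nm; several
proteins near one mRNA still count as one translation complex.  Nascent
transcripts per transcription site are the TS intensity divided by the mean
single-molecule intensity.  Population summaries average over expressing
cells (≥ 1 mRNA) only.

## Lineage analytics

Detections in consecutive frames are matched by minimum-total-distance
bipartite assignment with dummy nodes for births and deaths; edges of 200 px
or more are forbidden.  The method description mentions both 1/distance
edge weights and a minimum-total-distance objective; these disagree, and
the stated objective (minimum total distance) is implemented, which is also
the standard formulation.  Neck-track lengths × frame interval are the
budded-phase durations (manual budding-frame overrides supported).
Parent–bud disambiguation multiplies independent factors over ordered
pairs: uniform prior, area factor a_p/(a_p + a_b), a pair-symmetric overlap
factor (o_i + o_j)/Σo (the printed form is symmetric in the pair, so it
cannot order parent vs bud and acts as pair plausibility), ×2 if the
putative parent has a fluorescent nucleus, and zero for self-pairs;
multiplicative combination is assumed.  Group comparisons use the
with-replacement bootstrap of the mean (10000 draws of 250) and a
two-sided t-test (Welch by default; pooled variance behind a flag, since
the original test's variant is not stated).

## Synthetic data

Generators are pure functions of (parameters, seed) and emulate: mature
mRNA counts per cell (Poisson, mean 10.2 as in G2 cells) with Poisson
nascent counts at one TS (mean 2.9); uniform-in-ellipsoid spot placement
with bud probability p = 0.6 (the measured G2 enrichment is about 65 %,
and ~60 % is the working value used for recovery tests); protein foci on a
fraction q = 0.25 of mRNAs at |N(0, 80 nm)| offsets truncated at 250 nm
(matching the observed ~25 % of bud mRNAs near a focus), plus uniform
background foci; time-lapse objects on a sparse grid with 2 px jitter and
neck lifetimes from truncated normals, defaults N(48.2, 8²) and
N(53.5, 8²) min at n = 602/694 (the study-scale group sizes); and random
backgrounds with the minimal zipcode implanted at a known, in-frame
position.  The duration SD (8 min) and the jitter/background levels are the
package's own choices where no value is published.

What passing tests show: the estimators recover the generating parameters
under the model's own assumptions (uniform placement, isotropic offsets,
well-separated objects).  What they cannot show: robustness to segmentation
errors, anisotropic optics, spot-detection false positives, or crowded
fields — those enter upstream of this package.  Because background foci
create chance proximity, the colocalization fraction is recovered with a
matched null simulation (same population, q = 0): q̂ = (f_obs − f_0)/(1 −
f_0).

## Problem sizes and degenerate inputs

Tests run the solver at h = 0.5–0.8 (2·10⁴–10⁴ nodes, seconds), oracle
comparisons at n = 200–1000 spots and ≤ 6 objects/frame, recovery at
500 cells and one full-scale (n ≈ 600 per group) time-lapse; statistical
power uses 100 seeded replicates of the duration draw.  Degenerate inputs
are defined rather than fatal: empty sequences and spot tables yield empty
results; a zero-energy fold window passes the energy filter only against a
zero-energy constrained fold; constant bootstrap input returns a degenerate
distribution; equal-mean zero-variance groups compare with p = 1; an
infeasible folding constraint flags the result instead of raising.

## Known limitations

The scan is intentionally lenient, so random 2-kb backgrounds typically
contain a handful of structure-filter survivors besides the implant; on
real transcripts specificity rests on the folding filter and on the
biology, and hits are predictions of She2 binding competence, not of
localization sufficiency.  The PDE model is steady-state and deterministic:
no motor transport, no transients, no single-molecule noise.  Ellipsoid
cell models ignore non-ellipsoidal shapes.  The peripheral distribution
index, image segmentation, spot detection and deconvolution are upstream
tools' responsibilities and are out of scope.
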
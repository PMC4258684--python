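# Methods

## The two-state fast-exchange model

All analyses assume the protein exchanges between one inactive and one
active conformation, fast on the chemical-shift timescale, so the observed
amide shift of residue *r* in state *s* is the population-weighted average

δ(r,s) = (1 − p_s)·δ_inact(r) + p_s·δ_act(r),

where p_s ∈ [0,1] is the activation fraction locked in by the ligand of
state *s* (saturating conditions are assumed, so p_s is a property of the
ligand). Two consequences drive everything else:

1. across states, the shifts of any two residues sensing only this
   equilibrium are affine images of each other, i.e. Pearson |r| = 1 in the
   noiseless limit (the basis of the clustering schemes);
2. after per-residue centering, all such residues span a rank-1 matrix whose
   single right-singular vector orders the states by p_s (the basis of the
   SVD reconstruction).

Residues at the binding site additionally feel an occupancy offset and
ligand-specific nearest-neighbour effects (NNEs) that break linearity, which
is what lets the state dendrograms and SVD separate binding from allosteric
clusters.

## Compounded shift and projection geometry

CCS = δH + SF·δN with SF = 0.2 by default; SF is a parameter everywhere.
Algebraically CCS = α(δH·cosβ + δN·sinβ) with α = √(1+SF²) ≈ 1.02 and
β = arctan SF ≈ 11.3°: a rotated-axis projection. Its null direction
ΔδH = −SF·ΔδN ("iso-CCS") is the degeneracy exploited by the
projection-compression fixture and removed by the per-nucleus scheme.

## Clustering choices

- Distance d = 1 − |r| by default (anti-correlated residues also share the
  equilibrium, with opposite displacement signs); a `signed` flag gives
  1 − r.
- Linkage trees come from scipy's agglomerative implementation (single and
  complete); the test suite checks merge heights against a naive O(n³)
  agglomeration. Ties are resolved by scipy's deterministic ordering.
- Clusters are cut at d = 1 − cutoff (cutoff 0.98 for SL/CL on combined
  shifts, 0.95 per nucleus for the intersection scheme) and discarded below
  `min_size = 4` — a cluster must have more than three residues before a
  functional label is meaningful.
- **State dendrograms** use complete linkage on 1 − |r| between *uncentered*
  state columns of **M** restricted to the cluster's residues. Uncentered is
  deliberate: with row-centering all state columns of a noiseless two-state
  cluster become perfectly correlated and the tree degenerates; uncentered,
  1 − r grows with (p_s − p_t)², so the deepest bipartition separates
  inhibited from active states for allosteric clusters and apo from bound
  states for binding clusters. The inter-state measure is our choice; the
  inhibited/active and apo/bound templates are checked in that order, and
  when no reverse agonist or antagonist is present the two coincide (the
  allosteric label wins) — a reverse agonist in the library is what makes
  the distinction identifiable.
- `chain_path` finds the shortest path in the |r| ≥ cutoff graph, tie-broken
  by maximal bottleneck correlation, to exhibit the chain of strong pairwise
  correlations behind a single-linkage cluster.

## SVD reconstruction

Rows of **M** are centered per residue; scores are U·S, loadings V, with
component signs fixed so the apo loading is ≤ 0. A component is labelled
allosteric when its loadings place every inhibited state on one side of
every active state, binding when apo sits outside the loading range of the
bound states.

In CHESCA-CL/-I the SVD is computed on the union of residues of the
allosteric-classified complete-linkage clusters, not the full matrix: the
allosteric and binding response patterns are far from orthogonal (both
contrast apo-like with bound-like states), so a full-matrix PC1 is a mixture
and even noiseless allosteric residues would fail an axis-alignment test.
On the candidate subset the two-state model is exactly rank 1 and "the
sub-clusters share one component" becomes a clean criterion.

A residue is *aligned* when |score_ortho| ≤ tolerance·|score_main| (default
tolerance 0.1) and |score_main| is at least 10% of the largest score; the
floor keeps unresponsive residues, whose tiny scores trivially pass the
ratio, out of the set, at the cost of also flooring genuinely weak
responders. A cluster therefore qualifies for reconstruction when at least
`alignment_fraction` (default 0.5) of its members are aligned, rather than
all of them — one marginal member should not veto an otherwise coherent
cluster. `require_alignment=False` switches to the state-dendrogram label
alone.

## CHESPA conventions

Vectors live in the scaled plane (δH, SF·δN) with the same SF as the CCS,
so CHESCA and CHESPA share one geometry. X = A·B/|B|² is the standard
projection definition of fractional activation; Δδ_comb is the Euclidean
norm |A|. Undefined values (|A| = 0 or |B| = 0) are NaN, never 0.

Sign-outlier flagging inside a cluster takes the majority X sign (≥ 3
defined majority values required), forms the mean ± SD band over the
majority values, and flags opposite-sign members that lie outside the band
*and* exceed the band SD in magnitude. The last guard treats opposite-sign
values close to zero as noise rather than outliers. Trajectory
non-linearity is flagged at |cosθ| < 0.9 by default.

## Synthetic study conditions

Defaults emulate a five-state analog library: apo (p = 0.2), a reverse
agonist (0.1), a partial agonist (0.8) and two agonists (0.95, 1.0); the
true activation fractions of such analogs are not known numerically, so
these are qualitative stand-ins chosen once. 60 residues: 30 allosteric,
15 binding-only, 15 unresponsive. Random-coil positions δH ∈ [6.5, 10],
δN ∈ [103, 133] ppm; inactive→active displacements 0.02–0.15 ppm (¹H) and
0.2–1.5 ppm (¹⁵N) with independent random signs; binding offsets on the
same scale; NNE σ = 0.005/0.025 ppm (¹H/¹⁵N) applied to binding residues in
bound states; measurement noise σ = 0.002 ppm ¹H and 0.01 ppm ¹⁵N, i.e.
0.002 ppm per nucleus on the ¹H-equivalent CCS scale. All randomness flows
from one seeded generator; the seed is recorded in the ground truth.

What the generator does *not* emulate: intermediate/slow exchange
lineshapes, peak overlap and misassignment, exchange broadening that makes
peaks vanish in some states, temperature/pH drifts, and correlated (rather
than independent) noise between nuclei. Passing benchmarks therefore show
the algorithms behave correctly under the stated model, not that real
spectra meet the model.

The two targeted fixtures assert their own calibration before returning
data (a fixture violating its constraints raises, it is never silently
emitted):

- **chaining** — six residues whose centered state profiles rotate along the
  geodesic between a binding-like pattern (analog midway between apo and
  actives) and an allosteric one (apo between analog and actives):
  consecutive |r| ≈ 0.99, endpoint |r| ≈ 0.84–0.87, no non-consecutive pair
  above the 0.98 cutoff, so the chain path is exactly the construction
  order.
- **projection compression** — eight noisy allosteric residues (CCS
  displacement kept ≥ 0.1 ppm) plus one residue whose reverse-agonist peak
  is displaced along the iso-CCS direction until its CHESPA cosθ reaches
  0.5 with a positive X (solved by 1-D root finding); its combined-shift
  profile stays collinear with the allosteric block (|r| ≥ 0.98) while at
  least one single-nucleus profile decorrelates (< 0.95).

## Workflow escalation

`run_toolset` runs CHESCA-CL first; CHESPA on the reconstructed cluster
escalates to CHESCA-I when any sign outlier or non-collinear member is
flagged, and to CHESCA-SL when any unclustered residue carries a
majority-sign X inside the band (thresholds `max_outliers`/`max_missed`,
default 0). Without valid CHESPA states the workflow degrades to CHESCA-CL
with a warning.

## Structural comparison

`superpose` is a least-squares rigid fit (SVD-based) over the common
backbone N/CA/C/O atoms by default — the atom selection and fit region are
configurable since different conventions exist; `per_residue_rmsd` averages
over the selected atoms per residue; thresholding supports absolute (1 Å)
and fraction-of-max modes. `coordinate_rmsd` computes the unfitted RMSD: the
closed form d/√N for a single displaced atom holds only without refitting
(the fitted value is strictly smaller), so the two operations are kept
separate. Altlocs: first wins; occupancies are not weighted.

## Numerical notes and limitations

- Zero-variance residues are excluded from **R** (with a warning) using a
  relative tolerance of 1e-10·(1+|mean|), since the standard deviation of a
  constant profile computes to ~eps·|mean|, not exactly 0.
- Correlations are clipped to [−1, 1] and symmetrized before clustering;
  cluster cuts add 1e-12 to the distance threshold so |r| exactly at the
  cutoff is kept.
- Benchmarks in the tests and the acceptance script use 60-residue,
  5-state datasets and 20 seeds — sizes at which every property of interest
  is already expressed and the whole suite runs in seconds.
- The stringency ordering I ⊆ CL ⊆ SL holds on the canonical fixtures but is
  not a theorem under noise: a residue whose ¹H and ¹⁵N responses nearly
  cancel in the CCS (iso-CCS direction) can be kept by the per-nucleus
  scheme yet lost by the combined-shift schemes — the mirror image of the
  projection-compression false positive.
- CHESCA needs ≥ 4 states (correlations over fewer columns are not
  meaningful); CHESPA needs the 3 named states only. Residues missing in
  any state are dropped with a warning before covariance analysis
  (`drop_incomplete`); how exchange-broadened peaks should be treated is an
  open question of the method itself, and dropping is our policy.
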
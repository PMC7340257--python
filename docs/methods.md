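# Methods

## The screening problem

An equilibrium-dialysis metabolite-interaction screen (MIDAS-style)
dialyses a purified target protein against pooled metabolite standards and
measures, by flow-injection mass spectrometry (FIA-MS), each metabolite's
abundance on the protein side and the metabolite side of the dialysis
membrane.  At equilibrium a non-interacting metabolite distributes evenly;
binding enriches it in the protein chamber, enzymatic consumption depletes
it.  The reference design screens 412 metabolites in four pools at 50 µM,
in dialysis triplicate, with each dialysate injected in technical
triplicate, giving per-injection area-under-the-curve (AUC) intensities.

## Quantification (`midaskit.quant`)

For each sample the technical injections are averaged (arithmetic mean of
AUCs).  The per-replicate readout is

    log2 FC = log2( max(A_protein, floor) / max(A_metabolite, floor) )

with a scale-free floor of 1e-6 x the global median AUC guarding zeros
(both chambers under the floor give exactly 0, flagged).  Negative values
indicate depletion (consumption), positive values enrichment (binding).
The three replicate fold changes are averaged into one summary per
protein-metabolite pair.

### Outlier rejection

Gross corruption (failed injections, carry-over spikes) is rejected with a
leave-one-out z score at a cutoff of 5, removing at most one value per
triplicate.  Two numerical points matter:

* A conventional `(x - mean)/sd` over three points is bounded by ~1.15, so
  a cutoff of 5 can only ever trigger in the leave-one-out form
  `|x_i - mean(others)| / sd(others)`.
* The raw leave-one-out statistic over a triplicate is a ratio of normals
  with Cauchy-like tails: at a cutoff of 5 it would reject ~40% of
  perfectly clean triplicates.  The pipeline therefore floors the
  denominator at a robust screen-wide scale (the median triplicate SD).
  With that floor, a clean observation needs to sit ~5 population SDs from
  its companions to be rejected — on clean synthetic screens well under
  0.1% of observations are removed, while magnitude-six (log2) corruption
  is essentially always caught.

Rejection runs at both levels of the design: within each technical
injection triplet (on log2 AUC, before averaging) and across the three
per-replicate fold changes of a pair.  The injection-level pass is what
catches two independent corrupt injections hitting the same pair, which a
single fold-change-level pass (limited to one removal) cannot.

Pairs must keep at least two replicate fold changes; otherwise the run
aborts naming the pair.

## Screen statistics (`midaskit.stats`)

**Principal-component correction.**  Fold-change variation shared across
protein screens (batch, pool and drift effects) is not specific to any
pair.  The protein x metabolite matrix of mean fold changes is
column-centred (per metabolite), the rank-3 truncated SVD is subtracted,
and the column means are added back ("corrected fold change").  Restoring
column means keeps metabolite-level offsets for the null model to absorb.
Missing cells are imputed to the column mean for the decomposition and
restored to missing afterwards.  On screens generated at the default
conditions the three components carry ~75% of the observed variance.

**Robust no-signal model.**  Each metabolite's null across proteins is
summarised by its median and a spread extrapolated from the quartiles,
`(Q75 - Q25) / (2 * Phi^-1(0.75)) = IQR / 1.34898`, with quantiles by
linear interpolation between order statistics (the spread depends on this
convention, hence it is pinned).  Quartiles are insensitive to the genuine
interactions sitting in the tails, which is the point of the construction.
Metabolites with zero IQR or fewer than 8 screens are excluded with a
warning.

**Significance.**  z = (value - median)/spread, p = two-sided normal tail,
and Storey q values computed within one protein screen's metabolite family
(412 tests per target).  pi0 is estimated as `#{p > 0.5} / (m/2)` capped
at 1; a lambda-grid cubic-smoother variant is available behind a flag.
With pi0 forced to 1 the q values reduce exactly to Benjamini-Hochberg.  A
pair is called significant when p < 0.05 and q < 0.1; results are ranked
by |z|.

**Tail calibration at finite screen counts.**  The quantile-based spread
carries ~15% relative estimation noise at 60 screens, which visibly
inflates the extreme normal tail (a nominal 1e-5 two-sided tail is reached
several times too often).  This is intrinsic to estimating a null spread
from 60 robust order statistics, and it shrinks as the cumulative screen
count grows.  Consequently the per-family false-positive rate of the
q < 0.1 rule on pure-null screens sits near the nominal level only in the
aggregate sense that q-filtering suppresses > 85% of the nominal p < 0.05
noise calls; individual families reject more often than a perfectly
calibrated null would.  Users screening small panels should read marginal
calls accordingly.

## Synthetic screens (`midaskit.synth`)

The generator emulates the statistical structure of a pooled FIA-MS
dialysis screen:

| parameter | default | rationale |
| --- | --- | --- |
| proteins x metabolites | 60 x 412 | reference library size, panel of screens |
| dialysis x technical reps | 3 x 3 | reference design |
| baselines | log-uniform over 3 decades | FIA-MS dynamic range; exercises the abundance floor |
| replicate noise SD | 0.2 log2 units | ~15% CV between dialysis replicates |
| technical noise SD | 0.2 log2 units | ~15% CV between injections |
| latent structure | rank 3, 75% of fold-change variance | shared systematic variation for the PC correction to remove |
| outliers | rate 0.001, magnitude 6 log2 units | rare gross injection failures |

The latent term (random scores x loadings) is injected on the protein
chamber only, so it contaminates fold changes exactly as shared systematic
variation would; its mixing coefficient is solved by a 1-D root find so
the latent share of pair-mean fold-change variance hits the target.  Under
these defaults the per-pair null spread is ~0.19 log2 units, so a -0.28
effect lands near p ~ 0.15 (not callable) while -1.17 sits at |z| ~ 6 —
reproducing the qualitative split between the weak and strong depletions
the packaged DHTKD1-like preset encodes (-1.17, -0.28, -0.25, +0.92,
+1.27; one spiked target among 60 null proteins).

What the generator does *not* emulate: pool-specific ionisation chemistry,
isotopologue interference, metabolite-specific noise heterogeneity, and
chamber-correlated drift.  Passing tests therefore demonstrate the
correctness and calibration of the scoring machinery under a realistic
noise model, not instrument-level fidelity.

Everything is driven by a single seed; identical seed and configuration
give byte-identical outputs.

### Degeneracies at zero noise

The zero-noise preset switches off noise, outliers *and* the latent
structure, and is scored through the identity (k = 0) correction path:

* a spike-only fold-change matrix is rank 1, so removing three principal
  components would annihilate the very signal being checked, and
* every null metabolite has zero IQR, so the no-signal model is undefined.

The noiseless check therefore validates the quantification path exactly
(recovery to 1e-9), while calling behaviour (the -1.17 spike as the
top-|z| significant depletion) is checked at the preset's default noise.

## Auxiliary fits (`midaskit.biophys`)

**Hanes-Woolf kinetics.**  [S]/v is regressed on [S]; Vmax = 1/slope,
Km = intercept/slope.  The linearisation is exact on noiseless saturation
data for any positive (Km, Vmax).  Points with v <= 0 are excluded with a
warning; a non-positive slope or negative intercept is reported as "no
saturating fit".  An optional helper converts DCPIP absorbance slopes to
specific activity; its extinction coefficient default is an explicitly
flagged placeholder, since assay calibration is instrument-specific.  The
packaged substrate series uses seven distinct concentrations
(0.01-2 mM): the assay's published series lists "0.1" twice, which is
treated as a typographical duplicate of 0.01.

**Boltzmann melt fits.**  F(T) = F_low + (F_high - F_low)/(1 +
exp((Tm - T)/w)), fitted by nonlinear least squares on the window from the
curve's global minimum to its global maximum — the standard trim that
excludes the post-maximum aggregation decay of dye-based melts.  Tm must
land inside the window.  Variant destabilisation is the difference of two
fitted midpoints.

**Guinier analysis.**  ln I is regressed on q^2 inside the low-angle
window, iterating window selection until q*Rg <= 1.3 is stable;
Rg = sqrt(-3 x slope), I0 = exp(intercept).  When the window holds enough
points a q^4 term is included and the Guinier slope taken from the q^2
coefficient: a straight line fitted to a solid sphere over the full
q*Rg <= 1.3 window is biased ~2% high in Rg by the form factor's
curvature, while the curvature-corrected slope recovers the sphere Rg to
~0.1% and remains exact on a Gaussian profile.  If the corrected slope
leaves the Guinier regime (noise-dominated windows) the plain linear slope
is used; a non-negative linear slope raises "no Guinier regime".

**Stoichiometry.**  Candidate megacomplex models fix the acyltransferase
(E2) core at 24 protomers (eight trimers) and count decarboxylase (E1)
dimers 0-12; models are ranked by |total mass - target|, ties toward
fewer E1 copies.  Protomer masses can be computed from construct
sequences (average masses, matching solution-scattering-scale
comparisons); the packaged `NOMINAL_*` constants are synthetic stand-in
masses (97 kDa E1, 41 kDa E2) for the catalytic constructs, to be replaced
by `mass_from_sequence`/`masses_from_fasta` output when real sequences are
at hand.

## Problem sizes and tolerances

The test suite and the acceptance script run full-size screens
(60-61 proteins x 412 metabolites, ~450k injections each): 20 such screens
for the null-calibration checks, 100 replicates for noisy melt-fit
recovery, 200 for noisy kinetics.  Exact linear-algebra identities are
checked at 1e-8 to 1e-12; Monte-Carlo quantities at 2-10% as appropriate
to their sampling noise.
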
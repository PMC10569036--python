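# Methods

## The measurement model

`turbofp` computes solvent–water partition ratios from non-targeted
LC-MS peak areas. In a shake-flask experiment, a compound mixture is
spiked into water, equilibrated against an organic solvent, and only the
aqueous phase is injected. Two samples matter per solvent system: the
**partition sample** yields the analyte's post-equilibration water-phase
area `A_W`, and the **water control** (spiked water saturated with the
same solvent, never equilibrated) yields the total-analyte area `A_T`.
The solvent-phase area is obtained by difference, and the partition
ratio follows from the two areas and the phase volumes:

    A_S  = A_T − A_W
    K_SW = (A_S / A_W) · (V_W / V_S)

Because both areas are measured for the same analyte in the same
aqueous matrix, the relative response factor cancels in the ratio, so
no calibration is needed. The volume term corrects for the replicate
design (solvent:water 1:1, 2:1 and 0.5:1 for replicates 1–3); without
it, replicate log values would disagree by `log10` of the volume ratio.
The correction is switchable off (`volume_correction=False`) for strict
comparison with workflows that use the uncorrected area ratio.

Assumptions: areas are within the instrument's linear response range,
the analyte is at equilibrium, and ionized species remain in the
aqueous phase. When the third assumption is the only one violated, the
quantity actually measured is the distribution ratio
`D_SW = K_SW · f_u`, with `f_u` the un-ionized aqueous fraction at the
working pH — see *Standardization* below for why this does not matter
after z-scoring.

`A_S ≤ 0` (compound fully retained in water, or noise exceeding the
true difference) is not an error: the solvent is marked **missing** and
the compound is routed to read-across imputation. Likewise a water area
below the blank threshold counts as undetected, not as a tiny
denominator.

Aggregation order: duplicate injections are averaged in area space
(they estimate the same concentration), replicates in log space (they
have different volume ratios, comparable only after the volume-corrected
log transform).

## Feature matching and blank filtering

Features are matched to candidate compounds by neutral monoisotopic
mass after correcting the observed m/z for the configured adduct
([M+H]⁺ subtracts 1.007276 Da, [M−H]⁻ adds it). The ppm error uses the
theoretical mass as denominator, since matching is against known
candidates. Default windows: 10 ppm (QTOF), 5 ppm (Orbitrap). All
candidates inside the window are kept; ambiguity is resolved downstream
(fingerprint assembly takes the highest-area feature per compound and
warns). The comparison is inclusive at the boundary, with a 10⁻⁹ ppm
guard so that a feature at exactly the tolerance is not dropped by
floating-point rounding.

The blank filter retains a feature when its water-control area reaches
at least 1.3× the mean blank area (inclusive ≥) in any replicate; a
zero-blank feature is always retained, keeping the rule division-free.
The same reference-vs-blank rule is applied to both instrument
platforms.

## Read-across imputation

A missing `log K_SW` is predicted from three other solvents via

    K_target = a·K₁ + b·K₂ + d·K₃ + c

fitted by OLS on the complete-case rows of a reference database.
Predictor triplets are drawn uniformly without replacement from the
compound's *observed* solvents (sampling from unobserved ones would
make the prediction inputs themselves missing); 100 independent
iterations are averaged, and triplets may repeat across iterations —
with few observed solvents the pool is small and repetition is
unavoidable. Rank-deficient triplet designs are discarded and
resampled, up to 10× the iteration count. Fits are cached per
(target, triplet) pair, which is equivalent to refitting per iteration
but deterministic and cheaper. Compounds with fewer than 3 observed
solvents are excluded with a logged reason: the downstream model needs
the full panel and cannot be fed less.

The physical justification is that solvent–water partitioning is
governed by a handful of solute descriptors (LSER-style), so any three
generic solvents span the information needed for a fourth. The
synthetic generator encodes this literally (rank-3 latent structure),
which makes imputation *exact* on clean synthetic databases — the
oracle used in tests. One caveat carried by the real design: for an
ionizable compound the observed entries are `log D`, while the database
is `log K`; the per-compound offset `log10(f_u)` propagates through the
regression scaled by `(a+b+d−1)`, so imputed entries of strongly
ionized compounds carry a bias the measured entries do not. This is
inherent to imputing distribution ratios from a neutral-compound
database and is visible in the recovery experiments.

## Standardization and fingerprint comparison

Each compound's fingerprint (the vector of `log K_SW` over the declared
panel, default 10 solvents) is z-scored **across the solvent axis**
using the population (n) variance. Since `f_u` is a property of the
aqueous phase only, `log D − log K = log10(f_u)` is the same additive
offset in every solvent, and the per-compound z-score removes it
exactly: standardized D fingerprints equal standardized K fingerprints.
This is the property that lets a model trained on theoretical K values
consume experimental D measurements, and it fixes the comparison
statistics too — on standardized pairs the OLS intercept is exactly 0
and the slope equals the Pearson correlation. The scaler axis matters:
z-scoring per solvent across compounds would *not* cancel the offset.

Comparisons (observed vs theoretical fingerprints) report R² (squared
Pearson r), mean absolute difference, slope and intercept over the
pairwise-complete solvents, requiring at least 3. Cross-platform
selection keeps compounds with R² ≥ 0.8 (inclusive) between the two
instruments' fingerprints. A zero-variance fingerprint cannot be
standardized and raises an error naming the compound.

The anchored inference `log D_target = log K_target +
(log D_anchor − log K_anchor)` follows from the same offset algebra:
one measured distribution ratio at a given pH transfers to every other
solvent system whose K is known.

## Fragment priors

Molecular formulas rarely identify structures, but known isomers are
not equally plausible: each carries a "data sources" count (how many
curated databases report it). Weights are computed per formula by
**dividing by the maximum** count (not min–max: min–max would assign
weight zero to the least-referenced isomer and delete a real structure
from the prior; min–max remains available behind a flag). All-zero
counts fall back to uniform weight 1. The prior is the weighted sum of
the isomers' substructure counts — linear in the counts, monotone in
the popularity, permutation-invariant.

For real structures the substructure counts come from the RDKit
fragment descriptors (`fr_*` functions); for synthetic compounds from
the generator's ground truth.

## The substructure-count network

Inputs per compound: the standardized 10-solvent fingerprint, the
monoisotopic mass, the molecular formula encoded as counts over the
fixed element alphabet {C,H,N,O,S,P,F,Cl,Br,I} (elements outside the
alphabet are rejected at validation), and the formula's fragment prior.
All input columns are z-scored with training-set statistics stored on
the model; constant columns get unit scale. In cross-validation the
scaling is refit per fold to avoid leakage.

Architecture: input → 10 dense ReLU layers of 500 units → dropout →
1 dense layer of 500 units with exponential activation → linear output.
Training minimizes the mean absolute error with Adamax at step 0.001
for 200 epochs; evaluation uses an 80/20 shuffle-split 5-fold
cross-validation with per-fragment Pearson R² and MAE on the held-out
portions. Choices the protocol leaves open, fixed here: dropout rate
0.2 placed after the tenth ReLU layer; linear output activation with a
clamp at 0 at inference (the exponential penultimate layer already
biases the outputs positive); both configurable. The exponential
layer's weights are initialized at 10× smaller scale than the He
default so its activations start near `exp(0) = 1` rather than
saturating, and its argument is clamped at ±30 (gradient zeroed where
clamped) to keep activations finite.

The network runs directly on numpy in float32 with minibatch (512)
backpropagation; at this size (~2.6 M parameters) a framework would add
nothing but weight. Determinism: a single integer seed fixes
initialization, batch order and dropout masks, so identical seeds give
bit-identical models.

Predictions are non-negative decimals and are deliberately **not
rounded**: 0.3 benzene rings means "probably none", and rounding before
computing similarity metrics discards exactly the graded information
the model provides.

## The synthetic-data generator

The generator emulates the full chain so each stage can be tested
against exact ground truth:

* **Compounds** — small-integer substructure counts (binomial, max 4 by
  default) over a 12-entry catalog, formulas assembled from
  per-fragment element contributions on an alkyl skeleton, masses
  deterministic from the formula. Masses are spread until all pairwise
  gaps exceed 25 ppm, as a curated, mass-resolvable mixture would be —
  otherwise mass matching is ambiguous by construction.
* **Fingerprints** — three latent solute descriptors per compound, a
  linear function of its fragment counts plus Gaussian noise
  (`latent_noise_sd`, default 0.3), scaled to unit variance; each
  solvent's log K is an exact linear map of the latents plus an
  intercept. Solvent loadings are built mainly as between-solvent
  contrasts with a small shared hydrophobicity component, and
  intercepts are drawn near 0.8 ± 0.3 log units, which places the bulk
  of the panel inside the window where both phases keep detectable
  signal at the default spike level — the regime the shake-flask design
  targets. The rank-3 structure makes read-across imputation exact by
  construction, which is what the imputation oracle tests rely on.
* **Ionization** — a configurable fraction of compounds (default 0.3)
  get `f_u` drawn from [0.05, 1]; `log D = log K + log10(f_u)`.
* **Rendering** — water-control and partition areas follow the
  two-phase mass balance at the replicate's volume ratio
  (`C_W = N0/(V_W + D·V_S)`, control `C0 = N0/V_W`), scaled by a
  per-compound response factor (log-uniform over one decade — it must
  cancel in the area ratio, and tests verify it does), multiplied by
  lognormal noise (default 5% relative), passed through the configured
  response curve, floored at the blank level, with optional detection
  dropout; triplicate experiments and duplicate injections are emitted
  along with blank samples.
* **Saturation** — the optional response `a ↦ L/(1+(L/a)^s)` is a
  monotone sigmoid (in log-area) saturating at level `L`, set at a
  quantile (default 0.6) of the noiseless areas. It emulates a narrow
  intrascan dynamic range: areas in the upper tail compress, the
  A_T − A_W difference distorts, and recovered ratios degrade — the
  mechanism invoked to explain why a platform with a narrower linear
  range yields worse fingerprints and worse structure predictions.
* **Isomer metadata** — each compound is one isomer of its formula,
  with up to 3 decoy isomers whose counts are perturbed by ±1 and
  geometric data-sources counts (the true structure biased to be the
  best-known). This keeps the fragment priors informative but distinct
  from the truth.

What the generator does **not** emulate: chromatography (retention
times are decorative), isotope patterns, co-elution and matrix effects,
correlated noise between samples, and real LSER chemistry (the latent
maps are random, not fitted descriptor systems). Passing recovery tests
therefore demonstrates the pipeline's arithmetic and statistical
machinery, not the field accuracy of partition-based structure
elucidation on real extracts.

## Numerical choices and degenerate inputs

* Missingness is NaN end to end; it never enters means or regressions.
* `A_T − A_W` suffers catastrophic cancellation when `D·V_S/V_W` is far
  below the noise floor; recovered values at the extremes of the
  dynamic range are correspondingly less exact (the noiseless
  end-to-end identity is asserted at 10⁻⁹ rather than machine
  precision for this reason).
* OLS fits use `numpy.linalg.lstsq` with an explicit rank check;
  collinear triplets raise and are resampled.
* Population variance everywhere a z-score is taken.
* Ties in the multi-feature ambiguity resolution go to the
  highest-total-area feature.

## Problem sizes

The recovery experiments run at the sizes the checks are defined on:
200 compounds × 10 solvents for pipeline recovery, 2,000 compounds for
model recovery with 2 evaluation folds in the acceptance run (5-fold
CV remains the API default and the protocol used by `turbofp train`),
and 100-epoch training for the shuffled-target null, whose expectation
does not depend on training length. With larger databases and longer
training the held-out errors only improve; the reported numbers are
conservative in that sense.

## Known limitations

* Imputed entries of strongly ionized compounds inherit the
  `(a+b+d−1)·log10(f_u)` bias discussed above.
* The pipeline consumes aligned feature tables; peak picking, alignment
  and adduct/isotope annotation are upstream concerns.
* A single adduct per ionization mode is assumed; multi-adduct
  reconciliation is out of scope.
* Predicted fragment vectors are not chained into candidate-structure
  retrieval; they are evidence for downstream identification, not
  identifications.
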
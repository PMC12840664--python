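# Methods

## Model and procedure

The pipeline treats a multi-condition expression study as a 4-mode tensor
`x_ijkm` — gene, condition (HC/SD/RS), replicate, hour — built from a
genes × samples matrix and a design map.  Three modeling commitments
define the method:

1. **Zero-fill for missing cells.**  Not every (condition, replicate,
   hour) combination is measured; unmeasured cells are set to zero and
   flagged in an observation mask.  Zeros participate in the
   decomposition; this keeps a single dense HOSVD code path and follows
   common practice for highly incomplete multi-way omics arrays.  The
   consequences for interpretation are discussed under *Known
   limitations*.
2. **Per-slice standardization.**  Each observed slice is centered and
   scaled across genes to mean 0 and sum of squares N.  This removes
   sample-level location/scale (units, depth) but deliberately does
   *not* remove per-gene baselines: a gene's overall expression level
   survives standardization and concentrates in the leading components,
   as it does in real data.
3. **Gaussian null for gene scores.**  Gene selection treats the chosen
   gene-mode singular value vector `u_ℓ1i` as Gaussian for null genes;
   p-values are the χ²₁ survival function of `(u/σ)²`, identical to the
   two-sided Gaussian tail `2(1 − Φ(|u|/σ))` (enforced by test to 1e-12).

HOSVD is computed per mode as the left singular vectors of the mode-n
unfolding (mode on rows, remaining modes ascending on columns), economy
size on the gene mode (rank `min(N, J·K·M)` — higher columns have zero
singular value and are never scanned).  The core is the tensor contracted
with all transposed factors, so reconstruction is exact and core energy
equals data energy.

## Component selection

* **Replicate and hour components** (`ℓ3`, `ℓ4`): the most constant
  column of each factor, measured by `|Σ_k u_k| / (√K‖u‖)` (1 for a flat
  vector, 0 for one summing to zero); ties to the smaller index.
  Expression should not depend on the replicate, and no time dependence
  is imposed a priori, so the flat component is preferred for both.
* **Condition components** (`ℓ2`): each 3-vector over (HC, SD, RS) is
  scaled to unit RMS and classified with two thresholds: δ = 0.3 (how
  large a deviation counts as "altered") and θ = 0.5 (how close RS must
  be to HC or SD to count as recovered / not recovered).  Writing
  `dSD = u_SD − u_HC`, `dRS = u_RS − u_HC`: *constant* if no entry
  deviates from the mean by more than δ; else, when `|dSD| > δ`:
  *recovered* if `|dRS| ≤ θ|dSD|`, *not recovered* if
  `|u_RS − u_SD| ≤ θ|dSD|`, *overshoot* if `dRS` exceeds `θ|dSD|` on the
  opposite side of baseline from `dSD`; anything else is *other*.  The
  rules use only relative deviations, so labels are invariant to global
  sign flips and rescaling.  δ and θ quantify what would otherwise be a
  judgment by eye; the defaults reproduce the qualitative shapes the
  classification is meant to capture and are configurable.
  Components whose entries all share one strict sign are excluded before
  classification: a vector that never crosses the zero baseline contrasts
  nothing and, under zero-fill with unbalanced occupancy, the leading
  condition component is exactly such a one-signed, occupancy-weighted
  overall-level direction.  Columns orthogonal to a one-signed column
  necessarily change sign, so only baseline-like components are dropped.
* **Gene component** (`ℓ1`): for fixed (ℓ2, ℓ3, ℓ4), the `ℓ1 ≤ 10`
  (configurable) maximizing `|G(ℓ1, ℓ2, ℓ3, ℓ4)|`; ties to the smaller
  index.  Component indices are 1-based everywhere user-facing.

## σ calibration and gene selection

Estimating σ from all of `u` inflates it — outliers about to be selected
contribute — which weakens selection.  The calibration scans 100
log-spaced candidates spanning `[0.1·s, 10·s]` with `s = sd(u)` (a decade
each side brackets both the inflated and deflated regimes; outliers at
10σ with 5% mass inflate `s` by ≈ 2.4×, well inside).  Per candidate:
compute p-values, BH-adjust, drop genes with adjusted P < α (α = 0.01),
histogram `1 − P` of the rest into S = 100 equal-width bins on [0, 1],
and record the population standard deviation of the bin counts.  If the
candidate matches the true null scale, the retained `1 − P` are uniform
and the histogram flat; σ* is the argmin, ties to the smaller (more
conservative) σ.  A candidate retaining nothing gets infinite flatness.
S = 100 is a conventional bin count for 10⁴–10⁵ values on [0, 1]; both S
and the grid are configurable.  Final selection recomputes P at σ*,
BH-adjusts, and keeps adjusted P < α.  The BH step-up itself is
delegated to statsmodels and checked in the tests against a brute-force
double-loop oracle.

## Synthetic data

The generator emulates the study conditions the analysis assumes: the
bundled 42-sample design (3 × 5 × 5 grid, 42 cells observed; the
three-replicate groups occupy slots 2–4), per-gene baselines
N(8, 2²) (a log2-expression-like spread; slice standardization makes the
pipeline insensitive to the units), i.i.d. Gaussian noise with
`noise_sd = 1`, and a small planted fraction of genes carrying condition
offsets in noise-SD units — (0, ±e, ±e) for *not recovered*,
(0, ±e, ∓e) for *overshoot*, (0, ±e, 0) for *recovered* — constant
across replicates and hours (the flat hour component is the default
assumption; an `hour_modulation` hook exists but is off), with the sign
drawn per gene.  All randomness flows from one seed.  Default effect
size in the planted studies used by the acceptance script is e = 3 with
5% of genes per pattern, at 20 000 genes.

What it does not emulate: library-size or batch effects (removed
upstream in real pipelines), gene–gene correlation, count-distribution
mean–variance coupling, and hour-dependent effect shapes.  Passing the
planted-recovery tests therefore demonstrates the mechanics of the
selection — not robustness to those real-data features.  A Student-t
noise option (`noise_df`) exists as an explicitly non-default stress
knob.

Scoring against truth: sensitivity is the selected fraction of the
genes planted with the component's own pattern; only *null* genes count
toward the false-discovery proportion.  Under the unbalanced design the
two pattern subspaces are not orthogonal in sample space, so each
component's list legitimately contains some genes of the other planted
pattern — the two lists are overlapping by construction, which is also
what the method reports on real data.

## Numerical choices

* Factor sign indeterminacy is fixed by flipping each column so its
  largest-magnitude entry is positive (ties to the first), core
  recomputed afterwards; runs are bit-reproducible.
* Standardization uses `(x − mean)/rms` with `rms = √(Σ(x − mean)²/N)`,
  satisfying the sum-of-squares-N constraint exactly; a constant
  observed slice is an error (the constraint is unsatisfiable), and
  all-zero unobserved slices are skipped.
* Flatness uses the population (divide-by-S) standard deviation.
* Degenerate inputs error loudly: duplicate gene IDs, non-numeric cells
  (named by gene and sample), samples mapped to the same cell, zero
  condition vectors, empty σ grids, all-zero core fibers.

## Known limitations

* **Zero-fill shapes the condition components under unbalanced
  occupancy.**  With the bundled design, conditions share 23/11/8
  observed cells (HC/SD/RS) and co-observe 11 (HC–SD) or 8 (each–RS).
  Any shared gene-level structure — baselines above all — therefore
  enters the condition-mode covariance through this co-observation count
  matrix, whose eigenvectors are: a one-signed occupancy direction
  (excluded as baseline-like), an HC-versus-(SD, RS) contrast that the
  classifier reads as *not recovered*, and an SD-versus-RS contrast read
  as *overshoot*.  The second and third condition components of *any*
  data over this design, including pure-noise data, thus tend toward the
  two headline shapes; weak genuinely-recovered signal does not
  re-orient them.  Gene-level selection remains calibrated (pure-noise
  data selects essentially nothing, and planted genes are recovered with
  high sensitivity and low FDP — both measured by the acceptance tests),
  but a condition-component *label* on its own should not be read as
  evidence that the pattern exists in the data; the selected gene set
  carrying it should be inspected.  Balanced designs do not have this
  artifact.
* The Gaussian null is an assumption; heavy-tailed gene scores inflate
  selections.  The σ calibration compensates for outlier contamination
  of the scale estimate, not for a wrong null family.
* The PCA baseline drops missing cells instead of zero-filling, so it is
  a comparison method, not an equivalent reformulation.
* 3-mode studies are handled as 4-mode tensors with a singleton hour
  axis; results are identical to a native 3-mode decomposition.
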
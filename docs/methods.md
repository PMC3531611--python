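# Methods

`phosphozip` analyses how the position and charge state of phosphate
groups modulate amyloid formation by a short peptide, and turns the
position dependence into constraints on the cross-β ("steric zipper")
architecture of the fibrils. The model system is strand E of
β2-microglobulin — the tridecapeptide DWSFYLLYYTEFT (residues 59–71),
capped with an acetyl N terminus and an amide C terminus — together with
variants carrying a phosphate on one or two of its six Ser/Thr/Tyr
residues.

## Charge model

Each ionisable site is treated as an independent Henderson–Hasselbalch
equilibrium. Asp1 and Glu11 use pKa 4.0. A phosphomonoester is diprotic
with default pKa₁ = 2.1 and pKa₂ = 6.7, chosen so the *dominant* species
is neutral at pH 1.1, mono-anionic at pH 3.6 and di-anionic at pH 7.5 —
the three regimes probed experimentally. (The study states the 0/−1/−2
assignments at those pH values but not the pKa pair itself; 2.1/6.7 are
ordinary phosphomonoester values consistent with them, and both are
exposed in `ChargeModel`.) Capped termini contribute no charge.
Unphosphorylated Ser/Thr/Tyr are treated as non-ionisable: the analysis
never leaves pH ≤ 7.5, far below the tyrosine phenol pKa, and keeping
them inert preserves the clean identity *charge(control) − charge(pX) =
phosphate charge*. Basic side chains (absent from strand E) are covered
by an extensible table. Two modes exist: `dominant` (integer
most-populated species, ties at pH = pKa resolved toward the protonated
form) and `fractional` (population-weighted expectation).

## ThT kinetics and t50

Each condition is measured as ~40 replicate fluorescence time courses
plus a DMSO blank. Processing: blank subtraction (pointwise, multiple
blanks averaged first); per-curve normalisation to the mean of the final
10% of samples (the "plateau" — the 10% extent is a package choice,
configurable, robust to plateau drift); and t50 extraction as the first
upward crossing of 0.5 *after the curve's global minimum* (the
global-minimum gate discards early noise spikes), linearly interpolated
between the bracketing samples,

    t50 = t1 + (t2 − t1) · (0.5 − y1) / (y2 − y1).

The replicate t50 values are binned into a 10-bin equal-width histogram
and a Gaussian `amp·exp(−(x−μ)²/2σ²)` is least-squares fitted to the bin
counts (unweighted; initialised from sample moments). μ and |σ| are the
condition's mean t50 and SD. The fit is declared poor when R² < 0.5, σ
exceeds the data range, or the optimiser fails; the code then falls back
to sample statistics with a warning (bimodal sets end up here by
design). With 40 replicates in 10 bins, a single condition's σ estimate
carries ~±30% sampling noise; μ is recovered to ~1%. An all-identical
input returns that value with SD 0, skipping the fit.

Wells are called `fibrils` when the median final-plateau signal exceeds
`noise_k` (default 5) times the SD of the blank-subtracted early
baseline; otherwise `no_fibrils`, censored at the final observation time
(the ">4 days" style of call).

## Idealized zipper geometry

The builder replaces force-field model building with parametric ideal
geometry: deterministic, dependency-free, and sufficient to reproduce
the published inter-tyrosine distance pattern (distance targets
therefore carry a ±1.5 Å tolerance).

* **Strand** — backbone N/CA/C/O plus CB from ideal bond lengths and
  angles, φ = −139°, ψ = +135°, ω = 180°, CB placed tetrahedrally with
  L-chirality. Axial rise ≈ 3.47 Å/residue; side chains alternate faces.
  Convention: strand axis = x, sheet stacking (H-bond/fibril axis) = y,
  sheet separation = z; 1-based residues; Å units.
* **Sheet** — 8 strands at 4.8 Å stacking (the universal cross-β
  spacing). Antiparallel neighbours are generated by one of the two C2
  operations that reverse the strand direction: about the sheet normal
  (face-preserving — the in-register pairing i ↔ N+1−i) or about the
  stacking axis (face-exchanging — the *shifted* pairing i ↔ N+1−i+s).
  The default shift s = −1 places residue 5 opposite residue 8 and
  residue 9 opposite residue 4, the registry that maximises core π–π
  alignment and separates the position-9 tyrosines. Adjacent strands
  hydrogen-bond correctly: alternate residues show backbone N···O
  contacts of 2.8–3.1 Å to each neighbour.
* **Zipper** — the sheet is duplicated and packed at 12 Å mean-CA-plane
  separation (the intra-sheet spacing stays 4.8 Å). The eight symmetry
  classes are the cross-product of strand orientation, face packing and
  sheet polarity; for antiparallel sheets — which contain both strand
  senses — the polarity label is realised by the sheet arrangement
  itself (in-register ↔ up-up, shifted ↔ up-down), so the interface
  operation reduces to the face choice: class 7 packs *opposite* faces
  (pure translation, zero strand-axis slide) and class 8 packs
  *equivalent* faces (copy turned over about the strand axis, with a
  two-residue slide so side chains interleave instead of meeting
  tip-to-tip). Both slides are exposed via `BuildParams`. A cross-sheet
  clash check (< 2.2 Å) guards impossible packings.

**Cβ–Cβ separation.** The discriminating measurement is the proximity
of same-position side chains across the dry interface:
`average_cb_distance` takes, for every chain whose CB at the position
*faces the interface* (CA→CB component toward the opposite sheet), the
nearest interface-facing same-position CB on the other sheet, and
averages. Restricting to interface-facing CBs is essential: side chains
on the outer faces of the zipper are irrelevant to the electrostatics of
the dry interface and would otherwise cap the average. The default
builds give class 7 → 13.8 / 13.6 / 19.5 Å at positions 5/8/9 and class
8 → 11.2 / 10.9 / 11.1 Å, reproducing the published pattern (position 9
uniquely remote in class 7; everything comparable in class 8).

## Architecture inference

Two screens, both premised on (i) phosphate–phosphate electrostatic
repulsion controlling assembly and (ii) a common fibril morphology
across variants (stated, not tested — it heads the report):

1. **Arrangement screen** (schematic, residue units): the
   phosphate-to-phosphate offset between neighbouring strands is
   |p − q| for parallel and |p + q − P| for antiparallel pairing
   (P = N+1+s), minimised over site pairs. An arrangement is eliminated
   when a non-aggregating variant's offset is ≥ some aggregating
   variant's. On the study's pH 3.6 outcomes, parallel (all offsets 0)
   and in-register antiparallel (p5Y ties p9Y at 4) fall; the shifted
   arrangement (p5Y/p8Y at 3 < p9Y at 5; p3S10T's sites directly
   opposed at 0) survives alone.
2. **Class screen** (geometric, Å): for the two shifted-compatible
   classes, built models are screened with the rule *every aggregating
   variant's separation must exceed every non-aggregating one's by a
   margin* (default 3 Å ≈ the gap between the published 13.7 and 20.5 Å
   values minus build tolerance; a CLI flag). Only single-phosphosite
   variants enter this screen — a double variant can be blocked by
   intra-sheet pairing of its own sites, which a same-position
   cross-sheet metric cannot express; the double variant constrains the
   arrangement stage instead. Class 8's uniform ~11 Å separations
   violate the rule; class 7 survives, ending the chain
   3 arrangements → 1 → 2 classes → class 7.

pH 1.1 rows (all aggregate) and pH 7.5 rows (only the control) carry no
contrast between phosphovariants and contribute no constraints. The
screens are monotone in the margin (the consistent set only shrinks) and
invariant to row order and duplication. The package reports
*consistency*, not proof of structure.

## Interface-water analysis

Zipper integrity in a multi-frame trajectory is quantified by counting
water oxygens inside the dry interface. The region is the slab between
the two sheets' mean CA planes, inset 1.0 Å on each side, intersected
with the prism over the convex hull of the between-plane CB atoms
dilated by 2 Å; membership is strict (boundary excluded) and hydrogens
are ignored. The region is recomputed per frame, so sheet drift widens
or invalidates it naturally; if the mean-plane gap exceeds twice its
initial value the zipper is declared collapsed regardless of counts. A
trajectory is `stable` when every frame stays below 5 waters — the
count below which simulated zippers remain intact — else `dissolved`.
Sodium ions are counted with the same region but reported separately;
only waters enter the criterion.

## Synthetic data

No raw plates or trajectories are deposited, so generators close the
loop for every stage:

* **ThT plates** — well i is `blank + A_i·L(t; τ_i, k) + ε(t)` with L a
  logistic sigmoid (Gompertz available for asymmetry robustness), τ_i ~
  N(10 s, 1 s), A_i ~ N(100, 5%), ε white noise with SD 1, blank level
  5, 40 wells on a 301-point, 30 s grid. These emulate a fast-
  aggregating condition at realistic plate-reader noise; they do not
  emulate nucleation-elongation mechanism, well-to-well lag
  correlations, or ThT binding saturation, so passing recovery tests
  validates the *estimator*, not kinetic modelling of real data. The
  double-phosphovariant's broad rate spread is emulated by a high-τ-SD
  preset. Ground truth (τ_i, A_i) is returned alongside.
* **Trajectories** — jittered copies of a built zipper with an exact
  scheduled number of waters rejection-sampled strictly inside the
  (re-derived) interface region and decoys outside, at 2.8 Å mutual
  exclusion; an over-full schedule raises rather than silently
  truncates. Jitter is applied before placement so planted counts stay
  exact at any jitter.
* **Outcome fixture** — the transcribed variant-by-pH outcome matrix
  (all fibrils at pH 1.1; p5Y/p8Y/p3S10T blocked at pH 3.6; only the
  control at pH 7.5), with the published mean t50 values attached as
  annotations where they exist. The measured t50s (0.367/0.484/10.59 s
  for the control, 2.90/74.77 s for p9Y) and the reported ~60/20/55/35
  interface-water counts of the charged simulations require the
  original plate data and explicit-solvent MD runs; they appear only as
  annotations and generator presets and are never recomputed.

All generators are driven by a single integer seed; identical seeds give
bit-identical output.

## Numerical choices and limitations

* Ties at pH = pKa go to the protonated species (determinism).
* The t50 bracket requires a point < 0.5 followed by one ≥ 0.5; curves
  starting at/above 0.5 or never crossing raise typed errors that the
  pipeline converts to per-well failures or a `no_fibrils` call.
* Problem sizes: 8×2 strands of 13 residues (≈ 1000 atoms), 40-replicate
  plates over seeds 1–10, trajectories of ≤ 10 frames with ≤ 60 waters —
  the scales at which every documented number in the README is computed.
* The geometry is rigid and un-minimised: no side chains beyond CB, no
  fibril twist, no energetics. Distances inherit a ±1.5 Å tolerance from
  this idealisation; conclusions are ordinal (which positions are
  remote), not metric.
* The water criterion is only comparable under this package's region
  definition; absolute counts from differently defined interfaces are
  not interchangeable.
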
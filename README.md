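# phosphozip

Phospho-scanning analysis of amyloid fibril architecture for a model
peptide: process thioflavin-T (ThT) aggregation kinetics into half-times
(t50), model the pH-dependent charge states of phosphopeptides, build
idealized cross-β steric-zipper models, screen candidate architectures
against position-dependent aggregation outcomes, and quantify zipper
integrity by interface-water counting in multi-frame coordinate data.

**Who it is for.** Peptide self-assembly and structural bioinformatics
researchers who use chemical modification scanning — here, phosphate
groups placed at different Ser/Thr/Tyr positions — as a cheap probe of
fibril architecture, without crystallography or NMR.

**The idea.** The model peptide is strand E of β2-microglobulin,
DWSFYLLYYTEFT (capped termini), with six phosphorylatable residues. A
phosphomonoester titrates 0 → −1 → −2 across pH 1.1 / 3.6 / 7.5.
At pH 1.1 every phosphovariant aggregates; at pH 7.5 all are blocked; at
pH 3.6 the outcome depends on *where* the phosphate sits (p5Y and p8Y
blocked, p9Y and others aggregate). If phosphate–phosphate repulsion in
a common fibril architecture explains this, then inside a β-sheet with
neighbour-strand pairing i ↔ N+1−i+s the phosphate offset |p + q − P|
(P = N+1+s; |p − q| for parallel strands) must be smaller for blocked
variants than for aggregating ones — which eliminates parallel and
in-register antiparallel sheets, leaving the shifted antiparallel
registry (s = −1). Of the eight steric-zipper symmetry classes, two are
compatible with that registry (classes 7 and 8); measuring the average
cross-interface Cβ–Cβ separation at each phosphosite in built 8×2
models,

    d(p) = mean over interface-facing chains of the nearest
           same-position Cβ on the opposite sheet,

shows position 9 uniquely remote in class 7 (≈19.5 Å vs ≈13.7/13.6 Å
for 5/8) but all positions comparable in class 8 (≈11 Å), so only a
class 7 zipper is consistent with the outcomes. For trajectory data, a
zipper is scored `stable` when fewer than 5 water molecules enter the
dry inter-sheet interface in every frame.

## Worked example

```python
from phosphozip import (
    ArchitectureModel, ThTKineticsModel, ThTSimParams,
    simulate_tht_replicates, study_outcome_fixture,
    build_class_zipper, average_cb_distance, net_charge, table1_variants,
)

# charge states of the unphosphorylated control
control = table1_variants()["control"]
print(net_charge(control, 1.1), net_charge(control, 7.5))
# 0 -2        <- neutral at pH 1.1, -2 (Asp + Glu) at pH 7.5

# t50 extraction on a synthetic 40-replicate plate
reps, truth = simulate_tht_replicates(ThTSimParams(seed=1))
print(ThTKineticsModel(reps).fit().summary())
```

```
ThT kinetics summary
====================
variant:          synthetic
pH:               3.6
assembly call:    fibrils
wells used:       40
mean t50:         10.13 s
sd t50:           0.618 s
summary method:   gaussian_fit (10 bins)
```

The generator's true mean half-time was 10 s; the histogram + Gaussian
pipeline recovers it to ~1%.

```python
# geometry: the two shifted-compatible zipper classes
for cid in (7, 8):
    z = build_class_zipper("DWSFYLLYYTEFT", cid)
    print(cid, [round(average_cb_distance(z, p), 2) for p in (5, 8, 9)])
# 7 [13.76, 13.6, 19.5]     <- position 9 remote: phosphates far apart
# 8 [11.19, 10.91, 11.07]   <- all positions equivalent

# the full inference chain
print(ArchitectureModel(study_outcome_fixture()).fit().summary())
```

```
Fibril architecture inference
=============================
Assumes electrostatic phosphate-phosphate repulsion controls assembly and that all variants share a common fibril morphology.
screen pH: 3.6   class margin: 3 A

Strand arrangements:
  parallel_in_register         eliminated  [non-aggregating p8Y has phosphosite separation 0 >= aggregating p13T's 0]
      separations (residues): p10T=0, p13T=0, p3S=0, p3S10T=0, p5Y=0, p8Y=0, p9Y=0
  antiparallel_in_register     eliminated  [non-aggregating p5Y has phosphosite separation 4 >= aggregating p9Y's 4]
      separations (residues): p10T=6, p13T=12, p3S=8, p3S10T=1, p5Y=4, p8Y=2, p9Y=4
  antiparallel_shifted         consistent
      separations (residues): p10T=7, p13T=13, p3S=7, p3S10T=0, p5Y=3, p8Y=3, p9Y=5

Zipper classes:
  class 7                      consistent
      separations: p10T=25.8A, p13T=45.9A, p3S=25.9A, p5Y=13.8A, p8Y=13.6A, p9Y=19.5A
  class 8                      eliminated  [aggregating p10T separation 10.9 A does not exceed non-aggregating p5Y's 11.2 A by the 3 A margin]
      separations: p10T=10.9A, p13T=11.0A, p3S=11.3A, p5Y=11.2A, p8Y=10.9A, p9Y=11.1A

Winning architecture: class 7 steric zipper
```

The audit trail shows the contraction 3 arrangements → 1 → 2 classes →
class 7: the blocked variants' phosphosites are the ones in close
cross-interface proximity only in the class 7 packing.

The same operations are available from the shell:

```bash
phosphozip build --class 7 --out class7.pdb
phosphozip measure --model class7.pdb --positions 5,8,9
phosphozip infer --report report.json
phosphozip waters --traj traj.pdb --sheets A-H,I-P --threshold 5
```

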
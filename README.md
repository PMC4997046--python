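# spindlemetrics

Quantitative phenotyping of meiotic spindle pole organization from 3D
two-channel fluorescence microscopy, for plant cytogenetics work such as
characterizing maize *divergent spindle* (kinesin-14A) mutants.  The package
covers the full quantitative chain of such a study:

* **Spindle morphometry** from 3D z-stacks (tubulin + chromosome channels):
  metaphase plate width `W_C`, half-spindle length `L` (plate to pole),
  spindle width `W_S` at a fraction *f* (default 0.75) of `L`, and the
  **focus ratio** `W_S / W_C` — the pole-focus statistic.  A value near 1
  means the microtubule bundle has not converged (splayed, divergent poles);
  a small value means a tightly focused pole.  For an ideal cone the ratio is
  `1 − f`; for a non-converging cylinder it is 1.
* **Topology**: counting separate spindles within a cell and poles per
  spindle (multi-spindle and tripolar phenotypes).
* **Anaphase kinematics** from 4D time-lapse: chromosome offset (3D distance
  between chromosome-mass and spindle centroids at metaphase), anaphase A
  distance, and anaphase rate (distance / elapsed time).
* **Statistics**: one-way ANOVA with Tukey-HSD (or LSD) compact letter
  display, binomial proportions with Wilson confidence intervals, and
  relative expression by the 2^−ΔΔCt method.
* **CAPS genotyping in silico**: restriction-site search, linear digestion,
  and allele calls from fragment patterns, with the two bundled assays
  (MseI, 235 bp → 152 + 83; NsiI, 533 bp → 272 + 261).
* A **synthetic-data generator** producing seeded image stacks, time-lapse
  movies, Ct tables, count tables and amplicon sequences with full ground
  truth, so every stage of the pipeline is testable end to end.

## Worked example

Render a mutant-like meiocyte (divergence 0.8) with realistic optics and
measure both half-spindles:

```python
from spindlemetrics import (SpindleGroundTruth, generate_spindle_stack,
                            segment_stack, estimate_axis_and_plate,
                            measure_half_spindle, proportion)
from spindlemetrics.synthetic import Optics

truth = SpindleGroundTruth.bipolar(divergence=0.8, seed=1)
stack, _ = generate_spindle_stack(truth, Optics())
seg = segment_stack(stack, channels=("tubulin", "dna"))
frame = estimate_axis_and_plate(stack, seg)
for h in (1, 2):
    m = measure_half_spindle(stack, seg, frame.axis, frame.plate_center,
                             half_spindle_id=h)
    print(f"half-spindle {h}: W_C={m.w_c:.2f} um  L={m.length:.2f} um  "
          f"W_S={m.w_s:.2f} um  W_S/W_C={m.focus_ratio:.3f}")

res = proportion(3, 434)
print(f"mininuclei: {res.percent:.2f}% (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}%)")
```

prints

```
half-spindle 1: W_C=10.44 um  L=12.30 um  W_S=8.73 um  W_S/W_C=0.836
half-spindle 2: W_C=10.44 um  L=12.30 um  W_S=8.69 um  W_S/W_C=0.833
mininuclei: 0.69% (95% CI 0.24-2.01%)
```

The phantom was generated with a 10 μm plate, a 12 μm half-spindle and
divergence 0.8, so the expected focus ratio is 0.25 + 0.75 × 0.8 = 0.85;
the pipeline recovers the plate width, length and ratio to within a voxel.
The proportion line is the scored-count summary used for rare phenotypes
such as mininucleate tetrad cells: 3 positives of 434 scored is 0.69%,
below one percent.

The same operations are available from the shell:

```sh
spindlemetrics simulate --out-dir batch --seed 7 \
    --genotype wt=0.1 --genotype dv1=0.8 --n-cells 8
spindlemetrics measure batch --out measurements.csv
spindlemetrics stats measurements.csv --analysis anova --out letters.csv
spindlemetrics genotype amplicons.fasta --assay dv1-1 --out calls.csv
```

Each command writes tidy CSV plus a JSON run report with the full
configuration, seed and per-stage warnings; all tables carry seed,
config-hash and version provenance columns.

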
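# codonclusters

Codon-usage-cluster profiling and host/target comparison metrics for
heterologous protein expression studies.

## The problem

Roughly half of all proteins come out insoluble when overexpressed in
*E. coli*: the nascent chain misfolds and aggregates into inclusion bodies.
One driver is synonymous codon usage — clusters of rare codons slow the
ribosome locally and pace co-translational folding. When a gene moves to a
new host, the host's codon frequencies redraw that landscape, and the
degree to which the original rare/common *pattern* survives turns out to
track solubility, while the overall *offset* between the two landscapes
tracks expression level.

`codonclusters` implements the machinery to quantify this:

- **%MinMax profiles.** For a window of W = 18 consecutive codons with mean
  actual usage frequency A, and Max/Min/Avg the window means of each codon
  family's most frequent, rarest and average synonym,

      %MinMax =  100 · (A − Avg) / (Max − Avg)   if A ≥ Avg
      %MinMax = −100 · (Avg − A) / (Avg − Min)   otherwise

  so +100 is a maximally common-codon window and −100 a maximal rare-codon
  cluster. Windows advance one codon; a CDS of L sense codons gives
  L − 17 values.
- **Δ%MinMax** = (1/n) Σ |xᵢ − yᵢ|: mean absolute difference between the
  profiles of the same gene under the host's table (x) and the native
  organism's table (y). Offset between landscapes; anti-correlates with
  expression.
- **%MinMax correlation**: Pearson r between the same two profiles. Shape
  conservation of the landscape; correlates with solubility.
- **Stratification**: each window is assigned an α-helix / β-sheet / coil
  class from a 3-state secondary-structure annotation (centre-residue rule
  by default) and the correlation is recomputed per class; dataset-level
  per-class analyses keep only proteins with > 5% content of that class.
- **CAI** = exp((1/L) Σ ln w), the geometric mean of relative adaptiveness
  w (codon frequency over its most frequent synonym) — plus GC content,
  solubility quantification from gel band intensities
  (Isf / (Isf + Iif), soluble above 30%), predictor evaluation
  (prediction accuracy and Matthews correlation coefficient), and a
  regression-band outlier screen.
- **Synthetic screens**: a seeded generator emitting codon usage tables,
  genes under controllable recoding regimes (native-like sampling,
  rank-matched harmonization, one-amino-acid-one-codon optimisation),
  secondary-structure strings and outcome measurements with planted linear
  effects, so the entire pipeline is exercisable without any downloads.

## Worked example

```python
import pandas as pd
from codonclusters import (
    SimulationConfig, simulate_study, CodonUsageStudy,
)

bundle = simulate_study(SimulationConfig(seed=1))   # 30-gene synthetic screen
i = bundle.intensities
outcomes = pd.DataFrame({
    "orf_id": i["orf_id"],
    "solubility": i["I_sf"] / (i["I_sf"] + i["I_if"]),
    "expression": i["I_target"] / i["I_ladder"],
})
study = CodonUsageStudy(bundle.cds, bundle.host_table, bundle.target_table,
                        outcomes, ss=bundle.ss)
print(study.fit().summary())
```

prints (abridged):

```
Dataset-level Pearson correlations (feature vs outcome)
----------------------------------------------------------------
             feature    outcome      r        p  n  n_excluded
                 cai solubility +0.017    0.929 30           0
        delta_minmax solubility +0.021    0.912 30           0
  minmax_correlation solubility +0.877  2.1e-10 30           0
                 cai expression +0.428   0.0184 30           0
        delta_minmax expression -0.759 1.16e-06 30           0
  minmax_correlation expression -0.028    0.883 30           0
```

Read: in this simulated screen solubility is explained by profile-shape
conservation (r = +0.88 with the %MinMax correlation) and not by CAI, while
expression is explained by the landscape offset (r = −0.76 with Δ%MinMax)
and by CAI — the planted trade-off between optimising for expression and
preserving the native codon-cluster landscape.

The same analysis runs from the shell on files:

```sh
codonclusters simulate --seed 1 --out-dir screen/
codonclusters batch --manifest screen/manifest.json --out-dir reports/
```

Other subcommands: `profile`, `compare`, `cai`, `stratify`, `evaluate`,
`correlate`. All reports are tab-separated with a `#` header recording the
tool version, flags and input checksums; exit codes separate input
validation (2) from computation (3) failures.

## Acceptance script

`scripts/acceptance.py` regenerates a complete synthetic screen from a seed
and runs the full per-gene and dataset-level analysis end to end:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The fitted summary goes to stderr and the result manifest to `--out`.

See `docs/methods.md` for the model details, parameter choices and known
limitations.
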
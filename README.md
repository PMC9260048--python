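# efnet

Network engagement analysis for TMS targets: which canonical resting-state
networks does a stimulation site functionally engage, and how much of the
subject-to-subject variability in that engagement comes from cortical
geometry versus from individual functional connectivity?

Transcranial magnetic stimulation (TMS) induces a focal electric field
(E-field) on the cortical surface. Thresholding the field magnitude |E| at
0.9 V/m defines the stimulated *seed* patch; the seed's functional
connectivity (FC) through a vertex×vertex dense connectome then tells you
which downstream networks the stimulation is likely to propagate into.
`efnet` implements this pipeline for researchers in brain stimulation and
connectomics, together with a synthetic-cohort generator so the entire
analysis is runnable, testable and reproducible at desk scale.

## The statistic

For a seed S (all vertices with |E| ≥ 0.9 V/m) and dense connectome r(i, j):

* **seed FC map** — FC(j) = (1/|S|) Σ_{i∈S} r(i, j), the plain mean
  correlation from the seed to every vertex j;
* **vertex network FC** — for a vertex v and canonical network m,
  the mean of r(v, j) over all vertices j of m (excluding j = v);
* **network engagement** — each seed vertex is assigned to its
  maximum-FC network, and the engagement profile is the percentage of seed
  vertices assigned to each of the eight Yeo/Schaefer networks
  (Vis, SomMot, DAN, VAN, Limbic, FPN, TempPar, DMN — a fixed order that
  also breaks ties);
* **seed area** — in mm², summed over mesh triangles whose three vertices
  are all suprathreshold.

Three pairing variants separate the sources of inter-subject variability:

| variant    | E-field seed     | connectome      | isolates            |
|------------|------------------|-----------------|---------------------|
| `geom`     | subject-specific | group average   | cortical geometry   |
| `fconly`   | fixed template   | subject-specific| individual FC       |
| `combined` | subject-specific | subject-specific| the real-world case |

Engagement matrices (subjects × networks) are compared with a
repeated-measures one-way ANOVA over the within-subject factor NETWORK
(F = MS_levels/MS_error with df (k−1, (k−1)(n−1)), partial
η² = SS_levels/(SS_levels+SS_error)), Tukey-corrected pairwise post hocs
on the studentized range, paired t contrasts between targets, and Pearson
correlations of each network's engagement across subjects between
variants.

## Worked example

```python
from efnet import CohortSpec, generate_cohort
from efnet.model import TargetEngagement

cohort = generate_cohort(CohortSpec(master_seed=7, n_subjects=8,
                                    mesh_subdivision=3, n_timepoints=120))
res = TargetEngagement(cohort, target="dlpfc", variant="combined").fit()
print(res.summary())

geom = TargetEngagement(cohort, target="dlpfc", variant="geom").fit()
print("VAN engagement r (geometry-only vs combined):",
      round(geom.correlate_with(res, "VAN"), 3))
```

prints

```
Network engagement — target dlpfc, variant combined, threshold 0.9 V/m
subjects included: 8

 network   mean %     sd %  top-count
     Vis     42.3     26.6          3
  SomMot      0.0      0.0          0
     DAN      0.0      0.0          0
     VAN     50.3     31.6          5
  Limbic      0.0      0.0          0
     FPN      7.4      6.8          0
 TempPar      0.0      0.0          0
     DMN      0.0      0.0          0

RM-ANOVA (NETWORK): F(7, 49) = 14.25, p = 6.3e-10, partial eta^2 = 0.67

VAN engagement r (geometry-only vs combined): 0.986
```

Reading this: the dlPFC-like seed sits over parcels belonging mostly to
VAN and Vis in this synthetic parcellation; on average half of its
suprathreshold vertices engage the VAN, and 5 of the 8 subjects have VAN
as their most-engaged network. The ANOVA confirms the engagement
percentages differ strongly across networks, and the cross-variant
correlation says geometry alone predicts VAN engagement almost perfectly
in this small, low-FC-noise cohort.

The same pipeline is scriptable from the shell:

```bash
efnet simulate --config cohort.yaml --out run/
efnet run --out run/ --variant combined --target dlpfc
efnet stats --out run/
efnet report --out run/
```

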
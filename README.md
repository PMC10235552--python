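# resectmorph

Quantifying the remote structural effects of epilepsy surgery from paired
pre/postoperative T1-weighted MRI.

Resective surgery for drug-resistant temporal lobe epilepsy — anterior
temporal lobectomy (ATL) or selective amygdalohippocampectomy (SAH) —
removes the epileptogenic tissue, but its long-term effects reach far
beyond the cavity: cortex remote from the resection continues to thin in
the years after surgery. Measuring that thinning is technically awkward
because the cavity itself breaks standard longitudinal pipelines (template
averaging darkens the resection zone; deformable registration drags tissue
into it). `resectmorph` implements a resection-aware longitudinal pipeline
for researchers studying postoperative morphometry:

1. **Resection segmentation.** Both timepoints are segmented into six
   tissue classes (CSF, GM, WM, deep GM, cerebellum, brainstem) by an EM
   Gaussian mixture with optional spatial priors. The cavity is estimated
   from the CSF probability maps: smooth both with a Gaussian kernel
   (σ = 2 voxels), take Δ = post − pre, keep voxels with Δ > 0.25 that were
   GM or WM preoperatively, and retain the largest connected component.
   Externally edited masks are re-imported with provenance tracking, and
   per-(procedure × hemisphere) resection probability maps (0–100 %) are
   built by voxelwise averaging in a common space.
2. **Resection-aware single-subject template (SST).** The SST is the
   voxelwise mean of the rigidly co-registered timepoints with
   preoperative intensities imputed inside the cavity, so the template is
   not darkened by averaging tissue with cavity CSF. The tissue mixture is
   fitted once on the SST and both timepoints are classified with the
   shared parameters.
3. **Cortical thickness.** Laplacian (potential-field) thickness: solve
   ∇²u = 0 over the GM ribbon with u = 0 at the GM/WM interface and u = 1
   at the GM/CSF interface, then integrate streamline length through the
   field Eulerian-style. Thickness is averaged per region of a DKT-style
   atlas, excluding resected voxels and the ipsilateral mesial temporal
   regions (amygdala, hippocampus, entorhinal, parahippocampal), and the
   change is annualized: Δ = (post − pre) / interscan interval, in mm/yr
   (negative = thinning).
4. **Statistics.** Two-sample *t*-tests (pooled by default) of annualized
   change between procedures, per-region tests with Benjamini–Hochberg FDR
   correction within ipsilateral/contralateral families, one-sample tests
   of change against zero, Pearson correlations with clinical variables,
   χ² tests for demographics, and Engel outcome binarization
   (I vs II–IV).
5. **Phantoms.** A synthetic-MRI generator produces paired pre/post
   volumes with analytic ground truth — per-region cortical thickness,
   programmed annualized thinning, known spherical cavities (ATL-like
   large, SAH-like small), tissue noise, optional rigid misalignment, and
   whole cohorts with group thinning-rate distributions (ATL
   0.08 ± 0.11 mm/yr, SAH 0.01 ± 0.02 mm/yr) — so every pipeline stage is
   testable without patient data.

## Worked example

Generate a 6 + 6 synthetic cohort, run the pipeline on every subject, and
compare annualized thinning between procedures:

```python
import numpy as np, pandas as pd
from resectmorph import PipelineConfig, SubjectInput, run_subject
from resectmorph.phantom import (PhantomSpec, generate_phantom, plan_cohort,
                                 tissue_priors)
from resectmorph.stats import run_group_analysis

planned, cohort = plan_cohort(n_atl=6, n_sah=6,
                              template_spec=PhantomSpec(shape=(64, 64, 64)),
                              seed=42)
cfg = PipelineConfig(assume_aligned=True)   # phantom pairs share a grid
tables = []
for s in planned:
    pre, post, truth = generate_phantom(s.spec)
    meta = cohort.set_index("subject").loc[s.subject_id]
    res = run_subject(
        SubjectInput(s.subject_id, pre, post, brain_mask=truth.brain_mask,
                     seizure_side=meta["seizure_side"],
                     interscan_interval_years=meta["interscan_interval_years"],
                     tissue_priors=tissue_priors(truth)),
        truth.atlas, cfg)
    tables.append(res.regional)
regional = pd.concat(tables, ignore_index=True)
regional = regional[~regional.low_coverage & np.isfinite(regional.annualized_change)]
analysis = run_group_analysis(regional, cohort)
g = analysis.global_test
print(f"ATL {g.group_summaries['ATL'][0]:+.3f} vs "
      f"SAH {g.group_summaries['SAH'][0]:+.3f} mm/yr, "
      f"t = {g.statistic:.2f}, p = {g.p_value:.4f}")
```

Output (seed 42):

```
ATL -0.100 vs SAH -0.005 mm/yr, t = -2.29, p = 0.0451
```

The drawn ATL subjects in this cohort were programmed with a mean thinning
rate of 0.108 mm/yr and the SAH subjects with 0.007 mm/yr; the pipeline
recovers annualized group means of −0.100 and −0.005 mm/yr from the images
alone (errors below 0.01 mm/yr), and the pooled two-sample *t*-test
detects the group difference at α = 0.05 (negative values are thinning).

The same stages are available from the shell: `resectmorph phantom`,
`segment`, `resect`, `probmap`, `register`, `sst`, `thickness`, `stats`,
`run-subject`, and `run-cohort` (see `resectmorph --help`).

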
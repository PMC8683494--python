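# ieegcoverage

Probabilistic gray/white-matter coverage analysis for intracranial EEG
electrodes.

## The problem

When epilepsy patients undergo invasive monitoring, clinicians choose
between penetrating **depth electrodes** (SEEG) and **subdural strips and
grids** laid on the cortical surface. How much gray matter does each
strategy actually record from? The answer depends strongly on the assumed
**radius of influence (RoI)** — the distance around a contact centroid
within which tissue counts as covered — and on cortical folding: surface
contacts ride the smooth envelope of the brain and partially miss sulcal
gray matter, while depth leads reach sulci and deep structures such as the
hippocampus.

This package quantifies that trade-off. For each patient it computes

```
C_t(r) = Σ_{v ∈ U(r)}  p_t(v) · V_voxel ,      U(r) = ⋃_i  B(x_i, r)
```

the probability-weighted volume of tissue *t* (gray or white matter) inside
the **union** of spheres of radius *r* centered on the contact positions
`x_i` — overlap between neighboring contacts is counted once, which is what
makes closely spaced leads redundant. `p_t(v)` is the per-voxel tissue
probability (partial-volume segmentation); subcortical and cerebellar
parcels are excluded from the totals. The sweep runs r = 1–15 mm in 0.5 mm
steps, with per-contact curves `C_t(r)/N` compared across implant classes
(S, S+G, S+G+D, D) by Kruskal–Wallis tests with Bonferroni correction.

Supporting machinery, all included and tested:

- **Synthetic phantom patients** — an egg-crate-folded cortical ribbon with
  partial-volume GM/WM/CSF maps, atlas parcels (frontal, temporal,
  hippocampus, amygdala, insula, cingulate + excluded subcortical and
  cerebellar blocks), and clinical electrode layouts (depth leads at 5 mm
  inter-contact spacing, subdural arrays at 10 mm).
- **Brain-shift correction** — subdural contacts localized from a
  postoperative CT sit inside the preoperative brain; they are projected
  back onto the gray-matter surface smoothed by morphological closing
  (24 mm spherical kernel). Interhemispheric contacts are restricted to the
  hemisphere they record from.
- **FEM recording volumes** — a P1 tetrahedral solver for
  ∇·(σ∇V) = 0 with σ_CSF = 1.79, σ_GM = 0.33, σ_WM = 0.142 S/m and 1 mA
  injection; the recording volume at nominal radius r is the region where
  |V| exceeds its mean over the r-sphere, compared to the plain sphere with
  the Dice coefficient 2|A∩B|/(|A|+|B|).

## Worked example

Run the whole pipeline on a seeded synthetic cohort (8 patients, 2 per
implant class, 2 mm voxels):

```python
import tempfile
import ieegcoverage as ic
from ieegcoverage.pipeline import RunConfig, run_cohort
from ieegcoverage.stats import mean_curve_by_class, crossover_radius

cfg = RunConfig(
    cohort=ic.CohortConfig(phantom=ic.PhantomSpec(voxel_mm=2.0)),
    seed=1,
    out_dir=tempfile.mkdtemp(),
)
result = run_cohort(cfg)
gm = mean_curve_by_class(result.records, "gm", "per_contact")
print(gm.loc[[2.5, 5.0, 10.0, 15.0]].round(1))
print("crossover (D vs S):", crossover_radius(gm, "D", "S"), "mm")
```

prints

```
          S    S+G  S+G+D      D
2.5     5.5    5.4    8.2   11.5
5.0    38.4   33.7   53.1   66.5
10.0  261.8  181.8  260.5  276.9
15.0  565.6  336.4  452.7  433.6
crossover (D vs S): 11.0 mm
```

Each entry is mean gray-matter coverage per contact (mm³) at that RoI
radius. Depth-only patients (D) cover about twice the gray matter of strip
patients (S) at a 2.5 mm radius — their contacts sit inside cortical and
hippocampal gray matter — but the ordering reverses at the crossover
radius (here 11 mm): redundancy between 5 mm-spaced depth contacts caps
their union, while widely spaced surface contacts keep accumulating sulcal
gray matter. White-matter coverage (the `"wm"` curves) is dominated by
depth electrodes at every radius. `run_cohort` also writes tidy CSVs,
group-comparison tables and provenance to the output directory.

The same pipeline is exposed on the command line:

```sh
ieegcov run --seed 1 --voxel-mm 2.0 --out results/
ieegcov phantom --seed 1 --out patients/     # write NIfTI + CSV inputs
ieegcov run --input patients/ --out results/ # analyze files instead
```

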
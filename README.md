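# cytopheno

Decomposing cell-to-cell heterogeneity in transcription-factor activation
states from imaging flow cytometry time courses.

## The problem

Bulk readouts of TFEB (transcription factor EB) signaling — Western blots,
population-mean image statistics — average over cells that occupy very
different activation states. In imaging flow cytometry, each event is a
multichannel image of one cell (brightfield, nuclear stain, TFEB immunostain,
LAMP1 immunostain), so TFEB's nuclear/cytoplasmic partitioning can be measured
per cell and the population can be decomposed into *activity phenotypes*:
cells with cytoplasmic TFEB ("Inactive"), intermediate partitioning
("Medium"), and nuclear TFEB ("Active"). Treatment responses then become
redistributions of cells among phenotypes rather than shifts of one mean.

`cytopheno` implements that analysis end to end, for researchers analyzing
nuclear-translocation dynamics in imaging-cytometry data:

1. **Feature extraction** (`cytopheno.features`) — per-event masks
   (cell = default TFEB mask OR 5-px-eroded brightfield mask; nucleus =
   70%-of-total-intensity threshold mask on the nuclear stain; cytoplasm =
   cell AND NOT nucleus), single-cell/in-focus gating on brightfield area,
   aspect ratio, and gradient RMS, and the feature vector: background-
   subtracted intensities, areas, concentrations (intensity/µm²), nuclear
   percentage, the **Mean Pixel Nuc/Cyto** ratio on eroded compartment masks,
   and the **Max Contour Position** (normalized radial location of the
   highest-intensity ring: 0 = perinuclear, 1 = peripheral).
2. **Merge** (`cytopheno.framework.merge_experiments`) — all treatments and
   time points pooled, seeded shuffle, so clustering cannot exploit condition
   identity.
3. **Density-normalized clustering** (`cytopheno.clustering`) — arcsinh
   transform (cofactor 5), neighbor-count local density, density-dependent
   downsampling (keep probability min(1, TD/density), TD set by bisection;
   50 000 pooled max, 20 000 retained), k-means with restarts, and
   nearest-centroid assignment of every event. The fitted model (centroids +
   labels) transfers unchanged to new conditions.
4. **Phenotype assessment** — candidate models (feature combinations ×
   cluster numbers) must show reproducible cluster dynamics across replicates
   (criterion 1), non-redundant dynamics between clusters (criterion 2),
   statistically separated clusters (two-sided Wilcoxon rank-sum on
   1000-cell subsamples, p ≤ 0.001), and unimodal within-cluster feature
   distributions. The minimal passing model is selected.
5. **Time-course decomposition** (`cytopheno.framework`) — phenotype
   fractions per (treatment, time, replicate), response-region annotation,
   and prediction of the mean population response from subpopulation
   fractions × cluster means.

Because raw instrument data are rarely shareable, the package ships a
generator (`cytopheno.synthetic`) that emulates the measured single-cell
structure — three lognormal ratio phenotypes, a pooled correlation of ≈ 0.53
between nuclear localization and total TFEB concentration, a pooled
correlation of ≈ −0.25 between lysosomal radial position and localization,
and treatment-specific time-evolving mixture weights — with ground-truth
labels, optionally rendering each cell as a multichannel image.

## Worked example

```python
from cytopheno import clustering, framework, synthetic

cfg = synthetic.default_config(seed=1)          # 3 treatments x 7 times x 3 reps
events = synthetic.generate_timecourse(cfg)     # 630000 cells with true labels

train = events[events["treatment"].isin(["FM", "Torin1"])]
merged = framework.merge_experiments([train], seed=1)
search = framework.search_models(
    merged,
    feature_combos=[["mean_pixel_nuc_cyto"],
                    ["mean_pixel_nuc_cyto", "concentration_cell"]],
    k_values=[2, 3, 4],
    seed=1,
)
sel = search.selected
print(sel.features, sel.k)

labels = clustering.classify_events(search.selected_model, events)
tc = framework.compute_timecourse(labels, events)
base = tc[tc.time_h == 0].groupby("phenotype").fraction.mean()
print((100 * base).round(1).to_dict())
torin = (tc[tc.treatment == "Torin1"]
         .groupby(["time_h", "phenotype"]).fraction.mean().unstack())
print((100 * torin["Active"]).round(1).to_dict())
```

prints

```
('mean_pixel_nuc_cyto',) 3
{'Active': 9.2, 'Inactive': 44.8, 'Medium': 46.1}
{0.0: 9.1, 0.5: 38.6, 1.0: 52.1, 1.5: 56.9, 3.0: 42.1, 5.0: 24.9, 15.0: 7.6}
```

The search settles on a single feature (the nuclear/cytoplasmic ratio) and
three clusters: two clusters under-split the phenotypes (a merged, bimodal
cluster fails the unimodality check) and four over-split them (the split
halves co-move and fail the redundancy criterion). At baseline the population
sits at ≈ 45/46/9% Inactive/Medium/Active; under the mTOR-inhibitor-like
treatment the Active fraction rises from 9% to a 57% peak at 1.5 h and
relaxes to ≈ 8% by 15 h — the classifier recovers the generating composition
of every condition (including the held-out nutrient-deprivation-like
treatment, which it never saw during fitting) to within half a percentage
point.

A command-line interface wraps the stages:

```sh
cytopheno run-all --out results/            # full pipeline, default config
cytopheno simulate --out sim/ --images      # synthetic events + image stacks
cytopheno extract --images sim/images --out features.tsv
cytopheno cluster --features features.tsv --model-out model.json
cytopheno classify --features features.tsv --model model.json --out labeled.tsv
```

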
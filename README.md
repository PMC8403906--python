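# hippoparc

Individual-specific parcellation of the human hippocampus by its
resting-state functional connectivity to cortical networks, with the
statistical machinery to decide whether that organisation is a smooth
anterior–posterior **gradient**, discrete **parcels**, or both.

The package is aimed at precision-functional-mapping analyses of densely
sampled single subjects: hippocampal voxels, a cortical vertex set with
per-vertex network labels (e.g. from Infomap community detection), and long
concatenated BOLD runs. All of its analyses can also be exercised end to end
on a built-in synthetic cohort with known ground truth.

## What it computes

Let $x_v(t)$ be the BOLD series of hippocampal voxel $v$ and $\bar{y}_k(t)$
the mean series of cortical network $k$ over vertices more than 20 mm from
the hippocampus (a signal-bleed guard). With $z(r) = \operatorname{atanh} r$
the Fisher-transformed Pearson correlation:

- **Winner-take-all (WTA) parcellation** — each voxel is assigned to
  $\arg\max_k z(r_{vk})$ subject to $z(r_{vk}) > 0$; a *runner-up* network is
  recorded when its strength reaches 66% of the winner's. A two-alternative
  *forced choice* restricted to the default-mode (DMN) and parietal-memory
  (PMN) networks yields the binary anterior/posterior parcel masks, with
  parcel-to-winner strength checked against a $z(r) \ge 0.2$ floor.
- **Parcel-vs-chance null** — the forced choice is rerun on every other pair
  of usable networks (fronto-parietal excluded by default); each null
  parcel's mean winner-network $z(r)$ forms a participant-specific null, and
  the observed parcels are ranked with an empirical
  $p = (1 + \#\{\text{null} \ge \text{obs}\}) / (1 + N)$.
- **Gradient vs parcel variance partition** — per voxel,
  $\Delta\mathrm{FC} = z_{\mathrm{DMN}} - z_{\mathrm{PMN}}$ is regressed on
  the longitudinal-axis coordinate (gradient model), on parcel identity
  (parcel model), and on both; each factor's semi-partial $r^2$ is the full
  model's $r^2$ minus that of the model without it, with partial $F$ tests.
- **Border ROC** — border voxels (within a 2-voxel Chebyshev radius of the
  other parcel) are compared pairwise by the correlation of their cortical
  connectivity profiles; an ROC over same- vs different-parcel pairs gives an
  AUC (= normalised Mann–Whitney $U$), tested by voxel-level label
  permutation.
- **Anatomical validation** — head/body vs tail segmentation by a posterior
  20% axis split or an externally identified coronal landmark slice, compared
  to the functional parcels with Dice coefficients.
- **Task deactivation** — a finite-impulse-response GLM (8 delta regressors
  per condition) with the deactivation contrast "mean of post-onset
  timepoints 3 and 4 over all conditions", z-scored across sessions, and a
  paired sign-flip test of DMN-vs-PMN deactivation across subjects.

## Worked example

```python
import hippoparc as hp

spec = hp.GeneratorSpec(mode="mixed", n_timepoints=2000, seed=42)
subject = hp.make_subject(spec)

include = hp.exclusion_mask(subject.atlas, subject.mask, radius_mm=20.0)
tcs = hp.network_timecourses(subject.bold_cortex, subject.atlas, include)
fc = hp.voxel_network_fc(subject.bold_hippo, tcs)

parc = hp.forced_choice(fc, pair=(1, 2))   # DMN = 1, PMN = 2
print(parc.summary())

ax = hp.axis_coordinates(subject.mask)
res = hp.AxisVariancePartition(hp.delta_fc(fc, (1, 2)), ax.coord, parc.labels).fit()
print(res.summary())
```

prints

```
Winner-take-all parcellation
  mode: forced-choice (1, 2)
  voxels: 288 (288 assigned)
  network 1:  81.2% of assigned voxels
  network 2:  18.8% of assigned voxels
Gradient vs parcel variance partition (n = 288 voxels)
  r2 gradient-only : 0.7775
  r2 parcel-only   : 0.8765
  r2 full model    : 0.9898
  semi-partial r2  : gradient 0.1133 (F(1,285) = 3159.54, p = 2.93e-156)
                     parcel   0.2123 (F(1,285) = 5922.67, p = 1.02e-192)
```

The DMN parcel occupies the anterior 81% of this subject's hippocampus (the
generating truth placed the border at 0.8 of the axis), and — because the
subject was generated in *mixed* mode — both the gradient and the parcel
factor explain variance the other cannot, each semi-partial $r^2$ being
positive with a large partial $F$.

The same analyses are available from the shell via the `hippoparc` CLI
(`simulate`, `run-all`, `parcellate`, `nullcheck`, `axis-models`,
`border-roc`, `anatomy`, `task-contrast`, `cohort-eval`); `run-all` writes
per-stage outputs, a `summary.json` and a reproducibility manifest.

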
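# dysmap

Focal and connectome-projected ("dysconnectome") voxel-wise mapping of
sparsely sampled transient-disruption data, with permutation-based
family-wise error control and a bootstrapped ROI-vs-map predictive benchmark.

Sparse stimulation loci are transformed into dense volumes in one of two
ways — a truncated 3D Gaussian density centred on each locus (focal arm), or
the locus's adjacency row in a voxel-level structural connectome, clamped and
smoothed (dysconnectome arm) — and analysed with a voxel-wise
repeated-measures general linear model: one indicator column per subject plus
a binary behaviour regressor, within-subject error correlation removed by
compound-symmetry prewhitening, one-tailed t contrasts, and peak-voxel FWE
control by maxT permutation with subjects as exchangeability blocks.
A predictive module compares the resulting maps against an a-priori ROI
parcellation (per-region Fisher exact tests, BH-FDR) as spatial priors for
classifying held-out stimulations, with bootstrapped confusion metrics and
vertically averaged ROC curves. A synthetic-data module generates cohorts,
ground-truth effect maps and distance-decay connectomes with designated
long-range bundles so that every stage is testable offline.

## Layout

| module | contents |
|---|---|
| `dysmap.volumes` | voxel grids, Gaussian kernels, smoothing, NIfTI + stimulation-table IO |
| `dysmap.records` | stimulation records and cohort helpers |
| `dysmap.focal` | point→density transform, analysis mask, behaviour counts |
| `dysmap.glm` | design build, non-sphericity whitening, voxel-wise fit, t contrasts, maxT FWE, clusters |
| `dysmap.connectome` | connectome IO, seed projection, intensity clamping, dysconnectome pipeline |
| `dysmap.predictive` | ROI assignment, Fisher/FDR, SPM-vs-ROI bootstrap evaluation, ROC/AUC |
| `dysmap.simulate` | synthetic cohorts, truth regions, connectomes, parcellations, null cohorts |
| `dysmap.pipeline` | shared end-to-end runs (`run_focal_pipeline`, `run_glm_arm`) |
| `dysmap.cli` / `dysmap.config` | `dysmap` command-line tool and YAML run configuration |

## CLI

Four subcommands share `--config cfg.yaml --out DIR --seed N --log-level L`;
every run writes `resolved_config.yaml` and `run.log` next to its outputs.

```sh
# generate a synthetic cohort (stim.tsv, truth NIfTIs, optional connectome)
dysmap simulate --sim-config sim.yaml --out sim/ --seed 1

# focal arm: t-map, FWE + uncorrected significance maps, cluster table
dysmap focal --stim sim/stim.tsv --behaviour positive_motor --out focal/

# dysconnectome arm: same outputs on the connectome grid
dysmap dysconnect --stim sim/stim.tsv --connectome sim/connectome.mtx \
    --coords sim/nodes.tsv --behaviour positive_motor --out dys/

# bootstrapped SPM-vs-ROI predictive comparison (report.json, summary.tsv)
dysmap evaluate --stim sim/stim.tsv --parcellation parc.nii.gz \
    --behaviour positive_motor --n-boot 100 --out eval/
```

Key configuration defaults: focal kernel 10 mm FWHM (truncated at 90% of the
continuous 3D mass), dysconnectome smoothing 6 mm, density-mask thresholds
1e-5 (focal) / 1e-4 (predictive), intensity clamping at the 0.1/99.9
percentiles, alpha 0.05 with 2000 permutations, uncorrected display threshold
p = 0.001, 100 bootstraps with an 80–20 split. See `dysmap/config.py` for the
full list; unknown keys are rejected by name.

## File formats

NIfTI-1 (`.nii`/`.nii.gz`) for volumes; TSV/CSV with a header
(`subject_id, x_mm, y_mm, z_mm, <behaviour flags>`) for stimulation tables;
Matrix Market (`.mtx`) plus a `node_id, x_mm, y_mm, z_mm` TSV for
connectomes; JSON/TSV for evaluation reports.
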
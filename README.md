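# mifpipe

Automated single-cell analysis of **cyclic multiplexed immunofluorescence
(mIF)** imaging. In cyclic mIF a specimen is repeatedly stained with a
few fluorescent markers, imaged over many fields of view (FOVs),
quenched, and re-imaged, building up a panel of tens of protein markers
on the same cells. The raw output — thousands of stain and
quench-background TIFFs across FOV × cycle × channel — must be aligned
(slides shift when remounted between cycles), segmented into individual
cells, and reduced to per-cell marker profiles before any biology can be
read out. `mifpipe` does that end to end, for people who run cyclic
imaging (immune profiling of biopsies, tissue atlases) and for method
developers who need a fully ground-truthed testbed.

The pipeline:

1. **Grouping & pre-processing** — collate files into the
   (FOV, cycle, channel) grid; per image: quench subtraction, 25th/99th
   percentile normalization, Gaussian denoising.
2. **Registration** — per cycle, channels are collapsed by maximum
   projection, downsampled 2×, masked to cell-sized objects, and the
   translation is the peak of the **masked normalized cross-correlation**
   averaged over three random-crop trials (outlier trials dropped). One
   FOV's shift is applied to all FOVs of the cycle.
3. **Segmentation** — a three-head U-Net-style network (numpy, trained
   with explicit backprop) labels each pixel background / cell interior /
   cell **boundary** from the CD45 + DAPI channels; the boundary class
   keeps touching cells separable. Auxiliary cell-count and auto-encoding
   heads regularize the shared encoder under the composite loss

   L = L<sub>ce</sub> + α·L<sub>jacc</sub> + λ<sub>c</sub>·L<sub>count</sub> + λ<sub>a</sub>·L<sub>auto</sub> + β·L<sub>reg</sub>

   with class-weighted cross-entropy (3× interior/boundary, a further 2×
   for boundary-predicted-as-interior), soft per-class Jaccard, squared
   count error, reconstruction MSE and L2 (defaults α=10³, λ<sub>c</sub>=10³,
   λ<sub>a</sub>=0.5, β=10⁻⁴). Interior components seed a watershed
   through the boundary ring to produce instance masks.
4. **Profiling** — per-cell mean marker intensities (background-
   subtracted scale), MAD outlier removal, log transform, per-marker
   positivity thresholds, and rule-based immune phenotyping
   (CD4+/CD8+ T cells, NK, B cells, neutrophils, macrophages, dendritic
   cells, generic CD45+ immune cells).
5. **Clustering** — UMAP embedding (optionally phenotype-supervised) and
   HDBSCAN density clusters, with per-cluster marker profiles and
   phenotype × cluster composition tables.

A first-class **synthetic-data generator** plants shifts, cell masks,
phenotypes and marker levels with exact ground truth, so every stage is
testable without microscope data.

## Worked example

Recover planted inter-cycle shifts (`python examples/02_register_cycles.py`):

```
cycle  planted (dy, dx)   estimated        error
  0    (0.0, 0.0)       (0.0, 0.0)       0 px
  1    (14.0, 4.0)      (14.0, 4.0)      0 px
  2    (6.0, 12.0)      (7.0, 12.0)      1 px
  3    (2.0, 9.0)       (2.0, 10.0)      1 px
  4    (10.0, -9.0)     (10.0, -10.0)    1 px
```

Each row is one staining cycle of a simulated specimen: the translation
planted by the generator and the estimate from trial-averaged masked
cross-correlation. Estimates are made on a 2×-downsampled grid, so odd
shifts carry a 1 px quantization error — within the accuracy needed for
single-cell readout.

Profile and phenotype 400 synthetic cells with ground-truth masks
(`python examples/04_profile_and_phenotype.py`):

```
profiled 400 cells x 16 markers
phenotype calls:
Neutrophils             100
Macrophages              88
CD4+ T cells             60
CD8+ T cells             48
B cells                  40
Immune cells             32
Dendritic cells          16
Natural killer cells     16
agreement with planted phenotypes: 100.0%
```

The marker-combination gating reproduces every planted immune population
from the rendered images alone. The other examples cover dataset
simulation (`01`), network training (`03`) and the full orchestrated
pipeline with resumable stages (`05`); a `mifpipe` CLI
(`simulate / group / register / train / segment / profile / cluster /
run`, each with `--config config.yaml`) wraps the same library calls for
shell use.

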
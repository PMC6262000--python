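# rollfish

Simulation and analysis of **rolling-circle-amplified single-molecule FISH**
(RCA-FISH) data, aimed at quantifying transcript abundance per cell in
tissue sections and tissue microarrays (TMAs).

In this assay each probe for a transcript is a set of 80 nt
oligodeoxynucleotides (ODNs): a 30 nt arm complementary to the target RNA,
a TTTT hinge, and a shared 46 nt *docking sequence* orthogonal to the
transcriptome. A barcoded padlock probe hybridizes to the docking
sequence, is ligated into a circle, and rolling-circle amplification turns
each circle into a bright diffraction-limited spot read out by a
fluorescent detection oligo. The computational questions this package
addresses are:

* **Spot calling** — maximum-intensity projection, grid stitching, white
  top-hat background suppression, and watershed labeling of spots, each
  rolling-circle product getting a unique label.
* **Cell segmentation and classification** — nucleus segmentation with
  distance-transform watershed; tumor vs non-tumor calling from two shape
  descriptors, the area/perimeter ratio *r* = A/P (µm) and roundness
  (circularity) 4πA/P², with cutoffs calibrated as median − 3·sd of
  reference tumor nuclei (defaults 4.08 and 0.46).
* **Per-cell quantification** — spots assigned to cell territories after
  expanding each territory by a 9.75 µm margin; localization fractions in
  tumor cells / other cells / outside.
* **Detection efficiency** — two spectrally distinct padlocks reading the
  same docking sequence give a colocalization fraction
  c = matched/(n_A + n_B − matched); under independent equal-efficiency
  detection, c = q/(2−q), so the per-channel efficiency is
  **q = 2c/(1+c)** (c = 0.5 → q ≈ 0.67, i.e. ~70%).
* **Biomarker positivity** — ROC screening of 100 mean-spots-per-cell
  cutoffs (0.05 to 5.00 in 0.05 steps), IHC 2+/3+ as ground-truth
  positive, Youden-optimal operating point and trapezoidal AUC.
* **Probe design** — transcript tiling, k-mer-orthogonal docking sequence
  generation, barcoded padlock and detection oligo assembly, plus a full
  invariant validator.

Because the raw microscopy data of such studies are typically not
deposited, `rollfish.simgen` generates every input with known ground
truth: tissue images (Gaussian PSF spots, two nucleus shape classes,
autofluorescent cytoplasm), two-color spot sets with independent
per-channel detection, nucleus shape measurements, and negative-binomial
TMA count tables stratified by IHC score.

## Worked example

```bash
python examples/tissue_pipeline.py
```

```
cells segmented      : 18 (7 tumor)
spots called         : 72 (truth: 78)
localization         : 92% tumor / 8% stromal / 0% outside
spots/cell median    : 8.0 (IQR 4.5-10.0, signal-positive cells)
```

A simulated tissue field with 8 tumor and 12 stromal cells (10 vs 0.5
expected spots/cell) is pushed through the full pipeline: nuclei are
segmented and classified by shape, territories derived from the
autofluorescence channel, spots called and assigned with the margin
expansion. The localization line shows that nearly all transcripts land
in tumor cells, matching the simulated contrast; the per-cell summary
uses box-plot conventions (median, 25th–75th percentiles) after excluding
zero-signal cells.

The other examples each cover one capability:

```bash
python examples/simulate_and_call_spots.py   # spot caller vs ground truth
python examples/detection_efficiency.py      # q = 2c/(1+c) estimator
python examples/tma_roc.py                   # replicate R^2 and ROC screen
python examples/design_probes.py             # 48-ODN probe set + validation
```

For instance `detection_efficiency.py` prints, for a simulated assay with
10,000 molecules at true q = 0.7: `c = 0.541, estimated q = 0.702`.

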
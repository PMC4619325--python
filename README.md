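# lcqc

Targeted quality-control screening for centroided LC-HRMS metabolomics data.

Metabolomics campaigns routinely span hundreds of injections over days or
weeks, often split across several measurement sequences. Before any serious
data processing it is worth asking a simple question: did the instrument
behave? Detector sensitivity drifts, retention times wander, and the mass
axis shifts — within a sequence and, worse, between sequences. `lcqc`
answers that question for a user-defined list of target features (QC
standards, spiked compounds, known matrix constituents): it extracts each
feature from every mzXML file, measures four basic quality parameters, and
flags each measurement with a four-zone colour code so problematic files,
features or whole sequences stand out at a glance.

**Who it is for:** analysts running LC-HRMS (e.g. Orbitrap or QTOF full-scan)
metabolomics experiments who want a fast, descriptive data-suitability check
— conventional QC-chart thinking, no multivariate machinery.

## What is measured

For every target feature (defined by a molecular formula or target *m/z*, an
ion species and an expected retention time t_R) in every file:

* **Retention time** — apex of the chromatographic peak found by a
  continuous-wavelet-transform (Ricker/Mexican-hat) ridge-line picker on the
  extracted ion chromatogram (EIC), reported with its deviation
  Δt_R = t_R,meas − t_R,ref.
* **Mass accuracy** — intensity-weighted mean *m/z* over the peak, reported
  as δ = (m/z_meas − m/z_ref)/m/z_ref × 10⁶ ppm.
* **Feature area** — trapezoidal integral of the EIC between peak
  boundaries, reported with its relative bias (%) against the mean area of
  the same feature within the same sequence (areas have no theoretical
  reference).
* **RIA** (optional) — the relative isotopolog abundance for carbon,
  area(M+1)/area(M) ≈ n_C · a(¹³C)/a(¹²C), a quick check that the data
  support carbon-number estimation.

Each deviation d is classified against three ascending limits (g, y, o):
green |d| ≤ g, yellow g < |d| ≤ y, orange y < |d| ≤ o, red |d| > o. The
default mass-accuracy scheme is (3, 5, 8) ppm; retention time (6, 12, 30) s;
area bias (20, 30, 50) %. A feature that is not found at all is a quality
failure: its cells are flagged missing/red and it is excluded from
data-based reference means.

Ion *m/z* values are electron-mass correct: [M+H]⁺ adds the proton mass
1.00727646 Da, so e.g. jasmonic acid C₁₂H₁₈O₃ (monoisotopic 210.1256 Da)
gives [M+H]⁺ = 211.1329.

## Worked example

No real data at hand? The package ships a campaign simulator that writes
centroided mzXML with known ground truth. The spec below emulates a common
failure mode: two sequences of twelve QC-standard injections, where the
second sequence has twice the detector sensitivity and a mass-axis drift
from −5 to +5 ppm across its injections.

```bash
lcqc simulate --spec campaign.json --out campaign
#  wrote 24 mzXML file(s) in 2 sequence(s) to campaign
#    sequence1: 12 files, sensitivity ×1.0, rt drift 0.0 s/file, ppm shift +0.00 → +0.00
#    sequence2: 12 files, sensitivity ×2.0, rt drift 0.0 s/file, ppm shift -5.00 → +5.00

lcqc screen \
    --sequence campaign/sequence1.csv --sequence campaign/sequence2.csv \
    --targets targets.csv --out results --ria
#  zone summary: green=132, yellow=12, orange=0, red=0, missing=0
#  results written to results
```

with `targets.csv`:

```csv
name,formula,target_mz,ion,expected_tR_min,group
Jasmonic acid,C12H18O3,,[M+H]+,21.4,
Ferulic acid,C10H10O4,,[M+H]+,14.6,
```

The twelve yellow cells are exactly the drifted injections of sequence 2
whose injected mass shift exceeds ±3 ppm — the screen flags them without
being told anything about the defect. `results/` contains the coloured
overview (`overview.html` + machine-readable `overview_zones.csv`),
per-parameter tables (`results_tR.csv`, `results_mz.csv`, `results_area.csv`,
`results_ria.csv`, `summary.csv` with per-sequence and per-category
mean/SD/RSD), and per-feature plots: EIC overlays, area/t_R/m-z-vs-order
charts with tolerance bands, and per-category boxplots. A typical detail row:

```csv
feature,ion,sequence,order_index,file,category,found,mz,ppm_error,zone_mz
Jasmonic acid,[M+H]+,sequence1,1,QCstd_01.mzXML,QCstd,True,211.13286868434096,-0.010496513512247327,green
```

Everything is also available as a library — `lcqc.screen()` runs the
same pipeline on `SequenceEntry`/`TargetFeature` objects and returns the
results as dataclasses plus a pandas summary.

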
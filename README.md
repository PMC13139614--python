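# spheroid-doct

Dynamic optical coherence tomography (DOCT) analysis pipeline for
longitudinal tumor-spheroid drug-response studies, with a dynamic-speckle
simulator so every stage can be exercised and validated without an
instrument.

## The problem

Standard OCT sees structure: it measures a spheroid's volume, which changes
only late in drug-induced cell death. DOCT instead contrasts *intracellular
motion*: each B-scan location is revisited repeatedly (here 32 frames at a
204.8 ms interval, using an interleaved 8-block × 16-location raster, 4096
frames per volume in 52.4 s), and per-voxel fluctuation statistics of the
dB-scaled intensity I(t) are computed:

- **LIV** (logarithmic intensity variance), in dB²:

      LIV = (1/N) Σᵢ ( I_dB(tᵢ) − ⟨I_dB⟩ )²

  sensitive to the fraction of backscattered power coming from moving
  scatterers.

- **OCDS_l** (late OCT correlation decay speed), in ms⁻¹: minus the
  least-squares slope of the intensity autocorrelation ρ̂(τ) over a late
  delay window (204.8–1228.8 ms), sensitive to scatterer speed within the
  window's band.

The spheroid is segmented automatically from the product
LIV(x,y,z) × I_dB(x,y,z): the well-plate surface is bright but static, so
the product suppresses it while keeping dynamic tissue (Gaussian blur →
Otsu threshold → binary erosion → connected components → hole filling and
small-object removal). Inside the mask the pipeline reports volume, mean
LIV, mean OCDS_l, and the **low-dynamics volumes** (LDV): tissue with
LIV < 3 dB² or OCDS_l < 2×10⁻⁴ ms⁻¹, read as non-viable. Time courses
across treatment arms are compared per timepoint with one-way ANOVA,
Tukey-HSD post-hoc tests gated on ANOVA significance, and Pearson
correlation for concentration–response trends.

The synthetic-data generator models each voxel's complex field as a random
phasor sum, E = √(1−f)·E_static + √f·E_dyn(t), whose ensemble
autocorrelation is g₁(τ) = (1−f) + f·e^(−τ/τc); the dynamic fraction f
drives LIV and the decorrelation time τc drives OCDS_l. Phantoms are
spheres with a viable shell, optional low-dynamics core/spots, a static
bright plate plane, and longitudinal scenarios (control / growth arrest
with expanding core / slowed growth / accumulating spots).

## Worked example

```sh
python analysis/02_simulate_phantom.py
python analysis/03_doct_maps_segment.py
```

prints (seed 11):

```
mask                   : 22366 voxels, Dice vs truth 0.955, plate overlap 0
volume                 : 2.796e+06 um^3
mean LIV / LIV-LDV     : 20.52 dB^2 / 5.298e+05 um^3 (18.9% of volume; generated core 17.3%)
mean OCDS_l / LDV      : 4.34e-04 ms^-1 / 6.102e+05 um^3
```

The phantom is a 180 µm-radius spheroid with a 50 µm-radius low-dynamics
core on a static plate. The segmentation recovers the sphere (Dice 0.955)
without touching the plate, the mean LIV of mostly-viable tissue sits far
above the 3 dB² cut-off, and the LIV-LDV fraction (18.9 %) recovers the
generated core fraction (17.3 %).

The other analysis drivers follow the same pattern: `01_protocol_timing.py`
(acquisition arithmetic and study grids), `04_longitudinal_study.py`
(four-arm longitudinal run with ANOVA/Tukey reports), and
`05_early_detection_power.py` (the dynamics-before-morphology power
experiment). A `spheroid-doct` CLI exposes the stages
(`simulate | metrics | segment | quantify | timecourse | report`) on TIFF
stacks with JSON sidecars.

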
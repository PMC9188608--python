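# Methods

## Scope and model

The toolkit implements a monthly phantom-based QC protocol for in vivo
micro-CT and the downstream lung-densitometry analysis that a scanner
drift corrupts. All quantities live on the scanner's native grey-level
scale (no Hounsfield conversion): the protocol's whole point is to
monitor the *absolute* grey anchors (water ≈ 2000, air ≈ 449 on the
reference system) on which threshold-based lung segmentation depends.

Volumes are 3D voxel grids `[z, y, x]` with per-axis spacing in mm
(isotropic 0.05 mm default, the reconstructed voxel size of the
reference scanner), voxel-center physical coordinates, and 0-based
indices. NIfTI, multipage TIFF (+ YAML sidecar), and raw little-endian
binary (+ mandatory sidecar) are supported; integer grids round-trip
bit-exactly, and geometry survives to full precision in sidecar formats
and to float32 header precision in NIfTI.

## QC statistics

* ROI membership: a voxel belongs to a circular ROI iff its center lies
  inside the circle — deterministic, no partial-area weighting.
* All SDs use the sample (n−1) convention, including the per-slice noise
  SD and the baseline tolerance width; baselines are small-n estimates
  (five scans) and the sample convention is the defensible default.
* Noise / water / air are means over the five-slice protocol window;
  strict mode enforces the 5- and 100-slice windows, a lenient flag
  permits exploratory counts with a warning.
* Uniformity divides the peripheral sum by the number of peripheral
  ROIs (four). Peripheral ROI centers sit at 60 % of the phantom radius
  (0°/90°/180°/270°), all five ROIs sharing the central ROI's radius —
  positions are only shown graphically in the protocol's maps, and this
  choice keeps every ROI well inside the water.
* Low-contrast insert ROIs use 70 % of the insert diameter, keeping the
  measurement clear of the partial-volume rim; the background ROI sits
  on the phantom axis and the air ROI outside the phantom, as the
  protocol places them for this test.
* MTF is measured from line profiles crossing each bar pattern
  perpendicular to the bars. Plateau ("background") and valley ("bars")
  samples are separated by thresholding at the profile midrange
  (robust 2nd/98th-percentile extremes), discarding samples within a
  guard band of each crossing; the guard shrinks automatically when the
  bars are so narrow that it would swallow a whole class. Three
  parallel profiles at one-voxel offsets are averaged, standing in for
  repeated manual measurements. Only in-plane resolution is computed.

## Baselines and charts

Baseline BL = mean of five consecutive scans, tolerance width = 2 × SD,
range = BL ± width, closed interval (a value exactly on a bound is
within). The clinical BL ± 20 % noise rule is available as an explicit
comparison mode, off by default — the 2·SD band is what makes subtle
drifts visible. Dates are ordinal month labels; charts require strictly
increasing dates and serialize to CSV/JSON with exact float round-trip.

## Synthetic phantoms and study conditions

The generator emulates the three phantoms with exact ground truth:

* grey anchors 2000 (water), 449 (air), 1800 (resin/chip material);
* additive iid Gaussian noise, default SD 124 — the reference noise
  level (CT noise correlation is out of scope);
* isotropic Gaussian system blur, σ = 0.04 mm, chosen so the synthetic
  bar-pattern MTF falls from ≈ 50 % at 3.3 lp/mm to ≈ 23 % at 10 lp/mm,
  the regime of a 50 µm-voxel system;
* water-phantom radial non-uniformity g·(r − r_ref), with r_ref the mean
  radius of the standard central ROI so the configured water grey is
  what the water test reads regardless of g. The healthy-scanner default
  g = 6.25 grey/mm reproduces the reference uniformity anchor −41; the
  factor between g and the uniformity reading (−6.564 mm) is the exact
  difference of disk-averaged radii for the standard ROI layout;
* low-contrast insert greys satisfy
  m_k = m_air + (1 − c/100)(m_bg − m_air), so a noiseless measurement
  returns the nominal contrast level exactly — consistent with the
  measurement formula, and with baselines observed to sit near the
  nominal levels on real systems;
* bar patterns with line width 1/(2f) (150/100/50 µm), rasterized with
  exact 1D area coverage so sub-voxel lines are antialiased rather than
  aliased.

Toy lungs are two ellipsoidal fields (semi-axis ratio 1 : 1.3 : 1.7)
joined by a 0.4 mm airway bridge so the truth mask is one connected
component, embedded in soft tissue (1600 ± 50). The parenchyma
distribution is Gaussian for skew 0 and a moment-matched shifted gamma
otherwise (defaults mean 850, SD 130, skewness 2.3 — the healthy-lung
regime between air and water). The truth mask is trimmed to the exact
voxel count implied by the target volume (default 532 mm³, a healthy
total lung volume), and seeds change only the voxel noise, never the
geometry. Note a limitation of any single-distribution lung model: the
summary pair (skewness 2.3, kurtosis 4.2) reported for healthy-lung
histograms violates the moment inequality kurtosis ≥ skewness² + 1, so
the generator matches mean/SD/skewness and lets kurtosis follow
(≈ 10.9 for the gamma).

Drift injection adds a grey shift everywhere plus independent noise of
SD σ·(scale − 1); the total noise is σ·√(1 + (scale − 1)²). The
rehearsal's drifted month uses shift +174, noise scale 1.44 (measured
noise ≈ 135), and a deepened gradient 16.15 grey/mm (uniformity ≈ −106),
reproducing the reference drift episode.

## The drift rehearsal

`run_drift_rehearsal` simulates a campaign (default 13 months, drift in
the last). Baselines are anchored on a noiseless reference acquisition
of the same synthetic scanner (the noise BL is the configured noise
level), with tolerance widths from the packaged reference-chart presets
(water ±17, air ±33, noise ±2, uniformity ±22, contrast ±3/±1/±1,
MTF ±19/±17/±14). A 2·SD band recomputed from five scans whose only
variability is ROI estimation error would have roughly 14 % per-point
false-alarm probability (the small-n Student-t coverage problem), so the
preset widths — which on a real scanner absorb genuine session-to-session
variability — define the simulated study conditions; `compute_baseline`
remains the tool for commissioning a real system.

## Lung analysis

Segmentation is a fixed grey window restricted to the largest
26-connected component — a documented stand-in for semi-automatic
protocols, sharing their essential property of fixed thresholds.
AUC = masked voxel count × voxel volume (mm³, the total segmented lung
volume, independent of binning); skewness and kurtosis are computed on
the raw masked voxel values with bias-corrected estimators; kurtosis is
Pearson (normal = 3), the convention consistent with healthy-lung values
near 4. Histogram bin width defaults to 25 grey levels. Group comparison
uses Shapiro–Wilk normality per group, one-tailed unpaired t for AUC
(direction: after < before, the drift narrative; configurable),
two-tailed unpaired t for kurtosis, Mann–Whitney for skewness, α = 0.05.

## Numerical choices and problem sizes

* Voxel statistics are accumulated in float64; generated volumes are
  stored float32 (quantization ≪ 1 grey at the working scale).
* The rehearsal and tests run at scaled spacings chosen as the
  package's own problem sizes: water and low-contrast phantoms at
  0.1 mm (ROIs of 10³–10⁵ voxels), the bar phantom at 0.05 mm (≥ 1 voxel
  per 50 µm line), noise-recovery studies at 0.2 mm (ROI ≈ 2000 voxels
  per slice, 5 slices), toy lungs at 0.1 mm (≈ 5 × 10⁵ parenchyma
  voxels). The protocol-spacing (0.05 mm) lung is exercised once to
  verify the exact voxel-count contract (4,256,000 voxels for 532 mm³).
* Degenerate inputs raise typed errors: sub-voxel ROIs, inverted or
  empty threshold windows, background = air contrast denominators,
  constant line profiles, out-of-order chart dates.
* Ties at tolerance bounds count as within (closed interval).

## Known limitations

* Noise is spatially white; real CT noise is correlated and its ROI-SD
  statistics would be wider than the χ² bands used here.
* The system PSF is a single isotropic Gaussian; real MTF curves have
  detector and reconstruction structure the bar-modulation ratio cannot
  see.
* The lung model has no airways below the single bridge, no vasculature,
  no gravity-dependent aeration gradient; passing tests demonstrate the
  *mechanics* of threshold densitometry under drift, not biological
  realism.
* Phantom layouts are configured, not detected: there is no registration
  of ROI maps to a scanned phantom's actual position.
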
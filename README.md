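# pbtrack

Integrated-mode proton radiography simulation and moving-target tracking.

## The problem

Lung tumors move with breathing, and proton therapy is particularly sensitive
to that motion: a few millimetres of displacement changes the water-equivalent
thickness (WET) along the beam and shifts the Bragg peak in depth.  One
proposed way to watch the tumor *during* treatment is to image it with the
treatment beam itself: raise the energy so the pencil beams traverse the
patient, stop them in a monolithic scintillator, and read the residual range
of every beam from the depth of its Bragg peak in the camera images.  Each
scanned frame then yields a 2-D WET radiograph in which a water-equivalent
tumor sits on a low-density lung background with strong contrast, and its
centroid can be tracked frame by frame — no implanted markers, no extra
imaging dose beyond the radiograph itself.

`pbtrack` implements that measurement chain end to end as a simulation and
analysis library for medical-physics researchers:

- **scene** — phantoms (anthropomorphic thorax with a spherical insert; PMMA
  slab lung model) as geometric primitives with relative stopping powers
  (RSP), answering WET line-integral queries at any time `t` while the insert
  follows a periodic waveform `y(t)`;
- **acquisition** — timestamped pencil-beam scan patterns (serpentine
  horizontal/vertical, spiral, interleaved multi-pass) and synthetic
  scintillator camera views per beam: Gaussian beam footprint, analytic Bragg
  depth-light curve with range straggling, cos⁴ vignetting, camera noise;
- **signal** — optics correction, pristine-peak extraction per camera column,
  and conversion `WET = R₀ − depth · RSP_scint`;
- **recon** — weighted Gaussian back projection of the per-beam WET samples
  into per-frame radiographs, timestamped at the median beam time;
- **tracking** — strip-wise Otsu segmentation (11 horizontal strips, each
  thresholded independently), largest-component mask, binary centroid, and the
  MAE ± σ comparison against the programmed motion;
- **artifacts** — the scan-pattern/motion interplay study, quantifying shape
  distortion by the eccentricity of the moment ellipse of the segmented
  sphere;
- **runner** — YAML-configurable end-to-end experiments, multi-seed
  replication of the positional-accuracy study, and a thin `pbtrack` CLI.

## The core quantities

A pencil beam of water-equivalent range `R₀ = α E^p` that traverses material
of water-equivalent thickness `WET` stops at scintillator depth
`d = (R₀ − WET)/RSP_scint`; inverting the measured peak depth gives the WET
image value.  The programmed insert motion is the breathing-like waveform

    y(t) = (A/2) · (1 − cos 2πt/T)        (peak-to-peak excursion A, period T)

and tracking accuracy is summarised as `MAE ± σ`, the mean and standard
deviation of the per-frame absolute differences between the mask centroid and
`y(t_frame)` (both expressed as offsets from the field centre, with the field
centred on the time-averaged insert position and `t_frame` the median beam
timestamp of the frame).  Shape distortion from beam-scanning/motion
interplay is quantified by the moment-ellipse eccentricity
`e = √(1 − (b/a)²)` of the segmented sphere.

## Worked example

```bash
python examples/04_track_moving_insert.py
```

simulates twenty 1.4 s frames of a 30 mm insert moving with 20 mm
peak-to-peak excursion and a 24 s period over a 9 × 5 cm field (5 mm spot
spacing, 209 beams per frame) and prints the per-frame comparison:

```
 frame_index  timestamp_s  measured_offset_mm  expected_offset_mm  abs_error_mm
           0        0.697              -9.891              -9.834         0.057
           1        2.097              -8.531              -8.531         0.000
           ...
          19       27.297              -6.468              -6.501         0.033

MAE = 0.036 +- 0.021 mm over 20 frames
```

The measured centroid follows the programmed ±10 mm excursion with a mean
absolute error of a few hundredths of a millimetre in this idealised setting;
shorter motion periods and smaller inserts degrade the accuracy through
interplay artifacts and undersampling (`examples/05_interplay_artifacts.py`
quantifies the distortion each scan pattern produces).  Other examples cover
WET queries on the phantoms, the single-beam range round trip, and frame
reconstruction.

## Command line

```bash
pbtrack track -c config.yaml -o out/      # full tracking run from a YAML config
pbtrack simulate -c config.yaml -o out/   # write reconstructed WET frames (TIFF)
pbtrack artifacts -o artifacts.csv        # scan-pattern interplay study
pbtrack table1 --seeds 10                 # multi-seed accuracy replication
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
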
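"""Track a moving 30 mm insert through 20 radiograph frames.

Each frame is segmented with strip-wise Otsu thresholding; the mask centroid
gives the measured lateral offset, compared against the programmed waveform
at the frame's median-beam timestamp.  The summary statistic is the mean
absolute error (MAE) +- the standard deviation of the per-frame errors.
"""

from pbtrack import runner

config = runner.ExperimentConfig(
    insert_diameter=30.0,  # mm sphere in the lung
    amplitude=20.0,        # mm peak-to-peak lateral excursion
    period=24.0,           # s breathing period
    frame_time=1.4,        # s per 209-spot frame (9 x 5 cm field, 5 mm spots)
    n_frames=20,
    seed=1,
)
report = runner.run_experiment(config, keep_frames=False)

df = report.result.per_frame
print(df.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
print(f"\nMAE = {report.result.mae:.3f} +- {report.result.sigma:.3f} mm over "
      f"{len(df)} frames")
print("Each row compares the centroid of the segmented insert (measured) with "
      "the programmed position (expected); sub-millimetre MAE means the "
      "radiographs resolve the breathing motion frame by frame.")
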
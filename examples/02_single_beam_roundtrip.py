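"""Simulate one pencil beam and recover the WET it traversed.

The beam deposits a Bragg depth-light curve in the scintillator; the depth of
the pristine peak encodes the residual range, hence the upstream WET:
WET = R0 - depth x RSP_scint.
"""

import numpy as np

from pbtrack import acquisition as acq
from pbtrack import scene
from pbtrack import signal as sig

beam = acq.BeamModel()  # 230 MeV, 7.8 mm FWHM, scintillator RSP 1.043
print(f"beam range R0 = {beam.range_R0:.1f} mm water (alpha E^p power law)")

phantom = scene.build_slab_phantom()
true_wet = scene.wet_line_integral(phantom, (0, 0, -500), (0, 0, 1))

record = acq.simulate_pencil_beam(phantom, None, beam, spot=(0.0, 0.0),
                                  rng=np.random.default_rng(0))
top = record.views["top"]
print(f"top view: {top.pixels.shape} pixels of {top.pixel_size} mm")

samples = sig.beam_wet_samples(record, beam)
est = samples["wet"].mean()
print(f"true WET  : {true_wet:.2f} mm")
print(f"estimated : {est:.2f} mm  ({samples.size} lateral samples)")
print(f"error     : {est - true_wet:+.3f} mm for one beam with camera noise; "
      "hundreds of beams per frame average this down to the sub-millimetre "
      "image accuracy that makes millimetre tracking possible")
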
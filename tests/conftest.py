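import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))

from slicereg.phantom import PhantomSpec, RespirationModel, make_ct_phantom, simulate_us_sequence


def small_breathing_sample(seed=0, n_frames=9, base_pose=None, period=6):
    """A small-grid breathing phantom, cheap enough for unit tests."""
    spec = PhantomSpec(shape=(16, 24, 32), spacing=3.2,
                       semi_axes_mm=np.array([12.0, 18.0, 30.0]), asymmetry=1.0)
    ct, mask = make_ct_phantom(spec, seed=seed)
    resp = RespirationModel(period=period,
                            translation_amplitude_mm=np.array([0.3, 0.8, 3.0]),
                            rotation_amplitude_deg=np.array([1.0, 0.3, 0.3]))
    return simulate_us_sequence(ct, mask, resp, n_frames=n_frames, seed=seed,
                                base_pose=base_pose)
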
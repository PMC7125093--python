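"""From a raw epoch to the 8-feature channel block, step by step.

One channel of one epoch is decomposed by empirical mode decomposition; the
two intrinsic mode functions closest to the original signal (Minkowski
distance) are kept, and each is summarized by four features: instantaneous
energy, Teager energy, Higuchi fractal dimension and Petrosian fractal
dimension.
"""

import numpy as np

from eegselect import extract_channel_features, select_imfs_minkowski
from eegselect.features import FEATURE_NAMES, decompose

rng = np.random.default_rng(0)
t = np.arange(200) / 200.0  # one second at 200 Hz
signal = (6.0 * np.sin(2 * np.pi * 21 * t)       # fast personal rhythm
          + 9.0 * np.sin(2 * np.pi * 8 * t)      # slow personal rhythm
          + 1.0 * rng.standard_normal(200))      # measurement noise

imfset = decompose(signal)
print(f"number of IMFs:      {imfset.n_imfs}")
print(f"reconstruction err:  {imfset.reconstruction_error():.2e}")
first, second = select_imfs_minkowski(imfset)
print(f"selected IMFs:       {first} then {second} (closest to the signal)")

block = extract_channel_features(signal)
print("\n8-feature channel block:")
for name, value in zip(FEATURE_NAMES, block):
    print(f"  {name:32s} {value: .4f}")

# The energies are log10-scaled (0.0 means unit mean-square amplitude); the
# fractal dimensions lie between 1 (smooth curve) and 2 (space-filling
# noise).  Concatenating such blocks over the selected channels yields the
# instance vector fed to the classifiers.
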
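"""Constructive gaze fixtures shared across test modules."""

import numpy as np

from pdcflow.synthetic import mode_following_gaze_dataset as mode_following_dataset  # noqa: F401


def grid_mode(density):
    g = density.grid_size
    i, j = np.unravel_index(np.argmax(density.values), density.values.shape)
    return ((i + 0.5) / g, (j + 0.5) / g)
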
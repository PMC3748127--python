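"""Fixed 12-direction diffusion-encoding table.

Unit vectors obtained once by electrostatic repulsion of 12 antipodally
symmetrized points on the sphere and frozen here, so every simulation and
fit uses the same documented set.  Condition number of the corresponding
rank-6 tensor design matrix is 1.58.
"""

from __future__ import annotations

import numpy as np

TWELVE_DIRECTIONS = np.array(
    [
        (-0.841628, -0.151509, +0.518370),
        (-0.675233, +0.715384, +0.179685),
        (-0.457244, +0.352099, +0.816672),
        (-0.357099, -0.626687, +0.692635),
        (-0.269278, -0.960509, +0.070081),
        (-0.045752, +0.851058, +0.523074),
        (+0.029120, -0.122436, +0.992049),
        (+0.338648, -0.825889, +0.450804),
        (+0.480927, +0.446883, +0.754324),
        (+0.665557, -0.255279, +0.701332),
        (+0.817668, +0.562006, +0.124771),
        (+0.982631, -0.150600, +0.108422),
    ]
)
TWELVE_DIRECTIONS = TWELVE_DIRECTIONS / np.linalg.norm(
    TWELVE_DIRECTIONS, axis=1, keepdims=True
)
TWELVE_DIRECTIONS.setflags(write=False)
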
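"""Numba-compiled direct 3x3x3 convolution (channels-last layout).

Used for convolutions with very few input channels (the first layer of
each network), where a BLAS formulation is dominated by the memory
traffic of materializing per-tap products; everywhere else ``net3d``
uses BLAS tap loops.  Falls back transparently when numba is missing.

Loop order is fixed, so results are deterministic run to run.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def conv3_forward(xp, W, b, out):  # pragma: no cover - exercised via net3d
    """out[n,x,y,z,:] = b + sum_d xp[n,x+dx,y+dy,z+dz,:] @ W[dx,dy,dz]."""
    n = xp.shape[0]
    cin = xp.shape[4]
    X, Y, Z, cout = out.shape[1], out.shape[2], out.shape[3], out.shape[4]
    acc = np.empty(cout, dtype=np.float32)
    for ni in range(n):
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    for o in range(cout):
                        acc[o] = b[o]
                    for dx in range(3):
                        for dy in range(3):
                            for dz in range(3):
                                v = xp[ni, x + dx, y + dy, z + dz]
                                Wt = W[dx, dy, dz]
                                for c in range(cin):
                                    vc = v[c]
                                    for o in range(cout):
                                        acc[o] += vc * Wt[c, o]
                    for o in range(cout):
                        out[ni, x, y, z, o] = acc[o]
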
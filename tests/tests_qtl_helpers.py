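"""Shared builders for mapping tests."""
import numpy as np
import pandas as pd

from lobeqtl.genotyping import B, H, MarkerMatrix
from lobeqtl.qtl import haldane_r


def marker_matrix(calls, chroms=None, is_x=None, spacing=250_000):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "name": [f"m{j}" for j in range(m)],
            "chrom": chroms or ["2L"] * m,
            "start": np.arange(m) * spacing,
            "end": (np.arange(m) + 1) * spacing,
            "mid": np.arange(m) * spacing + spacing // 2,
            "is_x": is_x if is_x is not None else [False] * m,
        }
    )
    return MarkerMatrix(
        samples=[f"s{i}" for i in range(n)],
        roles=np.array(["rec"] * n),
        sex=np.array(["M"] * n),
        calls=calls,
        markers=markers,
    )


def informative_matrix(rng, n=120, m=6, spacing_cm=10.0):
    """Fully observed intercross genotypes from a two-gamete chain."""
    r = haldane_r(spacing_cm)
    gam = np.zeros((2, n, m), dtype=int)
    for g in range(2):
        gam[g, :, 0] = rng.random(n) < 0.5
        for j in range(1, m):
            flip = rng.random(n) < r
            gam[g, :, j] = np.where(flip, 1 - gam[g, :, j - 1], gam[g, :, j - 1])
    calls = (gam[0] + gam[1]).astype(np.int8)
    calls[calls == 1] = H
    calls[calls == 2] = B
    return marker_matrix(calls), gam
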
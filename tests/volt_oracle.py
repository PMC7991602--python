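"""Independent brute-force oracle for the local-threshold ensemble.

Recomputes, for every voxel and every classifier configuration, the window
statistics directly from the raw window contents (nan-aware slicing), with
no shared code with the production implementation beyond the tie rule.
"""

import numpy as np

from hydroquant.volt import TIE_TOL


def brute_force_votes(data, axis, algorithm, radius, k=-0.2, offset=0.0):
    """Reference slicewise local-threshold votes for one configuration."""
    data = np.asarray(data, dtype=np.float64)
    votes = np.zeros(data.shape, dtype=bool)
    in_slice_axes = [a for a in range(3) if a != axis]
    for idx in np.ndindex(data.shape):
        x = data[idx]
        if not np.isfinite(x):
            continue
        window_sel = [None, None, None]
        window_sel[axis] = slice(idx[axis], idx[axis] + 1)
        for a in in_slice_axes:
            window_sel[a] = slice(max(idx[a] - radius, 0), idx[a] + radius + 1)
        window = data[tuple(window_sel)]
        vals = window[np.isfinite(window)]
        mu = vals.mean()
        if algorithm == "niblack":
            t = mu + k * vals.std()
        else:
            t = mu + offset
        votes[idx] = x < t - TIE_TOL
    return votes


def brute_force_aggregation(data, cfg):
    """Sum of brute-force votes over every configuration of ``cfg``."""
    total = np.zeros(np.asarray(data).shape, dtype=np.uint8)
    for ax, algo, r in cfg.provenance():
        total += brute_force_votes(
            data, ax, algo, r, k=cfg.niblack_k, offset=cfg.mean_offset
        )
    return total
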
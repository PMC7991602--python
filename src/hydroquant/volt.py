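"""VOLT: volumetric local thresholding of the fusion volume.

The ensemble runs slicewise 2D local thresholding along the three grid
axes, with two algorithms (Niblack and local mean) at two window radii,
giving 2 x 2 x 3 = 12 binary classifications.  Endolymph is dark on the
HYDROPS-Mi2 fusion image, so a voxel votes "endolymph" when its intensity
falls strictly below the local threshold

* Niblack:    t = mu_w + k * sigma_w
* local mean: t = mu_w + offset

computed over a (2r+1) x (2r+1) window in the slice.  Sentinel (outside
hull) voxels never vote and are excluded from the window statistics;
windows are clipped at slice borders (no padding values are invented).
Votes are summed into an aggregation volume in a fixed provenance order;
voxels with at least ``vote_cutoff`` (default 11) of 12 votes inside the
hull are classified endolymph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import BinaryHull
from .volume import Volume

__all__ = [
    "VoltConfig",
    "AggregationVolume",
    "ElsMask",
    "TIE_TOL",
    "local_threshold_slicewise",
    "aggregate",
    "classify_els",
    "split_compartments",
    "run_volt",
]

# a voxel votes only when clearly below the threshold; breaks the tie on
# constant windows toward background and keeps the ensemble bit-stable
TIE_TOL = 1e-6


@dataclass
class VoltConfig:
    niblack_k: float = -0.2
    mean_offset: float = 0.0
    window_radii: tuple[int, ...] = (6, 10)
    orientations: tuple[int, ...] = (0, 1, 2)
    vote_cutoff: int = 11
    use_3d_windows: bool = False  # cubic windows instead of slicewise squares

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.window_radii):
            raise ValueError("window radii must be positive integers")
        n = self.n_classifiers
        if not 1 <= self.vote_cutoff <= n:
            raise ValueError(f"vote cutoff {self.vote_cutoff} outside [1, {n}]")

    @property
    def n_classifiers(self) -> int:
        return 2 * len(self.window_radii) * len(self.orientations)

    def provenance(self) -> list[tuple[int, str, int]]:
        """Fixed classifier order: (axis, algorithm, radius)."""
        return [
            (axis, algo, r)
            for axis in self.orientations
            for algo in ("niblack", "mean")
            for r in self.window_radii
        ]


@dataclass
class AggregationVolume:
    votes: Volume  # integer vote counts
    provenance: list[tuple[int, str, int]] = field(default_factory=list)

    @property
    def max_votes(self) -> int:
        return len(self.provenance)


@dataclass
class ElsMask:
    mask: Volume  # boolean, endolymph classification
    cochlear: Volume | None = None
    vestibular: Volume | None = None

    def volume_mm3(self, which: str = "mask") -> float:
        v: Volume = getattr(self, which)
        return float(np.count_nonzero(v.data)) * v.voxel_volume_mm3


def _window_size(axis: int, radius: int, use_3d: bool) -> tuple[int, int, int]:
    w = 2 * radius + 1
    if use_3d:
        return (w, w, w)
    size = [w, w, w]
    size[axis] = 1
    return tuple(size)  # type: ignore[return-value]


def local_threshold_slicewise(
    fused: Volume,
    axis: int,
    algorithm: str,
    radius: int,
    k: float = -0.2,
    offset: float = 0.0,
    use_3d: bool = False,
) -> Volume:
    """One member of the ensemble: a binary endolymph-vote volume.

    Window statistics are computed as masked means/variances so that
    sentinel voxels and out-of-border regions contribute nothing.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if algorithm not in ("niblack", "mean"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    slice_dims = [fused.shape[a] for a in range(3) if a != axis]
    if radius > max(slice_dims):
        raise ValueError(
            f"window radius {radius} exceeds slice extent {tuple(slice_dims)}"
        )
    data = np.asarray(fused.data, dtype=np.float64)
    valid = np.isfinite(data)
    x = np.where(valid, data, 0.0)
    m = valid.astype(np.float64)
    size = _window_size(axis, radius, use_3d)
    nw = float(np.prod(size))
    cnt = ndimage.uniform_filter(m, size=size, mode="constant", cval=0.0) * nw
    s1 = ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * nw
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0.5, s1 / np.maximum(cnt, 1.0), 0.0)
        if algorithm == "niblack":
            s2 = ndimage.uniform_filter(x * x, size=size, mode="constant", cval=0.0) * nw
            var = np.maximum(s2 / np.maximum(cnt, 1.0) - mean**2, 0.0)
            thresh = mean + k * np.sqrt(var)
        else:
            thresh = mean + offset
    votes = valid & (data < thresh - TIE_TOL)
    return fused.with_data(votes)


def aggregate(classifications: list[Volume], provenance=None) -> AggregationVolume:
    """Voxelwise sum of the ensemble votes (order-independent)."""
    if provenance is not None and len(classifications) != len(provenance):
        raise ValueError(
            f"expected {len(provenance)} classifications, got {len(classifications)}"
        )
    if not classifications:
        raise ValueError("no classifications to aggregate")
    ref = classifications[0]
    acc = np.zeros(ref.shape, dtype=np.uint8)
    for c in classifications:
        ref.require_same_grid(c, "aggregation inputs")
        acc += np.asarray(c.data, dtype=bool)
    return AggregationVolume(
        votes=ref.with_data(acc), provenance=list(provenance or [])
    )


def classify_els(agg: AggregationVolume, cfg: VoltConfig, hull: BinaryHull) -> ElsMask:
    """Threshold the vote map: endolymph where votes >= cutoff, within hull."""
    n = agg.max_votes or cfg.n_classifiers
    if not 1 <= cfg.vote_cutoff <= n:
        raise ValueError(f"vote cutoff {cfg.vote_cutoff} outside [1, {n}]")
    mask = (np.asarray(agg.votes.data) >= cfg.vote_cutoff) & np.asarray(
        hull.mask.data, dtype=bool
    )
    return ElsMask(mask=agg.votes.with_data(mask))


def run_volt(fused: Volume, cfg: VoltConfig, hull: BinaryHull) -> tuple[AggregationVolume, ElsMask]:
    """Run the full ensemble on a fusion volume."""
    prov = cfg.provenance()
    members = [
        local_threshold_slicewise(
            fused, axis, algo, r, k=cfg.niblack_k, offset=cfg.mean_offset,
            use_3d=cfg.use_3d_windows,
        )
        for axis, algo, r in prov
    ]
    agg = aggregate(members, prov)
    els = classify_els(agg, cfg, hull)
    return agg, els


def split_compartments(
    els: ElsMask,
    compartment_labels: Volume | None = None,
    boxes: dict[str, tuple[slice, slice, slice]] | None = None,
) -> ElsMask:
    """Assign ELS voxels to cochlea / vestibule.

    Either ground-truth compartment labels (phantoms; 1 = cochlea,
    2 = vestibule) or crop boxes stand in for the manual 3D cropping done
    on patient data.  Voxels in neither region are dropped from compartment
    totals but kept in the whole-ear mask.
    """
    mask = np.asarray(els.mask.data, dtype=bool)
    if compartment_labels is not None:
        els.mask.require_same_grid(compartment_labels, "ELS vs compartments")
        comp = np.asarray(compartment_labels.data)
        coch = mask & (comp == 1)
        vest = mask & (comp == 2)
    elif boxes is not None:
        coch_box = np.zeros(mask.shape, dtype=bool)
        vest_box = np.zeros(mask.shape, dtype=bool)
        if "cochlea" in boxes:
            coch_box[boxes["cochlea"]] = True
        if "vestibule" in boxes:
            vest_box[boxes["vestibule"]] = True
        if (coch_box & vest_box).any():
            raise ValueError("cochlear and vestibular crop boxes overlap")
        coch = mask & coch_box
        vest = mask & vest_box
    else:
        raise ValueError("either compartment labels or crop boxes are required")
    return ElsMask(
        mask=els.mask,
        cochlear=els.mask.with_data(coch),
        vestibular=els.mask.with_data(vest),
    )
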
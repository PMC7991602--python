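"""Shared fixtures: a reduced phantom configuration for fast end-to-end runs.

The reduced configuration keeps the physical window sizes, crop semantics
and intensity model of the default pipeline but rasterizes at 0.5 mm
without upsampling (window radii 3/5 voxels = the default 6/10 at the
upsampled 0.25 mm resolution), so a full subject runs in about a second.
"""

from __future__ import annotations

import numpy as np
import pytest

from hydroquant.hydrops import PreprocessConfig, preprocess_triplet
from hydroquant.metrics import compute_els_measures
from hydroquant.phantom import (
    CochleaSpec,
    PhantomSpec,
    VestibuleSpec,
    build_labyrinth,
    simulate_sequences,
)
from hydroquant.segmentation import (
    build_atlas,
    dilate_hull,
    extract_hull,
    fuse,
    register_affine,
    RegistrationConfig,
    resample_atlas,
)
from hydroquant.volt import VoltConfig, run_volt, split_compartments

SMALL_GRID = (36, 26, 52)
SMALL_CROP = (16.0, 11.0, 25.0)


def make_small_spec(
    vest_frac=(0.35, 0.35),
    coch_frac=(0.25, 0.25),
    noise_sd: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    spec = PhantomSpec(
        grid_shape=SMALL_GRID,
        voxel_size_mm=0.5,
        ear_separation_mm=16.0,
        vestibule=VestibuleSpec(endolymph_fraction=tuple(vest_frac)),
        cochlea=CochleaSpec(endolymph_fraction=tuple(coch_frac)),
        seed=seed,
    )
    spec.intensity.noise_sd = {s: float(noise_sd) for s in ("mrc", "ppi", "pei")}
    return spec


def small_preprocess_config() -> PreprocessConfig:
    return PreprocessConfig(crop_size_mm=SMALL_CROP, rescale_factor=1)


def small_volt_config(**kw) -> VoltConfig:
    kw.setdefault("window_radii", (3, 5))
    return VoltConfig(**kw)


def run_small_pipeline(spec: PhantomSpec, register: bool = True, reg_seed: int = 0):
    """Phantom -> measures on the reduced configuration; returns a dict of
    every intermediate for inspection."""
    truth = build_labyrinth(spec)
    triplet = simulate_sequences(truth, spec)
    pre = preprocess_triplet(
        triplet.mrc, triplet.ppi, triplet.pei, small_preprocess_config()
    )
    atlas = build_atlas([truth])
    if register:
        params = register_affine(
            atlas, pre.mrc, RegistrationConfig(seed=reg_seed, shrink_factors=(2, 1))
        )
    else:
        from hydroquant.pipeline import _identity_params

        params = _identity_params(pre.mrc)
    atlas_mask = resample_atlas(atlas, params, pre.mrc)
    hull = extract_hull(pre.mrc, atlas_mask)
    fused = fuse(dilate_hull(hull, 1), pre.mi2)
    agg, els = run_volt(fused, small_volt_config(), hull)
    truth_proc = build_labyrinth(
        spec, grid=(pre.mi2.shape, pre.mi2.voxel_size, pre.mi2.origin)
    )
    split = split_compartments(els, compartment_labels=truth_proc.as_volume("compartment"))
    measures = compute_els_measures(
        split, hull, truth_proc.as_volume("compartment"), leading_side="right"
    )
    return {
        "truth": truth,
        "triplet": triplet,
        "pre": pre,
        "atlas": atlas,
        "hull": hull,
        "fused": fused,
        "agg": agg,
        "els": split,
        "truth_proc": truth_proc,
        "measures": measures,
    }


@pytest.fixture(scope="session")
def small_noise_free():
    """One noise-free subject run end-to-end (shared; do not mutate)."""
    return run_small_pipeline(make_small_spec(noise_sd=0.0, seed=1), register=False)


@pytest.fixture(scope="session")
def small_truth():
    return build_labyrinth(make_small_spec(noise_sd=0.0, seed=1))
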
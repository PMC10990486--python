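"""Shared fixtures: stimulus designs and movie-ready populations."""

import dataclasses

import numpy as np
import pytest

from binocombine import synthetic_data as sd


@pytest.fixture(scope="session")
def design():
    return sd.build_stimulus_design()


@pytest.fixture(scope="session")
def tiny_design():
    """A 2-condition, 4-trial design that keeps rendered movies small."""
    return sd.build_stimulus_design({
        "orientations_deg": (0.0, 90.0),
        "spatial_frequencies_cpd": (1.0,),
        "sizes_low_sf": (0.64,),
        "sizes_high_sf": (0.64,),
        "trials_per_condition": 4,
        "eye_conditions": ("contra",),
    })


def plant_movie_population(n, fov_shape, seed, odi_range=(-0.5, 0.5),
                           amplitude=0.5):
    """Cells positioned for rendering, all preferring the tiny design's
    first condition (orientation 0, 1 cpd, size 0) so every cell responds
    strongly in the first differential image."""
    pop = sd.sample_population(
        n, odi_distribution=("uniform",) + tuple(odi_range), seed=seed,
        fov_shape=fov_shape,
        tuning_prior={"noise_sd": 0.0, "amplitude_scale": amplitude,
                      "direction_selective_frac": 0.0})
    return [dataclasses.replace(p, pref_orientation_deg=0.0, pref_sf_cpd=1.0,
                                pref_size_idx=0, ori_sigma_deg=30.0)
            for p in pop]


def planted_dff_trace(movie, neuron):
    """Per-frame planted dF/F of one cell, rebuilt from the sync table, the
    calcium kernel, and the noise-free expected responses -- the oracle for
    everything read out of rendered movies (it accounts for kernel carryover
    from the previous trial into the baseline window)."""
    kernel = sd.calcium_kernel(movie.design)
    trace = np.zeros(movie.n_frames)
    for _, row in movie.sync.iterrows():
        cond = sd.Condition(row["eye"], row["sf_cpd"], int(row["size_idx"]),
                            row["orientation_deg"])
        r = sd.expected_response(neuron, cond, movie.design)
        if neuron.direction_selective and row["direction"] != neuron.preferred_direction:
            r *= 1.0 - neuron.direction_attenuation
        onset = int(row["onset_frame"])
        stop = min(onset + kernel.size, movie.n_frames)
        trace[onset:stop] += r * kernel[:stop - onset]
    return trace


def iou_recall(planted_labels, roiset, min_iou=0.5):
    """Fraction of planted cells recovered by some ROI at IoU >= min_iou."""
    planted_ids = [i for i in np.unique(planted_labels) if i != 0]
    hits = 0
    for pid in planted_ids:
        planted = planted_labels == pid
        best = 0.0
        for mask in roiset.masks:
            inter = np.logical_and(planted, mask).sum()
            union = np.logical_or(planted, mask).sum()
            if union:
                best = max(best, inter / union)
        hits += best >= min_iou
    return hits / len(planted_ids), len(planted_ids)
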
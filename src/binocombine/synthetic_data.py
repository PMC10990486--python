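"""Synthetic two-photon data with known ground truth.

Emulates the stimulus protocol and response statistics of a macaque V1
ocular-dominance experiment so that every downstream stage (segmentation,
tuning analysis, model fitting) can be exercised against a known answer:

* a factorial Gabor stimulus design — 12 orientations x 6 spatial
  frequencies x 3 sizes x 2 drift directions, shown through the
  contralateral eye, the ipsilateral eye, or both;
* a neuron population with a chosen ocular dominance distribution whose
  mean responses follow the divisive binocular-combination model
  (:mod:`binocombine.binocular_model`) multiplied by separable orientation
  (base-2 Gaussian) and spatial-frequency (difference-of-Gaussians) tuning
  profiles;
* trialwise response tables with additive Gaussian noise; and
* small rendered movies (soft-disk cells, double-exponential calcium
  kernel, optional rigid motion) with ground-truth masks and offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

from .binocular_model import eval_binocular, eval_monocular

__all__ = [
    "StimulusDesign",
    "Condition",
    "NeuronGroundTruth",
    "SyntheticMovie",
    "build_stimulus_design",
    "sample_population",
    "expected_response",
    "generate_response_table",
    "generate_movie",
    "calcium_kernel",
    "save_movie",
    "load_movie",
    "population_to_frame",
]

EYES = ("contra", "ipsi", "binocular")
MONOCULAR_EYES = ("contra", "ipsi")


class Condition(NamedTuple):
    """One cell of the stimulus factorial (without direction/trial)."""

    eye: str
    sf_cpd: float
    size_idx: int
    orientation_deg: float


@dataclass(frozen=True)
class StimulusDesign:
    """Factorial stimulus protocol with Gabor geometry.

    Sizes are the Gaussian-envelope sigma in units of the grating wavelength
    (lambda); in degrees of visual angle sigma = sigma_lambda / SF.  Lower
    spatial frequencies use the smaller size triplet, higher ones the larger,
    so each Gabor keeps a sufficient number of cycles.
    """

    orientations_deg: tuple = tuple(float(o) for o in range(0, 180, 15))
    spatial_frequencies_cpd: tuple = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    sizes_low_sf: tuple = (0.42, 0.64, 0.85)    # sigma/lambda for SF <= 1 cpd
    sizes_high_sf: tuple = (0.64, 0.85, 1.06)   # sigma/lambda for SF >= 2 cpd
    directions_per_orientation: int = 2
    trials_per_condition: int = 12              # 6 per drift direction
    eye_conditions: tuple = EYES
    contrast: float = 0.9
    drift_rate_cps: float = 2.0
    frames_per_second: float = 8.0
    stim_frames: int = 8                        # 1000 ms
    isi_frames: int = 12                        # 1500 ms

    def __post_init__(self):
        if not self.orientations_deg or not self.spatial_frequencies_cpd:
            raise ValueError("factor lists must be non-empty")
        if any(sf <= 0 for sf in self.spatial_frequencies_cpd):
            raise ValueError("spatial frequencies must be positive")
        if len(self.sizes_low_sf) != len(self.sizes_high_sf):
            raise ValueError("size triplets must have equal length")
        if (self.directions_per_orientation <= 0 or self.trials_per_condition <= 0
                or self.stim_frames <= 0 or self.isi_frames < 4):
            raise ValueError("counts must be positive (and isi_frames >= 4)")

    @property
    def n_sizes(self) -> int:
        return len(self.sizes_low_sf)

    @property
    def trials_per_direction(self) -> int:
        return self.trials_per_condition // self.directions_per_orientation

    @property
    def n_monocular_conditions(self) -> int:
        """Conditions per monocular eye: SF x size x orientation."""
        return (len(self.spatial_frequencies_cpd) * self.n_sizes
                * len(self.orientations_deg))

    def sizes_for_sf(self, sf_cpd: float) -> tuple:
        """The sigma/lambda triplet used at a given spatial frequency."""
        return self.sizes_low_sf if sf_cpd <= 1.0 else self.sizes_high_sf

    def sigma_deg(self, sf_cpd: float, size_idx: int) -> float:
        """Gabor envelope sigma in degrees of visual angle."""
        return self.sizes_for_sf(sf_cpd)[size_idx] / sf_cpd

    def conditions(self, eye: str) -> Iterator[Condition]:
        """Conditions for one eye in screening order: SF, then size, then orientation."""
        for sf in self.spatial_frequencies_cpd:
            for z in range(self.n_sizes):
                for ori in self.orientations_deg:
                    yield Condition(eye, sf, z, ori)

    def all_conditions(self) -> Iterator[Condition]:
        for eye in self.eye_conditions:
            yield from self.conditions(eye)


def build_stimulus_design(overrides: dict | None = None) -> StimulusDesign:
    """The default factorial design, optionally with overridden factors.

    The default reproduces the experimental protocol: 12 orientations in 15
    degree steps, 6 SFs from 0.25 to 8 cpd in octave steps, 3 sizes per SF,
    2 opposite drift directions with 6 trials each, three eye conditions,
    yielding 216 conditions per monocular eye.
    """
    overrides = dict(overrides or {})
    for key in ("orientations_deg", "spatial_frequencies_cpd",
                "sizes_low_sf", "sizes_high_sf", "eye_conditions"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return StimulusDesign(**overrides)


# ---------------------------------------------------------------------------
# neuron population
# ---------------------------------------------------------------------------

@dataclass
class NeuronGroundTruth:
    """Planted parameters of one synthetic neuron."""

    neuron: int
    odi_true: float
    k_true: float
    m_c_true: float
    m_i_true: float
    b_supp_true: float
    pref_orientation_deg: float
    ori_sigma_deg: float          # half-width at half-height of the tuning curve
    pref_sf_cpd: float
    sf_bandwidth_oct: float       # full bandwidth at half height, octaves
    pref_size_idx: int
    amplitude_scale: float        # peak dF/F at the preferred condition, per eye factor 1
    direction_selective: bool
    preferred_direction: int
    direction_attenuation: float  # multiplier shortfall on the non-preferred direction
    noise_sd: float
    position_px: tuple = (0.0, 0.0)
    radius_px: float = 0.0


_DEFAULT_PRIOR = dict(
    k=1.0, m_c=-1.0, m_i=-1.0, b_supp=-0.9,
    amplitude_scale=1.0, noise_sd=0.05,
    direction_selective_frac=0.05, direction_attenuation=0.6,
    ori_sigma_range=(15.0, 40.0),
)

# DoG shape constants: sigma2 = sigma1 / 3 and a2 = a1 / 2 put the continuous
# peak at 0.4335 * sigma1 (solve d/ds [e^{-(s/s1)^2} - 0.5 e^{-(3 s/s1)^2}] = 0)
_DOG_SIGMA_RATIO = 3.0
_DOG_AMP_RATIO = 0.5
_DOG_PEAK_FACTOR = math.sqrt(math.log(_DOG_AMP_RATIO * _DOG_SIGMA_RATIO ** 2)
                             / (_DOG_SIGMA_RATIO ** 2 - 1.0))


#: Support cap of the default ODI mixture.  Measured ODI distributions
#: concentrate inside the open interval (-1, 1), and the divisive model's
#: w**m diverges at the endpoints; the generator therefore plants neurons
#: only in the data-supported region.
_ODI_CAP = 0.97


def _draw_odi(rng: np.random.Generator, n: int, spec) -> np.ndarray:
    """Draw ODIs; default mixture favors binocular neurons (|ODI| < 0.5)."""
    if spec is None:
        u = rng.random(n)
        odi = np.where(
            u < 0.5, rng.uniform(-0.5, 0.5, n),
            np.where(u < 0.75, rng.uniform(-_ODI_CAP, -0.5, n),
                     rng.uniform(0.5, _ODI_CAP, n)),
        )
    elif spec == "uniform":
        odi = rng.uniform(-1.0, 1.0, n)
    elif isinstance(spec, tuple) and spec[0] == "uniform":
        _, lo, hi = spec
        if lo < -1.0 or hi > 1.0:
            raise ValueError("ODI distribution support must lie inside [-1, 1]")
        odi = rng.uniform(lo, hi, n)
    elif callable(spec):
        odi = np.asarray(spec(rng, n), dtype=float)
    else:
        raise ValueError(f"unknown ODI distribution spec: {spec!r}")
    if odi.size and (odi.min() < -1.0 or odi.max() > 1.0):
        raise ValueError("ODI distribution produced values outside [-1, 1]")
    return odi


def sample_population(n: int, odi_distribution=None, tuning_prior: dict | None = None,
                      seed: int = 0, fov_shape: tuple | None = None,
                      radius_px_range: tuple = (3.5, 6.0),
                      margin_px: int = 12) -> list:
    """Draw `n` synthetic neurons, deterministically for a fixed seed.

    Parameters
    ----------
    n : int
        Population size (0 gives an empty list).
    odi_distribution : None, "uniform", ("uniform", lo, hi) or callable
        ODI sampler; the default mixture places half the mass on
        |ODI| < 0.5, echoing the binocular-heavy distributions seen in V1
        superficial layers.  Support must lie inside [-1, 1].
    tuning_prior : dict, optional
        Overrides for the shared model parameters (k, m_c, m_i, b_supp),
        amplitude_scale, noise_sd, direction_selective_frac,
        direction_attenuation, ori_sigma_range.
    fov_shape : (H, W), optional
        When given, neurons receive non-overlapping positions and radii so a
        movie can be rendered.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    prior = dict(_DEFAULT_PRIOR)
    prior.update(tuning_prior or {})
    rng = np.random.default_rng(seed)
    design = build_stimulus_design()

    odi = _draw_odi(rng, n, odi_distribution)
    pref_ori = rng.choice(np.asarray(design.orientations_deg), n) if n else np.empty(0)
    # interior SFs only: an on-grid peak keeps the planted preference identifiable
    pref_sf = rng.choice(np.asarray(design.spatial_frequencies_cpd[1:-1]), n) if n else np.empty(0)
    lo_s, hi_s = prior["ori_sigma_range"]
    ori_sigma = rng.uniform(lo_s, hi_s, n)
    pref_size = rng.integers(0, design.n_sizes, n)
    ds = rng.random(n) < prior["direction_selective_frac"]
    pref_dir = rng.integers(0, 2, n)

    positions = np.zeros((n, 2))
    radii = np.zeros(n)
    if fov_shape is not None and n:
        h, w = fov_shape
        placed = []
        for j in range(n):
            r = rng.uniform(*radius_px_range)
            for _attempt in range(5000):
                pos = (rng.uniform(margin_px + r, h - margin_px - r),
                       rng.uniform(margin_px + r, w - margin_px - r))
                if all(math.hypot(pos[0] - p[0], pos[1] - p[1]) > r + pr + 3.0
                       for p, pr in placed):
                    break
            else:
                raise ValueError(
                    f"could not place {n} non-overlapping cells in FOV {fov_shape}")
            placed.append((pos, r))
            positions[j], radii[j] = pos, r

    population = []
    for j in range(n):
        sigma1 = pref_sf[j] / _DOG_PEAK_FACTOR
        population.append(NeuronGroundTruth(
            neuron=j,
            odi_true=float(odi[j]),
            k_true=prior["k"], m_c_true=prior["m_c"], m_i_true=prior["m_i"],
            b_supp_true=prior["b_supp"],
            pref_orientation_deg=float(pref_ori[j]),
            ori_sigma_deg=float(ori_sigma[j]),
            pref_sf_cpd=float(pref_sf[j]),
            sf_bandwidth_oct=float(_dog_bandwidth_octaves(sigma1)),
            pref_size_idx=int(pref_size[j]),
            amplitude_scale=prior["amplitude_scale"],
            direction_selective=bool(ds[j]),
            preferred_direction=int(pref_dir[j]),
            direction_attenuation=prior["direction_attenuation"],
            noise_sd=prior["noise_sd"],
            position_px=tuple(positions[j]),
            radius_px=float(radii[j]),
        ))
    return population


def population_to_frame(population: Sequence[NeuronGroundTruth]) -> pd.DataFrame:
    """Ground-truth parameter table (one row per neuron)."""
    return pd.DataFrame([vars(nrn) | {"position_row": nrn.position_px[0],
                                      "position_col": nrn.position_px[1]}
                         for nrn in population]).drop(columns=["position_px"])


# ---------------------------------------------------------------------------
# tuning profiles and expected responses
# ---------------------------------------------------------------------------

def _circ_dist_deg(theta, theta0):
    """Orientation distance on the 180-degree circle."""
    d = np.abs(np.asarray(theta, dtype=float) - theta0) % 180.0
    return np.minimum(d, 180.0 - d)


def orientation_profile(theta_deg, pref_deg: float, sigma_deg: float):
    """Base-2 Gaussian orientation tuning, 1 at the peak, 1/2 at pref +- sigma."""
    d = _circ_dist_deg(theta_deg, pref_deg)
    return 2.0 ** (-((d / sigma_deg) ** 2))


def sf_profile(sf_cpd, pref_sf_cpd: float):
    """Difference-of-Gaussians SF tuning, normalized to 1 at the preferred SF."""
    sigma1 = pref_sf_cpd / _DOG_PEAK_FACTOR
    sigma2 = sigma1 / _DOG_SIGMA_RATIO
    sf = np.asarray(sf_cpd, dtype=float)
    dog = np.exp(-((sf / sigma1) ** 2)) - _DOG_AMP_RATIO * np.exp(-((sf / sigma2) ** 2))
    peak = (math.exp(-(_DOG_PEAK_FACTOR ** 2))
            - _DOG_AMP_RATIO * math.exp(-((_DOG_PEAK_FACTOR * _DOG_SIGMA_RATIO) ** 2)))
    return dog / peak


def _dog_bandwidth_octaves(sigma1: float) -> float:
    """Full bandwidth at half height of the normalized DoG, in octaves."""
    pref = sigma1 * _DOG_PEAK_FACTOR
    grid = pref * np.logspace(-4, 4, 4097, base=2.0)
    prof = sf_profile(grid, pref)
    above = grid[prof >= 0.5]
    if above.size < 2:
        return float("nan")
    return float(np.log2(above[-1] / above[0]))


_SIZE_SIGMA_IDX = 1.5  # Gaussian width of the size preference, in size-index units


def size_profile(size_idx, pref_idx: int):
    d = np.asarray(size_idx, dtype=float) - pref_idx
    return np.exp(-((d / _SIZE_SIGMA_IDX) ** 2))


def eye_factor(neuron: NeuronGroundTruth, eye: str) -> float:
    """The ocular-dominance-dependent response factor for one eye condition."""
    r_c, r_i = eval_monocular(neuron.odi_true, neuron.k_true,
                              neuron.m_c_true, neuron.m_i_true)
    if eye == "contra":
        return float(r_c)
    if eye == "ipsi":
        return float(r_i)
    if eye == "binocular":
        return float(eval_binocular(neuron.odi_true, neuron.k_true,
                                    neuron.m_c_true, neuron.m_i_true,
                                    neuron.b_supp_true))
    raise KeyError(f"unknown eye condition {eye!r}")


def expected_response(neuron: NeuronGroundTruth, condition: Condition,
                      design: StimulusDesign | None = None) -> float:
    """Noise-free mean dF/F of a neuron for one stimulus condition.

    The response is separable: the eye-condition factor from the combination
    model, times the orientation and SF tuning profiles (each 1 at the
    neuron's preference), times a mild size preference, times the amplitude
    scale.
    """
    design = design or build_stimulus_design()
    if condition.eye not in design.eye_conditions:
        raise KeyError(f"unknown eye condition {condition.eye!r}")
    if condition.sf_cpd not in design.spatial_frequencies_cpd:
        raise KeyError(f"SF {condition.sf_cpd} not in design")
    if condition.orientation_deg not in design.orientations_deg:
        raise KeyError(f"orientation {condition.orientation_deg} not in design")
    if not 0 <= condition.size_idx < design.n_sizes:
        raise KeyError(f"size index {condition.size_idx} out of range")
    value = (neuron.amplitude_scale
             * eye_factor(neuron, condition.eye)
             * float(orientation_profile(condition.orientation_deg,
                                         neuron.pref_orientation_deg,
                                         neuron.ori_sigma_deg))
             * float(sf_profile(condition.sf_cpd, neuron.pref_sf_cpd))
             * float(size_profile(condition.size_idx, neuron.pref_size_idx)))
    return float(value)


# ---------------------------------------------------------------------------
# trialwise response tables
# ---------------------------------------------------------------------------

def _expected_grid(population, design) -> np.ndarray:
    """Expected responses, shape (n, n_eyes, n_sf, n_sizes, n_ori)."""
    sfs = np.asarray(design.spatial_frequencies_cpd)
    oris = np.asarray(design.orientations_deg)
    n = len(population)
    grid = np.empty((n, len(design.eye_conditions), sfs.size, design.n_sizes, oris.size))
    for j, nrn in enumerate(population):
        prof = (sf_profile(sfs, nrn.pref_sf_cpd)[:, None, None]
                * size_profile(np.arange(design.n_sizes), nrn.pref_size_idx)[None, :, None]
                * orientation_profile(oris, nrn.pref_orientation_deg,
                                      nrn.ori_sigma_deg)[None, None, :])
        for e, eye in enumerate(design.eye_conditions):
            grid[j, e] = nrn.amplitude_scale * eye_factor(nrn, eye) * prof
    return grid


def generate_response_table(population: Sequence[NeuronGroundTruth],
                            design: StimulusDesign | None = None,
                            seed: int = 0,
                            noise_sd: float | None = None) -> pd.DataFrame:
    """Trialwise dF/F table covering the full factorial for every neuron.

    Each trial value is ``expected_response`` plus zero-mean Gaussian noise of
    scale ``noise_sd`` (default: each neuron's own ``noise_sd``).  Direction-
    selective neurons have the non-preferred direction attenuated by the
    factor ``1 - direction_attenuation``.

    Columns: neuron, eye, sf_cpd, size_idx, orientation_deg, direction,
    trial, response.
    """
    design = design or build_stimulus_design()
    rng = np.random.default_rng(seed)
    n = len(population)
    sfs = np.asarray(design.spatial_frequencies_cpd)
    oris = np.asarray(design.orientations_deg)
    n_e, n_s, n_z, n_o = len(design.eye_conditions), sfs.size, design.n_sizes, oris.size
    n_d, n_t = design.directions_per_orientation, design.trials_per_direction

    mean = _expected_grid(population, design)  # (n, e, s, z, o)
    dir_fac = np.ones((n, n_d))
    for j, nrn in enumerate(population):
        if nrn.direction_selective:
            for d in range(n_d):
                if d != nrn.preferred_direction:
                    dir_fac[j, d] = 1.0 - nrn.direction_attenuation

    full = mean[..., None, None] * dir_fac[:, None, None, None, None, :, None]
    full = np.broadcast_to(full, (n, n_e, n_s, n_z, n_o, n_d, n_t)).copy()
    sd = np.array([nrn.noise_sd for nrn in population]) if noise_sd is None \
        else np.full(n, float(noise_sd))
    full += sd[:, None, None, None, None, None, None] * rng.standard_normal(full.shape)

    idx = pd.MultiIndex.from_product(
        [[nrn.neuron for nrn in population], list(design.eye_conditions),
         sfs.tolist(), range(n_z), oris.tolist(), range(n_d), range(n_t)],
        names=["neuron", "eye", "sf_cpd", "size_idx", "orientation_deg",
               "direction", "trial"],
    )
    table = pd.DataFrame({"response": full.ravel()}, index=idx).reset_index()
    return table


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def calcium_kernel(design: StimulusDesign, rise_s: float = 0.05,
                   decay_s: float = 0.5) -> np.ndarray:
    """Per-frame calcium impulse response, normalized on the dF/F read window.

    Double exponential (fast rise, slow decay) sampled at frame centers,
    scaled so its mean over post-onset frames 5-8 (1-based) is 1; a trial
    response r then reads back as dF/F = r from those frames.  The transient
    decays to < 1% of peak within the 1500 ms inter-stimulus interval.
    """
    n_frames = design.stim_frames + design.isi_frames
    t = (np.arange(n_frames) + 0.5) / design.frames_per_second
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k[4:8].mean()


@dataclass
class SyntheticMovie:
    """Rendered movie stack plus everything needed to score recovery."""

    stack: np.ndarray          # (T, H, W) float32
    sync: pd.DataFrame         # one row per trial: onset_frame + condition key
    labels: np.ndarray         # (H, W) int32 ground-truth mask, 0 = background
    offsets: np.ndarray        # (T, 2) planted integer (row, col) shifts
    design: StimulusDesign
    population: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]


def _cell_profile(shape, center, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return 1.0 / (1.0 + np.exp((d - radius) / 0.6))


def generate_movie(population: Sequence[NeuronGroundTruth],
                   design: StimulusDesign | None = None,
                   fov_shape: tuple = (128, 128),
                   motion_amplitude_px: int = 0,
                   seed: int = 0,
                   cell_brightness: float = 100.0,
                   background: float = 0.0,
                   sensor_noise_sd: float = 0.0,
                   max_motion_margin_px: int = 10,
                   responses: pd.DataFrame | None = None) -> SyntheticMovie:
    """Render a movie of soft-disk cells following the calcium kernel.

    Every trial occupies ``isi_frames + stim_frames`` frames, the stimulus
    onset falling after the ISI so each trial has at least 4 pre-onset
    baseline frames; a trailing ISI block gives the last trial its full
    post-onset window.  Brightness of cell j at frame f is
    ``background + cell_brightness * profile * (1 + response * kernel)``.

    If `responses` (a table from :func:`generate_response_table`) is given,
    the planted trial responses are taken from it; otherwise a noiseless
    table is generated internally.
    """
    design = design or build_stimulus_design()
    rng = np.random.default_rng(seed)
    if motion_amplitude_px > max_motion_margin_px:
        raise ValueError(
            f"motion amplitude {motion_amplitude_px} exceeds margin {max_motion_margin_px}")
    for j, a in enumerate(population):
        if a.radius_px <= 0:
            raise ValueError("population must be sampled with fov_shape set "
                             "(cells need positions and radii)")
        if math.pi * a.radius_px ** 2 <= 25:
            raise ValueError(f"cell {j} area <= 25 px; increase radius")
        for b in population[j + 1:]:
            d = math.hypot(a.position_px[0] - b.position_px[0],
                           a.position_px[1] - b.position_px[1])
            if d <= a.radius_px + b.radius_px:
                raise ValueError(f"cells {a.neuron} and {b.neuron} overlap")

    if responses is None:
        responses = generate_response_table(population, design, seed=seed, noise_sd=0.0)

    profiles = np.stack([_cell_profile(fov_shape, nrn.position_px, nrn.radius_px)
                         for nrn in population])
    labels = np.zeros(fov_shape, dtype=np.int32)
    for j, nrn in enumerate(population):
        labels[profiles[j] > 0.5] = nrn.neuron + 1

    trial_len = design.isi_frames + design.stim_frames
    trials = (responses[["eye", "sf_cpd", "size_idx", "orientation_deg",
                         "direction", "trial"]]
              .drop_duplicates().reset_index(drop=True))
    n_trials = len(trials)
    n_frames = n_trials * trial_len + design.isi_frames
    kernel = calcium_kernel(design)

    resp_lookup = responses.set_index(
        ["neuron", "eye", "sf_cpd", "size_idx", "orientation_deg",
         "direction", "trial"])["response"]

    # per-neuron dF/F trace over the whole movie
    dff = np.zeros((len(population), n_frames))
    onsets = np.empty(n_trials, dtype=int)
    for t_idx in range(n_trials):
        onset = t_idx * trial_len + design.isi_frames
        onsets[t_idx] = onset
        key = trials.iloc[t_idx]
        stop = min(onset + kernel.size, n_frames)
        for j, nrn in enumerate(population):
            r = resp_lookup[(nrn.neuron, key["eye"], key["sf_cpd"],
                             int(key["size_idx"]), key["orientation_deg"],
                             int(key["direction"]), int(key["trial"]))]
            dff[j, onset:stop] += r * kernel[:stop - onset]

    base = background + cell_brightness * profiles.sum(axis=0)
    stack = np.empty((n_frames,) + tuple(fov_shape), dtype=np.float32)
    for f in range(n_frames):
        frame = base + cell_brightness * np.einsum("j,jhw->hw", dff[:, f], profiles)
        stack[f] = frame

    offsets = np.zeros((n_frames, 2), dtype=int)
    if motion_amplitude_px > 0:
        offsets = rng.integers(-motion_amplitude_px, motion_amplitude_px + 1,
                               size=(n_frames, 2))
        for f in range(n_frames):
            dy, dx = offsets[f]
            if dy or dx:
                shifted = np.roll(stack[f], (dy, dx), axis=(0, 1))
                med = np.median(stack[f])
                if dy > 0:
                    shifted[:dy] = med
                elif dy < 0:
                    shifted[dy:] = med
                if dx > 0:
                    shifted[:, :dx] = med
                elif dx < 0:
                    shifted[:, dx:] = med
                stack[f] = shifted
    if sensor_noise_sd > 0:
        stack += rng.normal(0.0, sensor_noise_sd, stack.shape).astype(np.float32)

    sync = trials.copy()
    sync.insert(0, "onset_frame", onsets)
    return SyntheticMovie(stack=stack, sync=sync, labels=labels,
                          offsets=offsets, design=design,
                          population=list(population))


def save_movie(movie: SyntheticMovie, movie_path, sync_path, labels_path=None):
    """Write the stack as a multi-page TIFF and the sync table as CSV."""
    tifffile.imwrite(movie_path, movie.stack)
    movie.sync.to_csv(sync_path, index=False)
    if labels_path is not None:
        tifffile.imwrite(labels_path, movie.labels)


def load_movie(movie_path, sync_path):
    """Read back a stack + sync table pair written by :func:`save_movie`."""
    stack = tifffile.imread(movie_path)
    sync = pd.read_csv(sync_path)
    return stack, sync
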
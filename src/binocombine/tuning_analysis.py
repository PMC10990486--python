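"""Trialwise responses, tuning screens, curve fits, and ocular dominance.

A neuron's response to one stimulus presentation is the fractional
fluorescence change dF_n/F0 = (F_n - F0)/F0, where F_n averages post-onset
frames 5-8 (1-based) and the baseline F0 averages the 4 pre-onset frames of
all 12 trials of the condition (pooling the baseline across trials reduces
its noise).  A condition's scalar response averages the 11 strongest of the
12 trials -- the single weakest, often negative, trial is dropped -- except
for direction-selective neurons, where only the 6 preferred-direction
trials count.

Tuned neurons are selected by a two-stage screen per monocular eye: a
Friedman test (alpha = 0.01) across the 12 orientations or 6 spatial
frequencies at the best condition, followed by a trial-level curve fit with
R**2 > 0.5 -- a base-2 Gaussian over orientation (sigma is the half-width at
half-height) and a difference-of-Gaussians over SF.  The ocular dominance
index ODI = (R_i - R_c)/(R_i + R_c) is computed from the fitted peak
responses of the two monocular conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import (MONOCULAR_EYES, Condition, StimulusDesign,
                             build_stimulus_design)

__all__ = [
    "friedman_test",
    "trial_dff",
    "extract_response_table",
    "aggregate_response",
    "direction_selectivity_test",
    "select_best_condition",
    "friedman_screen",
    "fit_orientation",
    "fit_sf",
    "compute_odi",
    "analyze_population",
    "render_od_map",
]

_FIT_SEED = 715  # jittered multi-start draws; fixed so reruns are identical
_SF_EVAL_GRID = np.logspace(np.log2(0.125), np.log2(16.0), 513, base=2.0)


# ---------------------------------------------------------------------------
# Friedman test (own implementation: the 2-treatment case is needed for the
# direction screen, which scipy's friedmanchisquare refuses)
# ---------------------------------------------------------------------------

def friedman_test(data: np.ndarray):
    """Friedman rank test over a (blocks x treatments) matrix.

    Mid-ranks for ties, Conover's tie-robust chi-square form with k-1
    degrees of freedom.  Degenerate data (every block fully tied) yields
    (0, 1) instead of raising.

    Returns
    -------
    (statistic, p_value)
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a (blocks >= 2) x (treatments >= 2) matrix")
    n, k = data.shape
    ranks = stats.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks ** 2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a <= c:  # all blocks fully tied
        return 0.0, 1.0
    statistic = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / (a - c)
    return statistic, float(stats.chi2.sf(statistic, k - 1))


# ---------------------------------------------------------------------------
# trial responses
# ---------------------------------------------------------------------------

def trial_dff(source, sync: pd.DataFrame | None, mask, condition: Condition) -> pd.DataFrame:
    """Per-trial dF_n/F0 of one ROI (or table neuron) for one condition.

    Movie-backed (`source` is a (T, H, W) stack, `mask` a boolean ROI mask):
    F_n averages post-onset frames 5-8 (1-based), F0_n the 4 pre-onset
    frames; the baseline F0 is the mean of F0_n over all the condition's
    trials (both drift directions).  Table-backed (`source` is a trialwise
    response table, `mask` the neuron id): the stored responses are returned
    unchanged.

    Raises
    ------
    ValueError if the pooled baseline F0 is non-positive (the ROI must then
    be flagged invalid and excluded downstream).
    """
    if isinstance(source, pd.DataFrame):
        sel = source[(source["neuron"] == mask)
                     & (source["eye"] == condition.eye)
                     & (source["sf_cpd"] == condition.sf_cpd)
                     & (source["size_idx"] == condition.size_idx)
                     & (source["orientation_deg"] == condition.orientation_deg)]
        if sel.empty:
            raise KeyError(f"no trials for condition {condition}")
        return sel[["direction", "trial", "response"]].reset_index(drop=True)

    stack = source
    sel = sync[(sync["eye"] == condition.eye)
               & (sync["sf_cpd"] == condition.sf_cpd)
               & (sync["size_idx"] == condition.size_idx)
               & (sync["orientation_deg"] == condition.orientation_deg)]
    if sel.empty:
        raise KeyError(f"no trials for condition {condition}")
    mask = np.asarray(mask, dtype=bool)
    f_n, f0_n = [], []
    for onset in sel["onset_frame"].to_numpy(dtype=int):
        f_n.append(stack[onset + 4:onset + 8, mask].mean())   # 1-based frames 5..8
        f0_n.append(stack[onset - 4:onset, mask].mean())
    f0 = float(np.mean(f0_n))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0} for condition {condition}")
    out = sel[["direction", "trial"]].copy().reset_index(drop=True)
    out["response"] = (np.asarray(f_n) - f0) / f0
    return out


def extract_response_table(stack: np.ndarray, sync: pd.DataFrame,
                           masks, design: StimulusDesign | None = None,
                           neuron_ids=None) -> pd.DataFrame:
    """Trialwise dF/F table for every ROI and condition present in the sync.

    Returns the same column layout the synthetic generator produces, so the
    downstream analysis is agnostic to whether responses came from a movie
    or straight from a table.
    """
    design = design or build_stimulus_design()
    if neuron_ids is None:
        neuron_ids = list(range(len(masks)))
    mask_arrays = [np.asarray(m, dtype=bool) for m in masks]

    # per-sync-row windows, then per-ROI means: one pass over the stack
    n_rows = len(sync)
    f_n = np.empty((n_rows, len(mask_arrays)))
    f0_n = np.empty((n_rows, len(mask_arrays)))
    onsets = sync["onset_frame"].to_numpy(dtype=int)
    for r, onset in enumerate(onsets):
        win = stack[onset + 4:onset + 8].mean(axis=0)
        base = stack[onset - 4:onset].mean(axis=0)
        for j, m in enumerate(mask_arrays):
            f_n[r, j] = win[m].mean()
            f0_n[r, j] = base[m].mean()

    sync_key = sync[["eye", "sf_cpd", "size_idx", "orientation_deg",
                     "direction", "trial"]].reset_index(drop=True)
    cond_key = sync_key[["eye", "sf_cpd", "size_idx", "orientation_deg"]]
    rows = []
    for j, nid in enumerate(neuron_ids):
        f0_cond = pd.Series(f0_n[:, j]).groupby(
            [cond_key[c] for c in cond_key.columns]).transform("mean").to_numpy()
        resp = (f_n[:, j] - f0_cond) / f0_cond
        chunk = sync_key.copy()
        chunk.insert(0, "neuron", nid)
        chunk["response"] = resp
        chunk["valid"] = f0_cond > 0
        rows.append(chunk)
    return pd.concat(rows, ignore_index=True)


def aggregate_response(responses, directions=None, direction_selective: bool = False,
                       preferred_direction: int | None = None) -> float:
    """Scalar response for one condition from its 12 trials.

    Non-selective neurons: mean of the 11 largest trials (the weakest, often
    negative, trial is dropped).  Direction-selective neurons: mean of the 6
    trials at the preferred direction.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.size < 2:
        raise ValueError(f"need the full trial set, got {responses.size} trials")
    if direction_selective:
        if directions is None or preferred_direction is None:
            raise ValueError("direction-selective aggregation needs directions "
                             "and a preferred direction")
        sel = np.asarray(directions) == preferred_direction
        return float(responses[sel].mean())
    return float((responses.sum() - responses.min()) / (responses.size - 1))


def direction_selectivity_test(responses_by_direction: np.ndarray,
                               alpha: float = 0.05):
    """Friedman screen for direction selectivity.

    Parameters
    ----------
    responses_by_direction : (blocks, 2) array
        Paired per-trial responses at the two opposite drift directions,
        blocked by (condition, trial).

    Returns
    -------
    (selective, preferred_direction, p_value)
    """
    data = np.asarray(responses_by_direction, dtype=float)
    _, p = friedman_test(data)
    preferred = int(np.argmax(data.mean(axis=0)))
    return bool(p < alpha), preferred, float(p)


def select_best_condition(response_grid: np.ndarray):
    """Argmax over the (SF, size, orientation) response grid of one eye.

    Ties resolve to the lowest flat index in design order (SF major, then
    size, then orientation).
    """
    flat = int(np.argmax(response_grid))
    return np.unravel_index(flat, response_grid.shape)


def friedman_screen(trial_matrix: np.ndarray, alpha: float = 0.01) -> bool:
    """True if responses differ across levels (Friedman p < alpha).

    `trial_matrix` is (levels, trials); blocks are trial indices.
    """
    _, p = friedman_test(np.asarray(trial_matrix, dtype=float).T)
    return bool(p < alpha)


# ---------------------------------------------------------------------------
# curve fits
# ---------------------------------------------------------------------------

def _circ_dist_deg(theta, theta0):
    d = np.abs(np.asarray(theta, dtype=float) - theta0) % 180.0
    return np.minimum(d, 180.0 - d)


def _r_squared(y, pred):
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -math.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class OrientationFit:
    a1: float
    theta0_deg: float
    sigma_deg: float      # half-width at half-height (base-2 Gaussian)
    baseline: float
    r2: float

    @property
    def peak(self) -> float:
        return self.a1 + self.baseline


@dataclass
class SfFit:
    a1: float
    sigma1: float
    a2: float
    sigma2: float
    baseline: float
    r2: float
    pref_sf_cpd: float
    peak: float


_FAILED_ORI = OrientationFit(math.nan, math.nan, math.nan, math.nan, -math.inf)
_FAILED_SF = SfFit(*([math.nan] * 5), -math.inf, math.nan, math.nan)


def fit_orientation(orientations_deg, trial_responses, n_starts: int = 5,
                    seed: int = _FIT_SEED) -> OrientationFit:
    """Least-squares fit of R(theta) = a1 * 2**(-(d(theta,theta0)/sigma)**2) + b.

    The fit targets are trial-level points, not condition means; the
    orientation distance is circular modulo 180 degrees, and sigma is
    literally the half-width at half-height of the tuning curve.  Multi-start
    (empirical peak plus jittered restarts, fixed seed) guards against local
    minima; total failure returns R**2 = -inf.
    """
    oris = np.asarray(orientations_deg, dtype=float)
    trials = np.asarray(trial_responses, dtype=float)   # (n_ori, n_trials)
    x = np.repeat(oris, trials.shape[1])
    y = trials.ravel()

    means = trials.mean(axis=1)
    i_max = int(np.argmax(means))
    base0 = np.array([means.max() - means.min(), oris[i_max], 30.0, means.min()])
    lo = np.array([0.0, -360.0, 5.0, -np.inf])
    hi = np.array([np.inf, 360.0, 90.0, np.inf])

    def resid(p):
        return p[0] * 2.0 ** (-((_circ_dist_deg(x, p[1]) / p[2]) ** 2)) + p[3] - y

    _ln2 = math.log(2.0)

    def jac(p):
        a1, th0, sig, _ = p
        u = (x - th0 + 90.0) % 180.0 - 90.0     # signed circular offset
        d = np.abs(u)
        g = 2.0 ** (-((d / sig) ** 2))
        cols = np.empty((x.size, 4))
        cols[:, 0] = g
        cols[:, 1] = a1 * g * _ln2 * (2.0 * d / sig ** 2) * np.sign(u)
        cols[:, 2] = a1 * g * _ln2 * (2.0 * d ** 2 / sig ** 3)
        cols[:, 3] = 1.0
        return cols

    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for s in range(n_starts):
        p0 = base0 if s == 0 else np.clip(
            base0 + np.array([0.3 * abs(base0[0]) + 0.05, 30.0, 15.0, 0.05])
            * rng.standard_normal(4), lo + 1e-9, np.minimum(hi - 1e-9, 1e9))
        try:
            sol = optimize.least_squares(resid, p0, jac=jac, bounds=(lo, hi),
                                         max_nfev=300)
        except (ValueError, RuntimeError):
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
            if _r_squared(y, resid(sol.x) + y) > 0.995:
                break
    if best is None:
        return _FAILED_ORI
    a1, th0, sig, b = best.x
    r2 = _r_squared(y, resid(best.x) + y)
    return OrientationFit(float(a1), float(th0 % 180.0), float(sig), float(b), r2)


def fit_sf(sfs_cpd, trial_responses, n_starts: int = 5,
           seed: int = _FIT_SEED) -> SfFit:
    """Least-squares difference-of-Gaussians fit over spatial frequency.

    R(sf) = a1*exp(-(sf/sigma1)**2) - a2*exp(-(sf/sigma2)**2) + b, fit to
    trial-level points; the baseline starts at the minimal mean response
    among the SFs.  The preferred SF and peak response are read off the
    fitted curve on a fine log-spaced grid.
    """
    sfs = np.asarray(sfs_cpd, dtype=float)
    trials = np.asarray(trial_responses, dtype=float)   # (n_sf, n_trials)
    x = np.repeat(sfs, trials.shape[1])
    y = trials.ravel()

    means = trials.mean(axis=1)
    b0 = means.min()
    sf_peak = sfs[int(np.argmax(means))]
    base0 = np.array([2.0 * max(means.max() - b0, 1e-3), 2.0 * sf_peak,
                      max(means.max() - b0, 1e-3), 0.5 * sf_peak, b0])
    lo = np.array([0.0, 1e-3, 0.0, 1e-3, -np.inf])
    hi = np.array([np.inf, 100.0, np.inf, 100.0, np.inf])

    def model(p, s):
        return (p[0] * np.exp(-((s / p[1]) ** 2))
                - p[2] * np.exp(-((s / p[3]) ** 2)) + p[4])

    def resid(p):
        return model(p, x) - y

    def jac(p):
        a1, s1, a2, s2, _ = p
        g1 = np.exp(-((x / s1) ** 2))
        g2 = np.exp(-((x / s2) ** 2))
        cols = np.empty((x.size, 5))
        cols[:, 0] = g1
        cols[:, 1] = a1 * g1 * 2.0 * x ** 2 / s1 ** 3
        cols[:, 2] = -g2
        cols[:, 3] = -a2 * g2 * 2.0 * x ** 2 / s2 ** 3
        cols[:, 4] = 1.0
        return cols

    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for s in range(n_starts):
        p0 = base0 if s == 0 else np.clip(
            base0 * (1.0 + 0.5 * rng.standard_normal(5)) + 0.01,
            lo + 1e-9, np.minimum(hi - 1e-9, 1e9))
        try:
            sol = optimize.least_squares(resid, p0, jac=jac, bounds=(lo, hi),
                                         max_nfev=300)
        except (ValueError, RuntimeError):
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
            if _r_squared(y, resid(sol.x) + y) > 0.995:
                break
    if best is None:
        return _FAILED_SF
    curve = model(best.x, _SF_EVAL_GRID)
    i_peak = int(np.argmax(curve))
    r2 = _r_squared(y, resid(best.x) + y)
    return SfFit(float(best.x[0]), float(best.x[1]), float(best.x[2]),
                 float(best.x[3]), float(best.x[4]), r2,
                 float(_SF_EVAL_GRID[i_peak]), float(curve[i_peak]))


def compute_odi(r_i: float, r_c: float) -> float:
    """Ocular dominance index (R_i - R_c)/(R_i + R_c) in [-1, 1].

    -1 is complete contralateral preference, +1 complete ipsilateral,
    0 balanced.  A non-positive denominator is an exclusion condition.
    """
    denom = r_i + r_c
    if denom <= 0:
        raise ValueError(f"R_i + R_c must be positive, got {denom}")
    return float(np.clip((r_i - r_c) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# population analysis
# ---------------------------------------------------------------------------

def _table_to_array(table: pd.DataFrame, design: StimulusDesign):
    """Reshape the trial table to (neuron, eye, sf, size, ori, dir, trial)."""
    eyes = list(design.eye_conditions)
    sfs = list(design.spatial_frequencies_cpd)
    oris = list(design.orientations_deg)
    t = table.copy()
    t["eye"] = pd.Categorical(t["eye"], categories=eyes, ordered=True)
    t = t.sort_values(["neuron", "eye", "sf_cpd", "size_idx",
                       "orientation_deg", "direction", "trial"], kind="mergesort")
    neurons = t["neuron"].unique()
    shape = (len(neurons), len(eyes), len(sfs), design.n_sizes, len(oris),
             design.directions_per_orientation, design.trials_per_direction)
    expected = int(np.prod(shape))
    if len(t) != expected:
        raise ValueError(f"table has {len(t)} rows, expected {expected} "
                         "(incomplete factorial?)")
    return neurons, t["response"].to_numpy(dtype=float).reshape(shape)


def analyze_population(table: pd.DataFrame, design: StimulusDesign | None = None,
                       alpha_direction: float = 0.05, alpha_friedman: float = 0.01,
                       r2_min: float = 0.5, fit_starts: int = 5) -> pd.DataFrame:
    """Per-neuron tuning screens, curve fits, and ocular dominance indices.

    Runs the whole selection cascade on a trialwise response table: direction
    selectivity, best-condition selection, Friedman orientation/SF screens on
    the monocular conditions, trial-level Gaussian and DoG fits for every eye
    condition, and the ODI from the fitted monocular peak responses.

    Returns one row per neuron; `tuned` marks neurons passing the joint
    screen in at least one monocular condition, `valid` marks a usable
    (positive) monocular peak sum.
    """
    design = design or build_stimulus_design()
    neurons, arr = _table_to_array(table, design)
    eyes = list(design.eye_conditions)
    mono_idx = [eyes.index(e) for e in MONOCULAR_EYES if e in eyes]
    sfs = np.asarray(design.spatial_frequencies_cpd)
    oris = np.asarray(design.orientations_deg)
    n_dir = design.directions_per_orientation
    n_tr = design.trials_per_direction

    rows = []
    for j, nid in enumerate(neurons):
        r = arr[j]                                  # (e, s, z, o, d, t)
        # direction screen over all monocular (condition, trial) blocks
        mono = r[mono_idx]                          # (2, s, z, o, d, t)
        blocks = mono.transpose(0, 1, 2, 3, 5, 4).reshape(-1, n_dir)
        selective, pref_dir, p_dir = direction_selectivity_test(blocks, alpha_direction)

        row = {"neuron": nid, "direction_selective": selective,
               "preferred_direction": pref_dir, "p_direction": p_dir}
        peaks, fried_ori, fried_sf, r2_ori_mono, r2_sf_mono = {}, [], [], [], []
        for e, eye in enumerate(eyes):
            if selective:
                trials_es = r[e, :, :, :, pref_dir, :]          # (s, z, o, t)
                agg = trials_es.mean(axis=-1)
            else:
                flat = r[e].reshape(r[e].shape[:3] + (n_dir * n_tr,))
                agg = (flat.sum(axis=-1) - flat.min(axis=-1)) / (flat.shape[-1] - 1)
                trials_es = flat
            s_b, z_b, o_b = select_best_condition(agg)
            ori_trials = trials_es[s_b, z_b]                    # (o, trials)
            sf_trials = trials_es[:, z_b, o_b]                  # (s, trials)

            ofit = fit_orientation(oris, ori_trials, n_starts=fit_starts)
            sfit = fit_sf(sfs, sf_trials, n_starts=fit_starts)
            peaks[eye] = ofit.peak if np.isfinite(ofit.r2) else sfit.peak
            if e in mono_idx:
                fried_ori.append(friedman_screen(ori_trials, alpha_friedman))
                fried_sf.append(friedman_screen(sf_trials, alpha_friedman))
                r2_ori_mono.append(ofit.r2)
                r2_sf_mono.append(sfit.r2)
            p = eye if eye != "binocular" else "binoc"
            row.update({f"{p}_best_sf_cpd": sfs[s_b], f"{p}_best_size_idx": z_b,
                        f"{p}_best_orientation_deg": oris[o_b],
                        f"{p}_a1": ofit.a1, f"{p}_theta0_deg": ofit.theta0_deg,
                        f"{p}_sigma_ori_deg": ofit.sigma_deg,
                        f"{p}_b_ori": ofit.baseline, f"{p}_r2_ori": ofit.r2,
                        f"{p}_a1_sf": sfit.a1, f"{p}_sigma1_sf": sfit.sigma1,
                        f"{p}_a2_sf": sfit.a2, f"{p}_sigma2_sf": sfit.sigma2,
                        f"{p}_b_sf": sfit.baseline, f"{p}_r2_sf": sfit.r2,
                        f"{p}_pref_sf_cpd": sfit.pref_sf_cpd,
                        f"{p}_peak": peaks[eye]})

        ori_tuned = any(f and r2 > r2_min for f, r2 in zip(fried_ori, r2_ori_mono))
        sf_tuned = any(f and r2 > r2_min for f, r2 in zip(fried_sf, r2_sf_mono))
        r_c, r_i = peaks.get("contra", math.nan), peaks.get("ipsi", math.nan)
        valid = np.isfinite(r_c) and np.isfinite(r_i) and (r_i + r_c) > 0
        row.update({
            "ori_tuned": ori_tuned, "sf_tuned": sf_tuned,
            "tuned": ori_tuned or sf_tuned, "valid": valid,
            "r_c": r_c, "r_i": r_i, "r_b": peaks.get("binocular", math.nan),
            "odi": compute_odi(r_i, r_c) if valid else math.nan,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def render_od_map(positions, odis, fov_shape=(256, 256), marker_radius: float = 4.0):
    """Ocular dominance map: one colored disk per neuron on a dark canvas.

    Colors run blue (ODI = -1, contralateral) through white (0) to red (+1,
    ipsilateral), the conventional coding for ocular dominance maps.
    """
    import matplotlib

    canvas = np.zeros(tuple(fov_shape) + (3,), dtype=float)
    cmap = matplotlib.colormaps["bwr"]
    for (row, col), odi in zip(positions, odis):
        color = np.array(cmap((float(odi) + 1.0) / 2.0)[:3])
        rr, cc = np.ogrid[:fov_shape[0], :fov_shape[1]]
        disk = (rr - row) ** 2 + (cc - col) ** 2 <= marker_radius ** 2
        canvas[disk] = color
    return canvas
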
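"""Ocular-dominance-dependent binocular combination model.

The model describes how a V1 neuron's monocular responses depend on its
ocular dominance index (ODI) and how the two monocular signals combine
under binocular stimulation.  With ``w_c = (ODI + 1) / 2`` and
``w_i = 1 - w_c`` the eye weights on [0, 1]:

    monocular:   R_c = w_c**m_c * k          R_i = w_i**m_i * k
    binocular:   R_b = (w_i**m_i * k) / w_i**b + (w_c**m_c * k) / w_c**b

``k`` is a divisive gain constant shared between the eyes, ``m_c`` and
``m_i`` are monocular nonlinearity exponents (empirically negative and
close to -1), and ``b`` is the interocular suppression exponent.  When
the other eye receives no stimulus the suppression factor is 1 and the
binocular expression reduces exactly to the sum of the monocular ones.

Fitting follows the population procedure: responses are normalized by the
field-of-view median binocular response, neurons are sorted by ODI into 60
equal-count bins, and bin medians are fit by least squares -- first the two
monocular curves jointly with a shared ``k``, then the binocular curve with
``b`` as the only free parameter.  Goodness of fit is summarised by
``q = 1 - RMS(residual) / mean(data)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "W_EPS",
    "BinnedPopulation",
    "CombinationModelFit",
    "ModulationRecord",
    "ModelCurves",
    "odi_to_weights",
    "eval_monocular",
    "eval_binocular",
    "normalize_population",
    "bin_by_odi",
    "fit_monocular",
    "fit_binocular",
    "fit_quality",
    "modulation_analysis",
    "simulate_curves",
]

#: Clipping bound on the eye weights w_c, w_i.  w**m diverges at w = 0 for
#: negative exponents; real populations contain no neurons at |ODI| = 1, so
#: the pole is never data-supported and is clipped away.
W_EPS = 1e-3

_FIT_BOUNDS_K = (1e-6, 100.0)
_FIT_BOUNDS_M = (-5.0, 5.0)
_FIT_BOUNDS_B = (-5.0, 5.0)
_N_STARTS = 5
_START_SEED = 20240403  # fixed: multi-start jitter is not a source of run-to-run variance


@dataclass
class BinnedPopulation:
    """ODI-ordered equal-count bins of median normalized responses."""

    odi: np.ndarray          # representative (median) ODI per bin
    r_c: np.ndarray          # median normalized contralateral response
    r_i: np.ndarray          # median normalized ipsilateral response
    r_b: np.ndarray          # median normalized binocular response
    counts: np.ndarray       # member count per bin
    norm_constant: float = float("nan")  # FOV median binocular response

    @property
    def n_bins(self) -> int:
        return len(self.odi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"odi": self.odi, "r_c": self.r_c, "r_i": self.r_i,
             "r_b": self.r_b, "count": self.counts}
        )


@dataclass
class CombinationModelFit:
    """Fitted parameters of the divisive combination model.

    The stimulus contrasts ``s_c`` and ``s_i`` are stored for provenance but
    drop out of the simplified equations (response saturation makes a 0.9
    contrast effectively full).
    """

    k: float
    m_c: float
    m_i: float
    b_supp: float
    q_contra: float
    q_ipsi: float
    q_binoc: float
    s_c: float = 0.9
    s_i: float = 0.9

    def as_dict(self) -> dict:
        return {
            "k": self.k, "m_c": self.m_c, "m_i": self.m_i,
            "b_supp": self.b_supp, "q_contra": self.q_contra,
            "q_ipsi": self.q_ipsi, "q_binoc": self.q_binoc,
            "s_c": self.s_c, "s_i": self.s_i,
        }


@dataclass
class ModulationRecord:
    """Per-neuron binocular modulation and its regression on |ODI|."""

    table: pd.DataFrame      # columns: neuron, r_b, r_mono_max, difference, index, abs_odi
    slope: float
    intercept: float
    p_value: float


@dataclass
class ModelCurves:
    """Model response functions on a dense ODI grid."""

    odi: np.ndarray
    r_c: np.ndarray
    r_i: np.ndarray
    r_sum: np.ndarray            # arithmetic sum R_c + R_i (no suppression)
    r_c_suppressed: np.ndarray   # R_c / w_c**b
    r_i_suppressed: np.ndarray   # R_i / w_i**b
    r_pref: np.ndarray           # preferred-eye envelope max(R_c, R_i)
    r_b: np.ndarray
    medians: dict = field(default_factory=dict)  # per-curve median over data ODI range


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def odi_to_weights(odi, eps: float = W_EPS):
    """Map ODI in [-1, 1] to clipped eye weights (w_c, w_i) in [eps, 1-eps]."""
    odi = np.asarray(odi, dtype=float)
    w_c = np.clip((odi + 1.0) / 2.0, eps, 1.0 - eps)
    w_i = np.clip(1.0 - (odi + 1.0) / 2.0, eps, 1.0 - eps)
    return w_c, w_i


def eval_monocular(odi, k: float, m_c: float, m_i: float, eps: float = W_EPS):
    """Monocular responses R_c = w_c**m_c * k and R_i = w_i**m_i * k.

    Parameters
    ----------
    odi : array-like
        Ocular dominance index, in [-1, 1].
    k : float
        Divisive gain constant, > 0, shared between the eyes.
    m_c, m_i : float
        Monocular nonlinearity exponents.

    Returns
    -------
    (R_c, R_i) : arrays matching the shape of `odi`.
    """
    if k <= 0:
        raise ValueError(f"gain constant k must be positive, got {k}")
    w_c, w_i = odi_to_weights(odi, eps)
    return w_c ** m_c * k, w_i ** m_i * k


def eval_binocular(odi, k: float, m_c: float, m_i: float, b_supp: float,
                   eps: float = W_EPS):
    """Binocular response with divisive interocular suppression.

    R_b = (w_i**m_i * k) / w_i**b + (w_c**m_c * k) / w_c**b

    Each eye's monocular drive is divided by the *other-eye weight* raised to
    the suppression exponent ``b_supp`` and the two suppressed signals are
    summed.  With ``b_supp = 0`` (one eye unstimulated) both suppression
    factors are 1 and the result equals ``R_c + R_i`` exactly.
    """
    r_c, r_i = eval_monocular(odi, k, m_c, m_i, eps)
    w_c, w_i = odi_to_weights(odi, eps)
    return r_i / w_i ** b_supp + r_c / w_c ** b_supp


# ---------------------------------------------------------------------------
# population normalization and binning
# ---------------------------------------------------------------------------

def normalize_population(records: pd.DataFrame,
                         columns: tuple = ("r_c", "r_i", "r_b")) -> pd.DataFrame:
    """Divide each neuron's responses by the population median binocular response.

    After normalization the median of ``r_b`` is 1 by construction (numpy's
    median of an even-sized set is the mean of the middle pair).
    """
    if "r_b" not in records:
        raise ValueError("records must carry a binocular response column 'r_b'")
    med = float(np.median(records["r_b"].to_numpy()))
    if not np.isfinite(med) or med <= 0:
        raise ValueError(f"median binocular response must be positive, got {med}")
    out = records.copy()
    for c in columns:
        out[c] = records[c] / med
    out.attrs["norm_constant"] = med
    return out


def bin_by_odi(records: pd.DataFrame, n_bins: int = 60) -> BinnedPopulation:
    """Sort neurons by ODI and split into `n_bins` contiguous equal-count bins.

    Ties in ODI are broken by neuron id so the split is deterministic.  With
    ``r = len(records) mod n_bins`` the first ``r`` bins receive one extra
    member; bin medians of ODI and of the three responses are returned.
    """
    n = len(records)
    if n < n_bins:
        raise ValueError(f"cannot split {n} records into {n_bins} bins")
    sort_cols = ["odi", "neuron"] if "neuron" in records else ["odi"]
    ordered = records.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])

    med = {c: np.empty(n_bins) for c in ("odi", "r_c", "r_i", "r_b")}
    for j in range(n_bins):
        chunk = ordered.iloc[edges[j]:edges[j + 1]]
        for c in med:
            med[c][j] = float(np.median(chunk[c].to_numpy()))
    return BinnedPopulation(
        odi=med["odi"], r_c=med["r_c"], r_i=med["r_i"], r_b=med["r_b"],
        counts=sizes, norm_constant=records.attrs.get("norm_constant", float("nan")),
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_quality(observed, predicted) -> float:
    """Fit quality index q = 1 - RMS(observed - predicted) / mean(observed).

    q equals 1 iff all residuals vanish and is invariant to a common positive
    rescaling of data and model.
    """
    r = np.asarray(observed, dtype=float)
    m = np.asarray(predicted, dtype=float)
    if r.shape != m.shape:
        raise ValueError("observed and predicted must have equal length")
    mean_r = r.mean()
    if mean_r <= 0:
        raise ValueError(f"observed responses must have positive mean, got {mean_r}")
    return 1.0 - float(np.sqrt(np.mean((r - m) ** 2))) / float(mean_r)


def _multi_starts(x0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                  n: int = _N_STARTS) -> list:
    rng = np.random.default_rng(_START_SEED)
    starts = [x0]
    for _ in range(n - 1):
        jitter = x0 * (1.0 + 0.3 * rng.standard_normal(x0.size)) \
            + 0.1 * rng.standard_normal(x0.size)
        starts.append(np.clip(jitter, lo + 1e-9, hi - 1e-9))
    return starts


def fit_monocular(binned: BinnedPopulation):
    """Jointly fit the two monocular curves with a shared gain constant.

    Least squares over the concatenated contralateral and ipsilateral bin
    medians with parameters (k, m_c, m_i); k is constrained equal across the
    two curves.  Multi-start from a fixed seed guards against local minima.

    Returns
    -------
    (k, m_c, m_i, q_contra, q_ipsi)
    """
    odi, r_c, r_i = binned.odi, binned.r_c, binned.r_i
    lo = np.array([_FIT_BOUNDS_K[0], _FIT_BOUNDS_M[0], _FIT_BOUNDS_M[0]])
    hi = np.array([_FIT_BOUNDS_K[1], _FIT_BOUNDS_M[1], _FIT_BOUNDS_M[1]])

    def resid(p):
        pc, pi = eval_monocular(odi, p[0], p[1], p[2])
        return np.concatenate([pc - r_c, pi - r_i])

    # k is the response at w = 1; seed it with the strongest monocular medians
    k0 = float(np.clip(np.median(np.concatenate([r_c, r_i])), 0.05, _FIT_BOUNDS_K[1] / 2))
    x0 = np.array([k0, -1.0, -1.0])
    best = None
    for start in _multi_starts(x0, lo, hi):
        try:
            sol = optimize.least_squares(resid, start, bounds=(lo, hi))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and not np.isfinite(best.cost):
        raise RuntimeError("monocular model fit failed to converge from all starts")
    k, m_c, m_i = best.x
    pred_c, pred_i = eval_monocular(odi, k, m_c, m_i)
    return float(k), float(m_c), float(m_i), fit_quality(r_c, pred_c), fit_quality(r_i, pred_i)


def fit_binocular(binned: BinnedPopulation, k: float, m_c: float, m_i: float):
    """Fit the suppression exponent with monocular parameters frozen.

    (k, m_c, m_i) are inherited from :func:`fit_monocular`; the suppression
    exponent is the single free parameter of the binocular curve.

    Returns
    -------
    (b_supp, q_binoc)
    """
    odi, r_b = binned.odi, binned.r_b

    def resid(p):
        return eval_binocular(odi, k, m_c, m_i, p[0]) - r_b

    best = None
    for b0 in (0.0, -0.5, -1.0, 0.5, -2.0):
        sol = optimize.least_squares(resid, [b0], bounds=([_FIT_BOUNDS_B[0]], [_FIT_BOUNDS_B[1]]))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("binocular model fit failed to converge")
    b_supp = float(best.x[0])
    q = fit_quality(r_b, eval_binocular(odi, k, m_c, m_i, b_supp))
    return b_supp, q


def fit_combination_model(binned: BinnedPopulation) -> CombinationModelFit:
    """Full two-stage fit: shared-k monocular fit, then inherited binocular fit."""
    k, m_c, m_i, q_c, q_i = fit_monocular(binned)
    b_supp, q_b = fit_binocular(binned, k, m_c, m_i)
    return CombinationModelFit(k=k, m_c=m_c, m_i=m_i, b_supp=b_supp,
                               q_contra=q_c, q_ipsi=q_i, q_binoc=q_b)


# ---------------------------------------------------------------------------
# population-level descriptive analyses
# ---------------------------------------------------------------------------

def modulation_analysis(records: pd.DataFrame) -> ModulationRecord:
    """Binocular modulation index vs |ODI| with an ordinary least-squares fit.

    The modulation index (R_b - max(R_i, R_c)) / (R_b + max(R_i, R_c)) is
    positive when binocular stimulation facilitates the response relative to
    the preferred eye, negative when it suppresses it.
    """
    r_b = records["r_b"].to_numpy(dtype=float)
    r_max = np.maximum(records["r_c"].to_numpy(dtype=float),
                       records["r_i"].to_numpy(dtype=float))
    diff = r_b - r_max
    index = diff / (r_b + r_max)
    abs_odi = np.abs(records["odi"].to_numpy(dtype=float))
    if np.allclose(abs_odi, abs_odi[0]):
        raise ValueError("regression undefined: all |ODI| identical")
    fit = stats.linregress(abs_odi, index)
    table = pd.DataFrame({
        "neuron": records["neuron"] if "neuron" in records else np.arange(len(records)),
        "r_b": r_b, "r_mono_max": r_max, "difference": diff,
        "index": index, "abs_odi": abs_odi,
    })
    return ModulationRecord(table=table, slope=float(fit.slope),
                            intercept=float(fit.intercept), p_value=float(fit.pvalue))


def simulate_curves(fit: CombinationModelFit, odi_grid=None,
                    data_odi_range: tuple | None = None) -> ModelCurves:
    """Evaluate all model response functions on a dense ODI grid.

    Returns the monocular curves, their arithmetic sum, the interocular-
    suppressed components, the preferred-eye envelope and the binocular
    curve, plus the median of each over the data-supported ODI range.
    """
    if odi_grid is None:  # default stops short of the poles at +-1
        odi_grid = np.linspace(-1.0 + 2.0 * W_EPS, 1.0 - 2.0 * W_EPS, 1001)
    odi_grid = np.asarray(odi_grid, dtype=float)
    if np.any(np.abs(odi_grid) > 1.0 - 2.0 * W_EPS):
        # |ODI| = 1 sits on the w**m pole; the weight clip bounds those
        # grid points, but they lie outside any real population's range
        warnings.warn("ODI grid touches the +-1 endpoints; weights are "
                      f"clipped at eps = {W_EPS}", RuntimeWarning,
                      stacklevel=2)
    r_c, r_i = eval_monocular(odi_grid, fit.k, fit.m_c, fit.m_i)
    w_c, w_i = odi_to_weights(odi_grid)
    r_c_sup = r_c / w_c ** fit.b_supp
    r_i_sup = r_i / w_i ** fit.b_supp
    curves = ModelCurves(
        odi=odi_grid, r_c=r_c, r_i=r_i, r_sum=r_c + r_i,
        r_c_suppressed=r_c_sup, r_i_suppressed=r_i_sup,
        r_pref=np.maximum(r_c, r_i), r_b=r_c_sup + r_i_sup,
    )
    if data_odi_range is not None:
        lo, hi = data_odi_range
        sel = (odi_grid >= lo) & (odi_grid <= hi)
        for name in ("r_c", "r_i", "r_sum", "r_pref", "r_b"):
            curves.medians[name] = float(np.median(getattr(curves, name)[sel]))
    return curves
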
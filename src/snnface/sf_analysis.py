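"""Spatial-frequency reference-frame analysis of final-layer units.

Each FC1 unit is probed with bandpass-filtered faces over a 61-value ladder
of object-based center SFs (1–64 cycles/object, 0.1 log2 steps) at two
stimulus sizes (198 and 99 px).  The unit's preferred SF is estimated at each
size and the normalized log2 difference

    shift = (log2 peak_large − log2 peak_small) / log2(size ratio)

distinguishes retina-based coding (shift = 1: the preferred object-based SF
doubles when the face halves, i.e. the unit tracks a fixed retinal frequency)
from object-based, size-invariant coding (shift = 0).

Units are excluded when they do not respond at all, when their tuning curve
is too flat to define a preference, or when the maximum sits at either end of
the tested ladder so the peak cannot be localized.

The population distribution of peak shifts is then summarized by Gaussian
kernel density estimation (mode locations and heights) and its number of
modes is tested with a bootstrap-calibrated excess-mass statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .architectures import Model
from .stimuli import CANVAS, bandpass_stimulus_batch, center_sf_grid

#: Flatness threshold: a curve with (max − min)/max below this has no usable
#: SF preference.
SF_INSENSITIVE_EPS = 0.1

FC1_LAYER = "relu_fc1"  # FC1 responses are taken after its ReLU


@dataclass(frozen=True)
class TuningRecord:
    """One unit × expression × size SF tuning curve."""

    unit: int
    expression: str
    size: int
    responses: np.ndarray  # length-61, over center_sf_grid()
    peak_sf: Optional[float]
    exclusion: str  # {none, unresponsive, sf_insensitive, boundary_peak}
    model_id: int = 0


@dataclass(frozen=True)
class PeakShiftRecord:
    unit: int
    expression: str
    peak_large: float
    peak_small: float
    shift: float
    model_id: int = 0


# ---------------------------------------------------------------------------
# Peak estimation
# ---------------------------------------------------------------------------


def estimate_peak_sf(
    responses: np.ndarray,
    grid: Optional[np.ndarray] = None,
    eps: float = SF_INSENSITIVE_EPS,
) -> tuple[Optional[float], str]:
    """Raw grid argmax with exclusion rules; ties break to the lower SF.

    Returns (peak_sf, exclusion) with peak_sf present iff exclusion is
    ``"none"``.
    """
    responses = np.asarray(responses, np.float64)
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    if responses.shape != grid.shape:
        raise ValueError("curve length must match the SF grid")
    mx = responses.max()
    if mx <= 0:
        return None, "unresponsive"
    if (mx - responses.min()) < eps * mx:
        return None, "sf_insensitive"
    idx = int(np.argmax(responses))
    if idx == 0 or idx == len(grid) - 1:
        return None, "boundary_peak"
    return float(grid[idx]), "none"


def make_tuning_record(
    responses: np.ndarray,
    unit: int,
    expression: str,
    size: int,
    grid: Optional[np.ndarray] = None,
    eps: float = SF_INSENSITIVE_EPS,
    model_id: int = 0,
) -> TuningRecord:
    peak, excl = estimate_peak_sf(responses, grid, eps)
    return TuningRecord(unit, expression, size, np.asarray(responses), peak, excl, model_id)


def peak_shift(large: TuningRecord, small: TuningRecord) -> PeakShiftRecord:
    """Normalized log2 peak difference between the two sizes of one pair.

    Positive when the large-stimulus peak is at a higher object-based SF.
    Excluded records cannot form a pair (the pair is dropped, never
    zero-filled).
    """
    if large.unit != small.unit or large.expression != small.expression:
        raise ValueError("records must describe the same unit and expression")
    if large.size <= small.size:
        raise ValueError("first record must be the larger stimulus size")
    if large.exclusion != "none" or small.exclusion != "none":
        raise ValueError("cannot compute a peak shift from an excluded record")
    denom = np.log2(large.size / small.size)
    shift = (np.log2(large.peak_sf) - np.log2(small.peak_sf)) / denom
    return PeakShiftRecord(
        large.unit, large.expression, large.peak_sf, small.peak_sf, float(shift), large.model_id
    )


# ---------------------------------------------------------------------------
# Model tuning curves
# ---------------------------------------------------------------------------


def fc1_tuning_curves(
    model: Model,
    faces: Sequence[np.ndarray],
    size: int,
    grid: Optional[np.ndarray] = None,
    batch: int = 61,
) -> np.ndarray:
    """(61, n_units) FC1 responses averaged over individuals' filtered faces.

    ``faces`` are 198×198 grayscale face images of different individuals
    sharing one expression.
    """
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    if len(faces) == 0:
        raise ValueError("at least one face image is required")
    total = None
    for face in faces:
        stims = bandpass_stimulus_batch(face, grid, size)
        _, rec = model.forward(stims, record=[FC1_LAYER])
        resp = rec[FC1_LAYER]
        total = resp if total is None else total + resp
    return total / len(faces)


def sf_tuning_curve(
    model: Model,
    unit: int,
    expression: str,
    size: int,
    faces: Sequence[np.ndarray],
    grid: Optional[np.ndarray] = None,
    eps: float = SF_INSENSITIVE_EPS,
    model_id: int = 0,
) -> TuningRecord:
    """TuningRecord for a single unit (see fc1_tuning_curves for batching)."""
    curves = fc1_tuning_curves(model, faces, size, grid)
    return make_tuning_record(curves[:, unit], unit, expression, size, grid, eps, model_id)


def unit_tuning_records(
    model: Model,
    faces_by_expression: dict[str, Sequence[np.ndarray]],
    sizes: tuple[int, int] = (CANVAS, CANVAS // 2),
    grid: Optional[np.ndarray] = None,
    eps: float = SF_INSENSITIVE_EPS,
    model_id: int = 0,
) -> list[TuningRecord]:
    """All FC1 tuning records: unit × expression × size."""
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    out: list[TuningRecord] = []
    for expression, faces in faces_by_expression.items():
        for size in sizes:
            curves = fc1_tuning_curves(model, faces, size, grid)
            for unit in range(curves.shape[1]):
                out.append(
                    make_tuning_record(
                        curves[:, unit], unit, expression, size, grid, eps, model_id
                    )
                )
    return out


def peak_shift_distribution(
    records: Sequence[TuningRecord],
    sizes: tuple[int, int] = (CANVAS, CANVAS // 2),
    grid: Optional[np.ndarray] = None,
) -> tuple[list[PeakShiftRecord], np.ndarray, dict]:
    """Pool peak shifts over (model, unit, expression) pairs.

    Returns (records, hist2d, bookkeeping).  ``hist2d`` is the 2-D histogram
    of (peak_large, peak_small) on the log2 SF grid with bin edges midway
    between ladder values.  Bookkeeping counts candidates, retained pairs and
    exclusions (retained + excluded = candidates).
    """
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    large_size, small_size = max(sizes), min(sizes)
    by_key: dict[tuple, dict[int, TuningRecord]] = {}
    for r in records:
        by_key.setdefault((r.model_id, r.unit, r.expression), {})[r.size] = r
    shifts: list[PeakShiftRecord] = []
    n_excluded = 0
    for key, pair in by_key.items():
        if set(pair) != {large_size, small_size}:
            raise ValueError(f"missing size for pair {key}")
        large, small = pair[large_size], pair[small_size]
        if large.exclusion != "none" or small.exclusion != "none":
            n_excluded += 1
            continue
        shifts.append(peak_shift(large, small))
    log_grid = np.log2(grid)
    step = log_grid[1] - log_grid[0]
    edges = np.concatenate([log_grid - step / 2, [log_grid[-1] + step / 2]])
    hist, _, _ = np.histogram2d(
        [np.log2(s.peak_large) for s in shifts],
        [np.log2(s.peak_small) for s in shifts],
        bins=(edges, edges),
    )
    bookkeeping = {
        "candidates": len(by_key),
        "retained": len(shifts),
        "excluded": n_excluded,
    }
    return shifts, hist, bookkeeping


# ---------------------------------------------------------------------------
# KDE mode localization
# ---------------------------------------------------------------------------


def kde_mode_locations(
    values: Sequence[float],
    bandwidth="silverman",
    grid_size: int = 2048,
) -> list[tuple[float, float]]:
    """Local maxima of a Gaussian KDE, as (location, height), tallest first."""
    values = np.asarray(values, np.float64)
    if values.size < 10:
        raise ValueError("need at least 10 values for KDE mode estimation")
    kde = gaussian_kde(values, bw_method=bandwidth)
    h = kde.factor * values.std(ddof=1)
    xs = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    dens = kde(xs)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior) + 1
    modes = sorted(((float(xs[i]), float(dens[i])) for i in idx), key=lambda t: -t[1])
    return modes


def _kde_mode_count(values: np.ndarray, h: float, grid_size: int = 512) -> int:
    lo = values.min() - 3 * h
    hi = values.max() + 3 * h
    xs = np.linspace(lo, hi, grid_size)
    # direct Gaussian KDE evaluation with explicit bandwidth h
    z = (xs[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    return int(interior.sum())


def critical_bandwidth(values: np.ndarray, k: int, tol: float = 1e-3) -> float:
    """Smallest Gaussian-KDE bandwidth giving at most k modes (Silverman).

    Mode count is non-increasing in bandwidth for the Gaussian kernel, so
    bisection is valid.
    """
    values = np.asarray(values, np.float64)
    spread = values.std(ddof=1)
    if spread == 0:
        raise ValueError("degenerate (constant) sample")
    lo, hi = 1e-4 * spread, 4.0 * spread
    while _kde_mode_count(values, hi) > k:
        hi *= 2.0
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        if _kde_mode_count(values, mid) <= k:
            hi = mid
        else:
            lo = mid
        if hi / lo < 1 + tol:
            break
    return float(hi)


# ---------------------------------------------------------------------------
# Excess-mass multimodality test
# ---------------------------------------------------------------------------


def _excess_masses(sorted_x: np.ndarray, lambdas: np.ndarray, kmax: int) -> np.ndarray:
    """Empirical excess masses E_1..E_kmax on a λ grid, batched.

    ``sorted_x`` has shape (B, n) with each row sorted ascending.  E_k(λ) is
    the maximum over k disjoint intervals [x_i, x_j] of
    Σ (count/n − λ·length), computed by dynamic programming in O(n·k) per λ.
    Returns shape (B, kmax, L).
    """
    B, n = sorted_x.shape
    L = len(lambdas)
    lam = lambdas[None, :]  # (1, L)
    A = np.zeros((kmax + 1, B, L))  # A[m] = best score with ≤ m intervals
    R = np.full((kmax + 1, B, L), -np.inf)  # running max over interval starts
    for j in range(1, n + 1):
        xj = sorted_x[:, j - 1][:, None]  # (B, 1)
        start_term = lam * xj - (j - 1) / n
        end_term = j / n - lam * xj
        for m in range(kmax, 0, -1):
            np.maximum(R[m], A[m - 1] + start_term, out=R[m])
            np.maximum(A[m], R[m] + end_term, out=A[m])
    return np.transpose(A[1:], (1, 0, 2))  # (B, kmax, L)


def _lambda_grid(values: np.ndarray, n_lambda: int = 40) -> np.ndarray:
    kde = gaussian_kde(values)
    peak = kde(np.linspace(values.min(), values.max(), 256)).max()
    return np.geomspace(0.002, 2.0, n_lambda) * peak


def excess_mass_statistic(
    values: np.ndarray, k: int, lambdas: Optional[np.ndarray] = None
) -> float:
    """Δ_{k+1,k} = max_λ [E_{k+1}(λ) − E_k(λ)]: evidence for > k modes."""
    values = np.sort(np.asarray(values, np.float64))
    if lambdas is None:
        lambdas = _lambda_grid(values)
    E = _excess_masses(values[None, :], lambdas, k + 1)[0]
    return float((E[k] - E[k - 1]).max())


def _dither_ties(values: np.ndarray, rng) -> np.ndarray:
    """Break exact ties with uniform jitter at the quantization scale.

    Peak SFs live on a discrete log2 ladder, so peak-shift samples carry many
    exact duplicates.  Tied clusters inflate the empirical excess mass (a
    zero-length interval captures the whole cluster at any λ), which the
    continuous bootstrap null cannot reproduce; dithering by ± half the
    smallest positive spacing restores a continuous sample while leaving the
    distribution's shape at any coarser scale untouched.
    """
    distinct = np.unique(values)
    if distinct.size == values.size:
        return values
    gaps = np.diff(distinct)
    # quantization step = smallest gap clearly above float-rounding noise
    # (grid values computed along different arithmetic paths split into
    # clusters a few ulp wide, so the raw minimum gap underestimates badly)
    eps = (distinct[-1] - distinct[0]) * 1e-9
    real = gaps[gaps > eps]
    if real.size == 0:
        return values
    d = float(real.min())
    return values + rng.uniform(-d / 2, d / 2, size=values.shape)


def excess_mass_test(
    values: Sequence[float],
    k: int = 1,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Bootstrap-calibrated excess-mass test of H0: exactly k modes.

    The null is calibrated by smoothed-bootstrap resampling from the Gaussian
    KDE at the critical bandwidth for k modes (variance-rescaled), the
    standard construction for mode-count tests.  Exactly tied values (from
    grid-quantized inputs) are dithered at the quantization scale first.
    Returns a dict with the observed statistic, p-value, and the critical
    bandwidth used.
    """
    values = np.asarray(values, np.float64)
    if values.size < 30:
        raise ValueError("need at least 30 values")
    if values.std(ddof=1) == 0:
        raise ValueError("degenerate (constant) sample")
    values = _dither_ties(values, np.random.default_rng(seed))
    lambdas = _lambda_grid(values)
    observed = excess_mass_statistic(values, k, lambdas)
    h = critical_bandwidth(values, k)
    rng = np.random.default_rng(seed)
    n = values.size
    mean = values.mean()
    shrink = 1.0 / np.sqrt(1.0 + h * h / values.var(ddof=1))
    picks = values[rng.integers(0, n, size=(n_boot, n))]
    boots = mean + (picks - mean + h * rng.standard_normal((n_boot, n))) * shrink
    boots.sort(axis=1)
    E = _excess_masses(boots, lambdas, k + 1)
    stats = (E[:, k, :] - E[:, k - 1, :]).max(axis=1)
    p = (1.0 + np.sum(stats >= observed)) / (n_boot + 1.0)
    return {"statistic": observed, "p_value": float(p), "bandwidth": h, "k": k}


def estimate_mode_count(
    values: Sequence[float],
    alpha: float = 0.05,
    max_k: int = 6,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[int, list[dict]]:
    """Smallest k whose excess-mass test is not rejected at level alpha."""
    results = []
    for k in range(1, max_k + 1):
        res = excess_mass_test(values, k, n_boot=n_boot, seed=seed + k)
        results.append(res)
        if res["p_value"] > alpha:
            return k, results
    return max_k, results
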
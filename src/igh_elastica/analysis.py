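"""Analysis of force-extension traces from modular-filament pulling.

Implements the standard single-molecule AFM workflow for saw-tooth
traces plus the plateau-specific procedures used for near-equilibrium
helix unfolding:

* ``detect_events``            -- saw-tooth unfolding-event detection;
* ``fit_wlc_segments``         -- per-segment WLC fits at fixed
  persistence length, yielding contour lengths and dL increments;
* ``contour_length_transform`` -- map each (force, extension) sample to
  the contour length of the WLC passing through it;
* ``fit_peak_spacing``         -- Gaussian decomposition of the
  contour-length histogram and the mean peak-to-peak spacing;
* ``detect_plateau``           -- locate a near-constant-force region
  and report its median force;
* ``hysteresis``               -- signed area between stretch and relax
  curves.

The persistence length is fixed (default 0.5 nm) during all fits, never
a free parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import minimize_scalar

from igh_elastica.mechanics import ForceExtensionTrace, _phi, _phi_inv, thermal_energy

__all__ = [
    "UnfoldingEvent",
    "ContourLengthSeries",
    "PeakSet",
    "PlateauResult",
    "detect_events",
    "fit_wlc_segments",
    "contour_length_transform",
    "fit_peak_spacing",
    "detect_plateau",
    "hysteresis",
]


@dataclass(frozen=True)
class UnfoldingEvent:
    """One saw-tooth unfolding event.

    ``segment`` is the index range [start, peak] of the rising branch
    that precedes the force drop.
    """

    segment: tuple[int, int]
    peak_index: int
    time: float
    peak_force: float
    force_drop: float
    contour_length: float | None = None


@dataclass(frozen=True)
class ContourLengthSeries:
    """Per-sample contour lengths (nm) for samples above the force floor."""

    values: np.ndarray
    sample_indices: np.ndarray
    n_below_floor: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PeakSet:
    """Gaussian components of a contour-length histogram, sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    spacing: float | None

    @property
    def n_peaks(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class PlateauResult:
    """A near-constant-force region of a stretch curve."""

    force: float  # median force over the plateau, pN
    extension_range: tuple[float, float]  # nm
    span: float  # nm
    n_samples: int


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    # reflect padding keeps the ends unbiased
    pad = width // 2
    yp = np.pad(y, pad, mode="reflect")
    out = np.convolve(yp, kernel, mode="same")[pad : pad + len(y)]
    return out


def detect_events(
    trace: ForceExtensionTrace,
    min_drop: float = 25.0,
    window: int | None = None,
    smooth: int | None = None,
) -> list[UnfoldingEvent]:
    """Detect saw-tooth unfolding events: sustained force drops >= ``min_drop``.

    The force is boxcar-smoothed (default half the drop window) and
    candidate peaks are taken where the smoothed force falls by at least
    ``min_drop`` within ``window`` samples (default 1 ms worth) while
    the stage keeps advancing.  The drop must persist to the end of the
    window: reversible helix flickers near the plateau recover within a
    fraction of a millisecond and are thereby rejected, while
    irreversible domain unfolding leaves the force low until the stage
    reloads the chain.  Events are ordered by time; an empty list is a
    valid result.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    rate = trace.metadata.get("protocol", {}).get("sampling_rate")
    if window is None:
        window = max(3, int(round((rate or 20_000.0) * 1e-3)))
    if smooth is None:
        smooth = max(1, window // 2)
    fs = _smooth(np.asarray(trace.force, dtype=float), smooth)

    peaks, props = signal.find_peaks(fs, prominence=min_drop)
    events: list[UnfoldingEvent] = []
    prev_end = 0
    n = len(fs)
    for p in peaks:
        hi = min(n, p + window + 1)
        drop = fs[p] - fs[p:hi].min()
        if drop < min_drop:
            continue
        if fs[p] - fs[hi - 1] < min_drop:
            continue  # transient flicker: force recovered within the window
        if trace.stage_position[min(n - 1, p + 1)] < trace.stage_position[max(0, p - 1)]:
            continue  # relaxation phase
        events.append(
            UnfoldingEvent(
                segment=(prev_end, p),
                peak_index=p,
                time=float(trace.time[p]),
                peak_force=float(trace.force[p]),
                force_drop=float(drop),
            )
        )
        # next rising branch starts once the force has fallen
        prev_end = int(p + np.argmin(fs[p:hi]))
    return events


def _fit_single_wlc(
    x: np.ndarray,
    F: np.ndarray,
    persistence: float,
    temperature: float,
) -> float:
    """Least-squares contour length of one WLC through (x, F) samples."""
    kp = thermal_energy(temperature) / persistence
    x_max = float(x.max())

    def cost(L: float) -> float:
        f = np.clip(x / L, 0.0, 1.0 - 1e-9)
        return float(np.sum((kp * _phi(f) - F) ** 2))

    res = minimize_scalar(
        cost,
        bounds=(x_max * 1.0000001, x_max * 4.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def fit_wlc_segments(
    trace: ForceExtensionTrace,
    events: list[UnfoldingEvent],
    persistence: float = 0.5,
    temperature: float = 298.0,
    fit_force_min: float = 30.0,
    min_samples: int = 10,
) -> tuple[list[float], list[float]]:
    """WLC contour length of each rising branch and the dL increments.

    For each event's rising segment (and the final branch after the last
    event), samples with force >= ``fit_force_min`` are fitted with a
    Marko-Siggia WLC whose persistence length is fixed; only the contour
    length is free.  The force floor keeps the fit on the taut part of
    the branch, above the helix-unfolding plateau.  Returns the list of
    fitted contour lengths and their successive differences dL.
    Segments with fewer than ``min_samples`` usable samples are skipped
    with a warning.
    """
    x_all = np.asarray(trace.molecular_extension, dtype=float)
    F_all = np.asarray(trace.force, dtype=float)

    bounds = [ev.segment for ev in events]
    if events:
        last_peak = events[-1].peak_index
        # final branch: from after the last drop to the end of the stretch
        start = min(len(trace) - 1, last_peak + 1)
        bounds = bounds + [(start, len(trace) - 1)]

    lengths: list[float] = []
    for lo, hi in bounds:
        x = x_all[lo : hi + 1]
        F = F_all[lo : hi + 1]
        keep = F >= fit_force_min
        if keep.sum() < min_samples:
            warnings.warn(
                f"segment [{lo}, {hi}] has {int(keep.sum())} samples above "
                f"{fit_force_min} pN (< {min_samples}); skipped"
            )
            continue
        lengths.append(
            _fit_single_wlc(x[keep], F[keep], persistence, temperature)
        )
    deltas = list(np.diff(lengths)) if len(lengths) > 1 else []
    return lengths, deltas


def contour_length_transform(
    trace: ForceExtensionTrace,
    persistence: float = 0.5,
    force_floor: float = 5.0,
    temperature: float = 298.0,
    extension_range: tuple[float, float] | None = None,
) -> ContourLengthSeries:
    """Contour length of the WLC through each (force, extension) sample.

    For the Marko-Siggia chain the relative extension f depends on force
    only, so L = x / f(F) sample by sample.  Samples below
    ``force_floor`` are excluded (the inversion amplifies noise there)
    and counted in ``n_below_floor``.  ``extension_range`` optionally
    restricts the transformation, e.g. to a detected plateau region.
    """
    if persistence <= 0 or force_floor <= 0:
        raise ValueError("persistence and force_floor must be > 0")
    x = np.asarray(trace.molecular_extension, dtype=float)
    F = np.asarray(trace.force, dtype=float)
    keep = F >= force_floor
    if extension_range is not None:
        lo, hi = extension_range
        keep &= (x >= lo) & (x <= hi)
    n_below = int((~keep).sum())
    idx = np.nonzero(keep)[0]
    phi = F[idx] * persistence / thermal_energy(temperature)
    f = _phi_inv(phi)
    values = x[idx] / f
    return ContourLengthSeries(values=values, sample_indices=idx, n_below_floor=n_below)


def fit_peak_spacing(
    series: ContourLengthSeries | np.ndarray,
    n_peaks: int | None = None,
    bin_width: float = 0.5,
    prominence_fraction: float = 0.08,
    max_samples: int = 50_000,
    seed: int = 0,
) -> PeakSet:
    """Gaussian decomposition of the contour-length histogram.

    The histogram's local maxima (above a prominence threshold relative
    to the tallest bin) initialize a Gaussian mixture fit of the sample
    values; ``n_peaks`` optionally caps the component count at the most
    prominent maxima.  The reported spacing is the mean of successive
    differences of the sorted component means, or None when fewer than
    two peaks resolve.
    """
    values = np.asarray(
        series.values if isinstance(series, ContourLengthSeries) else series,
        dtype=float,
    )
    if values.size == 0:
        raise ValueError("empty contour-length series")
    lo, hi = values.min(), values.max()
    if hi - lo < bin_width:
        return PeakSet(
            means=np.array([values.mean()]),
            sds=np.array([values.std()]),
            weights=np.array([1.0]),
            spacing=None,
        )
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # zero-pad so clusters in the first/last bin register as maxima
    padded = np.concatenate([[0.0], counts.astype(float), [0.0]])
    peaks, props = signal.find_peaks(
        padded, prominence=prominence_fraction * counts.max()
    )
    peaks = peaks - 1
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(counts))])
        props = {"prominences": np.array([float(counts.max())])}
    if n_peaks is not None and len(peaks) > n_peaks:
        top = np.argsort(props["prominences"])[::-1][:n_peaks]
        peaks = np.sort(peaks[top])
    means_init = centers[peaks].reshape(-1, 1)

    if len(peaks) == 1:
        return PeakSet(
            means=np.array([values.mean()]),
            sds=np.array([values.std()]),
            weights=np.array([1.0]),
            spacing=None,
        )

    from sklearn.mixture import GaussianMixture

    sample = values
    if sample.size > max_samples:
        rng = np.random.default_rng(seed)
        sample = rng.choice(sample, max_samples, replace=False)
    gm = GaussianMixture(
        n_components=len(peaks),
        means_init=means_init,
        covariance_type="full",
        random_state=seed,
        max_iter=500,
    ).fit(sample.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    spacing = float(np.mean(np.diff(means))) if len(means) > 1 else None
    return PeakSet(means=means, sds=sds, weights=weights, spacing=spacing)


def detect_plateau(
    trace: ForceExtensionTrace,
    slope_tol: float = 0.6,
    min_span: float = 10.0,
    force_floor: float = 15.0,
    bin_width: float = 1.0,
) -> PlateauResult | None:
    """Longest near-constant-force region of a stretch curve.

    A candidate extension interval qualifies when the least-squares line
    through its (extension, force) samples has |slope| <= ``slope_tol``
    (pN/nm) -- over the whole interval and over each half, so a steep
    approach cannot be traded against the plateau -- and every populated
    extension bin inside it has mean force >= ``force_floor``.  The
    longest qualifying interval of span >= ``min_span`` nm is returned
    with the median raw force over it, or None when nothing qualifies.

    The force floor discriminates a genuine plateau (near-constant force
    well above zero) from the gently rising low-force toe of a long
    worm-like chain, which is locally just as flat.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    x = np.asarray(trace.molecular_extension, dtype=float)
    F = np.asarray(trace.force, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < min_span:
        return None
    edges = np.arange(lo, hi + bin_width, bin_width)
    nb = len(edges) - 1
    which = np.clip(np.digitize(x, edges) - 1, 0, nb - 1)

    # per-bin aggregates -> exact least-squares slope over any bin range
    n_b = np.bincount(which, minlength=nb).astype(float)
    Sx = np.bincount(which, weights=x, minlength=nb)
    SF = np.bincount(which, weights=F, minlength=nb)
    SxF = np.bincount(which, weights=x * F, minlength=nb)
    Sxx = np.bincount(which, weights=x * x, minlength=nb)

    def cum(a):
        return np.concatenate([[0.0], np.cumsum(a)])

    cn, cx, cf, cxf, cxx = map(cum, (n_b, Sx, SF, SxF, Sxx))
    with np.errstate(invalid="ignore"):
        bin_mean = np.where(n_b > 0, SF / np.maximum(n_b, 1), np.inf)

    def fit(i: int, j: int) -> tuple[float, float, float] | None:
        """(slope, mean force, n) of the least-squares line over bins [i, j)."""
        n = cn[j] - cn[i]
        if n < 20:
            return None
        sx = cx[j] - cx[i]
        sf = cf[j] - cf[i]
        var = (cxx[j] - cxx[i]) - sx * sx / n
        if var <= 0:
            return None
        slope = ((cxf[j] - cxf[i]) - sx * sf / n) / var
        return slope, sf / n, n

    best: tuple[float, int, int] | None = None  # (span, i, j)
    min_bins = max(1, int(math.ceil(min_span / bin_width)))
    for i in range(nb):
        for j in range(i + min_bins, nb + 1):
            res = fit(i, j)
            if res is None:
                continue
            slope, _, _ = res
            if abs(slope) > slope_tol or bin_mean[i:j].min() < force_floor:
                continue
            # both halves must be flat too, so a steep approach or exit
            # cannot be traded against the plateau to lengthen the window
            mid = (i + j) // 2
            ok = True
            for a, b in ((i, mid), (mid, j)):
                half = fit(a, b)
                if half is None or abs(half[0]) > slope_tol:
                    ok = False
                    break
            if not ok:
                continue
            span = edges[j] - edges[i]
            if best is None or span > best[0]:
                best = (span, i, j)
    if best is None:
        return None
    _, i, j = best
    x_lo, x_hi = float(edges[i]), float(edges[j])
    mask = (x >= x_lo) & (x <= x_hi)
    return PlateauResult(
        force=float(np.median(F[mask])),
        extension_range=(x_lo, x_hi),
        span=x_hi - x_lo,
        n_samples=int(mask.sum()),
    )


def hysteresis(
    stretch: ForceExtensionTrace,
    relax: ForceExtensionTrace,
    n_grid: int = 512,
) -> float:
    """Signed area (pN nm) between stretch and relax force-extension curves.

    Both curves are interpolated onto a common extension grid over the
    overlap of their extension ranges; the result is the integral of
    (F_stretch - F_relax) dx.  Zero for identical curves; the sign is
    positive when the stretch curve lies above the relax curve.
    """
    xs = np.asarray(stretch.molecular_extension, dtype=float)
    Fs = np.asarray(stretch.force, dtype=float)
    xr = np.asarray(relax.molecular_extension, dtype=float)
    Fr = np.asarray(relax.force, dtype=float)
    lo = max(xs.min(), xr.min())
    hi = min(xs.max(), xr.max())
    if hi <= lo:
        raise ValueError("stretch and relax extension ranges do not overlap")
    grid = np.linspace(lo, hi, n_grid)

    def interp(x, F):
        order = np.argsort(x, kind="stable")
        xo, Fo = x[order], F[order]
        # average duplicate/noisy x by binning onto the grid neighbourhood
        return np.interp(grid, xo, Fo)

    diff = interp(xs, Fs) - interp(xr, Fr)
    return float(np.trapezoid(diff, grid))
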
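"""Chromatogram I/O, peak detection, identity assignment and peak integration.

An FLD chromatogram is a uniformly sampled time series of fluorescence
intensity (luminescence units, LU) versus retention time (minutes).  The
quantity every downstream stage consumes is the baseline-corrected area of
the sulfide-dibimane (SDB) peak, in LU·min.  Peak identity is assigned by
matching apex retention times against reference times (SDB elutes near
11.8 min, the monobromobimane excess near 12.8 min on the reference
gradient), which is how routine FLD runs are identified in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "Peak",
    "SDB_RETENTION_MIN",
    "MBB_RETENTION_MIN",
    "DEFAULT_REFERENCES",
    "read_chromatogram",
    "write_chromatogram",
    "detect_peaks",
    "integrate_peak",
    "assign_identity",
    "peaks_to_frame",
]

#: Reference apex retention times (minutes) on the standard water/acetonitrile
#: gradient: the sulfide-dibimane product and the monobromobimane reagent excess.
SDB_RETENTION_MIN = 11.8
MBB_RETENTION_MIN = 12.8
DEFAULT_REFERENCES = {"SDB": SDB_RETENTION_MIN, "MBB": MBB_RETENTION_MIN}

_KNOWN_LABELS = {"SDB", "MBB", "byproduct", "unknown"}


@dataclass
class Chromatogram:
    """Uniformly sampled fluorescence trace.

    Parameters
    ----------
    time : ndarray
        Retention time grid in minutes; strictly increasing, constant step.
    intensity : ndarray
        Fluorescence intensity in LU, same length as ``time``.
    metadata : dict
        Free-text acquisition metadata (detector, wavelengths, run id).
    """

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("chromatogram needs at least 2 time points")
        if self.intensity.shape != self.time.shape:
            raise ValueError("time and intensity must have the same length")
        if not (np.isfinite(self.time).all() and np.isfinite(self.intensity).all()):
            raise ValueError("chromatogram contains non-finite values")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            i = int(np.argmax(steps <= 0))
            raise ValueError(f"time grid not strictly increasing at index {i + 1}")
        step = steps[0]
        if np.any(np.abs(steps - step) > 1e-9 * max(abs(step), 1.0)):
            raise ValueError("time grid is not uniform")

    @property
    def step(self) -> float:
        """Grid spacing in minutes."""
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class Peak:
    """A detected chromatographic peak.

    ``area`` is the baseline-corrected integral in LU·min over ``window``;
    ``height`` is the apex intensity above the local baseline.
    """

    retention_time: float
    area: float
    height: float
    window: tuple[float, float]
    label: str = "unknown"
    overlapping: bool = False

    def __post_init__(self) -> None:
        if self.label not in _KNOWN_LABELS:
            raise ValueError(f"unknown peak label {self.label!r}")
        lo, hi = self.window
        if not (lo < self.retention_time < hi):
            raise ValueError("apex must lie strictly inside the window")


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram as CSV (time_min, intensity_lu) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_min": chrom.time, "intensity_lu": chrom.intensity}).to_csv(
        path, index=False, float_format="%.12g"
    )
    if chrom.metadata:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(chrom.metadata, indent=2, sort_keys=True)
        )


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a ``time_min,intensity_lu`` CSV; malformed rows are reported by line number."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing chromatogram file")
    df = pd.read_csv(path)
    expected = ["time_min", "intensity_lu"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}, got {','.join(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    vals = df[expected].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        lines = [str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:5]]
        raise ValueError(f"{path}: malformed rows at lines {', '.join(lines)}")
    t = vals["time_min"].to_numpy()
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise ValueError(f"{path}: time not strictly increasing at line {nonmono[0] + 3}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Chromatogram(t, vals["intensity_lu"].to_numpy(), metadata)


def _window_indices(chrom: Chromatogram, window: tuple[float, float]) -> tuple[int, int]:
    start, end = window
    if start >= end:
        raise ValueError("window start must be before end")
    t = chrom.time
    eps = 1e-9 * max(chrom.step, 1.0)
    if start < t[0] - eps or end > t[-1] + eps:
        raise ValueError(
            f"window [{start}, {end}] outside time range [{t[0]}, {t[-1]}]"
        )
    i0 = int(np.searchsorted(t, start - eps, side="left"))
    i1 = int(np.searchsorted(t, end + eps, side="right")) - 1
    if i1 - i0 < 1:
        raise ValueError("window spans fewer than 2 grid points")
    return i0, i1


def integrate_peak(
    chrom: Chromatogram,
    window: tuple[float, float],
    baseline: str = "linear_endpoints",
) -> float:
    """Trapezoidal peak area (LU·min) over ``window`` after baseline subtraction.

    ``baseline`` is one of ``linear_endpoints`` (a chord joining the signal at
    the two window endpoints — the default, auditable treatment), ``constant_min``
    (the window minimum) or ``none``.
    """
    i0, i1 = _window_indices(chrom, window)
    t = chrom.time[i0 : i1 + 1]
    y = chrom.intensity[i0 : i1 + 1].astype(float)
    if baseline == "none":
        base = np.zeros_like(y)
    elif baseline == "constant_min":
        base = np.full_like(y, y.min())
    elif baseline == "linear_endpoints":
        base = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(y - base, t))


def _refine_apex(t: np.ndarray, y: np.ndarray, i: int, half: int) -> float:
    # sub-sample apex via a local parabola; falls back to the grid apex when
    # the neighbourhood is not concave or the vertex strays from it
    lo, hi = max(i - half, 0), min(i + half + 1, y.size)
    if hi - lo < 3:
        return float(t[i])
    coefs = np.polyfit(t[lo:hi] - t[i], y[lo:hi], 2)
    if coefs[0] >= 0:
        return float(t[i])
    vertex = float(t[i] - coefs[1] / (2 * coefs[0]))
    step = float(t[1] - t[0])
    return vertex if abs(vertex - t[i]) <= 2 * step else float(t[i])


def detect_peaks(
    chrom: Chromatogram,
    min_height: float,
    min_prominence: float = 0.0,
    merge_window: float = 0.2,
    smooth_sigma: float = 0.0,
) -> list[Peak]:
    """Find local maxima above ``min_height`` and delimit their integration windows.

    ``smooth_sigma`` (minutes, default off) applies a Gaussian filter before
    detection — a matched-filter-style step that stabilises apex location on
    noisy traces; areas are always integrated on the raw signal.  Apices are
    refined to sub-sample precision with a local parabola.  Window bounds are
    placed at the prominence bases (baseline re-crossing) and, between adjacent
    peaks, at the inter-peak valley, so overlapping peaks are reported
    separately with truncated windows and an ``overlapping`` flag when their
    apices are closer than ``merge_window`` minutes.  A flat signal yields an
    empty list.
    """
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter1d

        y = gaussian_filter1d(chrom.intensity, smooth_sigma / chrom.step)
    else:
        y = chrom.intensity
    idx, props = find_peaks(y, height=min_height, prominence=max(min_prominence, 0.0) or None)
    if idx.size == 0:
        return []
    left = props.get("left_bases", np.zeros_like(idx))
    right = props.get("right_bases", np.full_like(idx, y.size - 1))
    # truncate shared windows at the valley between adjacent apices
    for k in range(idx.size - 1):
        a, b = idx[k], idx[k + 1]
        valley = a + int(np.argmin(y[a : b + 1]))
        right[k] = min(right[k], valley)
        left[k + 1] = max(left[k + 1], valley)
    peaks: list[Peak] = []
    t = chrom.time
    refine_half = max(2, int(round(smooth_sigma / chrom.step))) if smooth_sigma > 0 else 2
    for k, apex in enumerate(idx):
        lo = int(min(left[k], apex - 1))
        hi = int(max(right[k], apex + 1))
        lo = max(lo, 0)
        hi = min(hi, y.size - 1)
        # tighten to apex +/- 4 sigma (sigma from the half-height width), so the
        # baseline chord anchors near the peak instead of at distant noise dips
        chord = y[lo] + (y[hi] - y[lo]) * (t[apex] - t[lo]) / (t[hi] - t[lo])
        half = chord + 0.5 * (y[apex] - chord)
        il = apex
        while il > lo and y[il - 1] > half:
            il -= 1
        ir = apex
        while ir < hi and y[ir + 1] > half:
            ir += 1
        if ir > il:
            sigma_est = (t[ir] - t[il]) / 2.355
            width = 4.0 * sigma_est
            lo = max(lo, int(np.searchsorted(t, t[apex] - width, side="left")))
            hi = min(hi, int(np.searchsorted(t, t[apex] + width, side="right")) - 1)
            lo = min(lo, apex - 1)
            hi = max(hi, apex + 1)
        window = (float(t[lo]), float(t[hi]))
        base_apex = y[lo] + (y[hi] - y[lo]) * (t[apex] - t[lo]) / (t[hi] - t[lo])
        area = integrate_peak(chrom, window, baseline="linear_endpoints")
        overlapping = False
        if k > 0 and t[apex] - t[idx[k - 1]] < merge_window:
            overlapping = True
        if k < idx.size - 1 and t[idx[k + 1]] - t[apex] < merge_window:
            overlapping = True
        rt = _refine_apex(t, y, int(apex), refine_half)
        rt = min(max(rt, window[0] + 1e-12), window[1] - 1e-12)
        peaks.append(
            Peak(
                retention_time=rt,
                area=area,
                height=float(y[apex] - base_apex),
                window=window,
                overlapping=overlapping,
            )
        )
    return peaks


def assign_identity(
    peaks: list[Peak],
    references: dict[str, float] | None = None,
    tolerance: float = 0.2,
) -> list[Peak]:
    """Label peaks by nearest reference retention time within ``tolerance`` minutes.

    Each reference is claimed by at most one peak — the closer apex wins and
    any other candidate stays ``unknown``.  Returns new Peak objects; input
    order is preserved.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    refs = DEFAULT_REFERENCES if references is None else references
    candidates = sorted(
        (
            (abs(p.retention_time - rt), i, label)
            for i, p in enumerate(peaks)
            for label, rt in refs.items()
            if abs(p.retention_time - rt) <= tolerance
        ),
    )
    assigned: dict[int, str] = {}
    taken: set[str] = set()
    for _, i, label in candidates:
        if i in assigned or label in taken:
            continue
        assigned[i] = label
        taken.add(label)
    return [replace(p, label=assigned.get(i, "unknown")) for i, p in enumerate(peaks)]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    """Tabulate peaks as the CSV peak-table schema."""
    return pd.DataFrame(
        {
            "label": [p.label for p in peaks],
            "rt_min": [p.retention_time for p in peaks],
            "area_lu_min": [p.area for p in peaks],
            "height_lu": [p.height for p in peaks],
            "window_start": [p.window[0] for p in peaks],
            "window_end": [p.window[1] for p in peaks],
        }
    )
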
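"""Measurement procedures for intensity line profiles and kinetochore tracks.

These functions mirror the quantification steps applied to live-cell
microscopy of metaphase spindles: background-subtracted peak areas of
tubulin line scans, the bridging-fibre/k-fibre intensity ratio and the
microtubule-count estimate derived from it, contour angles, sister-
kinetochore tilt, interkinetochore distance and its post-ablation
relaxation, perpendicular kinetochore displacement, k-fibre stub length,
the kinetochore-to-bridge distance from paired profiles, and EB3 comet
rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


class QuantifyError(ValueError):
    pass


class BackgroundError(QuantifyError):
    pass


class PeakDetectionError(QuantifyError):
    pass


class DegenerateFitError(QuantifyError):
    pass


# ---------------------------------------------------------------------------
# intensity profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D fluorescence line scan: intensity vs position along the line."""

    position_um: np.ndarray
    intensity: np.ndarray
    background: Optional[float] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position_um, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "position_um", pos)
        object.__setattr__(self, "intensity", inten)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise QuantifyError("position and intensity must be equal-length 1-D")
        if pos.size < 2 or np.any(np.diff(pos) <= 0):
            raise QuantifyError("positions must be strictly increasing")

    @property
    def span_um(self) -> Tuple[float, float]:
        return float(self.position_um[0]), float(self.position_um[-1])


def flank_statistics(
    profile: IntensityProfile, flank_um: float = 0.5
) -> Tuple[float, float]:
    """Mean and s.d. of the cytoplasmic flanks (outermost ``flank_um`` on
    each side of the scan)."""
    pos = profile.position_um
    lo, hi = profile.span_um
    mask = (pos <= lo + flank_um) | (pos >= hi - flank_um)
    if mask.sum() < 4:
        raise BackgroundError("flank region too small to estimate background")
    vals = profile.intensity[mask]
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def subtract_background(
    profile: IntensityProfile,
    background: Optional[float] = None,
    flank_um: Optional[float] = None,
) -> IntensityProfile:
    """Subtract the mean cytoplasmic background from a line scan.

    The background is, in order of precedence: the ``background`` argument,
    the profile's own ``background`` attribute, or the mean of the flank
    region of width ``flank_um``. Intensities are shifted, not clipped.
    """
    if background is None:
        background = profile.background
    if background is None:
        if flank_um is None:
            raise BackgroundError(
                "no background available: pass a value or a flank_um region"
            )
        background, _ = flank_statistics(profile, flank_um)
    return IntensityProfile(
        position_um=profile.position_um,
        intensity=profile.intensity - background,
        background=0.0,
    )


def _detect_peaks(
    profile: IntensityProfile, min_prominence: Optional[float]
) -> np.ndarray:
    if min_prominence is None:
        try:
            _, noise_sd = flank_statistics(profile)
        except BackgroundError:
            noise_sd = 0.0
        min_prominence = 2.0 * noise_sd if noise_sd > 0 else None
    idx, _ = find_peaks(profile.intensity, prominence=min_prominence)
    return idx


def peak_area(
    profile: IntensityProfile,
    window_width_um: float,
    window_center_um: Optional[float] = None,
    kinetochore_um: Optional[float] = None,
    min_prominence: Optional[float] = None,
) -> float:
    """Trapezoidal area under one peak of a background-subtracted scan.

    The window is centred on ``window_center_um`` if given; otherwise on the
    detected local maximum nearest ``kinetochore_um`` (default: scan centre).
    Peak detection uses a minimum prominence of twice the flank noise s.d.
    A window extending beyond the scan raises :class:`QuantifyError`.
    """
    pos, inten = profile.position_um, profile.intensity
    if window_center_um is None:
        idx = _detect_peaks(profile, min_prominence)
        if idx.size == 0:
            if np.allclose(inten, 0.0):
                return 0.0
            raise PeakDetectionError("no peak above the noise floor")
        ref = (
            kinetochore_um
            if kinetochore_um is not None
            else 0.5 * (pos[0] + pos[-1])
        )
        window_center_um = float(pos[idx[np.argmin(np.abs(pos[idx] - ref))]])
    lo = window_center_um - window_width_um / 2
    hi = window_center_um + window_width_um / 2
    if lo < pos[0] - 1e-9 or hi > pos[-1] + 1e-9:
        raise QuantifyError(
            f"window [{lo:.3f}, {hi:.3f}] exceeds the profile span {profile.span_um}"
        )
    grid = np.unique(np.concatenate([[lo], pos[(pos > lo) & (pos < hi)], [hi]]))
    vals = np.interp(grid, pos, inten)
    return float(np.trapezoid(vals, grid))


def bridge_fraction(r: float) -> float:
    """Convert the measured ratio r = I_b/I_bk into I_b/I_k = r/(1-r)."""
    if not (0.0 <= r < 1.0):
        raise QuantifyError(f"ratio I_b/I_bk must lie in [0, 1); got {r}")
    return r / (1.0 - r)


def estimate_bridge_mt_number(r: float, n_k: int) -> int:
    """Estimate the microtubule count of the bridging fibre.

    n_b = round(n_k * r/(1-r)), rounding half away from zero. The unrounded
    value is ``n_k * bridge_fraction(r)``.
    """
    if n_k <= 0:
        raise QuantifyError(f"n_k must be positive; got {n_k}")
    raw = n_k * bridge_fraction(r)
    return int(math.floor(raw + 0.5)) if raw >= 0 else -int(math.floor(-raw + 0.5))


def dbk_from_profiles(
    bridge_profile: IntensityProfile,
    kinetochore_profile: IntensityProfile,
    min_prominence: Optional[float] = None,
) -> float:
    """Signed kinetochore-to-bridge distance from paired line scans.

    Both profiles are sampled along the same outward-oriented line
    (increasing position = away from the spindle long axis). The distance is
    the kinetochore peak position minus the bridging-fibre peak position, so
    it is positive when the kinetochore lies on the outer side of the bridge.
    """
    positions = []
    for prof in (bridge_profile, kinetochore_profile):
        idx = _detect_peaks(prof, min_prominence)
        if idx.size == 0:
            raise PeakDetectionError("no peak above the noise floor")
        best = idx[np.argmax(prof.intensity[idx])]
        positions.append(float(prof.position_um[best]))
    return positions[1] - positions[0]


# ---------------------------------------------------------------------------
# kinetochore / contour tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinetochoreTrack:
    """Time-stamped 2-D positions of tracked objects around one ablation.

    ``objects`` maps an object id (``sister1`` = kinetochore proximal to the
    cut, ``sister2`` its sister, optionally ``stub_tip``) to an (n, 3) array
    of rows (time_s, x_um, y_um). Sisters must share a time base. The spindle
    long axis is given explicitly by an origin point and a unit direction.
    """

    objects: Mapping[str, np.ndarray]
    axis_origin: Tuple[float, float] = (0.0, 0.0)
    axis_direction: Tuple[float, float] = (1.0, 0.0)
    t_cut_s: float = 0.0

    def __post_init__(self) -> None:
        objs = {k: np.asarray(v, dtype=float) for k, v in self.objects.items()}
        for name, arr in objs.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise QuantifyError(f"object {name!r} must be (n, 3): t, x, y")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise QuantifyError(f"object {name!r} has non-increasing times")
        if "sister1" in objs and "sister2" in objs:
            if not np.array_equal(objs["sister1"][:, 0], objs["sister2"][:, 0]):
                raise QuantifyError("sisters must share the time base")
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise QuantifyError("axis direction must be non-zero")
        object.__setattr__(self, "axis_direction", (d[0] / n, d[1] / n))
        object.__setattr__(self, "objects", objs)

    @property
    def frame_interval_s(self) -> float:
        t = next(iter(self.objects.values()))[:, 0]
        return float(np.median(np.diff(t)))

    def position(self, obj: str, t: float, tol_frames: float = 1.0) -> np.ndarray:
        """Position of ``obj`` at the acquired frame nearest ``t`` (within
        ``tol_frames`` frame intervals)."""
        if obj not in self.objects:
            raise QuantifyError(f"object {obj!r} not present in track")
        arr = self.objects[obj]
        i = int(np.argmin(np.abs(arr[:, 0] - t)))
        if abs(arr[i, 0] - t) > tol_frames * self.frame_interval_s + 1e-9:
            raise QuantifyError(
                f"no frame of {obj!r} within {tol_frames} frame(s) of t={t}"
            )
        return arr[i, 1:3]

    def _axis_normal(self) -> np.ndarray:
        dx, dy = self.axis_direction
        return np.array([-dy, dx])


def sister_tilt(track: KinetochoreTrack, t: float) -> float:
    """Unsigned angle (degrees) between the sister–sister segment and the
    spindle long axis at time ``t``."""
    p1 = track.position("sister1", t)
    p2 = track.position("sister2", t)
    seg = p2 - p1
    norm = np.linalg.norm(seg)
    if norm < 1e-12:
        raise QuantifyError("sisters coincide; tilt undefined")
    cosang = abs(float(np.dot(seg, track.axis_direction))) / norm
    return math.degrees(math.acos(min(1.0, cosang)))


def interkinetochore_distance(track: KinetochoreTrack, t: float) -> float:
    """Euclidean distance between sister kinetochores at time ``t``."""
    p1 = track.position("sister1", t)
    p2 = track.position("sister2", t)
    return float(np.linalg.norm(p1 - p2))


def kk_relaxation(track: KinetochoreTrack, dt_s: float = 4.0) -> float:
    """Decrease of the interkinetochore distance ``dt_s`` after the cut.

    Positive values mean the sisters moved closer (loss of tension). Frames
    are matched to the nearest acquisition within one frame interval.
    """
    d0 = interkinetochore_distance(track, track.t_cut_s)
    d1 = interkinetochore_distance(track, track.t_cut_s + dt_s)
    return d0 - d1


def perpendicular_displacement(track: KinetochoreTrack, obj: str, t: float) -> float:
    """Signed displacement of ``obj`` perpendicular to the spindle long axis
    relative to its position at the cut, positive away from the axis."""
    p0 = track.position(obj, track.t_cut_s)
    p = track.position(obj, t)
    n = track._axis_normal()
    side = float(np.dot(np.asarray(p0) - np.asarray(track.axis_origin), n))
    sign = 1.0 if side >= 0 else -1.0
    return sign * float(np.dot(p - p0, n))


def stub_length(
    track: KinetochoreTrack,
    t_first_after_cut: Optional[float] = None,
    kinetochore: str = "sister1",
    tip: str = "stub_tip",
) -> float:
    """Length of the severed k-fibre stub: kinetochore centre to stub tip,
    measured in the first frame after the cut."""
    if tip not in track.objects:
        raise QuantifyError("stub tip not present in track")
    if t_first_after_cut is None:
        times = track.objects[tip][:, 0]
        after = times[times > track.t_cut_s]
        if after.size == 0:
            raise QuantifyError("no stub-tip frame after the cut")
        t_first_after_cut = float(after[0])
    p_k = track.position(kinetochore, t_first_after_cut)
    p_t = track.position(tip, t_first_after_cut)
    return float(np.linalg.norm(p_k - p_t))


def angle_from_contour(
    points: np.ndarray,
    axis_direction: Sequence[float] = (1.0, 0.0),
) -> float:
    """Angle (degrees, in [0, 90]) between a fitted line through three
    consecutive contour points and the spindle long axis.

    The line is the total-least-squares fit (principal direction) of the
    three points, matching a local 3-point contour-angle measurement.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 2):
        raise QuantifyError(f"expected exactly 3 (x, y) points; got {pts.shape}")
    centred = pts - pts.mean(axis=0)
    if np.allclose(centred, 0.0):
        raise DegenerateFitError("contour points coincide")
    _, _, vt = np.linalg.svd(centred)
    direction = vt[0]
    ax = np.asarray(axis_direction, dtype=float)
    ax = ax / np.linalg.norm(ax)
    cosang = abs(float(np.dot(direction, ax)))
    return math.degrees(math.acos(min(1.0, cosang)))


# ---------------------------------------------------------------------------
# comet events
# ---------------------------------------------------------------------------

def comet_rate(
    events: Union[pd.DataFrame, Sequence[str], int],
    duration_min: float,
) -> Union[float, Dict[str, float]]:
    """Event rate (events per minute), per direction class when available.

    ``events`` may be an integer count, a sequence of direction labels, or a
    DataFrame with a ``direction`` column. Returns a float for a plain count
    and a dict {direction: rate} otherwise (empty input gives {}).
    """
    if duration_min <= 0:
        raise QuantifyError("duration must be positive")
    if isinstance(events, (int, np.integer)):
        return float(events) / duration_min
    if isinstance(events, pd.DataFrame):
        labels = events["direction"].tolist() if len(events) else []
    else:
        labels = list(events)
    out: Dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0
    return {k: v / duration_min for k, v in out.items()}
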
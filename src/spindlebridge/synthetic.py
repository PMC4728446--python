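"""Synthetic-data generation emulating the measured spindle statistics.

Every input the quantification and beam-model layers consume can be
generated here with the population statistics of the corresponding live-cell
measurements: spindle geometry distributions (per cell type), two-peak
tubulin line profiles over cytoplasmic background, post-ablation sister-
kinetochore kinematics (outward excursion, interkinetochore relaxation,
tilt), noisy fibre contours resampled from the forward beam model, and EB3
comet event streams.

All generators are deterministic given a seed (or an explicit
``numpy.random.Generator``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .beam import SpindleShape
from .geometry import SpindleGeometry
from .quantify import IntensityProfile, KinetochoreTrack

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# geometry populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Mean, s.d. and truncation bounds of one population parameter."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd < 0:
            raise ValueError("s.d. must be >= 0")
        if self.sd == 0:
            vals = np.full(n, self.mean)
            if np.any(vals < self.lo) or np.any(vals > self.hi):
                raise ValueError("degenerate distribution outside truncation bounds")
            return vals
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        if not a < b:
            raise ValueError("infeasible truncation bounds")
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


@dataclass(frozen=True)
class GeometryPopulationParams:
    """Per-cell-type population statistics of the measured shape parameters."""

    n_b: ParamDist
    theta0_deg: ParamDist
    thetak_deg: ParamDist
    dbk_um: ParamDist
    dk_um: ParamDist
    L_um: ParamDist
    hk_um: ParamDist

    @classmethod
    def hela(cls) -> "GeometryPopulationParams":
        return cls(
            n_b=ParamDist(14, 2, lo=1),
            theta0_deg=ParamDist(65.5, 8.8, lo=5, hi=85),
            thetak_deg=ParamDist(13.7, 10.1, lo=0, hi=85),
            dbk_um=ParamDist(0.24, 0.15),
            dk_um=ParamDist(1.05, 0.32, lo=0.1),
            L_um=ParamDist(11.1, 1.2, lo=4),
            hk_um=ParamDist(5.0, 0.7, lo=1),
        )

    @classmethod
    def ptk1(cls) -> "GeometryPopulationParams":
        return cls(
            n_b=ParamDist(6, 1, lo=1),
            theta0_deg=ParamDist(52.6, 8.4, lo=5, hi=85),
            thetak_deg=ParamDist(21.2, 10.2, lo=0, hi=85),
            dbk_um=ParamDist(0.20, 0.10),
            dk_um=ParamDist(1.92, 0.54, lo=0.1),
            L_um=ParamDist(11.8, 1.7, lo=4),
            hk_um=ParamDist(4.0, 0.6, lo=1),
        )

    @classmethod
    def for_cell_type(cls, cell_type: str) -> "GeometryPopulationParams":
        try:
            return {"hela": cls.hela, "ptk1": cls.ptk1}[cell_type.lower()]()
        except KeyError:
            raise ValueError(f"unknown cell type {cell_type!r}") from None


def sample_geometry(
    params: GeometryPopulationParams,
    n_cells: int,
    seed: RngLike = None,
) -> Tuple[List[SpindleGeometry], np.ndarray]:
    """Draw ``n_cells`` spindle geometries from truncated-normal populations.

    Parameters are sampled independently; the horizontal kinetochore position
    follows from symmetry about the metaphase plate, x_k = L/2 - d_k/2.
    Returns the geometries and the sampled bridging-fibre MT counts.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed)
    cols = {
        name: getattr(params, name).sample(n_cells, rng)
        for name in ("n_b", "theta0_deg", "thetak_deg", "dbk_um", "dk_um",
                     "L_um", "hk_um")
    }
    # keep the kinetochore inside the half-spindle even for extreme draws
    cols["dk_um"] = np.minimum(cols["dk_um"], 0.9 * cols["L_um"])
    geoms = []
    for i in range(n_cells):
        geoms.append(
            SpindleGeometry(
                theta0_deg=float(cols["theta0_deg"][i]),
                thetak_deg=float(cols["thetak_deg"][i]),
                L_um=float(cols["L_um"][i]),
                hk_um=float(cols["hk_um"][i]),
                xk_um=float(cols["L_um"][i] / 2 - cols["dk_um"][i] / 2),
                dk_um=float(cols["dk_um"][i]),
                dbk_um=float(cols["dbk_um"][i]),
            )
        )
    return geoms, np.rint(cols["n_b"]).astype(int)


# ---------------------------------------------------------------------------
# intensity profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileParams:
    """Shape of synthetic tubulin line scans.

    Peak widths are full widths at the base; the Gaussian sigma is width/4
    so that the stated base width covers +-2 sigma. The sampling step
    defaults to the 81-nm pixel size of the source imaging.
    """

    bridge_width_um: float = 0.6
    kfibre_width_um: float = 1.0
    background: float = 100.0
    amplitude: float = 200.0  # peak area scale (a.u. * um) of the combined scan
    noise_sd: float = 4.0
    step_um: float = 0.081
    span_um: float = 4.0

    def __post_init__(self) -> None:
        if self.bridge_width_um <= 0 or self.kfibre_width_um <= 0:
            raise ValueError("widths must be positive")
        if self.step_um <= 0:
            raise ValueError("sampling step must be positive")


def _gaussian(pos: np.ndarray, center: float, area: float, sigma: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((pos - center) / sigma) ** 2
    )


def generate_intensity_profile(
    params: ProfileParams,
    target_ratio_r: float,
    seed: RngLike = None,
) -> Tuple[IntensityProfile, IntensityProfile]:
    """Generate a paired (bridge scan, k-fibre scan) with analytic areas
    satisfying I_b / (I_b + I_k) = r.

    The bridge scan crosses only the bridging fibre between the sister
    kinetochores (peak area I_b = r * S); the k-fibre scan crosses the
    k-fibre plus underlying bridge near a kinetochore (one merged peak of
    area I_bk = S). Both sit on a flat cytoplasmic background with additive
    Gaussian noise.
    """
    if not (0.0 < target_ratio_r < 1.0):
        raise ValueError("target ratio must lie in (0, 1)")
    rng = _rng(seed)
    pos = np.arange(
        -params.span_um / 2, params.span_um / 2 + params.step_um / 2, params.step_um
    )
    S = params.amplitude
    scans = []
    for area, width in (
        (target_ratio_r * S, params.bridge_width_um),
        (S, params.kfibre_width_um),
    ):
        inten = params.background + _gaussian(pos, 0.0, area, width / 4.0)
        inten = inten + rng.normal(0.0, params.noise_sd, size=pos.size)
        scans.append(IntensityProfile(position_um=pos.copy(), intensity=inten))
    return scans[0], scans[1]


def generate_dbk_profiles(
    params: ProfileParams,
    dbk_um: float = 0.24,
    kinetochore_area: Optional[float] = None,
    seed: RngLike = None,
) -> Tuple[IntensityProfile, IntensityProfile]:
    """Paired bridge / kinetochore scans along an outward-oriented line with
    peak positions offset by ``dbk_um`` (kinetochore on the outer side for
    positive values)."""
    rng = _rng(seed)
    pos = np.arange(
        -params.span_um / 2, params.span_um / 2 + params.step_um / 2, params.step_um
    )
    bridge = params.background + _gaussian(
        pos, 0.0, params.amplitude, params.bridge_width_um / 4.0
    )
    k_area = params.amplitude if kinetochore_area is None else kinetochore_area
    kin = params.background + _gaussian(pos, dbk_um, k_area, 0.15)
    bridge = bridge + rng.normal(0.0, params.noise_sd, size=pos.size)
    kin = kin + rng.normal(0.0, params.noise_sd, size=pos.size)
    return (
        IntensityProfile(position_um=pos.copy(), intensity=bridge),
        IntensityProfile(position_um=pos.copy(), intensity=kin),
    )


# ---------------------------------------------------------------------------
# post-ablation kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutResponseParams:
    """Population kinematics of the response to k-fibre severing (HeLa
    defaults).

    Between-cell spreads are population s.d. values derived from the reported
    mean +- s.e.m. via sd = s.e.m. * sqrt(n). The outward excursion rises
    smoothly to a cell-specific peak (population mean 0.32 um at 11 s) and
    relaxes back exponentially. The interkinetochore distance contracts over
    ``relax_time_s`` by an amount depending on stub length through a logistic
    step centred at the transition length (1 um): cuts closer to the
    kinetochore release more tension. Sister tilt ramps to a per-n_b-class
    value at 4 s.
    """

    peak_displacement_um: float = 0.32
    peak_displacement_sd_um: float = 0.04 * math.sqrt(52)
    time_to_peak_s: float = 11.0
    return_tau_s: float = 20.0
    relax_lo_um: float = 0.05
    relax_hi_um: float = 0.25
    relax_transition_um: float = 1.0
    relax_width_um: float = 0.2
    relax_sd_um: float = 0.06 * math.sqrt(52)
    relax_time_s: float = 4.0
    tilt_by_nb_deg: Mapping = None  # type: ignore[assignment]
    tilt_sd_deg: float = 3.3
    frame_interval_s: float = 4.0
    t_start_s: float = -12.0
    t_end_s: float = 48.0
    noise_sd_um: float = 0.025

    def __post_init__(self) -> None:
        if self.tilt_by_nb_deg is None:
            object.__setattr__(
                self, "tilt_by_nb_deg", {3: 2.9, 14: 4.0, 23: 15.9}
            )
        if self.time_to_peak_s <= 0 or self.relax_time_s <= 0:
            raise ValueError("times must be positive")
        if self.noise_sd_um < 0:
            raise ValueError("noise s.d. must be >= 0")

    def mean_relaxation_um(self, stub_length_um: float) -> float:
        """Expected interkinetochore relaxation for a given stub length
        (logistic step: larger for cuts closer to the kinetochore)."""
        z = (self.relax_transition_um - stub_length_um) / self.relax_width_um
        return self.relax_lo_um + (self.relax_hi_um - self.relax_lo_um) / (
            1.0 + math.exp(-z)
        )

    def tilt_at_4s_deg(self, n_b: int) -> float:
        classes = sorted(self.tilt_by_nb_deg)
        nearest = min(classes, key=lambda c: abs(c - n_b))
        return float(self.tilt_by_nb_deg[nearest])


def _displacement_profile(t: np.ndarray, t_peak: float, tau: float) -> np.ndarray:
    """Unit-peak excursion: smooth sine rise to t_peak, exponential return."""
    out = np.zeros_like(t)
    rising = (t > 0) & (t <= t_peak)
    out[rising] = np.sin(0.5 * math.pi * t[rising] / t_peak)
    after = t > t_peak
    out[after] = np.exp(-(t[after] - t_peak) / tau)
    return out


def generate_cut_response(
    cut_params: CutResponseParams,
    geometry: SpindleGeometry,
    stub_length_um: float = 1.0,
    n_cells: int = 1,
    seed: RngLike = None,
    n_b: int = 14,
) -> List[KinetochoreTrack]:
    """Simulate sister-kinetochore (plus stub-tip) tracks around an ablation.

    Per cell: the proximal sister's perpendicular excursion follows a smooth
    rise to a cell-specific peak then exponential return; the interkinetochore
    distance contracts linearly over ``relax_time_s`` by a cell-specific
    amount centred on the logistic stub-length law; the sister pair tilts,
    ramping to a per-n_b-class angle at 4 s. Frame-rate sampling with
    isotropic Gaussian positional noise; the stub tip is placed at the
    programmed stub length from the proximal kinetochore after the cut.
    """
    p = cut_params
    rng = _rng(seed)
    times = np.arange(p.t_start_s, p.t_end_s + p.frame_interval_s / 2,
                      p.frame_interval_s)
    dk0 = geometry.dk_um if geometry.dk_um is not None else 1.05
    h = geometry.hk_um
    xc = geometry.L_um / 2

    tracks: List[KinetochoreTrack] = []
    for _ in range(n_cells):
        peak = rng.normal(p.peak_displacement_um, p.peak_displacement_sd_um)
        relax = rng.normal(p.mean_relaxation_um(stub_length_um), p.relax_sd_um)
        tilt4 = max(0.0, rng.normal(p.tilt_at_4s_deg(n_b), p.tilt_sd_deg))

        disp = peak * _displacement_profile(times, p.time_to_peak_s, p.return_tau_s)
        ramp = np.clip(times / p.relax_time_s, 0.0, 1.0)
        dk_t = dk0 - relax * ramp
        tilt_t = np.radians(tilt4) * ramp

        # proximal sister: programmed perpendicular excursion
        px = np.full_like(times, xc + dk0 / 2)
        py = h + disp
        # sister: offset along the tilted pair axis, toward the spindle centre
        sx = px - dk_t * np.cos(tilt_t)
        sy = py - dk_t * np.sin(tilt_t)
        # stub tip: fixed offset from the proximal sister toward the pole
        alpha = math.radians(20.0)
        tx = px + stub_length_um * math.cos(math.pi - alpha)
        ty = py - stub_length_um * math.sin(alpha)

        def noisy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
            return np.column_stack(
                [
                    times,
                    x + rng.normal(0.0, p.noise_sd_um, size=times.size),
                    y + rng.normal(0.0, p.noise_sd_um, size=times.size),
                ]
            )

        objects = {
            "sister1": noisy(px, py),
            "sister2": noisy(sx, sy),
        }
        post = times > 0
        if post.any():
            stub = noisy(tx, ty)[post]
            objects["stub_tip"] = stub
        tracks.append(
            KinetochoreTrack(
                objects=objects,
                axis_origin=(0.0, 0.0),
                axis_direction=(1.0, 0.0),
                t_cut_s=0.0,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# contours from the forward beam model
# ---------------------------------------------------------------------------

def generate_contour_observation(
    shape: SpindleShape,
    spacing_um: float = 0.25,
    noise_sd_um: float = 0.0,
    seed: RngLike = None,
    rods: Sequence[str] = ("p", "k"),
) -> np.ndarray:
    """Resample a solved fibre contour at fixed arc spacing plus noise.

    By default the k-fibre contour (rods p then k, pole to kinetochore) is
    traced, emulating manual contour clicking at ~250-nm spacing with
    isotropic Gaussian localization noise. Returns an (n, 2) array.
    """
    xs, ys = [], []
    for rid in rods:
        rod = shape.rods[rid]
        xs.append(rod.x_um if not xs else rod.x_um[1:])
        ys.append(rod.y_um if not ys else rod.y_um[1:])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    seglen = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if spacing_um <= 0 or spacing_um > total:
        raise ValueError(
            f"spacing {spacing_um} incompatible with contour length {total:.3f}"
        )
    s_new = np.arange(0.0, total + spacing_um / 2, spacing_um)
    s_new = s_new[s_new <= total]
    pts = np.column_stack([np.interp(s_new, s, x), np.interp(s_new, s, y)])
    if noise_sd_um > 0:
        rng = _rng(seed)
        pts = pts + rng.normal(0.0, noise_sd_um, size=pts.shape)
    return pts


# ---------------------------------------------------------------------------
# EB3 comet events
# ---------------------------------------------------------------------------

#: measured comet statistics in the bridging fibre: rates in events/min by
#: direction class, plus growth velocity (um/min)
DEFAULT_COMET_RATES = {"toward_cut": 1.9, "away_from_cut": 0.6}
DEFAULT_COMET_VELOCITY = (13.1, 1.1)


def generate_comet_events(
    rates_per_min: Mapping,
    duration_min: float,
    velocity_um_min: Tuple[float, float] = DEFAULT_COMET_VELOCITY,
    seed: RngLike = None,
) -> pd.DataFrame:
    """Homogeneous-Poisson comet crossings per direction class.

    Returns a DataFrame with columns time_min, direction, velocity_um_min
    sorted by time (empty for zero rates).
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    rows = []
    vmean, vsd = velocity_um_min
    for direction in sorted(rates_per_min):
        rate = rates_per_min[direction]
        if rate < 0:
            raise ValueError("rates must be >= 0")
        n = rng.poisson(rate * duration_min)
        t = np.sort(rng.uniform(0.0, duration_min, size=n))
        v = rng.normal(vmean, vsd, size=n)
        for ti, vi in zip(t, v):
            rows.append({"time_min": ti, "direction": direction,
                         "velocity_um_min": vi})
    df = pd.DataFrame(rows, columns=["time_min", "direction", "velocity_um_min"])
    return df.sort_values("time_min", ignore_index=True) if len(df) else df
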
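"""File formats: CSV schemas for profiles, tracks and shapes; YAML/JSON config.

Column schemas
--------------
intensity profile CSV : position_um, intensity
track CSV             : time_s, object_id, x_um, y_um
shape CSV             : rod_id, x_um, y_um, slope
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .beam import SpindleShape
from .geometry import FibreArchitecture, SpindleGeometry
from .quantify import IntensityProfile, KinetochoreTrack
from .solve import ForceBalanceSolution, SolverConfig

PROFILE_COLUMNS = ["position_um", "intensity"]
TRACK_COLUMNS = ["time_s", "object_id", "x_um", "y_um"]


class ValidationError(ValueError):
    """A structured input-file validation failure with line-level messages."""

    def __init__(self, messages: List[str]):
        self.messages = messages
        super().__init__("; ".join(messages))


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def read_profile(path: Union[str, Path]) -> IntensityProfile:
    df = pd.read_csv(path)
    diags = _check_profile_frame(df)
    if diags:
        raise ValidationError(diags)
    return IntensityProfile(
        position_um=df["position_um"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
    )


def write_profile(profile: IntensityProfile, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"position_um": profile.position_um, "intensity": profile.intensity}
    ).to_csv(path, index=False)


def _check_profile_frame(df: pd.DataFrame) -> List[str]:
    msgs = []
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            msgs.append(f"missing required column {col!r}")
    if msgs:
        return msgs
    pos = df["position_um"].to_numpy(float)
    bad = np.where(np.diff(pos) <= 0)[0]
    for i in bad[:5]:
        # +2: header line plus 1-based indexing
        msgs.append(f"row {i + 2}: position_um not strictly increasing")
    if df[PROFILE_COLUMNS].isna().any().any():
        msgs.append("profile contains missing values")
    return msgs


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def read_track(
    path: Union[str, Path],
    axis_origin: Tuple[float, float] = (0.0, 0.0),
    axis_direction: Tuple[float, float] = (1.0, 0.0),
    t_cut_s: float = 0.0,
) -> KinetochoreTrack:
    df = pd.read_csv(path)
    diags = _check_track_frame(df)
    if diags:
        raise ValidationError(diags)
    objects: Dict[str, np.ndarray] = {}
    for name, grp in df.groupby("object_id", sort=True):
        objects[str(name)] = grp[["time_s", "x_um", "y_um"]].to_numpy(float)
    return KinetochoreTrack(
        objects=objects,
        axis_origin=axis_origin,
        axis_direction=axis_direction,
        t_cut_s=t_cut_s,
    )


def write_track(track: KinetochoreTrack, path: Union[str, Path]) -> None:
    frames = []
    for name, arr in track.objects.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": arr[:, 0],
                    "object_id": name,
                    "x_um": arr[:, 1],
                    "y_um": arr[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _check_track_frame(df: pd.DataFrame) -> List[str]:
    msgs = []
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            msgs.append(f"missing required column {col!r}")
    if msgs:
        return msgs
    if df[TRACK_COLUMNS].isna().any().any():
        msgs.append("track contains missing values")
        return msgs
    for name, grp in df.groupby("object_id", sort=False):
        t = grp["time_s"].to_numpy(float)
        bad = np.where(np.diff(t) <= 0)[0]
        for i in bad[:5]:
            row = grp.index[i + 1] + 2
            msgs.append(f"row {row}: time_s not strictly increasing for {name!r}")
    return msgs


def validate_inputs(path: Union[str, Path]) -> List[str]:
    """Schema/invariant check of a CSV input; returns diagnostics (empty = ok).

    The file kind is inferred from its header (profile vs track columns).
    """
    path = Path(path)
    if not path.exists():
        return [f"file not found: {path}"]
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        return [f"unreadable CSV: {exc}"]
    cols = set(df.columns)
    if set(PROFILE_COLUMNS) <= cols:
        if cols - set(PROFILE_COLUMNS):
            extra = sorted(cols - set(PROFILE_COLUMNS))
            return [f"unexpected columns for a profile: {extra}"] + _check_profile_frame(df)
        return _check_profile_frame(df)
    if set(TRACK_COLUMNS) <= cols:
        return _check_track_frame(df)
    return [
        "unrecognized header: expected profile columns "
        f"{PROFILE_COLUMNS} or track columns {TRACK_COLUMNS}; got {sorted(cols)}"
    ]


# ---------------------------------------------------------------------------
# shapes and solutions
# ---------------------------------------------------------------------------

def shape_to_frame(shape: SpindleShape) -> pd.DataFrame:
    rows = []
    for rid in ("p", "k", "b"):
        rod = shape.rods[rid]
        rows.append(
            pd.DataFrame(
                {"rod_id": rid, "x_um": rod.x_um, "y_um": rod.y_um,
                 "slope": rod.slope}
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_shape(shape: SpindleShape, path: Union[str, Path]) -> None:
    shape_to_frame(shape).to_csv(path, index=False)


def solution_to_dict(sol: ForceBalanceSolution) -> Dict[str, object]:
    return {
        "F0_pN": sol.loads.F0_pN,
        "Fk_pN": sol.loads.Fk_pN,
        "M0_pN_um": sol.loads.M0_pN_um,
        "xj_um": sol.xj_um,
        "junction_distance_um": sol.junction_distance_um,
        "h_um": sol.shape.h_um,
        "hj_um": sol.shape.hj_um,
        "residuals": {
            "midpoint_slope": float(sol.residuals[0]),
            "hk_um": float(sol.residuals[1]),
            "thetak_slope": float(sol.residuals[2]),
        },
        "converged": sol.converged,
        "branch": sol.branch,
        "diagnostics": {
            k: v for k, v in sol.diagnostics.items() if k != "distinct_roots"
        },
    }


def write_solution(sol: ForceBalanceSolution, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(solution_to_dict(sol), indent=2))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_GEOM_KEYS = {f.name for f in fields(SpindleGeometry)}
_ARCH_KEYS = {f.name for f in fields(FibreArchitecture)}
_SOLVER_KEYS = {f.name for f in fields(SolverConfig)}


@dataclass
class RunConfig:
    geometry: SpindleGeometry
    architecture: FibreArchitecture
    solver: SolverConfig
    seed: int = 0
    out_dir: Optional[str] = None


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Required blocks: ``geometry`` and ``architecture``; optional: ``solver``,
    ``seed``, ``out_dir``. Unknown keys are rejected.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(["config root must be a mapping"])
    msgs: List[str] = []
    known = {"geometry", "architecture", "solver", "seed", "out_dir"}
    for key in data:
        if key not in known:
            msgs.append(f"unknown top-level key {key!r}")
    for block, allowed in (("geometry", _GEOM_KEYS), ("architecture", _ARCH_KEYS),
                           ("solver", _SOLVER_KEYS)):
        for key in (data.get(block) or {}):
            if key not in allowed:
                msgs.append(f"unknown key {key!r} in block {block!r}")
    if "geometry" not in data:
        msgs.append("missing required block 'geometry'")
    if "architecture" not in data:
        msgs.append("missing required block 'architecture'")
    if msgs:
        raise ValidationError(msgs)
    try:
        geometry = SpindleGeometry(**data["geometry"])
        architecture = FibreArchitecture(**data["architecture"])
        solver_kwargs = dict(data.get("solver") or {})
        for key in ("f0_starts", "fk_starts", "xj_offsets_um", "f0_bounds",
                    "fk_bounds"):
            if key in solver_kwargs:
                solver_kwargs[key] = tuple(solver_kwargs[key])
        solver = SolverConfig(**solver_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValidationError([str(exc)]) from exc
    return RunConfig(
        geometry=geometry,
        architecture=architecture,
        solver=solver,
        seed=int(data.get("seed", 0)),
        out_dir=data.get("out_dir"),
    )
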
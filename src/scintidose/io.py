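"""CSV/JSON interchange for pulse trains, curves and run configuration.

Open text dialects (no vendor formats):

* pulse CSV — header ``t_s,Rs_nC,Rc_nC``, one row per pulse, '.' decimal,
  comma separator, UTF-8, LF line endings;
* curve CSV — header ``abscissa_mm,value`` plus a JSON sidecar
  (``<name>.meta.json``) carrying ``kind``, ``depth_mm``, ``normalized`` and
  ``field_cm``;
* config JSON — calibration, gamma criteria, smoothing window, scan speeds,
  depth schedule, seed and a k-value table.

Numbers are serialized with 17 significant digits (shortest round-trippable
double precision), so write/read round-trips are bit-exact.  All writes go
through a temp file and an atomic rename.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .curves import Curve
from .errors import ConfigError, ParseError
from .gamma import GammaCriteria
from .pulses import CalibrationSet, PulseTrain

__all__ = [
    "read_pulse_csv", "write_pulse_csv",
    "read_curve_csv", "write_curve_csv",
    "RunConfig", "load_config",
]

logger = logging.getLogger("scintidose")

_PULSE_COLUMNS = ["t_s", "Rs_nC", "Rc_nC"]
_CURVE_COLUMNS = ["abscissa_mm", "value"]
_SIDECAR_KEYS = ("depth_mm", "normalized", "field_cm", "d_max_mm", "center_mm")


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise ParseError(f"{path}: non-numeric value in column {col!r} "
                         f"at line {bad[0] + 2}")  # +2: header + 1-based
    return vals


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if list(df.columns) != columns:
        raise ParseError(f"{path}: expected header {','.join(columns)}, "
                         f"got {','.join(map(str, df.columns))}")
    return df


def read_pulse_csv(path) -> PulseTrain:
    """Read a pulse train; rejects missing columns, non-numeric cells and
    non-monotone time, naming the offending line."""
    path = Path(path)
    df = _read_table(path, _PULSE_COLUMNS)
    if len(df) == 0:
        raise ParseError(f"{path}: header only, no pulse rows")
    t = _numeric(df, "t_s", path)
    rs = _numeric(df, "Rs_nC", path)
    rc = _numeric(df, "Rc_nC", path)
    drop = np.flatnonzero(np.diff(t) < 0.0)
    if drop.size:
        raise ParseError(f"{path}: pulse time decreases at line {drop[0] + 3}")
    return PulseTrain(t, rs, rc)


def write_pulse_csv(train: PulseTrain, path) -> None:
    path = Path(path)
    text = train.to_frame().to_csv(index=False, float_format="%.17g",
                                   lineterminator="\n")
    _atomic_write_text(path, text)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_curve_csv(path, kind: Optional[str] = None) -> Curve:
    """Read a curve and its JSON sidecar.

    Without a sidecar the curve kind must be supplied by the caller (a
    warning is logged).  Samples are sorted by abscissa; duplicate abscissa
    values are rejected.
    """
    path = Path(path)
    df = _read_table(path, _CURVE_COLUMNS)
    if len(df) == 0:
        raise ParseError(f"{path}: header only, no samples")
    x = _numeric(df, "abscissa_mm", path)
    v = _numeric(df, "value", path)
    order = np.argsort(x, kind="stable")
    x, v = x[order], v[order]
    dup = np.flatnonzero(np.diff(x) == 0.0)
    if dup.size:
        raise ParseError(f"{path}: duplicate abscissa value {x[dup[0]]:g} mm")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            loaded = json.loads(sidecar.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ParseError(f"{sidecar}: invalid JSON sidecar: {exc}") from exc
        kind = loaded.pop("kind", kind)
        meta.update({k: loaded[k] for k in _SIDECAR_KEYS if k in loaded})
    else:
        if kind is None:
            raise ParseError(f"{path}: no sidecar and no curve kind given")
        logger.warning("%s: no sidecar %s, defaulting kind=%r",
                       path, sidecar.name, kind)
    return Curve(x, v, kind, meta)


def write_curve_csv(curve: Curve, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"abscissa_mm": curve.abscissa, "value": curve.values})
    _atomic_write_text(path, df.to_csv(index=False, float_format="%.17g",
                                       lineterminator="\n"))
    meta = {"kind": curve.kind}
    meta.update({k: curve.meta[k] for k in _SIDECAR_KEYS if k in curve.meta})
    _atomic_write_text(_sidecar_path(path), json.dumps(meta, indent=2) + "\n")


@dataclass
class RunConfig:
    """Validated run configuration for the pipeline CLI."""

    calibration: CalibrationSet = field(
        default_factory=lambda: CalibrationSet(acr=0.963, cr=1.0))
    gamma: GammaCriteria = field(
        default_factory=lambda: GammaCriteria(dose_tol=3.0, dist_tol=1.0,
                                              depth_min=5.0))
    smoothing_window_ms: float = 40.0
    scan_speeds: dict = field(default_factory=lambda: {"small": 10.0, "large": 20.0})
    depth_schedule: Optional[list] = None
    seed: int = 0
    k_values: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a JSON object")
    cfg = RunConfig()
    try:
        if "calibration" in raw:
            cfg.calibration = CalibrationSet(**raw["calibration"])
        if "gamma" in raw:
            cfg.gamma = GammaCriteria(**raw["gamma"])
        if "smoothing_window_ms" in raw:
            w = float(raw["smoothing_window_ms"])
            if w <= 0:
                raise ValueError("smoothing_window_ms must be positive")
            cfg.smoothing_window_ms = w
        if "scan_speeds" in raw:
            cfg.scan_speeds = {str(k): float(v) for k, v in raw["scan_speeds"].items()}
        if "depth_schedule" in raw:
            sched = [float(d) for d in raw["depth_schedule"]]
            if sorted(sched) != sched:
                raise ValueError("depth_schedule must be increasing")
            cfg.depth_schedule = sched
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "k_values" in raw:
            cfg.k_values = {str(det): {str(f): float(k) for f, k in tab.items()}
                            for det, tab in raw["k_values"].items()}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return cfg
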
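"""Scan drivers and structured logging for parameter sweeps.

The delay-axis scan is the package's central in-silico experiment: hold the
calibrated clock fixed, add extra transcriptional delay, and record how
period and classification respond.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import pandas as pd

from .errors import Hes7ClockError, InvalidParameterError
from .metrics import DEFAULT_BURN_IN_MIN, trajectory_metrics
from .model import WILD_TYPE, ClockParameters, integrate

__all__ = ["run_scan", "SCAN_AXES"]

logger = logging.getLogger(__name__)

SCAN_AXES = ("delay", "translation_scale", "mrna_output_scale")


def _apply_axis(base: ClockParameters, axis: str, value: float) -> ClockParameters:
    if axis == "delay":
        return base.with_added_delay(value)
    if axis == "translation_scale":
        return replace(base, protein_synthesis=base.protein_synthesis * value)
    if axis == "mrna_output_scale":
        return replace(base, mrna_synthesis_max=base.mrna_synthesis_max * value)
    raise InvalidParameterError(f"unknown scan axis {axis!r}; choose from {SCAN_AXES}")


def run_scan(
    axis: str,
    grid: list[float],
    base: ClockParameters = WILD_TYPE,
    t_end: float = 2400.0,
    dt: float = 0.05,
    burn_in_min: float = DEFAULT_BURN_IN_MIN,
    channel: str = "mrna",
) -> pd.DataFrame:
    """One row of (value, period, damping ratio, classification) per grid
    value.  Rows are independent; a failure in one row is recorded in that
    row's ``error`` column and the scan continues."""
    if len(grid) == 0:
        raise InvalidParameterError("scan grid must be non-empty")
    if sorted(grid) != list(grid):
        raise InvalidParameterError("scan grid must be sorted")
    if axis not in SCAN_AXES:
        raise InvalidParameterError(
            f"unknown scan axis {axis!r}; choose from {SCAN_AXES}"
        )
    rows = []
    for value in grid:
        row = {
            "value": value,
            "period_min": math.nan,
            "damping_ratio": math.nan,
            "classification": "",
            "error": "",
        }
        try:
            params = _apply_axis(base, axis, value)
            traj = integrate(params, t_end=t_end, dt=dt)
            m = trajectory_metrics(traj, channel=channel, burn_in_min=burn_in_min)
            row.update(
                period_min=m.period_min,
                damping_ratio=m.damping_ratio,
                classification=m.classification,
            )
            logger.debug(
                "scan %s=%g: fingerprint=%s period=%.3f class=%s burn_in=%g",
                axis, value, params.fingerprint(), m.period_min,
                m.classification, burn_in_min,
            )
        except Hes7ClockError as exc:
            row["error"] = str(exc)
            logger.warning("scan %s=%g failed: %s", axis, value, exc)
        rows.append(row)
    return pd.DataFrame(rows)
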
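"""Inducer and comparison stimulus sets for the afterimage experiments.

The paradigms sample isoluminant hue circles around a neutral background:
a 24-hue circle at fixed CIELUV chroma (9-alternative matching), a 72-hue
circle at 5-degree steps (hue+chroma adjustment, in CIELUV or DKL), and a
hue x chroma grid including per-hue maximum chroma within the monitor
gamut.  All generated stimuli are validated to be renderable and
isoluminant with the background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .colorimetry import (
    DKLSpace,
    GamutError,
    MonitorModel,
    circular_signed_difference,
    wrap_degrees,
)

__all__ = [
    "InducerSpec",
    "ComparisonSet",
    "TrialSeries",
    "max_chroma_in_gamut",
    "make_hue_circle_set",
    "make_comparison_set",
    "make_chroma_series_set",
    "make_trial_series",
    "inducers_to_frame",
]


@dataclass(frozen=True)
class InducerSpec:
    """One adapting colour: a hue direction and radial strength in either
    CIELUV (chroma units) or gamut-scaled DKL (radius units), at a fixed
    lightness plane isoluminant with the background."""

    space: str  # "CIELUV" | "DKL"
    hue_azimuth: float  # degrees in [0, 360)
    chroma: float  # CIELUV chroma or DKL radius
    Lstar: float = 70.0
    label: str = ""

    def __post_init__(self):
        if self.space not in ("CIELUV", "DKL"):
            raise ValueError(f"unknown stimulus space {self.space!r}")
        object.__setattr__(self, "hue_azimuth", float(wrap_degrees(self.hue_azimuth)))
        if self.chroma < 0:
            raise ValueError("chroma/radius must be >= 0")

    def to_XYZ(self, monitor: MonitorModel, dkl: DKLSpace = None) -> np.ndarray:
        if self.space == "CIELUV":
            return monitor.XYZ_of_luv_polar(self.Lstar, self.chroma, self.hue_azimuth)
        dkl = dkl or DKLSpace(monitor)
        return dkl.XYZ_of_polar(self.chroma, self.hue_azimuth)


@dataclass(frozen=True)
class ComparisonSet:
    """The nine comparison colours of the matching task: the hue opponent
    to the inducer plus four 10-degree steps to either side, at a fixed
    comparison chroma (30 by default)."""

    inducer: InducerSpec
    hues: tuple
    chroma: float = 30.0
    Lstar: float = 70.0


@dataclass(frozen=True)
class TrialSeries:
    """One measurement series: eight hues 45 degrees apart; the nine series
    with starting azimuths 0, 5, ..., 40 partition the 72-hue circle."""

    series_index: int
    start_azimuth: float
    hues: tuple


def max_chroma_in_gamut(
    hue_azimuth: float,
    Lstar: float,
    monitor: MonitorModel,
    space: str = "CIELUV",
    resolution: float = 1e-4,
    dkl: DKLSpace = None,
) -> float:
    """Largest chroma (CIELUV) or radius (DKL) along a hue ray that stays
    inside the monitor gamut, found by bisection to `resolution`."""
    if not monitor.in_gamut(monitor.background_XYZ):
        raise GamutError("monitor background is out of gamut")
    if space == "DKL":
        dkl = dkl or DKLSpace(monitor)

    def ok(c):
        probe = InducerSpec(space, hue_azimuth, c, Lstar)
        return monitor.in_gamut(probe.to_XYZ(monitor, dkl))

    lo, hi = 0.0, 1.0
    while ok(hi):
        lo, hi = hi, hi * 2.0
        if hi > 1e6:  # pragma: no cover
            raise GamutError("gamut appears unbounded along this ray")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _validate_in_gamut(inducers, monitor, dkl=None):
    if any(i.space == "DKL" for i in inducers):
        dkl = dkl or DKLSpace(monitor)
    bad = [
        i.hue_azimuth
        for i in inducers
        if not monitor.in_gamut(i.to_XYZ(monitor, dkl))
    ]
    if bad:
        raise GamutError(f"stimuli out of gamut at hues {bad}")


def make_hue_circle_set(
    step_deg: float,
    chroma: float,
    space: str,
    monitor: MonitorModel,
    Lstar: float = 70.0,
    label: str = "",
) -> list:
    """Sample a full isoluminant hue circle at fixed chroma in `step_deg`
    steps starting at 0 degrees (e.g. 24 x 15 deg, or 72 x 5 deg)."""
    if not float(360 / step_deg).is_integer():
        raise ValueError("360 must be divisible by step_deg")
    hues = np.arange(0.0, 360.0, step_deg)
    inducers = [InducerSpec(space, h, chroma, Lstar, label) for h in hues]
    _validate_in_gamut(inducers, monitor)
    return inducers


def make_comparison_set(
    inducer: InducerSpec,
    comparison_chroma: float = 30.0,
    monitor: MonitorModel = None,
) -> ComparisonSet:
    """Nine comparison hues: opponent azimuth +/- {0,10,20,30,40} degrees."""
    centre = wrap_degrees(inducer.hue_azimuth + 180.0)
    hues = tuple(float(wrap_degrees(centre + d)) for d in range(-40, 50, 10))
    cs = ComparisonSet(inducer, hues, chroma=comparison_chroma, Lstar=inducer.Lstar)
    if monitor is not None:
        comp = [
            InducerSpec("CIELUV", h, comparison_chroma, inducer.Lstar)
            for h in hues
        ]
        _validate_in_gamut(comp, monitor)
    return cs


def make_chroma_series_set(
    hues,
    levels,
    monitor: MonitorModel,
    space: str = "CIELUV",
    Lstar: float = 70.0,
    label: str = "",
) -> list:
    """Cartesian product of hue directions and chroma levels; the token
    "maximum" expands per hue via max_chroma_in_gamut."""
    dkl = DKLSpace(monitor) if space == "DKL" else None
    out = []
    for h in hues:
        for lev in levels:
            c = (
                max_chroma_in_gamut(h, Lstar, monitor, space, dkl=dkl)
                if isinstance(lev, str) and lev.lower() in ("max", "maximum")
                else float(lev)
            )
            out.append(InducerSpec(space, h, c, Lstar, label))
    _validate_in_gamut(out, monitor, dkl)
    return out


def make_trial_series() -> list:
    """Nine series of eight hues covering the 72-inducer circle exactly
    once: series s starts at 5*s degrees with 45-degree spacing."""
    series = []
    for s in range(9):
        start = 5.0 * s
        hues = tuple(float(wrap_degrees(start + 45.0 * k)) for k in range(8))
        series.append(TrialSeries(series_index=s, start_azimuth=start, hues=hues))
    return series


def inducers_to_frame(inducers, experiment: str = "") -> pd.DataFrame:
    """Export a stimulus list as the package's CSV schema."""
    series_of = {}
    for s in make_trial_series():
        for h in s.hues:
            series_of[h] = s.series_index
    return pd.DataFrame(
        {
            "experiment": experiment or [i.label for i in inducers],
            "space": [i.space for i in inducers],
            "hue_azimuth_deg": [i.hue_azimuth for i in inducers],
            "chroma": [i.chroma for i in inducers],
            "Lstar": [i.Lstar for i in inducers],
            "series_index": [series_of.get(i.hue_azimuth, -1) for i in inducers],
        }
    )
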
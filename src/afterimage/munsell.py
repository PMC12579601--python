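"""Munsell renotation table: parsing, CIELAB interpolation, and the
Munsell-opponent afterimage model.

The Munsell system arranges hues on a 100-step circle (ten sectors R, YR,
Y, GY, G, BG, B, PB, P, RP of ten steps each); the opponent of a hue is
the hue 50 steps away at the same value and chroma.  The renotation table
gives colorimetric coordinates (x, y, Y) for the hue/value/chroma lattice;
colours between lattice points are located by interpolating the table's
CIELAB coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .colorimetry import (
    Lab_to_XYZ,
    XYZ_to_Lab,
    XYZ_to_Luv,
    luv_polar,
    wrap_degrees,
    xyY_to_XYZ,
)

__all__ = [
    "MunsellTable",
    "parse_hue_label",
    "format_hue_label",
    "opposite_hue_step",
    "read_munsell_renotation",
    "synthetic_renotation_table",
    "predict_munsell",
]

_SECTORS = ("R", "YR", "Y", "GY", "G", "BG", "B", "PB", "P", "RP")
_LABEL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(R|YR|Y|GY|G|BG|B|PB|P|RP)\s*$")


class MunsellRangeError(ValueError):
    """Inducer outside the interpolable range of the renotation table."""


def parse_hue_label(label: str) -> float:
    """'7.5GY' -> position on the 100-step hue circle (R starts at 0)."""
    m = _LABEL_RE.match(str(label))
    if not m:
        raise ValueError(f"unparseable Munsell hue label {label!r}")
    num = float(m.group(1))
    if not (0 < num <= 10):
        raise ValueError(f"hue number out of range in {label!r}")
    return _SECTORS.index(m.group(2)) * 10.0 + num


def format_hue_label(step: float) -> str:
    step = float(np.mod(step, 100.0))
    idx = int(step // 10)
    num = step - 10.0 * idx
    if num == 0:
        idx, num = (idx - 1) % 10, 10.0
    num_s = f"{num:g}"
    return f"{num_s}{_SECTORS[idx]}"


def opposite_hue_step(step: float) -> float:
    """Opponent hue on the 100-step circle (+50, an involution)."""
    return float(np.mod(step + 50.0, 100.0))


@dataclass(frozen=True)
class MunsellTable:
    """Renotation lattice with derived CIELAB coordinates.

    ``data`` columns: hue_label, hue_step, value, chroma, x, y, Y, Lstar,
    astar, bstar.  ``white_xy`` is the neutral chromaticity under which
    the CIELAB coordinates were computed (luminance factor 100).
    """

    data: pd.DataFrame
    white_xy: tuple

    @property
    def white_XYZ(self) -> np.ndarray:
        return xyY_to_XYZ([self.white_xy[0], self.white_xy[1], 100.0])

    @classmethod
    def from_records(cls, df: pd.DataFrame, white_xy) -> "MunsellTable":
        df = df.copy()
        df["hue_step"] = df["hue_label"].map(parse_hue_label)
        dup = df.duplicated(subset=["hue_step", "value", "chroma"])
        if dup.any():
            raise ValueError(
                f"duplicate renotation keys at rows {list(df.index[dup])}"
            )
        white = xyY_to_XYZ([white_xy[0], white_xy[1], 100.0])
        lab = XYZ_to_Lab(xyY_to_XYZ(df[["x", "y", "Y"]].to_numpy()), white)
        df[["Lstar", "astar", "bstar"]] = lab
        return cls(data=df, white_xy=tuple(white_xy))

    # -- interpolation -----------------------------------------------------

    def value_plane(self, Lstar: float) -> pd.DataFrame:
        """Rows of the Munsell value whose L* is nearest the target."""
        lstar_of = self.data.groupby("value")["Lstar"].mean()
        v = (lstar_of - Lstar).abs().idxmin()
        return self.data[self.data["value"] == v]

    def _ab_at(self, plane: pd.DataFrame, hue_step: float, chroma: float):
        """Bilinear (a*, b*) at fractional hue_step/chroma on one plane."""
        hues = np.sort(plane["hue_step"].unique())
        h = np.mod(hue_step, 100.0)
        i = np.searchsorted(hues, h)
        h_lo, h_hi = hues[i - 1], hues[i % len(hues)]
        span = np.mod(h_hi - h_lo, 100.0) or 100.0
        t = np.mod(h - h_lo, 100.0) / span

        def column(hs):
            col = plane[plane["hue_step"] == hs].sort_values("chroma")
            cs = col["chroma"].to_numpy()
            if not (cs[0] <= chroma <= cs[-1]):
                raise MunsellRangeError(
                    f"chroma {chroma:.2f} outside table range "
                    f"[{cs[0]}, {cs[-1]}] at hue {format_hue_label(hs)}"
                )
            a = np.interp(chroma, cs, col["astar"].to_numpy())
            b = np.interp(chroma, cs, col["bstar"].to_numpy())
            return np.array([a, b])

        return (1 - t) * column(h_lo) + t * column(h_hi)

    def locate(self, Lab) -> tuple:
        """Invert the interpolation: CIELAB -> (hue_step, value, chroma)."""
        plane = self.value_plane(Lab[0])
        target = np.asarray(Lab[1:], dtype=float)
        d2 = (plane["astar"] - target[0]) ** 2 + (plane["bstar"] - target[1]) ** 2
        near = plane.loc[d2.idxmin()]

        cmax = plane["chroma"].max()

        def resid(p):
            h = np.mod(p[0], 100.0)
            c = np.clip(p[1], plane["chroma"].min(), cmax)
            return self._ab_at(plane, h, c) - target

        sol = least_squares(
            resid,
            x0=[near["hue_step"], near["chroma"]],
            diff_step=1e-4,
            xtol=1e-12,
            ftol=1e-12,
        )
        if np.linalg.norm(sol.fun) > 0.5:
            raise MunsellRangeError(
                "colour outside the interpolable renotation range"
            )
        return (
            float(np.mod(sol.x[0], 100.0)),
            float(near["value"]),
            float(np.clip(sol.x[1], plane["chroma"].min(), cmax)),
        )

    def Lab_of(self, hue_step: float, value: float, chroma: float) -> np.ndarray:
        plane = self.data[self.data["value"] == value]
        if plane.empty:
            raise MunsellRangeError(f"value {value} not in table")
        ab = self._ab_at(plane, hue_step, chroma)
        return np.array([plane["Lstar"].mean(), ab[0], ab[1]])


def read_munsell_renotation(path, white_xy=(0.31006, 0.31616)) -> MunsellTable:
    """Read a renotation-layout delimited text file (columns: hue label,
    value, chroma, x, y, Y; whitespace or comma separated, header
    optional).  Default white is illuminant C, the renotation's own
    reference; pass the monitor white chromaticity to work in the
    monitor's frame."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [c.strip().lower().lstrip("﻿") for c in df.columns]
    rename = {}
    for want, aliases in {
        "hue_label": ("h", "hue", "hue_label"),
        "value": ("v", "value"),
        "chroma": ("c", "chroma"),
        "x": ("x",),
        "y": ("y",),
        "Y": ("y_lum", "y_luminance", "big_y", "yy"),
    }.items():
        for i, c in enumerate(cols):
            if c in aliases and df.columns[i] not in rename:
                rename[df.columns[i]] = want
                break
    # the two y columns: lower-case y first occurrence is chromaticity,
    # second (or capital Y) is the luminance factor
    df = df.rename(columns=rename)
    if "Y" not in df.columns:
        ycols = [c for c in df.columns if str(c).strip() in ("y", "y.1", "Y")]
        if len(ycols) >= 2:
            df = df.rename(columns={ycols[-1]: "Y"})
    missing = {"hue_label", "value", "chroma", "x", "y", "Y"} - set(df.columns)
    if missing:
        raise ValueError(f"renotation file missing columns {sorted(missing)}")
    for c in ("value", "chroma", "x", "y", "Y"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    return MunsellTable.from_records(
        df[["hue_label", "value", "chroma", "x", "y", "Y"]], white_xy
    )


def synthetic_renotation_table(
    white_xy=(0.31006, 0.31616),
    values=(5, 6, 7, 8),
    chromas=tuple(range(2, 33, 2)),
    hue_step_deg: float = 2.5,
) -> MunsellTable:
    """A synthetic renotation-format lattice for tests and demos.

    This is *not* the measured RIT renotation: it is a smooth, idealized
    stand-in built by inverting CIELAB from an analytic hue/value/chroma
    lattice (monotone hue warping, value-dependent radius), shipped so the
    interpolation machinery can be exercised without the external table.
    """
    white = xyY_to_XYZ([white_xy[0], white_xy[1], 100.0])
    rows = []
    steps = np.arange(hue_step_deg, 100.0 + 1e-9, hue_step_deg)
    for v in values:
        L = 10.0 * v + 1.5 * np.sin(0.7 * v)  # roughly L* ~ 10V
        for s in steps:
            # monotone, warped mapping from Munsell steps to Lab hue angle
            theta = np.radians(3.6 * s + 12.0 * np.sin(2 * np.pi * s / 100.0))
            for c in chromas:
                r = 5.2 * c * (1.0 + 0.12 * np.cos(3 * theta)) * (0.8 + 0.04 * v)
                lab = np.array([L, r * np.cos(theta), r * np.sin(theta)])
                XYZ = Lab_to_XYZ(lab, white)
                s_sum = XYZ.sum()
                rows.append(
                    {
                        "hue_label": format_hue_label(s),
                        "value": float(v),
                        "chroma": float(c),
                        "x": XYZ[0] / s_sum,
                        "y": XYZ[1] / s_sum,
                        "Y": XYZ[1],
                    }
                )
    return MunsellTable.from_records(pd.DataFrame(rows), white_xy)


def predict_munsell(inducer, table: MunsellTable, monitor, cfg=None):
    """Munsell-opponent afterimage prediction.

    The effective adapting colour is located in the renotation lattice by
    CIELAB interpolation; its opponent (hue + 50 steps, same value and
    chroma) is mapped back through the table and reported in the common
    CIELUV polar frame.  Convention: the value plane nearest the
    background L* and the inducer's interpolated Munsell chroma.
    """
    from .models import AdaptationConfig, AfterimagePrediction, effective_adapting_colour
    from .colorimetry import LMS_to_XYZ

    cfg = cfg or AdaptationConfig()
    ad_lms = effective_adapting_colour(inducer, monitor, cfg)
    ad_XYZ = LMS_to_XYZ(ad_lms, monitor.fundamentals)
    # renotation frame: luminance-factor scale with white at Y = 100
    scale = 100.0 / monitor.white_XYZ[1]
    lab = XYZ_to_Lab(ad_XYZ * scale, table.white_XYZ)
    hue_step, value, chroma = table.locate(lab)
    opp_lab = table.Lab_of(opposite_hue_step(hue_step), value, chroma)
    opp_XYZ = Lab_to_XYZ(opp_lab, table.white_XYZ)
    if cfg.project_to_background_Lstar:
        Yb = table.white_XYZ[1] * (((monitor.background_Lstar + 16) / 116.0) ** 3)
        opp_XYZ = opp_XYZ * (Yb / opp_XYZ[1])
    Lstar, c, h = luv_polar(XYZ_to_Luv(opp_XYZ, table.white_XYZ))
    return AfterimagePrediction(
        "munsell",
        inducer,
        float(h),
        float(c),
        {
            "munsell_hue": format_hue_label(hue_step),
            "munsell_hue_step": hue_step,
            "value": value,
            "munsell_chroma": chroma,
            "opp_hue": format_hue_label(opposite_hue_step(hue_step)),
            "value_convention": "nearest-background-Lstar",
        },
    )
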
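"""Colorimetric spaces and the calibrated-monitor model.

Implements the tristimulus-level colour pipeline used throughout the
package: CIE xyY/XYZ, Stockman-Sharpe cone excitations, CIELUV and CIELAB
under an explicit reference white, and the cone-opponent DKL plane scaled
to a calibrated monitor's gamut.  Everything runs from tristimulus values;
no spectral computation is involved.

Conventions
-----------
* Hue azimuths are degrees in [0, 360), counterclockwise, 0 deg = +u*
  (or +a*, or +L-M, per space).
* Cone excitations are luminance-scaled: L + M equals the CIE luminance Y
  as a matrix identity, and S equals Z (so the equal-energy white has
  S = L + M).  The cone-adaptation predictions are invariant to any
  per-channel rescaling of these conventions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromaticityY",
    "ConeFundamentals",
    "DEFAULT_MONITOR",
    "STOCKMAN_SHARPE_2DEG",
    "MonitorModel",
    "DKLSpace",
    "xyY_to_XYZ",
    "XYZ_to_xyY",
    "XYZ_to_LMS",
    "LMS_to_XYZ",
    "XYZ_to_Luv",
    "Luv_to_XYZ",
    "luv_polar",
    "luv_from_polar",
    "XYZ_to_Lab",
    "Lab_to_XYZ",
    "circular_signed_difference",
    "wrap_degrees",
]

# CIE L* compression constants
_EPS = 216.0 / 24389.0
_KAPPA = 24389.0 / 27.0


class DegenerateColourError(ValueError):
    """Raised for colorimetric inputs with no defined conversion."""


class GamutError(ValueError):
    """Raised when a requested colour cannot be rendered on the monitor."""


class IsoluminanceError(ValueError):
    """Raised when a DKL isoluminant-plane conversion receives a
    non-isoluminant tristimulus."""


def wrap_degrees(angle):
    """Wrap angle(s) to [0, 360)."""
    out = np.mod(angle, 360.0)
    # np.mod can return 360.0 exactly for tiny negative inputs
    out = np.where(out >= 360.0, out - 360.0, out)
    if np.ndim(out) == 0:
        return float(out)
    return out


def circular_signed_difference(a, b):
    """Signed circular difference a - b in degrees, wrapped to (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


# ---------------------------------------------------------------------------
# xyY <-> XYZ


@dataclass(frozen=True)
class ChromaticityY:
    """CIE 1931 chromaticity coordinates with luminance (cd/m^2)."""

    x: float
    y: float
    Y: float

    def __post_init__(self):
        if not (self.x >= 0 and self.y > 0 and self.x + self.y <= 1 + 1e-12):
            raise DegenerateColourError(
                f"invalid chromaticity (x={self.x}, y={self.y})"
            )
        if self.Y < 0:
            raise DegenerateColourError(f"negative luminance Y={self.Y}")

    def to_XYZ(self) -> np.ndarray:
        return xyY_to_XYZ([self.x, self.y, self.Y])


def xyY_to_XYZ(xyY) -> np.ndarray:
    """Convert xyY to XYZ.  X = x*Y/y, Z = (1-x-y)*Y/y."""
    xyY = np.asarray(xyY, dtype=float)
    x, y, Y = xyY[..., 0], xyY[..., 1], xyY[..., 2]
    if np.any(y <= 0):
        raise DegenerateColourError("chromaticity y must be > 0")
    X = x * Y / y
    Z = (1.0 - x - y) * Y / y
    return np.stack([X, np.asarray(Y, dtype=float), Z], axis=-1)


def XYZ_to_xyY(XYZ) -> np.ndarray:
    XYZ = np.asarray(XYZ, dtype=float)
    s = XYZ.sum(axis=-1)
    if np.any(s <= 0):
        raise DegenerateColourError("X+Y+Z must be > 0")
    x = XYZ[..., 0] / s
    y = XYZ[..., 1] / s
    return np.stack([x, y, XYZ[..., 1]], axis=-1)


# ---------------------------------------------------------------------------
# Cone excitations


def _build_default_fundamentals() -> np.ndarray:
    # CIE-2006-style (Stockman & Sharpe) 2-deg XYZ->LMS matrix.  The L row is
    # rescaled by the luminous-efficiency weight 1.980647 and normalised so
    # that the L+M row sum is exactly (0, 1, 0); M is defined as luminance
    # minus scaled L, which makes L + M = Y an identity of the matrix.
    base_L = np.array([0.210576, 0.855098, -0.0396983])
    w = 1.980647
    s = w * base_L[1] + 1.177260  # Y coefficient of w*L + M in the source matrix
    L_row = w * base_L / s
    M_row = np.array([0.0, 1.0, 0.0]) - L_row
    S_row = np.array([0.0, 0.0, 1.0])  # S scaled so EE white has S = L + M
    return np.vstack([L_row, M_row, S_row])


@dataclass(frozen=True)
class ConeFundamentals:
    """A fixed 3x3 XYZ -> LMS transform with an identifying name.

    The default is a Stockman-Sharpe 2-degree transform, luminance-scaled
    (L + M = Y) with S = Z.  Alternative fundamentals can be supplied as any
    invertible matrix; all model predictions that should be scale-free are
    tested to be invariant under per-channel rescaling.
    """

    name: str = "stockman-sharpe-2deg"
    matrix: np.ndarray = field(default_factory=_build_default_fundamentals)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("cone-fundamental matrix must be invertible 3x3")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def rescaled(self, scales) -> "ConeFundamentals":
        """Return fundamentals with each cone channel multiplied by a factor."""
        s = np.asarray(scales, dtype=float)
        return ConeFundamentals(
            name=f"{self.name}-rescaled", matrix=s[:, None] * self.matrix
        )


STOCKMAN_SHARPE_2DEG = ConeFundamentals()


def XYZ_to_LMS(XYZ, fundamentals: ConeFundamentals = STOCKMAN_SHARPE_2DEG):
    XYZ = np.asarray(XYZ, dtype=float)
    return XYZ @ fundamentals.matrix.T


def LMS_to_XYZ(LMS, fundamentals: ConeFundamentals = STOCKMAN_SHARPE_2DEG):
    LMS = np.asarray(LMS, dtype=float)
    return LMS @ fundamentals.inverse.T


# ---------------------------------------------------------------------------
# CIELUV / CIELAB


def _f_lstar(t):
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def _f_lstar_inv(f):
    f = np.asarray(f, dtype=float)
    f3 = f**3
    return np.where(f3 > _EPS, f3, (116.0 * f - 16.0) / _KAPPA)


def _uv_prime(XYZ):
    XYZ = np.asarray(XYZ, dtype=float)
    d = XYZ[..., 0] + 15.0 * XYZ[..., 1] + 3.0 * XYZ[..., 2]
    return 4.0 * XYZ[..., 0] / d, 9.0 * XYZ[..., 1] / d


def XYZ_to_Luv(XYZ, white) -> np.ndarray:
    """Standard CIELUV under the given reference white; returns (L*, u*, v*)."""
    XYZ = np.asarray(XYZ, dtype=float)
    white = np.asarray(white, dtype=float)
    if white[..., 1] <= 0:
        raise DegenerateColourError("reference white must have Y > 0")
    L = 116.0 * _f_lstar(XYZ[..., 1] / white[..., 1]) - 16.0
    up, vp = _uv_prime(XYZ)
    upn, vpn = _uv_prime(white)
    u = 13.0 * L * (up - upn)
    v = 13.0 * L * (vp - vpn)
    return np.stack([L, u, v], axis=-1)


def Luv_to_XYZ(Luv, white) -> np.ndarray:
    Luv = np.asarray(Luv, dtype=float)
    white = np.asarray(white, dtype=float)
    L, u, v = Luv[..., 0], Luv[..., 1], Luv[..., 2]
    upn, vpn = _uv_prime(white)
    Y = white[..., 1] * _f_lstar_inv((L + 16.0) / 116.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        up = np.where(L != 0, u / (13.0 * L) + upn, upn)
        vp = np.where(L != 0, v / (13.0 * L) + vpn, vpn)
    X = Y * 9.0 * up / (4.0 * vp)
    Z = Y * (12.0 - 3.0 * up - 20.0 * vp) / (4.0 * vp)
    return np.stack([X, Y, Z], axis=-1)


def luv_polar(Luv):
    """(L*, u*, v*) -> (L*, chroma, hue azimuth deg in [0, 360))."""
    Luv = np.asarray(Luv, dtype=float)
    c = np.hypot(Luv[..., 1], Luv[..., 2])
    h = wrap_degrees(np.degrees(np.arctan2(Luv[..., 2], Luv[..., 1])))
    return np.stack([Luv[..., 0], c, h], axis=-1)


def luv_from_polar(Lstar, chroma, hue_deg) -> np.ndarray:
    hr = np.radians(hue_deg)
    return np.stack(
        np.broadcast_arrays(
            np.asarray(Lstar, dtype=float),
            chroma * np.cos(hr),
            chroma * np.sin(hr),
        ),
        axis=-1,
    )


def XYZ_to_Lab(XYZ, white) -> np.ndarray:
    XYZ = np.asarray(XYZ, dtype=float)
    white = np.asarray(white, dtype=float)
    f = _f_lstar(XYZ / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def Lab_to_XYZ(Lab, white) -> np.ndarray:
    Lab = np.asarray(Lab, dtype=float)
    white = np.asarray(white, dtype=float)
    fy = (Lab[..., 0] + 16.0) / 116.0
    fx = fy + Lab[..., 1] / 500.0
    fz = fy - Lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _f_lstar_inv(f) * white


# ---------------------------------------------------------------------------
# Monitor model


@dataclass(frozen=True)
class MonitorModel:
    """Calibrated display: primaries at full drive, per-channel gamma,
    white point, and the lightness of the neutral adapting background.

    The rendering transform is the usual gamma + primary-matrix model:
    linear drive = drive**gamma, XYZ = M @ linear_rgb with M's columns the
    primaries' tristimulus at full drive.
    """

    primaries: tuple  # (R, G, B) ChromaticityY
    gamma: float = 2.2
    white: ChromaticityY = None
    background_Lstar: float = 70.0
    fundamentals: ConeFundamentals = STOCKMAN_SHARPE_2DEG

    def __post_init__(self):
        prim = tuple(
            p if isinstance(p, ChromaticityY) else ChromaticityY(*p)
            for p in self.primaries
        )
        object.__setattr__(self, "primaries", prim)
        if self.white is not None and not isinstance(self.white, ChromaticityY):
            object.__setattr__(self, "white", ChromaticityY(*self.white))
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if abs(np.linalg.det(self.rgb_matrix)) < 1e-9:
            raise ValueError("monitor primaries are colorimetrically degenerate")

    @property
    def rgb_matrix(self) -> np.ndarray:
        """3x3 matrix with columns = primaries' XYZ at full drive."""
        return np.column_stack([p.to_XYZ() for p in self.primaries])

    @property
    def white_XYZ(self) -> np.ndarray:
        if self.white is not None:
            return self.white.to_XYZ()
        return self.rgb_matrix @ np.ones(3)

    @property
    def background_XYZ(self) -> np.ndarray:
        """Neutral background: white-point chromaticity at the luminance
        giving L* = background_Lstar."""
        w = self.white_XYZ
        Y = w[1] * _f_lstar_inv((self.background_Lstar + 16.0) / 116.0)
        return w * (Y / w[1])

    @property
    def background_LMS(self) -> np.ndarray:
        return XYZ_to_LMS(self.background_XYZ, self.fundamentals)

    def rgb_to_XYZ(self, rgb) -> np.ndarray:
        rgb = np.asarray(rgb, dtype=float)
        if np.any(rgb < 0) or np.any(rgb > 1):
            raise ValueError("drive values must lie in [0, 1]")
        return (rgb**self.gamma) @ self.rgb_matrix.T

    def XYZ_to_linear_rgb(self, XYZ) -> np.ndarray:
        XYZ = np.asarray(XYZ, dtype=float)
        return XYZ @ np.linalg.inv(self.rgb_matrix).T

    def in_gamut(self, XYZ, tol: float = 1e-6):
        """True where the inverse rendering transform yields all linear
        drives in [-tol, 1+tol]."""
        lin = self.XYZ_to_linear_rgb(XYZ)
        ok = np.all((lin >= -tol) & (lin <= 1.0 + tol), axis=-1)
        if np.ndim(ok) == 0:
            return bool(ok)
        return ok

    # -- CIELUV helpers tied to this monitor's white ------------------------

    def luv_polar_of_XYZ(self, XYZ) -> np.ndarray:
        return luv_polar(XYZ_to_Luv(XYZ, self.white_XYZ))

    def XYZ_of_luv_polar(self, Lstar, chroma, hue_deg) -> np.ndarray:
        return Luv_to_XYZ(luv_from_polar(Lstar, chroma, hue_deg), self.white_XYZ)


# ---------------------------------------------------------------------------
# DKL isoluminant plane


@dataclass(frozen=True)
class DKLSpace:
    """Cone-opponent (Derrington-Krauskopf-Lennie) isoluminant plane around
    a monitor's neutral background.

    Raw mechanism coordinates are in cone-contrast units relative to the
    background: lm_raw = dL/L_bg - dM/M_bg (constant S, constant luminance)
    and s_raw = dS/S_bg (constant L and M).  Each axis is then rescaled so
    that coordinate +/-1 touches the monitor gamut boundary along that axis
    at background luminance; the scaling constants are exposed as
    ``lm_unit`` and ``s_unit``.
    """

    monitor: MonitorModel
    lm_unit: float = None
    s_unit: float = None

    def __post_init__(self):
        if not self.monitor.in_gamut(self.monitor.background_XYZ):
            raise GamutError("monitor background is out of gamut")
        if self.lm_unit is None:
            object.__setattr__(self, "lm_unit", self._axis_unit(axis="lm"))
        if self.s_unit is None:
            object.__setattr__(self, "s_unit", self._axis_unit(axis="s"))

    def _raw_to_XYZ(self, lm_raw, s_raw) -> np.ndarray:
        bg = self.monitor.background_LMS
        lm_raw = np.asarray(lm_raw, dtype=float)
        s_raw = np.asarray(s_raw, dtype=float)
        # dM = -dL keeps L+M (= luminance) constant
        dL = lm_raw / (1.0 / bg[0] + 1.0 / bg[1])
        dS = s_raw * bg[2]
        LMS = np.stack(
            np.broadcast_arrays(bg[0] + dL, bg[1] - dL, bg[2] + dS), axis=-1
        )
        return LMS_to_XYZ(LMS, self.monitor.fundamentals)

    def _axis_unit(self, axis: str) -> float:
        # largest raw radius with both +r and -r inside the gamut
        def ok(r):
            if axis == "lm":
                pts = self._raw_to_XYZ([r, -r], [0.0, 0.0])
            else:
                pts = self._raw_to_XYZ([0.0, 0.0], [r, -r])
            return bool(np.all(self.monitor.in_gamut(pts)))

        lo, hi = 0.0, 1.0
        while ok(hi):
            lo, hi = hi, hi * 2.0
            if hi > 1e6:  # pragma: no cover - defensive
                raise GamutError("gamut appears unbounded")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ok(mid):
                lo = mid
            else:
                hi = mid
        return lo

    def XYZ_to_dkl(self, XYZ, rtol: float = 1e-6) -> np.ndarray:
        """Isoluminant-plane DKL coordinates (lm, s); background -> (0, 0)."""
        XYZ = np.asarray(XYZ, dtype=float)
        bg = self.monitor.background_LMS
        Ybg = self.monitor.background_XYZ[1]
        if np.any(np.abs(XYZ[..., 1] - Ybg) / Ybg > rtol):
            raise IsoluminanceError(
                "tristimulus is not isoluminant with the background"
            )
        LMS = XYZ_to_LMS(XYZ, self.monitor.fundamentals)
        d = LMS - bg
        lm_raw = d[..., 0] / bg[0] - d[..., 1] / bg[1]
        s_raw = d[..., 2] / bg[2]
        return np.stack([lm_raw / self.lm_unit, s_raw / self.s_unit], axis=-1)

    def dkl_to_XYZ(self, dkl) -> np.ndarray:
        dkl = np.asarray(dkl, dtype=float)
        return self._raw_to_XYZ(
            dkl[..., 0] * self.lm_unit, dkl[..., 1] * self.s_unit
        )

    def XYZ_of_polar(self, radius, azimuth_deg) -> np.ndarray:
        az = np.radians(azimuth_deg)
        return self.dkl_to_XYZ(
            np.stack(
                np.broadcast_arrays(radius * np.cos(az), radius * np.sin(az)),
                axis=-1,
            )
        )

    @staticmethod
    def polar(dkl) -> np.ndarray:
        """(lm, s) -> (radius, azimuth deg in [0, 360))."""
        dkl = np.asarray(dkl, dtype=float)
        r = np.hypot(dkl[..., 0], dkl[..., 1])
        a = wrap_degrees(np.degrees(np.arctan2(dkl[..., 1], dkl[..., 0])))
        return np.stack([r, a], axis=-1)


def monitor_from_dict(cfg: dict) -> MonitorModel:
    """Build a MonitorModel from a config mapping (see io.load_config)."""
    prim = cfg["primaries"]
    order = ("R", "G", "B") if isinstance(prim, dict) else range(3)
    primaries = tuple(ChromaticityY(*prim[k]) for k in order)
    return MonitorModel(
        primaries=primaries,
        gamma=float(cfg.get("gamma", 2.2)),
        white=ChromaticityY(*cfg["white"]) if "white" in cfg else None,
        background_Lstar=float(cfg.get("background_Lstar", 70.0)),
    )


# Default calibrated display: the Eizo ColorEdge-class monitor of the
# afterimage experiments this package models (gamma-corrected at 2.2).
DEFAULT_MONITOR = MonitorModel(
    primaries=(
        ChromaticityY(0.6847, 0.3111, 26.4),
        ChromaticityY(0.2138, 0.7263, 69.9),
        ChromaticityY(0.1521, 0.0453, 4.8),
    ),
    gamma=2.2,
    white=ChromaticityY(0.3304, 0.3526, 101.1),
    background_Lstar=70.0,
)
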
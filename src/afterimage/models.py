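"""Candidate models of complementary afterimage colour.

Each model predicts the colour perceived on a neutral probe after local
adaptation to a coloured inducer, reported as hue azimuth and chroma in a
common CIELUV polar frame:

* ``cone`` — divisive (Weber-law) adaptation of the L, M, S cones: the
  probe's cone contrast relative to the inducer, re-embedded under global
  adaptation to the background.  Because the inducer enters a denominator,
  predictions are non-opponent: hue deviates from the 180-degree opposite
  direction and chroma peaks where single cones escape adaptation.
* ``dkl`` — subtractive adaptation of the cone-opponent (DKL) mechanisms:
  the prediction is exactly minus k times the inducer's opponent signal,
  i.e. the hue 180 degrees away.
* ``cieluv`` / ``cielab`` / ``ciecam02`` — corresponding-colour transforms
  of the standard appearance spaces with the inducer as adapting white
  (u'v' subtraction, the CIELAB white-substitution pseudo von Kries, and
  the CAT02 chromatic adaptation transform respectively).
* ``hering`` — opponency between empirically measured unique-hue
  prototypes (red<->green, yellow<->blue), hue only.
* ``munsell`` — opponency on the 100-step Munsell hue circle via the
  renotation table (see :mod:`afterimage.munsell`).

Adaptation is partial: afterimages are less saturated than their inducers,
so every model adapts to an *effective* adapting colour at the inducer's
hue but at the grand-average matched strength (CIELUV chroma 27.0, DKL
radius 0.47 by default).  None of the models has a free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .colorimetry import (
    DKLSpace,
    GamutError,
    MonitorModel,
    XYZ_to_LMS,
    LMS_to_XYZ,
    XYZ_to_Lab,
    Lab_to_XYZ,
    XYZ_to_Luv,
    Luv_to_XYZ,
    circular_signed_difference,
    luv_polar,
    wrap_degrees,
)
from .stimuli import InducerSpec

__all__ = [
    "MODEL_LABELS",
    "AdaptationConfig",
    "AfterimagePrediction",
    "HeringPrototypes",
    "cone_contrast",
    "effective_adapting_colour",
    "predict_cone_adaptation",
    "predict_cone_opponent",
    "predict_appearance_model",
    "predict_hering",
    "predict",
    "predict_all",
    "add_response_noise",
]

MODEL_LABELS = ("cone", "dkl", "cieluv", "cielab", "ciecam02", "munsell", "hering")

# CAT02 sharpened sensor matrix (CIECAM02)
_M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
_M_CAT02_INV = np.linalg.inv(_M_CAT02)


@dataclass(frozen=True)
class AdaptationConfig:
    """Shared model configuration.

    Parameters
    ----------
    adapt_chroma_luv : float
        CIELUV chroma of the effective adapting colour (grand-average
        matched afterimage strength; 27.0).
    adapt_radius_dkl : float
        Same strength expressed as gamut-scaled DKL radius (0.47), used
        when the inducer is specified in DKL space.
    k : float or None
        Explicit strength of the subtractive opponent model.  None (the
        default) sets the opponent prediction's radius to the effective
        adapting strength, i.e. k = strength / inducer chroma.
    halfwave_rectify : bool
        Split each opponent channel into two single-signed mechanisms
        before subtracting.  Provably a no-op for these stimuli; kept as
        an explicit variant.
    surround_F : float
        CIECAM02 surround factor entering the degree of adaptation
        (1.0 = average surround).
    adapting_luminance : float or None
        La (cd/m^2) for the CAT02 degree of adaptation; None uses
        background luminance / 5.
    degree_of_adaptation : float or None
        Override D directly (None = CIECAM02 formula, not clamped).
    project_to_background_Lstar : bool
        Report predicted chroma in the background-L* plane (the plane all
        stimuli and matches live in) by rescaling the predicted
        tristimulus to background luminance; hue is unaffected.
    """

    adapt_chroma_luv: float = 27.0
    adapt_radius_dkl: float = 0.47
    k: float = None
    halfwave_rectify: bool = False
    surround_F: float = 1.0
    adapting_luminance: float = None
    degree_of_adaptation: float = None
    project_to_background_Lstar: bool = True

    def strength_for(self, inducer: InducerSpec) -> float:
        return self.adapt_chroma_luv if inducer.space == "CIELUV" else self.adapt_radius_dkl


@dataclass(frozen=True)
class AfterimagePrediction:
    """A model's predicted afterimage colour in the common CIELUV frame.

    ``chroma`` is None for models without a chroma prediction (hering);
    ``hue_azimuth`` is NaN when the prediction is achromatic (hue
    undefined).  ``native`` carries model-space coordinates and flags.
    """

    model: str
    inducer: InducerSpec
    hue_azimuth: float
    chroma: float
    native: dict = field(default_factory=dict)

    @property
    def hue_defined(self) -> bool:
        return not math.isnan(self.hue_azimuth)


@dataclass(frozen=True)
class HeringPrototypes:
    """CIELUV azimuths of the measured unique-hue prototypes, in the cyclic
    order red, yellow, green, blue."""

    red: float
    yellow: float
    green: float
    blue: float

    def __post_init__(self):
        a = [self.red, self.yellow, self.green, self.blue]
        d = [wrap_degrees(a[(i + 1) % 4] - a[i]) for i in range(4)]
        if abs(sum(d) - 360.0) > 1e-9 or any(x <= 0 for x in d):
            raise ValueError(
                "prototypes must appear in cyclic order red, yellow, green, blue"
            )


def _polar_prediction(model, inducer, XYZ, monitor, cfg, native):
    """Convert a predicted tristimulus to the common CIELUV polar frame."""
    XYZ = np.asarray(XYZ, dtype=float)
    native = dict(native)
    native["XYZ"] = XYZ
    if cfg.project_to_background_Lstar:
        # u'v' chromaticity is invariant under luminance scaling, so this
        # moves the prediction into the background-L* plane along its ray.
        XYZ = XYZ * (monitor.background_XYZ[1] / XYZ[1])
    Lstar, chroma, hue = monitor.luv_polar_of_XYZ(XYZ)
    if chroma < 1e-9:
        hue = math.nan
    native["Lstar"] = float(Lstar)
    return AfterimagePrediction(model, inducer, float(hue), float(chroma), native)


# ---------------------------------------------------------------------------
# First-stage (cone) adaptation


def cone_contrast(stimulus, adapting) -> np.ndarray:
    """Weber cone contrast (stimulus - adapting) / adapting, per cone."""
    stimulus = np.asarray(stimulus, dtype=float)
    adapting = np.asarray(adapting, dtype=float)
    if np.any(adapting <= 0):
        raise GamutError("adapting cone excitations must be positive")
    return (stimulus - adapting) / adapting


def effective_adapting_colour(
    inducer: InducerSpec,
    monitor: MonitorModel,
    cfg: AdaptationConfig = AdaptationConfig(),
    dkl: DKLSpace = None,
) -> np.ndarray:
    """Cone excitations of the effective adapting colour: the inducer's hue
    direction at the configured (partial) adaptation strength."""
    strength = cfg.strength_for(inducer)
    adapting = replace(inducer, chroma=strength)
    XYZ = adapting.to_XYZ(monitor, dkl)
    if not monitor.in_gamut(XYZ):
        raise GamutError(
            f"adapting colour (strength {strength}) is outside the gamut"
        )
    return XYZ_to_LMS(XYZ, monitor.fundamentals)


def predict_cone_adaptation(
    inducer: InducerSpec,
    monitor: MonitorModel,
    cfg: AdaptationConfig = AdaptationConfig(),
    dkl: DKLSpace = None,
) -> AfterimagePrediction:
    """Divisive cone-adaptation prediction.

    The neutral probe's cone contrast under local adaptation to the
    inducer, CC = (bg - i)/i, is re-embedded under global adaptation to
    the background: LMS_afterimage = bg * (1 + CC) = bg^2 / i per cone.
    """
    bg = monitor.background_LMS
    i_lms = effective_adapting_colour(inducer, monitor, cfg, dkl)
    cc = cone_contrast(bg, i_lms)
    after_lms = bg * (1.0 + cc)
    XYZ = LMS_to_XYZ(after_lms, monitor.fundamentals)
    return _polar_prediction(
        "cone", inducer, XYZ, monitor, cfg,
        {"LMS": after_lms, "cone_contrast": cc},
    )


# ---------------------------------------------------------------------------
# Second-stage (cone-opponent, DKL) adaptation


def _halfwave_subtract(bg_dkl, i_dkl, k):
    # split each channel into +/- mechanisms, adapt each subtractively,
    # recombine; algebraically identical to bg - k*i on a neutral bg
    pos = np.clip(bg_dkl, 0, None) - k * np.clip(i_dkl, 0, None)
    neg = np.clip(-bg_dkl, 0, None) - k * np.clip(-i_dkl, 0, None)
    return pos - neg


def predict_cone_opponent(
    inducer: InducerSpec,
    monitor: MonitorModel,
    cfg: AdaptationConfig = AdaptationConfig(),
    dkl: DKLSpace = None,
) -> AfterimagePrediction:
    """Subtractive cone-opponent prediction: DKL = bgDKL - k * iDKL with a
    neutral background (bgDKL = 0), i.e. exactly -k times the inducer's
    opponent signal — the hue 180 degrees from the inducer, with radius k
    times the inducer's."""
    dkl = dkl or DKLSpace(monitor)
    i_dkl = dkl.XYZ_to_dkl(inducer.to_XYZ(monitor, dkl))
    if cfg.k is not None:
        k = float(cfg.k)
    else:
        # radius of the effective adapting colour along the inducer ray
        ad_lms = effective_adapting_colour(inducer, monitor, cfg, dkl)
        ad_dkl = dkl.XYZ_to_dkl(LMS_to_XYZ(ad_lms, monitor.fundamentals))
        i_r = float(np.hypot(*i_dkl))
        k = float(np.hypot(*ad_dkl)) / i_r if i_r > 0 else 0.0
    if cfg.halfwave_rectify:
        pred_dkl = _halfwave_subtract(np.zeros(2), i_dkl, k)
    else:
        pred_dkl = -k * i_dkl
    XYZ = dkl.dkl_to_XYZ(pred_dkl)
    radius, az = DKLSpace.polar(pred_dkl)
    return _polar_prediction(
        "dkl", inducer, XYZ, monitor, cfg,
        {"dkl": pred_dkl, "dkl_radius": float(radius),
         "dkl_azimuth": float(az), "k": k},
    )


# ---------------------------------------------------------------------------
# Colour-appearance corresponding-colour models


def _cat02_degree_of_adaptation(cfg: AdaptationConfig, monitor: MonitorModel):
    if cfg.degree_of_adaptation is not None:
        return float(cfg.degree_of_adaptation)
    La = (
        cfg.adapting_luminance
        if cfg.adapting_luminance is not None
        else monitor.background_XYZ[1] / 5.0
    )
    return cfg.surround_F * (1.0 - (1.0 / 3.6) * math.exp((-La - 42.0) / 92.0))


def _cat02_corresponding(XYZ, white_adapt, white_ref, D):
    rgb = _M_CAT02 @ XYZ
    rgb_wa = _M_CAT02 @ white_adapt
    rgb_wr = _M_CAT02 @ white_ref
    gain = D * rgb_wr / rgb_wa + (1.0 - D)
    return _M_CAT02_INV @ (rgb * gain)


def predict_appearance_model(
    inducer: InducerSpec,
    monitor: MonitorModel,
    cfg: AdaptationConfig = AdaptationConfig(),
    which: str = "ciecam02",
    dkl: DKLSpace = None,
) -> AfterimagePrediction:
    """Corresponding-colour prediction of an appearance space.

    The grey background's coordinates are computed with the effective
    adapting colour as white point; the prediction is the tristimulus
    with those same coordinates under the global (background) white.  The
    adapting white keeps the reference white's luminance (chromatic
    adaptation only), so CIELUV/CIELAB correspondence preserves L*.
    """
    if which not in ("cieluv", "cielab", "ciecam02"):
        raise ValueError(f"unknown appearance model {which!r}")
    ad_lms = effective_adapting_colour(inducer, monitor, cfg, dkl)
    ad_XYZ = LMS_to_XYZ(ad_lms, monitor.fundamentals)
    white = monitor.white_XYZ
    white_adapt = ad_XYZ * (white[1] / ad_XYZ[1])
    bg = monitor.background_XYZ
    native = {"adapting_white_XYZ": white_adapt}
    if which == "cieluv":
        coords = XYZ_to_Luv(bg, white_adapt)
        XYZ = Luv_to_XYZ(coords, white)
    elif which == "cielab":
        coords = XYZ_to_Lab(bg, white_adapt)
        XYZ = Lab_to_XYZ(coords, white)
    else:
        D = _cat02_degree_of_adaptation(cfg, monitor)
        XYZ = _cat02_corresponding(bg, white_adapt, white, D)
        native["D"] = D
    native["unrealizable"] = bool(np.any(np.asarray(XYZ) < 0))
    return _polar_prediction(which, inducer, XYZ, monitor, cfg, native)


# ---------------------------------------------------------------------------
# Hering opponency


def predict_hering(
    inducer: InducerSpec,
    prototypes: HeringPrototypes,
    monitor: MonitorModel = None,
    cfg: AdaptationConfig = None,
) -> AfterimagePrediction:
    """Hering-opponent prediction: if the inducer lies fraction t of the
    way from one unique-hue prototype to the next, the afterimage lies
    fraction t of the way between their opponents (red<->green,
    yellow<->blue).  No chroma prediction."""
    order = ("red", "yellow", "green", "blue")
    opp = {"red": "green", "yellow": "blue", "green": "red", "blue": "yellow"}
    az = {n: wrap_degrees(getattr(prototypes, n)) for n in order}
    h = wrap_degrees(inducer.hue_azimuth)
    for i, name in enumerate(order):
        a, b = order[i], order[(i + 1) % 4]
        span = wrap_degrees(az[b] - az[a])
        off = wrap_degrees(h - az[a])
        if off <= span + 1e-12:
            t = off / span
            oa, ob = az[opp[a]], az[opp[b]]
            ospan = wrap_degrees(ob - oa)
            pred = wrap_degrees(oa + t * ospan)
            return AfterimagePrediction(
                "hering", inducer, float(pred), None,
                {"segment": (a, b), "t": float(t)},
            )
    raise RuntimeError("unreachable: prototypes cover the circle")


# ---------------------------------------------------------------------------
# Dispatch & response noise


def predict(
    model: str,
    inducer: InducerSpec,
    monitor: MonitorModel,
    cfg: AdaptationConfig = AdaptationConfig(),
    dkl: DKLSpace = None,
    prototypes: HeringPrototypes = None,
    munsell_table=None,
) -> AfterimagePrediction:
    """Predict one inducer's afterimage under the named model."""
    if model == "cone":
        return predict_cone_adaptation(inducer, monitor, cfg, dkl)
    if model == "dkl":
        return predict_cone_opponent(inducer, monitor, cfg, dkl)
    if model in ("cieluv", "cielab", "ciecam02"):
        return predict_appearance_model(inducer, monitor, cfg, model, dkl)
    if model == "hering":
        if prototypes is None:
            raise ValueError("hering model requires measured prototypes")
        return predict_hering(inducer, prototypes)
    if model == "munsell":
        if munsell_table is None:
            raise ValueError("munsell model requires a renotation table")
        from .munsell import predict_munsell

        return predict_munsell(inducer, munsell_table, monitor, cfg)
    raise ValueError(f"unknown model {model!r}")


def predict_all(models, inducers, monitor, cfg=AdaptationConfig(), **kw):
    """Predictions for every model x inducer, as a tidy DataFrame."""
    import pandas as pd

    dkl = kw.pop("dkl", None) or DKLSpace(monitor)
    rows = []
    for model in models:
        for ind in inducers:
            p = predict(model, ind, monitor, cfg, dkl=dkl, **kw)
            rows.append(
                {
                    "model": model,
                    "space": ind.space,
                    "inducer_hue_deg": ind.hue_azimuth,
                    "inducer_chroma": ind.chroma,
                    "pred_hue_deg": p.hue_azimuth,
                    "pred_chroma": p.chroma if p.chroma is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def add_response_noise(predictions, sigma_hue, n_per_inducer, seed):
    """Wrapped-Gaussian hue samples around each prediction.

    Returns an array of shape (len(predictions), n_per_inducer) of hue
    azimuths in [0, 360); with sigma 0 every sample equals the predicted
    hue.  Deterministic for a given seed.
    """
    if sigma_hue < 0:
        raise ValueError("sigma_hue must be >= 0")
    if n_per_inducer < 1:
        raise ValueError("n_per_inducer must be >= 1")
    rng = np.random.default_rng(seed)
    mus = np.array(
        [p.hue_azimuth if hasattr(p, "hue_azimuth") else float(p) for p in predictions]
    )
    draws = rng.normal(0.0, sigma_hue, size=(len(mus), int(n_per_inducer)))
    return wrap_degrees(mus[:, None] + draws)
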
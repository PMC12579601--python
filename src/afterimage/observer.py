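"""Synthetic psychophysical observers.

Generates simulated datasets with the statistical structure the analysis
pipeline assumes, for each paradigm: 9-alternative hue matching (choose
the comparison closest to the afterimage, with a skip probability) and
continuous hue+chroma adjustment (including the hue x chroma grid of the
chroma-series design).  The observer's "true" afterimage is a chosen
generative model's prediction plus wrapped-Gaussian hue noise and
rectified-Gaussian chroma noise; everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .colorimetry import DKLSpace, MonitorModel, circular_signed_difference, wrap_degrees
from .models import AdaptationConfig, HeringPrototypes, predict
from .stimuli import InducerSpec, make_comparison_set

__all__ = [
    "ObserverConfig",
    "simulate_exp1_matching",
    "simulate_exp2_adjustment",
    "simulate_exp3_series",
    "run_model_recovery",
]

_COLUMNS = [
    "experiment",
    "participant",
    "block",
    "trial",
    "space",
    "inducer_hue_deg",
    "inducer_chroma",
    "inducer_Lstar",
    "response_hue_deg",
    "response_chroma",
    "skipped",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Generative settings of a simulated observer population.

    sigma_hue is the wrapped-Gaussian response-noise sd in degrees (the
    scale of the measured trial-to-trial variability), sigma_chroma the
    Gaussian chroma-noise sd in CIELUV units, p_skip the probability of
    skipping a matching trial.
    """

    truth_model: str = "cone"
    sigma_hue: float = 10.0
    sigma_chroma: float = 5.0
    p_skip: float = 0.02
    n_participants: int = 10
    n_reps: int = 1
    seed: int = 0
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)

    def __post_init__(self):
        if self.sigma_hue < 0 or self.sigma_chroma < 0:
            raise ValueError("noise sds must be >= 0")
        if not (0 <= self.p_skip <= 1):
            raise ValueError("p_skip must be in [0, 1]")


def _truth_predictions(inducers, cfg, monitor, dkl, **model_kw):
    return [
        predict(cfg.truth_model, ind, monitor, cfg.adaptation, dkl=dkl, **model_kw)
        for ind in inducers
    ]


def simulate_exp1_matching(
    inducers,
    cfg: ObserverConfig,
    monitor: MonitorModel,
    comparison_chroma: float = 30.0,
    experiment: str = "1b",
    **model_kw,
) -> pd.DataFrame:
    """Simulate the 9-alternative matching task.

    Per participant x inducer x rep the true afterimage hue is drawn as
    the truth model's prediction plus wrapped-Gaussian noise; the response
    is the comparison hue at minimum absolute circular distance (ties to
    the lower azimuth).  With probability p_skip the trial is skipped.
    """
    rng = np.random.default_rng(cfg.seed)
    dkl = DKLSpace(monitor) if any(i.space == "DKL" for i in inducers) else None
    preds = _truth_predictions(inducers, cfg, monitor, dkl, **model_kw)
    rows = []
    for pp in range(cfg.n_participants):
        for rep in range(cfg.n_reps):
            for ind, pred in zip(inducers, preds):
                row = {
                    "experiment": experiment,
                    "participant": f"s{pp:02d}",
                    "block": rep,
                    "trial": len(rows),
                    "space": ind.space,
                    "inducer_hue_deg": ind.hue_azimuth,
                    "inducer_chroma": ind.chroma,
                    "inducer_Lstar": ind.Lstar,
                }
                if rng.random() < cfg.p_skip:
                    row.update(
                        response_hue_deg=np.nan, response_chroma=np.nan, skipped=1
                    )
                else:
                    true_hue = wrap_degrees(
                        pred.hue_azimuth + rng.normal(0.0, cfg.sigma_hue)
                    )
                    comp = make_comparison_set(ind, comparison_chroma).hues
                    dist = np.abs(
                        circular_signed_difference(np.array(comp), true_hue)
                    )
                    # stable argmin -> tie broken towards lower azimuth
                    order = np.lexsort((np.array(comp), dist))
                    row.update(
                        response_hue_deg=comp[order[0]],
                        response_chroma=np.nan,
                        skipped=0,
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def simulate_exp2_adjustment(
    inducers,
    cfg: ObserverConfig,
    monitor: MonitorModel,
    experiment: str = "2a",
    **model_kw,
) -> pd.DataFrame:
    """Simulate the continuous hue+chroma adjustment task: the settled
    match is the truth prediction plus wrapped-Gaussian hue noise and
    zero-truncated Gaussian chroma noise."""
    rng = np.random.default_rng(cfg.seed)
    dkl = DKLSpace(monitor) if any(i.space == "DKL" for i in inducers) else None
    preds = _truth_predictions(inducers, cfg, monitor, dkl, **model_kw)
    rows = []
    for pp in range(cfg.n_participants):
        for rep in range(cfg.n_reps):
            for ind, pred in zip(inducers, preds):
                hue = wrap_degrees(pred.hue_azimuth + rng.normal(0.0, cfg.sigma_hue))
                if pred.chroma is None:
                    chroma = np.nan
                else:
                    chroma = max(
                        0.0, pred.chroma + rng.normal(0.0, cfg.sigma_chroma)
                    )
                rows.append(
                    {
                        "experiment": experiment,
                        "participant": f"s{pp:02d}",
                        "block": rep,
                        "trial": len(rows),
                        "space": ind.space,
                        "inducer_hue_deg": ind.hue_azimuth,
                        "inducer_chroma": ind.chroma,
                        "inducer_Lstar": ind.Lstar,
                        "response_hue_deg": hue,
                        "response_chroma": chroma,
                        "skipped": 0,
                    }
                )
    return pd.DataFrame(rows, columns=_COLUMNS)


def simulate_exp3_series(
    hues,
    levels,
    cfg: ObserverConfig,
    monitor: MonitorModel,
    space: str = "CIELUV",
    Lstar: float = 70.0,
    **model_kw,
) -> pd.DataFrame:
    """Adjustment-style records across a hue x chroma-level grid (levels
    may include the token "maximum")."""
    from .stimuli import make_chroma_series_set

    inducers = make_chroma_series_set(hues, levels, monitor, space, Lstar)
    return simulate_exp2_adjustment(
        inducers, cfg, monitor, experiment="3", **model_kw
    )


def run_model_recovery(
    configs,
    models,
    monitor: MonitorModel,
    inducers=None,
    **model_kw,
) -> pd.DataFrame:
    """Simulate datasets and ask the analysis which model wins.

    For each ObserverConfig, an adjustment-task dataset is generated from
    its truth model, per-inducer aggregates are compared against every
    candidate model's predictions, and the winner is the model with the
    lowest mean absolute hue error; the sign test against the runner-up
    quantifies the preference.  Returns one row per configuration.
    """
    from .models import predict_all
    from .stats import aggregate_measurements, compare_models_sign, model_prediction_errors
    from .stimuli import make_hue_circle_set

    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    if inducers is None:
        inducers = make_hue_circle_set(5.0, 50.0, "CIELUV", monitor)
    pred_frame = predict_all(models, inducers, monitor, configs[0].adaptation, **model_kw)
    rows = []
    for cfg in configs:
        sim = simulate_exp2_adjustment(inducers, cfg, monitor, **model_kw)
        agg = aggregate_measurements(sim)
        errors = model_prediction_errors(agg, pred_frame)
        mean_err = errors.groupby("model")["hue_abs_error"].mean().sort_values()
        win, second = mean_err.index[0], mean_err.index[1]
        e_win = errors[errors["model"] == win].sort_values("inducer_hue_deg")
        e_2nd = errors[errors["model"] == second].sort_values("inducer_hue_deg")
        st = compare_models_sign(
            e_win["hue_abs_error"].to_numpy(), e_2nd["hue_abs_error"].to_numpy()
        )
        rows.append(
            {
                "truth_model": cfg.truth_model,
                "seed": cfg.seed,
                "sigma_hue": cfg.sigma_hue,
                "winner": win,
                "runner_up": second,
                "winner_mean_abs_error": mean_err.iloc[0],
                "sign_S": st.S,
                "sign_n": st.n,
                "sign_p": st.p,
            }
        )
    return pd.DataFrame(rows)
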
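"""Model/Results interface for a full afterimage experiment.

`AfterimageExperiment` is built from a trial-level measurements table
(one row per response: participant, inducer hue/chroma/space, matched
hue/chroma, skipped flag) plus a calibrated monitor.  ``fit()`` runs the
whole analysis — per-inducer aggregation, model predictions, deviation
curves, correlations with Fisher confidence intervals, hue histograms
with noise-convolved model simulation, per-model error tables, and model
comparison tests — and returns an `AfterimageResults` with a printable
``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import DEFAULT_MONITOR, DKLSpace, MonitorModel
from .models import AdaptationConfig, HeringPrototypes, MODEL_LABELS, predict_all
from .stats import (
    CorrelationResult,
    DegenerateDataError,
    aggregate_measurements,
    circular_mean_hue,
    circular_signed_difference,
    compare_models_paired_t,
    compare_models_sign,
    deviation_from_opponency,
    hue_histogram,
    histogram_model_correlation,
    model_prediction_errors,
    pearson_fisher_ci,
    smooth_circular,
    smoothed_variance_explained,
    zscore,
)
from .stimuli import InducerSpec

__all__ = ["AfterimageExperiment", "AfterimageResults"]

_REQUIRED = {
    "participant",
    "space",
    "inducer_hue_deg",
    "inducer_chroma",
    "response_hue_deg",
    "skipped",
}


class AfterimageExperiment:
    """An afterimage measurement campaign plus the candidate models.

    Parameters
    ----------
    data : DataFrame
        Trial-level measurements (io.read_measurements schema).
    monitor : MonitorModel
        The calibrated display the stimuli were rendered on.
    models : sequence of str
        Candidate models to evaluate (subset of MODEL_LABELS); models
        needing external inputs (hering prototypes, munsell table) are
        skipped unless those are supplied.
    adaptation : AdaptationConfig
        Shared partial-adaptation configuration.
    reference_model : str
        The model other models are compared against (default "cone").
    """

    def __init__(
        self,
        data: pd.DataFrame,
        monitor: MonitorModel = DEFAULT_MONITOR,
        models=("cone", "dkl", "cieluv", "cielab", "ciecam02"),
        adaptation: AdaptationConfig = AdaptationConfig(),
        prototypes: HeringPrototypes = None,
        munsell_table=None,
        reference_model: str = "cone",
        n_bins: int = 24,
        smooth_window: int = 9,
        sigma_hue: float = None,
        histogram_seed: int = 0,
        histogram_draws: int = 100_000,
    ):
        missing = _REQUIRED - set(data.columns)
        if missing:
            raise ValueError(f"measurements table missing columns {sorted(missing)}")
        models = tuple(models)
        unknown = set(models) - set(MODEL_LABELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        if "hering" in models and prototypes is None:
            raise ValueError("hering model requested without prototypes")
        if "munsell" in models and munsell_table is None:
            raise ValueError("munsell model requested without a renotation table")
        if reference_model not in models:
            raise ValueError("reference_model must be among the fitted models")
        self.data = data.reset_index(drop=True)
        self.monitor = monitor
        self.models = models
        self.adaptation = adaptation
        self.prototypes = prototypes
        self.munsell_table = munsell_table
        self.reference_model = reference_model
        self.n_bins = n_bins
        self.smooth_window = smooth_window
        self.sigma_hue = sigma_hue
        self.histogram_seed = histogram_seed
        self.histogram_draws = histogram_draws

    @classmethod
    def from_csv(cls, path, **kw) -> "AfterimageExperiment":
        from .io import read_measurements

        return cls(read_measurements(path), **kw)

    # ------------------------------------------------------------------

    def inducers(self) -> list:
        cols = ["space", "inducer_hue_deg", "inducer_chroma"]
        uni = self.data[cols + ["inducer_Lstar"]] if "inducer_Lstar" in self.data else self.data[cols].assign(inducer_Lstar=70.0)
        uni = uni.drop_duplicates(cols).sort_values(cols)
        return [
            InducerSpec(r.space, r.inducer_hue_deg, r.inducer_chroma, r.inducer_Lstar)
            for r in uni.itertuples()
        ]

    def estimate_sigma_hue(self) -> float:
        """Circular sd of responses about each inducer's mean, pooled —
        the default response-noise scale for histogram simulation."""
        d = self.data[~self.data["skipped"].astype(bool)]
        devs = []
        for _, g in d.groupby(["space", "inducer_hue_deg", "inducer_chroma"]):
            if len(g) < 2:
                continue
            mu = circular_mean_hue(g["response_hue_deg"])
            devs.extend(
                np.atleast_1d(
                    circular_signed_difference(g["response_hue_deg"].to_numpy(), mu)
                )
            )
        if len(devs) < 2:
            raise DegenerateDataError("not enough repeated responses to estimate noise")
        return float(np.std(devs, ddof=1))

    def fit(self, compute_histograms: bool = True) -> "AfterimageResults":
        dkl = DKLSpace(self.monitor)
        inducers = self.inducers()
        predictions = predict_all(
            self.models,
            inducers,
            self.monitor,
            self.adaptation,
            dkl=dkl,
            prototypes=self.prototypes,
            munsell_table=self.munsell_table,
        )
        agg = aggregate_measurements(self.data)
        errors = model_prediction_errors(agg, predictions)

        # deviation-from-opponency curves
        agg = agg.sort_values("inducer_hue_deg").reset_index(drop=True)
        agg["meas_dev_opp"] = deviation_from_opponency(
            agg["matched_hue"].to_numpy(), agg["inducer_hue_deg"].to_numpy()
        )

        sigma = self.sigma_hue if self.sigma_hue is not None else self.estimate_sigma_hue()

        correlations = {}
        for model in self.models:
            pm = (
                predictions[predictions["model"] == model]
                .sort_values("inducer_hue_deg")
                .reset_index(drop=True)
            )
            merged = agg.merge(
                pm,
                on=["space", "inducer_hue_deg", "inducer_chroma"],
                validate="one_to_one",
            ).sort_values("inducer_hue_deg")
            pred_dev = deviation_from_opponency(
                merged["pred_hue_deg"].to_numpy(), merged["inducer_hue_deg"].to_numpy()
            )
            entry = {}
            try:
                entry["hue_deviation"] = pearson_fisher_ci(
                    merged["meas_dev_opp"], pred_dev
                )
                entry["hue_deviation_sR2"] = smoothed_variance_explained(
                    merged["meas_dev_opp"], pred_dev, self.smooth_window
                )
            except (DegenerateDataError, ValueError):
                pass
            if (
                merged["pred_chroma"].notna().all()
                and merged["matched_chroma"].notna().all()
            ):
                try:
                    entry["chroma"] = pearson_fisher_ci(
                        merged["matched_chroma"], merged["pred_chroma"]
                    )
                    entry["chroma_sR2"] = smoothed_variance_explained(
                        merged["matched_chroma"], merged["pred_chroma"], self.smooth_window
                    )
                except (DegenerateDataError, ValueError):
                    pass
            correlations[model] = entry

        # hue histograms: measured responses vs noise-convolved predictions
        resp = self.data.loc[~self.data["skipped"].astype(bool), "response_hue_deg"]
        measured_hist = hue_histogram(resp, self.n_bins)
        histogram_corr = {}
        if compute_histograms:
            for model in self.models:
                pm = predictions[predictions["model"] == model]
                try:
                    histogram_corr[model] = histogram_model_correlation(
                        measured_hist,
                        pm["pred_hue_deg"].to_numpy(),
                        sigma,
                        self.histogram_seed,
                        self.histogram_draws,
                    )
                except (DegenerateDataError, ValueError):
                    pass

        comparisons = self._compare(errors)

        return AfterimageResults(
            experiment=self,
            aggregates=agg,
            predictions=predictions,
            errors=errors,
            correlations=correlations,
            histogram_correlations=histogram_corr,
            measured_histogram=measured_hist,
            comparisons=comparisons,
            sigma_hue=sigma,
        )

    def _compare(self, errors: pd.DataFrame) -> pd.DataFrame:
        """Reference model vs each alternative: sign tests across inducers
        on hue and z-scored chroma errors; paired t across participants
        on per-participant mean absolute hue error when available."""
        ref = self.reference_model
        rows = []
        key = ["space", "inducer_hue_deg", "inducer_chroma"]
        e_ref = errors[errors["model"] == ref].sort_values(key)
        # per-participant errors for the paired t-test
        per_pp = self._per_participant_errors()
        for model in self.models:
            if model == ref:
                continue
            e_m = errors[errors["model"] == model].sort_values(key)
            row = {"model": model, "reference": ref}
            try:
                st = compare_models_sign(
                    e_ref["hue_abs_error"].to_numpy(), e_m["hue_abs_error"].to_numpy()
                )
                row.update(hue_sign_n=st.n, hue_sign_S=st.S, hue_sign_p=st.p)
            except DegenerateDataError:
                pass
            if e_m["chroma_abs_error"].notna().all() and e_ref["chroma_abs_error"].notna().all():
                try:
                    st = compare_models_sign(
                        e_ref["chroma_abs_error"].to_numpy(),
                        e_m["chroma_abs_error"].to_numpy(),
                    )
                    row.update(
                        chroma_sign_n=st.n, chroma_sign_S=st.S, chroma_sign_p=st.p
                    )
                except DegenerateDataError:
                    pass
            if per_pp is not None and model in per_pp and ref in per_pp:
                try:
                    tt = compare_models_paired_t(per_pp[ref], per_pp[model])
                    row.update(
                        Mdiff=tt.mean, t=tt.t, df=tt.df,
                        ci_low=tt.ci_low, ci_high=tt.ci_high, p=tt.p, d=tt.d,
                    )
                except (DegenerateDataError, ValueError):
                    pass
            rows.append(row)
        return pd.DataFrame(rows)

    def _per_participant_errors(self):
        """Mean absolute hue error per participant per model, aligned."""
        pps = sorted(self.data["participant"].unique())
        if len(pps) < 2:
            return None
        dkl = DKLSpace(self.monitor)
        predictions = predict_all(
            self.models,
            self.inducers(),
            self.monitor,
            self.adaptation,
            dkl=dkl,
            prototypes=self.prototypes,
            munsell_table=self.munsell_table,
        )
        out = {m: [] for m in self.models}
        for pp in pps:
            sub = self.data[self.data["participant"] == pp]
            agg = aggregate_measurements(sub)
            err = model_prediction_errors(agg, predictions)
            for m in self.models:
                out[m].append(
                    err.loc[err["model"] == m, "hue_abs_error"].mean()
                )
        return {m: np.array(v) for m, v in out.items()}


@dataclass
class AfterimageResults:
    """Fitted results of an AfterimageExperiment.

    Attributes
    ----------
    aggregates : per-inducer circular-mean hues / mean chromas and the
        measured deviation-from-opponency curve.
    predictions : tidy per-model, per-inducer predicted hue and chroma.
    errors : per-model, per-inducer absolute hue and z-scored chroma errors.
    correlations : per-model CorrelationResults for the deviation curve and
        chroma profile, with smoothed-variance-explained (sR^2) figures.
    histogram_correlations : per-model correlation between the measured hue
        histogram and the model's noise-convolved simulated histogram.
    comparisons : reference-vs-alternative test table (sign tests across
        inducers; paired t-tests across participants when available).
    """

    experiment: AfterimageExperiment
    aggregates: pd.DataFrame
    predictions: pd.DataFrame
    errors: pd.DataFrame
    correlations: dict
    histogram_correlations: dict
    measured_histogram: object
    comparisons: pd.DataFrame
    sigma_hue: float

    def mean_abs_hue_error(self) -> pd.Series:
        return (
            self.errors.groupby("model")["hue_abs_error"].mean().sort_values()
        )

    def best_model(self) -> str:
        return self.mean_abs_hue_error().index[0]

    # ------------------------------------------------------------------

    def summary(self) -> str:
        lines = []
        ex = self.experiment
        n_ind = self.aggregates.shape[0]
        n_pp = ex.data["participant"].nunique()
        lines.append("Afterimage experiment analysis")
        lines.append("=" * 62)
        lines.append(
            f"inducers: {n_ind}   participants: {n_pp}   "
            f"trials: {len(ex.data)} (skipped {int(ex.data['skipped'].sum())})"
        )
        lines.append(
            f"models: {', '.join(ex.models)}   reference: {ex.reference_model}"
        )
        lines.append(
            f"adaptation strength: CIELUV {ex.adaptation.adapt_chroma_luv}, "
            f"DKL {ex.adaptation.adapt_radius_dkl}   sigma_hue: {self.sigma_hue:.2f} deg"
        )
        lines.append("")
        lines.append(
            f"{'model':10s} {'mean|hue err|':>13s} {'r(dev)':>8s} "
            f"{'r(chroma)':>10s} {'r(hist)':>8s} {'sR2(dev)%':>10s}"
        )
        mae = self.mean_abs_hue_error()
        for m in mae.index:
            c = self.correlations.get(m, {})
            hd = c.get("hue_deviation")
            ch = c.get("chroma")
            hh = self.histogram_correlations.get(m)
            lines.append(
                f"{m:10s} {mae[m]:13.2f} "
                f"{hd.r if hd else float('nan'):8.2f} "
                f"{ch.r if ch else float('nan'):10.2f} "
                f"{hh.r if hh else float('nan'):8.2f} "
                f"{c.get('hue_deviation_sR2', float('nan')):10.1f}"
            )
        if len(self.comparisons):
            lines.append("")
            lines.append(f"comparisons vs {ex.reference_model} (sign test, hue):")
            for _, r in self.comparisons.iterrows():
                if "hue_sign_S" in r and not pd.isna(r.get("hue_sign_S", np.nan)):
                    extra = ""
                    if "t" in r and not pd.isna(r.get("t", np.nan)):
                        extra = f"   paired t({int(r['df'])}) = {r['t']:.2f}, p = {r['p']:.3g}"
                    lines.append(
                        f"  {r['model']:10s} S = {int(r['hue_sign_S'])}/{int(r['hue_sign_n'])}, "
                        f"p = {r['hue_sign_p']:.3g}{extra}"
                    )
        lines.append("")
        lines.append(f"best model (lowest mean |hue error|): {self.best_model()}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable report mirroring the summary tables."""

        def corr(c):
            return None if c is None else {
                "r": c.r, "df": c.df, "ci": [c.ci_low, c.ci_high], "p": c.p
            }

        return {
            "n_inducers": int(self.aggregates.shape[0]),
            "n_participants": int(self.experiment.data["participant"].nunique()),
            "sigma_hue_deg": self.sigma_hue,
            "mean_abs_hue_error": self.mean_abs_hue_error().to_dict(),
            "best_model": self.best_model(),
            "correlations": {
                m: {
                    "hue_deviation": corr(c.get("hue_deviation")),
                    "hue_deviation_sR2": c.get("hue_deviation_sR2"),
                    "chroma": corr(c.get("chroma")),
                    "chroma_sR2": c.get("chroma_sR2"),
                }
                for m, c in self.correlations.items()
            },
            "histogram_correlations": {
                m: corr(c) for m, c in self.histogram_correlations.items()
            },
            "comparisons": json.loads(
                self.comparisons.to_json(orient="records")
            ) if len(self.comparisons) else [],
        }

    def save_report(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)

    # ------------------------------------------------------------------

    def plot_deviation_curves(self, ax=None, models=None):
        """Deviation-from-opponency of measurements and model predictions
        as a function of inducer hue."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        agg = self.aggregates.sort_values("inducer_hue_deg")
        ax.plot(
            agg["inducer_hue_deg"], agg["meas_dev_opp"], "k.-", label="measured"
        )
        for m in models or self.experiment.models:
            pm = self.predictions[self.predictions["model"] == m].sort_values(
                "inducer_hue_deg"
            )
            dev = deviation_from_opponency(
                pm["pred_hue_deg"].to_numpy(), pm["inducer_hue_deg"].to_numpy()
            )
            ax.plot(pm["inducer_hue_deg"], dev, label=m, alpha=0.8)
        ax.set_xlabel("inducer hue azimuth (deg)")
        ax.set_ylabel("deviation from opponency (deg)")
        ax.axhline(0, color="0.8", lw=0.8)
        ax.legend(fontsize=8)
        return ax

    def plot_hue_histogram(self, ax=None):
        """Polar plot of the measured hue histogram."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        h = self.measured_histogram.normalized()
        theta = np.radians(h.centres)
        ax.bar(theta, h.counts, width=np.radians(360 / h.n_bins), alpha=0.5)
        return ax
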
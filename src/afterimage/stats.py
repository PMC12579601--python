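"""Analysis pipeline for afterimage measurements.

Circular hue statistics (deviations from opponency, circular means, hue
histograms, circular smoothing), the correlation and test machinery of the
model comparisons (Pearson correlations with Fisher-transform confidence
intervals, one-sample and paired t-tests with Cohen's d, exact binomial
sign tests), and the chroma-series analysis that isolates hue changes
across inducer chroma via a per-hue average reference line.

All hue arithmetic is in degrees and rotation-equivariant; two-tailed
p-values throughout; z-scores use the sample-sd (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .colorimetry import circular_signed_difference, wrap_degrees

__all__ = [
    "HueHistogram",
    "CorrelationResult",
    "TTestResult",
    "SignTestResult",
    "deviation_from_opponency",
    "circular_mean_hue",
    "circular_sd_hue",
    "hue_histogram",
    "smooth_circular",
    "pearson_fisher_ci",
    "one_sample_deviation_test",
    "zscore",
    "aggregate_measurements",
    "model_prediction_errors",
    "compare_models_paired_t",
    "compare_models_sign",
    "smoothed_variance_explained",
    "histogram_model_correlation",
    "chroma_series_analysis",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# circular primitives


def deviation_from_opponency(matched_hue, inducer_hue):
    """Signed deviation of a matched afterimage hue from the hue opponent
    (180 deg away) to the inducer, in (-180, 180]."""
    return circular_signed_difference(matched_hue, np.asarray(inducer_hue) + 180.0)


def circular_mean_hue(hues) -> float:
    """Resultant-vector mean azimuth in degrees."""
    h = np.radians(np.asarray(hues, dtype=float))
    if h.size == 0:
        raise DegenerateDataError("circular mean of empty sample")
    c, s = np.cos(h).mean(), np.sin(h).mean()
    if np.hypot(c, s) < 1e-12:
        raise DegenerateDataError("circular mean undefined (zero resultant)")
    return float(wrap_degrees(np.degrees(np.arctan2(s, c))))


def circular_sd_hue(hues) -> float:
    """Circular standard deviation, degrees: sqrt(-2 ln R)."""
    h = np.radians(np.asarray(hues, dtype=float))
    R = np.hypot(np.cos(h).mean(), np.sin(h).mean())
    R = min(R, 1.0)
    if R <= 0:
        raise DegenerateDataError("circular sd undefined (zero resultant)")
    return float(np.degrees(np.sqrt(-2.0 * np.log(R))))


@dataclass(frozen=True)
class HueHistogram:
    """Circular binned counts over azimuth; bins tile [0, 360) exactly,
    left-closed right-open, first edge at 0."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalized(self) -> "HueHistogram":
        if self.counts.sum() == 0:
            raise DegenerateDataError("cannot normalize an empty histogram")
        return HueHistogram(self.bin_edges, self.counts / self.counts.sum(), self.n)


def hue_histogram(hues, n_bins: int = 24) -> HueHistogram:
    """Count hue responses in `n_bins` equal intervals (e.g. 24 bins of
    15 degrees)."""
    if 360 % n_bins != 0:
        raise ValueError("n_bins must divide 360")
    h = wrap_degrees(np.asarray(hues, dtype=float))
    h = h[~np.isnan(h)]
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(h, bins=edges)
    return HueHistogram(edges, counts.astype(float), int(h.size))


def smooth_circular(values, window: int = 9) -> np.ndarray:
    """Centre-aligned running mean with circular wrap-around."""
    v = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > v.size:
        raise ValueError("window larger than the series")
    k = window // 2
    out = np.zeros_like(v)
    for off in range(-k, k + 1):
        out += np.roll(v, -off)
    return out / window


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    ci_low: float
    ci_high: float
    p: float

    @property
    def n(self) -> int:
        return self.df + 2


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    ci_low: float
    ci_high: float
    p: float
    d: float
    mean: float
    alpha: float = 0.05


@dataclass(frozen=True)
class SignTestResult:
    n: int
    S: int
    p: float
    ties_dropped: int = 0


# ---------------------------------------------------------------------------
# correlations & tests


def pearson_fisher_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval and a two-tailed p
    from the t-distribution with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    df = n - 2
    zcrit = sps.norm.ppf(0.5 + conf / 2.0)
    if abs(r) >= 1.0:
        lo, hi = (r, 1.0) if r > 0 else (-1.0, r)
        p = 0.0
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r, df, float(lo), float(hi), float(p))


def one_sample_deviation_test(
    deviations, n_tests_for_alpha: int = 1, popmean: float = 0.0
) -> TTestResult:
    """One-sample t-test of signed hue deviations against zero, with
    Cohen's d = mean/sd = t/sqrt(n) and the Bonferroni-corrected
    significance level for the test family reported alongside."""
    x = np.asarray(deviations, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance sample")
    n = x.size
    mean = x.mean()
    se = sd / np.sqrt(n)
    t = (mean - popmean) / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(
        t=float(t),
        df=df,
        ci_low=float(mean - tcrit * se),
        ci_high=float(mean + tcrit * se),
        p=float(p),
        d=float(mean / sd),
        mean=float(mean),
        alpha=0.05 / n_tests_for_alpha,
    )


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("z-score undefined for constant input")
    return (v - v.mean()) / sd


def compare_models_paired_t(errors_a, errors_b) -> TTestResult:
    """Paired t-test on per-participant mean absolute errors (B - A):
    positive mean means model B is worse than model A."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired samples with n >= 2")
    return one_sample_deviation_test(b - a)


def compare_models_sign(errors_a, errors_b) -> SignTestResult:
    """Exact-binomial sign test across inducers: S = number of inducers
    where model B's error exceeds model A's; ties dropped."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size != b.size:
        raise ValueError("need paired samples")
    diff = b - a
    ties = int(np.sum(diff == 0))
    diff = diff[diff != 0]
    if diff.size == 0:
        raise DegenerateDataError("all pairs tied")
    S = int(np.sum(diff > 0))
    p = sps.binomtest(S, diff.size, 0.5).pvalue
    return SignTestResult(n=int(diff.size), S=S, p=float(p), ties_dropped=ties)


def smoothed_variance_explained(measured, simulated, window: int = 9) -> float:
    """Percentage variance explained by the correlation of the circularly
    smoothed measured series with the simulated series (sR^2)."""
    r = pearson_fisher_ci(smooth_circular(measured, window), simulated).r
    return float(100.0 * r * r)


def histogram_model_correlation(
    measured: HueHistogram,
    model_predictions,
    sigma_hue: float,
    seed: int,
    n_draws_per_inducer: int = 100_000,
) -> CorrelationResult:
    """Correlate a measured hue histogram with a Monte-Carlo histogram of
    a model's predictions under wrapped-Gaussian response noise."""
    from .models import add_response_noise

    samples = add_response_noise(
        model_predictions, sigma_hue, n_draws_per_inducer, seed
    ).ravel()
    sim = hue_histogram(samples, measured.n_bins).normalized()
    meas = measured.normalized()
    return pearson_fisher_ci(meas.counts, sim.counts)


# ---------------------------------------------------------------------------
# measurement aggregation & model errors


def aggregate_measurements(
    df: pd.DataFrame, within_participant_first: bool = True
) -> pd.DataFrame:
    """Per-inducer aggregate of non-skipped responses.

    Default pools repeated adjustments within participant by circular
    mean, then across participants by circular mean (chroma: arithmetic
    means); ``within_participant_first=False`` pools all trials directly.
    """
    d = df[~df["skipped"].astype(bool)].copy()
    keys = ["space", "inducer_hue_deg", "inducer_chroma"]

    def _agg(g):
        out = {"matched_hue": circular_mean_hue(g["response_hue_deg"])}
        if "response_chroma" in g and g["response_chroma"].notna().any():
            out["matched_chroma"] = g["response_chroma"].mean()
        else:
            out["matched_chroma"] = np.nan
        out["n"] = len(g)
        return pd.Series(out)

    if within_participant_first:
        per_pp = (
            d.groupby(keys + ["participant"]).apply(_agg, include_groups=False).reset_index()
        )
        agg = (
            per_pp.groupby(keys)
            .apply(
                lambda g: pd.Series(
                    {
                        "matched_hue": circular_mean_hue(g["matched_hue"]),
                        "matched_chroma": g["matched_chroma"].mean(),
                        "n": g["n"].sum(),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )
    else:
        agg = d.groupby(keys).apply(_agg, include_groups=False).reset_index()
    return agg


def model_prediction_errors(
    measurements: pd.DataFrame, predictions: pd.DataFrame
) -> pd.DataFrame:
    """Per-inducer, per-model absolute hue errors and z-scored chroma
    errors.

    ``measurements``: per-inducer aggregates (aggregate_measurements
    output).  ``predictions``: tidy frame from predict_all.  Models
    without a chroma prediction (hering) get NaN chroma errors.
    """
    rows = []
    for model, pred in predictions.groupby("model"):
        merged = measurements.merge(
            pred,
            on=["space", "inducer_hue_deg", "inducer_chroma"],
            how="inner",
            validate="one_to_one",
        )
        if len(merged) != len(measurements):
            raise ValueError(
                f"prediction set for {model!r} does not align with measurements"
            )
        hue_err = np.abs(
            circular_signed_difference(
                merged["matched_hue"].to_numpy(), merged["pred_hue_deg"].to_numpy()
            )
        )
        chroma_err = np.full(len(merged), np.nan)
        if (
            merged["pred_chroma"].notna().all()
            and merged["matched_chroma"].notna().all()
            and len(merged) > 2
        ):
            chroma_err = np.abs(
                zscore(merged["matched_chroma"]) - zscore(merged["pred_chroma"])
            )
        for i, (_, row) in enumerate(merged.iterrows()):
            rows.append(
                {
                    "model": model,
                    "space": row["space"],
                    "inducer_hue_deg": row["inducer_hue_deg"],
                    "inducer_chroma": row["inducer_chroma"],
                    "hue_abs_error": hue_err[i],
                    "chroma_abs_error": chroma_err[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chroma-series analysis


@dataclass(frozen=True)
class ChromaSeriesResult:
    """Per-record deviations and the two summary correlations of the
    chroma-series analysis."""

    table: pd.DataFrame
    corr_opponency: CorrelationResult
    corr_reference: CorrelationResult
    excluded_hues: tuple = ()


def chroma_series_analysis(
    measurements: pd.DataFrame, predictions: pd.DataFrame
) -> ChromaSeriesResult:
    """Hue changes across inducer chroma.

    For each inducer hue, the circular mean of its matched afterimage hues
    across chroma levels defines a reference line; measured and predicted
    hues are expressed (a) as deviations from opponency and (b) as
    deviations from their respective hue-specific reference.  Returns the
    per-record table and the measured-vs-predicted correlation for both
    framings.  Hues with a single chroma level are excluded.
    """
    agg = aggregate_measurements(measurements)
    merged = agg.merge(
        predictions,
        on=["space", "inducer_hue_deg", "inducer_chroma"],
        how="inner",
        validate="one_to_one",
    )
    excluded = []
    parts = []
    for hue, g in merged.groupby("inducer_hue_deg"):
        if g["inducer_chroma"].nunique() < 2:
            excluded.append(float(hue))
            continue
        g = g.copy()
        ref_meas = circular_mean_hue(g["matched_hue"])
        ref_pred = circular_mean_hue(g["pred_hue_deg"])
        g["meas_dev_opp"] = deviation_from_opponency(
            g["matched_hue"].to_numpy(), hue
        )
        g["pred_dev_opp"] = deviation_from_opponency(
            g["pred_hue_deg"].to_numpy(), hue
        )
        g["meas_dev_ref"] = circular_signed_difference(
            g["matched_hue"].to_numpy(), ref_meas
        )
        g["pred_dev_ref"] = circular_signed_difference(
            g["pred_hue_deg"].to_numpy(), ref_pred
        )
        parts.append(g)
    if not parts:
        raise DegenerateDataError("no inducer hue has >= 2 chroma levels")
    table = pd.concat(parts, ignore_index=True)

    def _corr(a, b):
        try:
            return pearson_fisher_ci(table[a], table[b])
        except DegenerateDataError:
            return None

    return ChromaSeriesResult(
        table=table,
        corr_opponency=_corr("meas_dev_opp", "pred_dev_opp"),
        corr_reference=_corr("meas_dev_ref", "pred_dev_ref"),
        excluded_hues=tuple(excluded),
    )
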
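"""Comparison criteria and the multi-method benchmark harness.

Three criteria quantify artifact removal:

* ``mse`` — mean squared difference between two signals.  On synthetic
  scenarios the benchmark computes it between the cleaned output and the
  ground-truth clean EEG, which only simulation can provide.
* ``correlation_criterion`` — Pearson correlation between a signal and
  the reference artifact channel, before vs after cleaning.  Successful
  cancellation collapses this correlation toward zero.  An unnormalized
  variant (raw inner product of the mean-removed signals) is exposed for
  users who want magnitude-style values; it is scale-dependent.
* ``power_spectrum_magnitude`` — Welch power spectral density, for
  inspecting which frequency bands the cleaning removed.

``compare_methods`` runs any subset of {anfis, rbfn, fln-rbfn, wavelet}
over a list of seeds and aggregates per-method medians, mirroring a
benchmark table of MSE / neuron count / correlation per filter type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .adaptive_filters import (
    GrowthParams,
    TrainConfig,
    cancel,
    fit_anfis,
    fit_fln_rbfn,
    fit_rbfn,
    predict,
)
from .signal_model import TimeSeries, build_regressors
from .synthetic_data import ContaminationScenario
from .wavelet_baseline import WaveletConfig, wavelet_remove

logger = logging.getLogger(__name__)

__all__ = [
    "mse",
    "correlation_criterion",
    "power_spectrum_magnitude",
    "EvaluationReport",
    "compare_methods",
    "run_method",
    "ADAPTIVE_METHODS",
]


def mse(y: TimeSeries | np.ndarray, q: TimeSeries | np.ndarray) -> float:
    """Mean squared error ``(1/N) sum (y(k) - q(k))^2``; symmetric, >= 0."""
    ya = y.samples if isinstance(y, TimeSeries) else np.asarray(y, dtype=np.float64)
    qa = q.samples if isinstance(q, TimeSeries) else np.asarray(q, dtype=np.float64)
    if ya.shape != qa.shape:
        raise ValueError("mse requires equal-length signals")
    return float(np.mean((ya - qa) ** 2))


def correlation_criterion(a: TimeSeries | np.ndarray, b: TimeSeries | np.ndarray,
                          normalized: bool = True) -> float:
    """Correlation between two signals.

    ``normalized=True`` gives the Pearson coefficient in [-1, 1] (raises
    on constant input, where it is undefined); ``normalized=False`` gives
    the raw inner product of the mean-removed signals, a scale-dependent
    magnitude.
    """
    xa = a.samples if isinstance(a, TimeSeries) else np.asarray(a, dtype=np.float64)
    xb = b.samples if isinstance(b, TimeSeries) else np.asarray(b, dtype=np.float64)
    if xa.shape != xb.shape:
        raise ValueError("correlation requires equal-length signals")
    da = xa - xa.mean()
    db = xb - xb.mean()
    if not normalized:
        return float(np.dot(da, db))
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        raise ValueError("Pearson correlation is undefined for a constant signal")
    return float(np.dot(da, db) / (na * nb))


def power_spectrum_magnitude(series: TimeSeries, segment_length: int = 256,
                             overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (frequencies in Hz, density units).

    Default 256-sample segments with 50% overlap; when the signal is
    shorter than one segment, falls back to a single-segment periodogram
    (logged).  Integrating the density over frequency recovers the
    signal's variance up to windowing effects.
    """
    x = series.samples
    if x.size < 8:
        raise ValueError("power spectrum needs at least 8 samples")
    if x.size < segment_length:
        logger.info("signal shorter than one Welch segment; using a single-segment periodogram")
        f, p = sps.periodogram(x, fs=series.sampling_rate_hz, detrend=False)
    else:
        f, p = sps.welch(x, fs=series.sampling_rate_hz, nperseg=segment_length,
                         noverlap=int(segment_length * overlap), detrend=False)
    return f, p


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class MethodResult:
    cleaned: TimeSeries
    estimate: TimeSeries
    n_neurons: int | None
    model: object | None = None


#: builders: method name -> callable(scenario, seed, config dict) -> MethodResult
def _run_adaptive(fit_fn, scenario: ContaminationScenario, seed: int, options: dict) -> MethodResult:
    cfg = TrainConfig(seed=seed, **options.get("train", {}))
    reg = build_regressors(scenario.reference_artifact, options.get("delay_d", cfg.delay_d))
    model = fit_fn(reg, scenario.contaminated, cfg, **options.get("fit", {}))
    est = predict(model, reg, sampling_rate_hz=scenario.contaminated.sampling_rate_hz)
    cleaned = cancel(scenario.contaminated, est)
    return MethodResult(cleaned, est, model.n_neurons, model)


def _run_wavelet(scenario: ContaminationScenario, seed: int, options: dict) -> MethodResult:
    config = options.get("wavelet_config") or WaveletConfig()
    cleaned, removed = wavelet_remove(scenario.contaminated, config)
    return MethodResult(cleaned, removed, None, None)


ADAPTIVE_METHODS = ("anfis", "rbfn", "fln-rbfn")
_METHOD_RUNNERS: dict[str, Callable] = {
    "anfis": lambda sc, seed, opt: _run_adaptive(fit_anfis, sc, seed, opt),
    "rbfn": lambda sc, seed, opt: _run_adaptive(fit_rbfn, sc, seed, opt),
    "fln-rbfn": lambda sc, seed, opt: _run_adaptive(fit_fln_rbfn, sc, seed, opt),
    "wavelet": _run_wavelet,
}


def run_method(method: str | Callable, scenario: ContaminationScenario, seed: int = 0,
               options: dict | None = None) -> MethodResult:
    """Run one cancellation method on one scenario.

    ``method`` is a registered name (anfis, rbfn, fln-rbfn, wavelet) or a
    callable ``(scenario, seed, options) -> MethodResult`` for custom or
    oracle methods.
    """
    options = options or {}
    if callable(method):
        return method(scenario, seed, options)
    try:
        runner = _METHOD_RUNNERS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_METHOD_RUNNERS)}"
        ) from None
    return runner(scenario, seed, options)


@dataclass
class EvaluationReport:
    """Per-(method, seed) records plus per-method median aggregates.

    Record columns: method, seed, n_neurons, mse, corr_before,
    corr_after.  MSE is cleaned-vs-ground-truth-clean when the scenario
    carries ground truth.
    """

    records: list[dict] = field(default_factory=list)
    scenario_description: str = ""
    seeds: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["method", "seed", "n_neurons", "mse", "corr_before", "corr_after"]
        return pd.DataFrame(self.records, columns=cols)

    def aggregate(self) -> pd.DataFrame:
        """Median mse/correlations per method (median neuron count too)."""
        df = self.to_frame()
        return df.groupby("method", sort=False).agg(
            # methods without neurons (wavelet) aggregate to NaN quietly
            n_neurons=("n_neurons", lambda s: s.dropna().median() if s.notna().any()
                       else float("nan")),
            mse=("mse", "median"),
            corr_before=("corr_before", "median"),
            corr_after=("corr_after", "median"),
            n_runs=("seed", "size"),
        ).reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "scenario": self.scenario_description,
            "seeds": list(self.seeds),
            "records": self.records,
            "aggregate": self.aggregate().to_dict(orient="records"),
        }
        if path is None:
            return json.dumps(payload, indent=2, sort_keys=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return None


def compare_methods(scenario: ContaminationScenario | Callable[[int], ContaminationScenario],
                    methods: Sequence[str | Callable], seeds: Sequence[int],
                    options: dict | None = None) -> EvaluationReport:
    """Benchmark several methods across seeds.

    ``scenario`` is either a fixed :class:`ContaminationScenario` (seeds
    then only vary training randomness) or a callable ``seed ->
    scenario`` so every seed draws a fresh recording.  For each
    method x seed the harness trains on (regressors, contaminated),
    cleans, and records MSE against the ground-truth clean EEG together
    with the reference correlation before and after cleaning.
    """
    if not methods:
        raise ValueError("need at least one method")
    if not seeds:
        raise ValueError("need at least one seed")
    options = options or {}
    report = EvaluationReport(seeds=list(seeds))
    for seed in seeds:
        sc = scenario(seed) if callable(scenario) else scenario
        if not report.scenario_description:
            report.scenario_description = sc.description
        corr_before = correlation_criterion(sc.contaminated, sc.reference_artifact)
        for method in methods:
            res = run_method(method, sc, seed=seed, options=options.get(
                method if isinstance(method, str) else "custom", {}))
            name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
            report.records.append({
                "method": name,
                "seed": int(seed),
                "n_neurons": res.n_neurons,
                "mse": mse(res.cleaned, sc.clean_eeg),
                "corr_before": corr_before,
                "corr_after": correlation_criterion(res.cleaned, sc.reference_artifact),
            })
    return report
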
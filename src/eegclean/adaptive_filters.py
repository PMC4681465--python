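"""Nonlinear adaptive filters for reference-based artifact cancellation.

The cancellation scheme is classic adaptive noise cancellation: train a
nonlinear regressor to map ``[r(k), r(k-d)]`` — the reference artifact
channel and its delayed copy — onto the contaminated EEG.  Because the
clean EEG is uncorrelated with the reference, the best the filter can do
is reproduce the artifact's contribution; its prediction is therefore
the artifact estimate, and subtracting it leaves the cleaned EEG.

Three filter families are implemented:

``ANFIS``
    A first-order Takagi-Sugeno fuzzy system on a grid partition of the
    two inputs (Gaussian membership functions), trained by hybrid
    learning: ridge least squares for the rule consequents, gradient
    descent with backtracking for the membership centers/widths.  The
    backtracking line search makes the per-epoch training MSE
    non-increasing by construction.

``RBFN``
    A Gaussian radial basis function network: centers by (seeded)
    k-means on the regressor rows, widths from the nearest-center
    distance heuristic, output weights by ridge least squares.

``FLN-RBFN``
    An RBFN in a trigonometric functional-link expansion of the inputs,
    grown sequentially by a resource-allocating novelty criterion: a new
    neuron is allocated only when the current sample is both poorly
    predicted and far from every existing center, otherwise the output
    weights take a normalized-LMS step.  The network therefore sizes
    itself from the data; a final ridge refit of the output layer
    polishes the weights on the allocated centers.

All filters standardize their inputs and target internally (so widths
and novelty thresholds are scale-free) and destandardize predictions
back to signal units.  All training is deterministic given (data,
config, seed), and models serialize to JSON round-trippable to
bit-identical predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_model import (
    RegressorMatrix,
    StandardizationParams,
    TimeSeries,
    apply_params,
    invert_params,
    standardize_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "GrowthParams",
    "ANFISModel",
    "RBFNModel",
    "FLNRBFNModel",
    "functional_expand",
    "fit_anfis",
    "fit_rbfn",
    "fit_fln_rbfn",
    "predict",
    "cancel",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
]


@dataclass(frozen=True)
class TrainConfig:
    """Shared training hyperparameters.

    ``learning_rate`` scales the premise gradient step (ANFIS) or the
    normalized-LMS step (FLN-RBFN); ``epochs`` counts hybrid-learning
    epochs (ANFIS) or sequential passes (FLN-RBFN); ``ridge_lambda``
    regularizes every least-squares solve so degenerate inputs stay
    well-posed; ``delay_d`` is recorded for provenance.
    """

    learning_rate: float = 0.05
    epochs: int = 20
    seed: int = 0
    ridge_lambda: float = 1e-6
    delay_d: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be positive")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be non-negative")


@dataclass(frozen=True)
class GrowthParams:
    """Resource-allocating growth rule for the FLN-RBFN.

    A neuron is allocated at sample ``k`` when the prediction error
    exceeds ``novelty_error`` AND the distance from the expanded input
    to the nearest existing center exceeds ``novelty_distance`` (both in
    standardized units).  ``overlap`` sets the new width as a fraction
    of that distance, floored at ``width_floor``.
    """

    novelty_distance: float = 0.7
    novelty_error: float = 0.05
    max_neurons: int = 50
    overlap: float = 0.8
    width_floor: float = 0.05

    def __post_init__(self) -> None:
        if not (self.novelty_distance > 0 and self.novelty_error > 0):
            raise ValueError("novelty thresholds must be positive")
        if self.max_neurons < 1:
            raise ValueError("max_neurons must be >= 1")


@dataclass
class _ModelBase:
    input_params: list[StandardizationParams]
    target_params: StandardizationParams
    # Fitted values on the training inputs from the final epoch, in signal
    # units; cached so prediction consistency is testable. Not serialized.
    training_prediction: np.ndarray | None = field(default=None, repr=False, compare=False)
    mse_history: list[float] = field(default_factory=list, repr=False, compare=False)


@dataclass
class ANFISModel(_ModelBase):
    """Trained first-order Takagi-Sugeno model (grid partition)."""

    n_mfs_per_input: int = 3
    # (n_inputs, n_mfs) Gaussian premise parameters.
    mf_centers: np.ndarray = None
    mf_widths: np.ndarray = None
    # (n_rules, n_inputs + 1) consequent coefficients [p, q, bias] per rule.
    consequents: np.ndarray = None

    @property
    def n_rules(self) -> int:
        return self.n_mfs_per_input ** self.mf_centers.shape[0]

    @property
    def n_neurons(self) -> int:
        """Rule count — the model-size figure reported in benchmarks."""
        return self.n_rules


@dataclass
class RBFNModel(_ModelBase):
    """Trained Gaussian RBF network."""

    centers: np.ndarray = None   # (n_neurons, n_inputs)
    widths: np.ndarray = None    # (n_neurons,)
    weights: np.ndarray = None   # (n_neurons,)
    bias: float = 0.0

    @property
    def n_neurons(self) -> int:
        return int(self.centers.shape[0])


@dataclass
class FLNRBFNModel(_ModelBase):
    """Self-growing RBF network in functional-link expanded space."""

    expansion_order: int = 1
    centers: np.ndarray = None   # (n_neurons, expanded_dim)
    widths: np.ndarray = None
    weights: np.ndarray = None
    bias: float = 0.0
    growth_params: GrowthParams = field(default_factory=GrowthParams)
    neuron_history: list[int] = field(default_factory=list, repr=False, compare=False)

    @property
    def n_neurons(self) -> int:
        return 0 if self.centers is None else int(self.centers.shape[0])


# ---------------------------------------------------------------------------
# shared numerics


def _ridge_lstsq(Phi: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve min ||Phi theta - y||^2 + lam ||theta||^2 (normal equations)."""
    n, p = Phi.shape
    if lam == 0.0 and n < p:
        raise ValueError(
            f"underdetermined system ({n} samples < {p} parameters) with ridge_lambda=0"
        )
    A = Phi.T @ Phi + lam * np.eye(p)
    b = Phi.T @ y
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _gaussian_activations(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """exp(-||x - c||^2 / (2 sigma^2)); equals 1 at the center for any width."""
    d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    return np.exp(-0.5 * d2 / widths[None, :] ** 2)


# ---------------------------------------------------------------------------
# ANFIS


def _anfis_design(X: np.ndarray, mf_centers: np.ndarray, mf_widths: np.ndarray) -> np.ndarray:
    """Normalized rule firing strengths -> TS design matrix.

    Grid partition: rule (i, j) pairs MF i of input 1 with MF j of input 2;
    firing strength is the product t-norm of the Gaussian memberships.
    Returns (N, n_rules * (n_inputs + 1)) with columns
    [w_r * x1, w_r * x2, w_r] grouped per rule.
    """
    n, n_in = X.shape
    mu = np.exp(-0.5 * ((X[:, :, None] - mf_centers[None, :, :]) / mf_widths[None, :, :]) ** 2)
    # product over inputs on the MF grid
    w = mu[:, 0, :, None] * mu[:, 1, None, :]            # (N, m, m)
    w = w.reshape(n, -1)                                  # (N, R)
    w_norm = w / (np.sum(w, axis=1, keepdims=True) + 1e-300)
    cols = [w_norm * X[:, [i]] for i in range(n_in)] + [w_norm]
    # interleave per rule: [w_r x1, w_r x2, w_r]
    R = w.shape[1]
    Phi = np.empty((n, R * (n_in + 1)))
    for r in range(R):
        for i in range(n_in):
            Phi[:, r * (n_in + 1) + i] = cols[i][:, r]
        Phi[:, r * (n_in + 1) + n_in] = cols[n_in][:, r]
    return Phi


def _anfis_loss(X, y, mf_centers, mf_widths, lam):
    """Optimal-consequent training MSE for given premise parameters."""
    Phi = _anfis_design(X, mf_centers, mf_widths)
    theta = _ridge_lstsq(Phi, y, lam)
    resid = Phi @ theta - y
    return float(np.mean(resid**2)), theta, Phi


def fit_anfis(regressors: RegressorMatrix, target: TimeSeries, config: TrainConfig,
              n_mfs_per_input: int = 3) -> ANFISModel:
    """Fit the Takagi-Sugeno model by hybrid learning.

    Premise Gaussians start on an even grid over each input's range and
    are tuned by gradient descent on the optimal-consequent loss
    (gradient by central differences); consequents are re-solved by ridge
    least squares after every premise update.  A backtracking step —
    halve the step and retry, revert if no improvement — keeps the
    training MSE non-increasing across epochs.
    """
    if n_mfs_per_input < 2:
        raise ValueError("n_mfs_per_input must be >= 2")
    if len(regressors) != len(target):
        raise ValueError("regressor row count must equal target length")

    X_raw = regressors.rows
    input_params = []
    X = np.empty_like(X_raw)
    for i in range(X_raw.shape[1]):
        X[:, i], p = standardize_array(X_raw[:, i])
        input_params.append(p)
    y, target_params = standardize_array(target.samples)

    m = n_mfs_per_input
    n_in = X.shape[1]
    mf_centers = np.empty((n_in, m))
    mf_widths = np.empty((n_in, m))
    for i in range(n_in):
        lo, hi = X[:, i].min(), X[:, i].max()
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        mf_centers[i] = np.linspace(lo, hi, m)
        mf_widths[i] = np.full(m, (hi - lo) / (2.0 * (m - 1)))

    lam = config.ridge_lambda
    mse, theta, _ = _anfis_loss(X, y, mf_centers, mf_widths, lam)
    history = [mse]
    lr = config.learning_rate
    h = 1e-5

    for _ in range(config.epochs):
        # central-difference gradient of the optimal-consequent loss
        grad_c = np.zeros_like(mf_centers)
        grad_w = np.zeros_like(mf_widths)
        for arr, grad in ((mf_centers, grad_c), (mf_widths, grad_w)):
            it = np.nditer(arr, flags=["multi_index"])
            for _v in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp, _, _ = _anfis_loss(X, y, mf_centers, mf_widths, lam)
                arr[idx] = orig - h
                lm, _, _ = _anfis_loss(X, y, mf_centers, mf_widths, lam)
                arr[idx] = orig
                grad[idx] = (lp - lm) / (2.0 * h)
        gnorm = np.sqrt(np.sum(grad_c**2) + np.sum(grad_w**2))
        if gnorm == 0.0:
            history.append(mse)
            continue
        step = lr / gnorm
        improved = False
        for _try in range(8):  # backtracking line search
            cand_c = mf_centers - step * grad_c
            cand_w = np.maximum(np.abs(mf_widths - step * grad_w), 1e-3)
            cand_mse, cand_theta, _ = _anfis_loss(X, y, cand_c, cand_w, lam)
            if cand_mse <= mse:
                mf_centers, mf_widths, mse, theta = cand_c, cand_w, cand_mse, cand_theta
                improved = True
                break
            step *= 0.5
        if not improved:
            lr *= 0.5  # keep premises; shrink future steps
        history.append(mse)

    _, theta, Phi = _anfis_loss(X, y, mf_centers, mf_widths, lam)
    consequents = theta.reshape(-1, n_in + 1)
    model = ANFISModel(
        input_params=input_params,
        target_params=target_params,
        n_mfs_per_input=m,
        mf_centers=mf_centers,
        mf_widths=mf_widths,
        consequents=consequents,
        mse_history=history,
    )
    model.training_prediction = invert_params(Phi @ theta, target_params)
    return model


def _anfis_predict_std(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    Phi = _anfis_design(X, model.mf_centers, model.mf_widths)
    return Phi @ model.consequents.reshape(-1)


# ---------------------------------------------------------------------------
# RBFN


def fit_rbfn(regressors: RegressorMatrix, target: TimeSeries, config: TrainConfig,
             n_neurons: int = 9, width_overlap: float = 1.5) -> RBFNModel:
    """Fit a Gaussian RBF network.

    Centers come from k-means on the (standardized) regressor rows,
    seeded from ``config.seed``; each width is ``width_overlap`` times
    the distance to the nearest other center (floored at 1e-6); output
    weights and bias are solved by ridge least squares on the Gaussian
    activations.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if len(regressors) < n_neurons:
        raise ValueError("need at least as many samples as neurons")
    if len(regressors) != len(target):
        raise ValueError("regressor row count must equal target length")

    X_raw = regressors.rows
    input_params = []
    X = np.empty_like(X_raw)
    for i in range(X_raw.shape[1]):
        X[:, i], p = standardize_array(X_raw[:, i])
        input_params.append(p)
    y, target_params = standardize_array(target.samples)

    if n_neurons == 1:
        centers = np.mean(X, axis=0, keepdims=True)
        widths = np.array([1.0])
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_neurons, n_init=4, random_state=config.seed)
        with np.errstate(all="ignore"):
            km.fit(X)
        centers = km.cluster_centers_
        d = np.sqrt(np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=2))
        np.fill_diagonal(d, np.inf)
        widths = np.maximum(width_overlap * d.min(axis=1), 1e-6)
        # duplicate centers collapse the nearest-center distance to ~0;
        # fall back to the median width so activations stay informative
        finite = widths[widths > 1e-5]
        if finite.size:
            widths[widths <= 1e-5] = np.median(finite)
        else:
            widths[:] = 1.0

    Phi = _gaussian_activations(X, centers, widths)
    Phi1 = np.column_stack([Phi, np.ones(len(X))])
    theta = _ridge_lstsq(Phi1, y, config.ridge_lambda)
    fitted = Phi @ theta[:-1] + theta[-1]  # same expression as predict
    model = RBFNModel(
        input_params=input_params,
        target_params=target_params,
        centers=centers,
        widths=widths,
        weights=theta[:-1],
        bias=float(theta[-1]),
        mse_history=[float(np.mean((fitted - y) ** 2))],
    )
    model.training_prediction = invert_params(fitted, target_params)
    return model


def _rbfn_predict_std(model: RBFNModel, X: np.ndarray) -> np.ndarray:
    Phi = _gaussian_activations(X, model.centers, model.widths)
    return Phi @ model.weights + model.bias


# ---------------------------------------------------------------------------
# FLN-RBFN


def functional_expand(x: np.ndarray, order: int = 1) -> np.ndarray:
    """Trigonometric functional-link expansion.

    Per input value ``v`` (expected roughly in [-1, 1]) emit
    ``[v, sin(pi v), cos(pi v), sin(2 pi v), cos(2 pi v), ...]`` up to
    ``order`` harmonics, concatenated over inputs.  Output dimension is
    ``n_inputs * (1 + 2 * order)``.  Accepts a single vector or a matrix
    of row vectors.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    parts = []
    for i in range(X.shape[1]):
        v = X[:, i]
        parts.append(v)
        for j in range(1, order + 1):
            parts.append(np.sin(j * np.pi * v))
            parts.append(np.cos(j * np.pi * v))
    Z = np.column_stack(parts)
    return Z[0] if single else Z


def fit_fln_rbfn(regressors: RegressorMatrix, target: TimeSeries, config: TrainConfig,
                 growth: GrowthParams | None = None, expansion_order: int = 1,
                 refit: bool = True) -> FLNRBFNModel:
    """Grow and train the functional-link RBF network.

    Inputs are max-abs scaled to [-1, 1] (the trigonometric basis is
    periodic, so bounded inputs matter) and expanded; the target is
    z-scored.  Each sequential pass applies the resource-allocating rule
    per sample: allocate a neuron when the error and the distance to the
    nearest center are both novel, otherwise take a normalized-LMS step
    on weights and bias.  After the passes the output layer is refit by
    ridge least squares on the allocated centers, which leaves the
    architecture data-chosen but the weights batch-optimal.
    """
    if growth is None:
        growth = GrowthParams()
    if len(regressors) != len(target):
        raise ValueError("regressor row count must equal target length")

    X_raw = regressors.rows
    input_params = []
    X = np.empty_like(X_raw)
    for i in range(X_raw.shape[1]):
        X[:, i], p = standardize_array(X_raw[:, i], method="maxabs")
        input_params.append(p)
    y, target_params = standardize_array(target.samples)
    Z = functional_expand(X, expansion_order)

    centers: list[np.ndarray] = []
    widths: list[float] = []
    weights: list[float] = []
    bias = 0.0
    mu = min(config.learning_rate * 10.0, 1.0)  # NLMS step in (0, 2)
    eps = growth.novelty_distance
    neuron_history: list[int] = []
    warned_full = False

    for _pass in range(config.epochs):
        for k in range(Z.shape[0]):
            z = Z[k]
            if centers:
                C = np.asarray(centers)
                W = np.asarray(widths)
                d = np.sqrt(np.sum((C - z) ** 2, axis=1))
                phi = np.exp(-0.5 * (d / W) ** 2)
                pred = float(np.dot(weights, phi) + bias)
                delta = float(d.min())
            else:
                phi = np.zeros(0)
                pred = bias
                delta = np.inf
            e = y[k] - pred
            novel = abs(e) > growth.novelty_error and delta > eps
            if novel and len(centers) < growth.max_neurons:
                width = max(growth.overlap * min(delta, 10.0 * eps)
                            if np.isfinite(delta) else growth.overlap * eps,
                            growth.width_floor)
                centers.append(z.copy())
                widths.append(width)
                weights.append(e)
            else:
                if novel and not warned_full:
                    logger.warning(
                        "FLN-RBFN reached max_neurons=%d; continuing with LMS-only updates",
                        growth.max_neurons,
                    )
                    warned_full = True
                g = np.append(phi, 1.0)
                norm = float(np.dot(g, g)) + 1e-12
                step = mu * e / norm
                if phi.size:
                    w = np.asarray(weights) + step * phi
                    weights = list(w)
                bias += step
            neuron_history.append(len(centers))

    if centers:
        C = np.asarray(centers)
        W = np.asarray(widths)
        Phi = _gaussian_activations(Z, C, W)
        Phi1 = np.column_stack([Phi, np.ones(len(Z))])
        if refit:
            theta = _ridge_lstsq(Phi1, y, config.ridge_lambda)
        else:
            theta = np.append(np.asarray(weights), bias)
        w_final = theta[:-1]
        bias = float(theta[-1])
        fitted = Phi @ w_final + bias  # same expression as predict
    else:
        C = np.zeros((0, Z.shape[1]))
        W = np.zeros(0)
        w_final = np.zeros(0)
        fitted = np.full(len(Z), bias)

    model = FLNRBFNModel(
        input_params=input_params,
        target_params=target_params,
        expansion_order=expansion_order,
        centers=C,
        widths=W,
        weights=w_final,
        bias=bias,
        growth_params=growth,
        neuron_history=neuron_history,
        mse_history=[float(np.mean((fitted - y) ** 2))],
    )
    model.training_prediction = invert_params(fitted, target_params)
    return model


def _fln_predict_std(model: FLNRBFNModel, X: np.ndarray) -> np.ndarray:
    Z = functional_expand(X, model.expansion_order)
    if model.n_neurons == 0:
        return np.full(Z.shape[0], model.bias)
    Phi = _gaussian_activations(Z, model.centers, model.widths)
    return Phi @ model.weights + model.bias


# ---------------------------------------------------------------------------
# prediction / cancellation / serialization


def predict(model, regressors: RegressorMatrix, sampling_rate_hz: float | None = None) -> TimeSeries:
    """Artifact estimate for each regressor row, in signal units."""
    X_raw = regressors.rows
    if X_raw.shape[1] != len(model.input_params):
        raise ValueError("regressor dimension does not match the trained model")
    X = np.column_stack([
        apply_params(X_raw[:, i], model.input_params[i])
        for i in range(X_raw.shape[1])
    ])
    if isinstance(model, ANFISModel):
        z = _anfis_predict_std(model, X)
    elif isinstance(model, FLNRBFNModel):
        z = _fln_predict_std(model, X)
    elif isinstance(model, RBFNModel):
        z = _rbfn_predict_std(model, X)
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    est = invert_params(z, model.target_params)
    return TimeSeries(est, sampling_rate_hz or 1.0, label="artifact estimate")


def cancel(contaminated: TimeSeries, estimate: TimeSeries) -> TimeSeries:
    """Subtract the artifact estimate: cleaned(k) = contaminated(k) - estimate(k).

    Exact elementwise subtraction, so cleaned + estimate reproduces the
    contaminated signal bit-exactly.
    """
    if len(contaminated) != len(estimate):
        raise ValueError("contaminated and estimate must have equal lengths")
    return contaminated.with_samples(contaminated.samples - estimate.samples,
                                     label="cleaned EEG")


# --- JSON serialization ----------------------------------------------------

def _params_to_dict(p: StandardizationParams) -> dict:
    return {"mean": p.mean, "scale": p.scale, "method": p.method}


def model_to_dict(model) -> dict:
    common = {
        "input_params": [_params_to_dict(p) for p in model.input_params],
        "target_params": _params_to_dict(model.target_params),
    }
    if isinstance(model, ANFISModel):
        return {
            "type": "anfis", **common,
            "n_mfs_per_input": model.n_mfs_per_input,
            "mf_centers": model.mf_centers.tolist(),
            "mf_widths": model.mf_widths.tolist(),
            "consequents": model.consequents.tolist(),
        }
    if isinstance(model, FLNRBFNModel):
        g = model.growth_params
        return {
            "type": "fln-rbfn", **common,
            "expansion_order": model.expansion_order,
            "centers": model.centers.tolist(),
            "widths": model.widths.tolist(),
            "weights": model.weights.tolist(),
            "bias": model.bias,
            "growth_params": {
                "novelty_distance": g.novelty_distance,
                "novelty_error": g.novelty_error,
                "max_neurons": g.max_neurons,
                "overlap": g.overlap,
                "width_floor": g.width_floor,
            },
        }
    if isinstance(model, RBFNModel):
        return {
            "type": "rbfn", **common,
            "centers": model.centers.tolist(),
            "widths": model.widths.tolist(),
            "weights": model.weights.tolist(),
            "bias": model.bias,
        }
    raise TypeError(f"unknown model type {type(model).__name__}")


def model_from_dict(d: dict):
    input_params = [StandardizationParams(**p) for p in d["input_params"]]
    target_params = StandardizationParams(**d["target_params"])
    kind = d["type"]
    if kind == "anfis":
        return ANFISModel(
            input_params=input_params, target_params=target_params,
            n_mfs_per_input=d["n_mfs_per_input"],
            mf_centers=np.asarray(d["mf_centers"]),
            mf_widths=np.asarray(d["mf_widths"]),
            consequents=np.asarray(d["consequents"]),
        )
    if kind == "rbfn":
        return RBFNModel(
            input_params=input_params, target_params=target_params,
            centers=np.asarray(d["centers"]), widths=np.asarray(d["widths"]),
            weights=np.asarray(d["weights"]), bias=d["bias"],
        )
    if kind == "fln-rbfn":
        return FLNRBFNModel(
            input_params=input_params, target_params=target_params,
            expansion_order=d["expansion_order"],
            centers=np.asarray(d["centers"]).reshape(len(d["widths"]), -1)
            if d["widths"] else np.zeros((0, 1)),
            widths=np.asarray(d["widths"]),
            weights=np.asarray(d["weights"]), bias=d["bias"],
            growth_params=GrowthParams(**d["growth_params"]),
        )
    raise ValueError(f"unknown model type {kind!r}")


def save_model(model, path) -> None:
    """Write a model as JSON; loading reproduces predictions bit-identically
    (Python's JSON float encoding is exact round-trip)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
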
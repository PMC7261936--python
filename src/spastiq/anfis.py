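"""First-order Sugeno ANFIS with subtractive-clustering structure identification.

The network is the classic five-layer adaptive neuro-fuzzy inference
system: Gaussian premise memberships (layer 1), product firing strengths
(layer 2), normalisation (layer 3), linear (first-order) rule consequents
weighted by normalised strengths (layer 4), and summation (layer 5).  For
input x and rule i with premise centers c_i, widths d_i, consequent
coefficients p_i and bias r_i:

    mu_id(x_d) = exp(-0.5 ((x_d - c_id)/d_id)^2)
    w_i        = prod_d mu_id(x_d)
    wbar_i     = w_i / sum_j w_j
    y(x)       = sum_i wbar_i (p_i . x + r_i)

Structure identification uses subtractive clustering: every training point
is a candidate center with density

    D_i = sum_j exp(-||x_i - x_j||^2 / (r_a/2)^2)

computed on inputs min-max scaled to [0, 1] (the radius r_a is meaningful
only on a normalised space).  The densest point becomes a center, densities
are revised by subtracting a Gaussian bump of radius r_b = squash * r_a
around it (negative revised densities are clamped to 0), and selection
repeats under the standard accept/reject stopping rule.  One fuzzy rule is
created per center; premise widths follow the radius-to-sigma convention
sigma_d = r_a * range_d / sqrt(8).

Consequents are trained by global linear least squares (minimum-norm
solution when rank-deficient), which converges in a single pass; an
optional hybrid mode additionally takes monotone gradient steps on the
premise parameters between least-squares passes.  Everything in this module
is deterministic; all ties break toward the lowest index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, InputError


@dataclass
class GaussianMF:
    """Gaussian membership function exp(-0.5 ((x - c)/delta)^2)."""

    center: float
    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ConfigError(f"membership width must be positive, got {self.delta}")


def membership(mf: GaussianMF, x: float) -> float:
    """Membership grade of x under a Gaussian MF (1 at the center)."""
    z = (x - mf.center) / mf.delta
    return float(np.exp(-0.5 * z * z))


@dataclass
class FuzzyRule:
    """One Sugeno rule: a premise MF per input plus a linear consequent."""

    premise: list[GaussianMF]
    coefficients: np.ndarray  # p, one per input
    bias: float               # r

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.premise),):
            raise ConfigError("consequent length must equal the input dimension")


@dataclass(frozen=True)
class ClusteringConfig:
    """Subtractive-clustering parameters (radius on the [0, 1]-scaled space).

    ``reject_ratio`` is the stop threshold as a fraction of the first
    center's density.  Window clouds from stretch cohorts have one dominant,
    very compact background cluster (quiet muscle) that sets the reference
    density, while the informative severity clusters are an order of
    magnitude sparser; a cut at the textbook 0.15 then lands right on those
    clusters' density and yields near-degenerate one/two-rule structures
    whose quality degrades as windows accumulate.  0.05 accepts them with a
    stable margin while still rejecting noise centers (which sit well below
    0.03 on such data).
    """

    radius: float = 0.65
    squash: float = 1.5
    accept_ratio: float = 0.5
    reject_ratio: float = 0.05

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigError("radius must be positive")
        if not self.squash >= 1:
            raise ConfigError("squash factor must be >= 1")
        if not 0 < self.reject_ratio < self.accept_ratio <= 1:
            raise ConfigError("need 0 < reject_ratio < accept_ratio <= 1")


@dataclass
class AnfisModel:
    """A fitted (or zero-initialised) Sugeno fuzzy rule base."""

    rules: list[FuzzyRule]
    n_inputs: int
    clustering: ClusteringConfig = ClusteringConfig()
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rules) < 1:
            raise ConfigError("a model needs at least one rule")
        for rule in self.rules:
            if len(rule.premise) != self.n_inputs:
                raise ConfigError("all rules must share the model's input dimension")

    # -- parameter views ---------------------------------------------------

    @property
    def centers(self) -> np.ndarray:
        return np.array([[mf.center for mf in r.premise] for r in self.rules])

    @property
    def widths(self) -> np.ndarray:
        return np.array([[mf.delta for mf in r.premise] for r in self.rules])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "spastiq-anfis",
            "version": 1,
            "n_inputs": self.n_inputs,
            "clustering": {
                "radius": self.clustering.radius,
                "squash": self.clustering.squash,
                "accept_ratio": self.clustering.accept_ratio,
                "reject_ratio": self.clustering.reject_ratio,
            },
            "rules": [
                {
                    "centers": [mf.center for mf in r.premise],
                    "widths": [mf.delta for mf in r.premise],
                    "coefficients": r.coefficients.tolist(),
                    "bias": r.bias,
                }
                for r in self.rules
            ],
            "training_meta": self.training_meta,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "AnfisModel":
        if doc.get("format") != "spastiq-anfis":
            raise ConfigError("not a spastiq ANFIS document")
        rules = [
            FuzzyRule(
                premise=[GaussianMF(c, d) for c, d in zip(r["centers"], r["widths"])],
                coefficients=np.asarray(r["coefficients"], dtype=float),
                bias=float(r["bias"]),
            )
            for r in doc["rules"]
        ]
        return cls(
            rules=rules,
            n_inputs=int(doc["n_inputs"]),
            clustering=ClusteringConfig(**doc["clustering"]),
            training_meta=dict(doc.get("training_meta", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "AnfisModel":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# forward pass


def _as_batch(x: np.ndarray, n_inputs: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != n_inputs:
        raise InputError(f"expected inputs of dimension {n_inputs}, got shape {x.shape}")
    return x, single


def _log_strengths(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """(n, R) matrix of log firing strengths (finite for finite inputs)."""
    z = (X[:, None, :] - model.centers[None, :, :]) / model.widths[None, :, :]
    return -0.5 * np.sum(z * z, axis=2)


def firing_strengths(model: AnfisModel, x: np.ndarray) -> np.ndarray:
    """Layer-2 rule firing strengths w_i (product of premise memberships)."""
    X, single = _as_batch(x, model.n_inputs)
    w = np.exp(_log_strengths(model, X))
    return w[0] if single else w


def normalize(w: np.ndarray) -> np.ndarray:
    """Layer-3 normalisation: w_i / sum(w); sums to 1 exactly."""
    w = np.asarray(w, dtype=float)
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total <= 0.0):
        raise InputError("cannot normalise: firing strengths sum to zero")
    return w / total


def _normalized_strengths(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Numerically stable layer-3 output (log-sum-exp shifted)."""
    logw = _log_strengths(model, X)
    logw = logw - logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def predict(model: AnfisModel, x: np.ndarray) -> float | np.ndarray:
    """Layer-5 output: sum_i wbar_i (p_i . x + r_i) for one input or a batch."""
    X, single = _as_batch(x, model.n_inputs)
    wbar = _normalized_strengths(model, X)                       # (n, R)
    P = np.array([r.coefficients for r in model.rules])          # (R, m)
    b = np.array([r.bias for r in model.rules])                  # (R,)
    f = X @ P.T + b[None, :]                                     # (n, R)
    y = np.sum(wbar * f, axis=1)
    return float(y[0]) if single else y


# ---------------------------------------------------------------------------
# structure identification


def subtractive_cluster(X: np.ndarray, cfg: ClusteringConfig | None = None) -> np.ndarray:
    """Greedy density-based cluster-center selection (Chiu's method).

    Returns the selected centers as an ``(n_centers, m)`` array in the
    original coordinate space; densities are computed on a min-max [0, 1]
    scaling of the inputs.  Deterministic; ties go to the lowest index.
    """
    cfg = cfg or ClusteringConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n == 0:
        raise InputError("cannot cluster an empty matrix")

    lo = X.min(axis=0)
    span = np.ptp(X, axis=0)
    span[span == 0.0] = 1.0
    Z = (X - lo) / span

    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)
    alpha = 1.0 / (cfg.radius / 2.0) ** 2
    beta = 1.0 / (cfg.squash * cfg.radius / 2.0) ** 2
    D = np.exp(-alpha * d2).sum(axis=1)

    first = int(np.argmax(D))
    d_ref = float(D[first])
    centers = [first]

    # Selection continues until the best remaining revised density drops
    # below reject_ratio * D_c1; candidates at or above accept_ratio * D_c1
    # are always taken (they clear the stop threshold a fortiori).
    while True:
        last = centers[-1]
        D = D - D[last] * np.exp(-beta * d2[:, last])
        D[D < 0.0] = 0.0
        cand = int(np.argmax(D))
        d_cand = float(D[cand])
        if cand in centers or d_cand <= 0.0 or d_cand < cfg.reject_ratio * d_ref:
            break
        centers.append(cand)

    return X[np.array(centers, dtype=int)]


def init_structure(X: np.ndarray, cfg: ClusteringConfig | None = None) -> AnfisModel:
    """Build a zero-consequent rule base from subtractive clustering.

    One rule per center; the premise MF of rule i on input d is centred at
    the cluster center with width ``radius * range_d / sqrt(8)`` (a
    degenerate constant input falls back to unit range).
    """
    cfg = cfg or ClusteringConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    centers = subtractive_cluster(X, cfg)
    span = np.ptp(X, axis=0)
    span[span == 0.0] = 1.0
    deltas = cfg.radius * span / np.sqrt(8.0)
    m = X.shape[1]
    rules = [
        FuzzyRule(
            premise=[GaussianMF(float(c[d]), float(deltas[d])) for d in range(m)],
            coefficients=np.zeros(m),
            bias=0.0,
        )
        for c in centers
    ]
    return AnfisModel(rules=rules, n_inputs=m, clustering=cfg)


# ---------------------------------------------------------------------------
# training


def _design_matrix(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    wbar = _normalized_strengths(model, X)                       # (n, R)
    blocks = [
        np.hstack([wbar[:, i : i + 1] * X, wbar[:, i : i + 1]]) for i in range(len(model.rules))
    ]
    return np.hstack(blocks)                                     # (n, R*(m+1))


def _set_consequents(model: AnfisModel, theta: np.ndarray) -> None:
    m = model.n_inputs
    for i, rule in enumerate(model.rules):
        chunk = theta[i * (m + 1) : (i + 1) * (m + 1)]
        rule.coefficients = chunk[:m].copy()
        rule.bias = float(chunk[m])


def _lse_pass(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> float:
    phi = _design_matrix(model, X)
    theta, *_ = np.linalg.lstsq(phi, y, rcond=None)
    _set_consequents(model, theta)
    resid = phi @ theta - y
    return float(np.sqrt(np.mean(resid**2)))


def train_consequents(
    model: AnfisModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 20,
    mode: str = "lse",
    learning_rate: float = 0.01,
) -> AnfisModel:
    """Fit the linear consequents by global least squares (in place).

    ``mode="lse"`` (default) holds premises fixed; the least-squares
    solution is exact in one pass, so the epoch count is irrelevant.
    ``mode="hybrid"`` interleaves gradient steps on the premise centers and
    widths with a fresh least-squares pass each epoch, backtracking the step
    size so the training residual never increases.
    """
    X, _ = _as_batch(np.asarray(X, dtype=float), model.n_inputs)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise InputError("X and y must have the same number of rows")
    n_params = len(model.rules) * (model.n_inputs + 1)
    if X.shape[0] < n_params:
        warnings.warn(
            f"{X.shape[0]} rows for {n_params} consequent parameters: "
            "minimum-norm (rank-deficient) solution"
        )
    if mode not in ("lse", "hybrid"):
        raise ConfigError(f"unknown training mode {mode!r}")

    rmse = _lse_pass(model, X, y)
    history = [rmse]
    if mode == "hybrid":
        for _ in range(max(epochs - 1, 0)):
            improved = _premise_step(model, X, y, rmse, learning_rate)
            rmse = _lse_pass(model, X, y)
            history.append(min(rmse, history[-1]) if not improved else rmse)
            rmse = history[-1]
    model.training_meta = {"mode": mode, "epochs": len(history), "rmse": history[-1],
                           "history": history}
    return model


def _premise_step(
    model: AnfisModel, X: np.ndarray, y: np.ndarray, current_rmse: float, lr: float
) -> bool:
    """One backtracked gradient step on {centers, widths}; returns True if it improved."""
    centers = model.centers
    widths = model.widths
    eps = 1e-6

    def rmse_with(c: np.ndarray, d: np.ndarray) -> float:
        saved = [(mf.center, mf.delta) for r in model.rules for mf in r.premise]
        for i, rule in enumerate(model.rules):
            for j, mf in enumerate(rule.premise):
                mf.center, mf.delta = float(c[i, j]), float(max(d[i, j], eps))
        pred = predict(model, X)
        out = float(np.sqrt(np.mean((pred - y) ** 2)))
        it = iter(saved)
        for rule in model.rules:
            for mf in rule.premise:
                mf.center, mf.delta = next(it)
        return out

    # numerical gradient (premise count is tiny: R x m x 2 parameters)
    grad_c = np.zeros_like(centers)
    grad_d = np.zeros_like(widths)
    h = 1e-5
    base = rmse_with(centers, widths)
    for i in range(centers.shape[0]):
        for j in range(centers.shape[1]):
            dc = centers.copy()
            dc[i, j] += h
            grad_c[i, j] = (rmse_with(dc, widths) - base) / h
            dd = widths.copy()
            dd[i, j] += h
            grad_d[i, j] = (rmse_with(centers, dd) - base) / h

    step = lr
    for _ in range(12):
        c_new = centers - step * grad_c
        d_new = np.maximum(widths - step * grad_d, eps)
        if rmse_with(c_new, d_new) < base:
            for i, rule in enumerate(model.rules):
                for j, mf in enumerate(rule.premise):
                    mf.center, mf.delta = float(c_new[i, j]), float(d_new[i, j])
            return True
        step /= 2.0
    return False
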
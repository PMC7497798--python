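"""One-hidden-layer feed-forward network trained by regularized LM.

The classifier mirrors the shallow architecture used for FLIM pixel-block
labeling: ``n_inputs`` (7 lifetime parameters or 256 decay bins) -> 10 tanh
hidden units -> one logistic output in [0, 1].  Training minimizes mean
squared error against {0,1} labels with full-batch Levenberg–Marquardt
steps, with an L2 weight penalty whose strength is re-estimated each
accepted step by MacKay's evidence approximation (Bayesian regularization):

    F = beta * sum(e^2) + alpha * sum(w^2)
    gamma = P - 2 alpha tr(H^-1),  alpha = gamma / (2 E_W),
    beta = (N - gamma) / (2 E_D)

where ``P`` counts regularized parameters and ``H`` is the Gauss–Newton
Hessian of ``F``.  Biases are excluded from the penalty so constant targets
can be fit exactly.  A fixed-penalty mode (``lam``) is available for
reproducibility studies, and very large tables are subsampled once (seeded)
before training since LM normal equations scale with rows x params.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from .labelprep import FeatureTable, NormStats, SplitAssignment, TRAIN, VAL, TEST

__all__ = [
    "NetworkSpec",
    "TrainOptions",
    "TrainReport",
    "init_network",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_MODEL_VERSION = 1


@dataclasses.dataclass
class NetworkSpec:
    """Weights of the 1-hidden-layer network plus its normalization stats."""

    W1: np.ndarray          # (n_hidden, n_inputs)
    b1: np.ndarray          # (n_hidden,)
    w2: np.ndarray          # (n_hidden,)
    b2: float
    norm_stats: NormStats | None = None

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = float(self.b2)
        if self.W1.ndim != 2 or self.b1.shape != (self.W1.shape[0],) \
                or self.w2.shape != (self.W1.shape[0],):
            raise ValueError("inconsistent weight shapes")
        for arr in (self.W1, self.b1, self.w2, (self.b2,)):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1


@dataclasses.dataclass
class TrainOptions:
    """Knobs for LM training; ``lam=None`` enables Bayesian regularization."""

    max_iter: int = 120
    tol: float = 1e-7
    lam: float | None = None
    mu0: float = 5e-3
    max_rows: int = 50_000
    seed: int = 0


@dataclasses.dataclass
class TrainReport:
    train_mse: float
    val_mse: float
    test_mse: float
    effective_lambda: float
    iterations: int
    seed: int
    converged: bool = True

    def __post_init__(self):
        for name in ("train_mse", "val_mse", "test_mse"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def init_network(n_inputs: int, n_hidden: int = 10, seed: int = 0) -> NetworkSpec:
    """Small scaled-uniform random weights, deterministic under seed."""
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError("n_inputs and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    r1 = 1.0 / np.sqrt(n_inputs)
    r2 = 1.0 / np.sqrt(n_hidden)
    return NetworkSpec(
        W1=rng.uniform(-r1, r1, (n_hidden, n_inputs)),
        b1=rng.uniform(-r1, r1, n_hidden),
        w2=rng.uniform(-r2, r2, n_hidden),
        b2=float(rng.uniform(-r2, r2)),
    )


def _forward(net: NetworkSpec, X: np.ndarray):
    h = np.tanh(X @ net.W1.T + net.b1)
    out = _sigmoid(h @ net.w2 + net.b2)
    return out, h


def predict(net: NetworkSpec, features: np.ndarray, apply_stats: bool = True) -> np.ndarray:
    """Network scores in [0, 1] for raw feature rows.

    When the network carries normalization statistics they are applied to
    the input first (pass ``apply_stats=False`` for pre-normalized rows).
    A pure function of the inputs and weights.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise ValueError(f"expected {net.n_inputs} features, got {X.shape[1]}")
    if apply_stats and net.norm_stats is not None:
        X = net.norm_stats.apply(X)
    out, _ = _forward(net, X)
    return out


# ---------------------------------------------------------------------------
# parameter packing and Jacobian
# ---------------------------------------------------------------------------


def _pack(net: NetworkSpec) -> np.ndarray:
    return np.concatenate([net.W1.ravel(), net.b1, net.w2, [net.b2]])


def _unpack(theta: np.ndarray, n_inputs: int, n_hidden: int,
            stats: NormStats | None) -> NetworkSpec:
    k = n_hidden * n_inputs
    return NetworkSpec(
        W1=theta[:k].reshape(n_hidden, n_inputs),
        b1=theta[k:k + n_hidden],
        w2=theta[k + n_hidden:k + 2 * n_hidden],
        b2=float(theta[-1]),
        norm_stats=stats,
    )


def _reg_mask(n_inputs: int, n_hidden: int) -> np.ndarray:
    """1 for weights, 0 for biases (biases escape the L2 penalty)."""
    k = n_hidden * n_inputs
    mask = np.ones(k + 2 * n_hidden + 1)
    mask[k:k + n_hidden] = 0.0
    mask[-1] = 0.0
    return mask


def _jtj_jte(net: NetworkSpec, X: np.ndarray, e: np.ndarray,
             chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate J^T J and J^T e without materializing the full Jacobian.

    J is d(out)/d(theta); for large input dimensions (DBM: 2581 params)
    the (n, p) Jacobian is built chunk-wise.
    """
    p = net.n_params
    d, nh = net.n_inputs, net.n_hidden
    JtJ = np.zeros((p, p))
    Jte = np.zeros(p)
    for lo in range(0, X.shape[0], chunk):
        Xc = X[lo:lo + chunk]
        ec = e[lo:lo + chunk]
        out, h = _forward(net, Xc)
        s = out * (1.0 - out)                      # d out / d z2
        dh = (1.0 - h * h) * net.w2                # (n, nh): d z2 / d z1
        n = Xc.shape[0]
        J = np.empty((n, p))
        J[:, :d * nh] = np.einsum("ni,nj->nij", s[:, None] * dh, Xc).reshape(n, -1)
        J[:, d * nh:d * nh + nh] = s[:, None] * dh
        J[:, d * nh + nh:d * nh + 2 * nh] = s[:, None] * h
        J[:, -1] = s
        JtJ += J.T @ J
        Jte += J.T @ ec
    return JtJ, Jte


def train(net: NetworkSpec, table: FeatureTable, split: SplitAssignment,
          options: TrainOptions | None = None) -> tuple[NetworkSpec, TrainReport]:
    """Levenberg–Marquardt training with Bayesian (or fixed) regularization.

    Expects a normalized table (``table.stats`` present); the statistics are
    stored on the returned network so prediction on raw features reuses
    them.  The report carries the MSE on each partition — the test-partition
    value is the held-out "performance index".
    """
    options = options or TrainOptions()
    if table.stats is None:
        raise ValueError("table must be normalized before training "
                         "(see labelprep.normalize_features)")
    if table.n_features != net.n_inputs:
        raise ValueError(f"network expects {net.n_inputs} inputs, "
                         f"table has {table.n_features}")
    X_all = table.features
    y_all = table.labels.astype(float)
    tr = split.mask(TRAIN)
    te = split.mask(TEST)
    if not tr.any() or not te.any():
        raise ValueError("train and test partitions must be non-empty")
    X, y = X_all[tr], y_all[tr]
    if X.shape[0] > options.max_rows:
        rng = np.random.default_rng(options.seed)
        pick = rng.choice(X.shape[0], options.max_rows, replace=False)
        X, y = X[pick], y[pick]

    n, p = X.shape[0], net.n_params
    mask = _reg_mask(net.n_inputs, net.n_hidden)
    n_reg = int(mask.sum())
    theta = _pack(net)
    stats = table.stats

    bayesian = options.lam is None
    alpha = 1e-2 if bayesian else float(options.lam)
    beta = 1.0

    def objective(th):
        nt = _unpack(th, net.n_inputs, net.n_hidden, stats)
        out, _ = _forward(nt, X)
        e = y - out
        ed = float(e @ e)
        ew = float((th * mask) @ (th * mask))
        return beta * ed + alpha * ew, e, ed, ew, nt

    F, e, ed, ew, cur = objective(theta)
    if not np.isfinite(F):
        raise FloatingPointError("non-finite loss at initialization")
    mu = options.mu0
    iterations = 0
    converged = False
    eye = np.eye(p)

    for iterations in range(1, options.max_iter + 1):
        JtJ, Jte = _jtj_jte(cur, X, e)
        grad = -2.0 * beta * Jte + 2.0 * alpha * mask * theta
        H = 2.0 * beta * JtJ + 2.0 * alpha * np.diag(mask)
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(H + mu * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            F_try, e_try, ed_try, ew_try, net_try = objective(theta + step)
            if np.isfinite(F_try) and F_try <= F:
                rel = (F - F_try) / max(F, 1e-300)
                theta = theta + step
                F, e, ed, ew, cur = F_try, e_try, ed_try, ew_try, net_try
                mu = max(mu / 3.0, 1e-12)
                accepted = True
                if rel < options.tol:
                    converged = True
                break
            mu *= 4.0
            if mu > 1e10:
                break
        if not accepted:
            converged = ed / n < 1e-12 or F == 0.0
            break
        if bayesian:
            # evidence update; guards keep alpha/beta positive and sane
            try:
                Hinv_diag = np.diag(np.linalg.inv(H))
            except np.linalg.LinAlgError:
                Hinv_diag = 1.0 / np.maximum(np.diag(H), 1e-12)
            gamma = n_reg - 2.0 * alpha * float(Hinv_diag @ mask)
            gamma = float(np.clip(gamma, 1e-3, min(n_reg, 0.99 * n)))
            alpha = gamma / max(2.0 * ew, 1e-10)
            beta = max(n - gamma, 1e-3) / max(2.0 * ed, 1e-10)
            F = beta * ed + alpha * ew
        if converged:
            break
        if np.isnan(F):
            raise FloatingPointError("loss became NaN during training")

    trained = _unpack(theta, net.n_inputs, net.n_hidden, stats)

    def mse(part):
        m = split.mask(part)
        if not m.any():
            return float("nan")
        out, _ = _forward(trained, X_all[m])
        return float(np.mean((y_all[m] - out) ** 2))

    report = TrainReport(
        train_mse=mse(TRAIN), val_mse=mse(VAL), test_mse=mse(TEST),
        effective_lambda=float(alpha / beta), iterations=iterations,
        seed=options.seed, converged=converged,
    )
    return trained, report


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(net: NetworkSpec, path) -> None:
    """JSON round-trip at full float precision, including norm stats."""
    obj = {
        "format_version": _MODEL_VERSION,
        "W1": net.W1.tolist(), "b1": net.b1.tolist(),
        "w2": net.w2.tolist(), "b2": net.b2,
        "norm_stats": net.norm_stats.to_json() if net.norm_stats else None,
    }
    pathlib.Path(path).write_text(json.dumps(obj))


def load_model(path) -> NetworkSpec:
    try:
        obj = json.loads(pathlib.Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    version = obj.get("format_version")
    if version != _MODEL_VERSION:
        raise ValueError(
            f"model format version {version!r} unsupported; this build reads "
            f"version {_MODEL_VERSION}")
    stats = NormStats.from_json(obj["norm_stats"]) if obj.get("norm_stats") else None
    return NetworkSpec(W1=np.array(obj["W1"]), b1=np.array(obj["b1"]),
                       w2=np.array(obj["w2"]), b2=obj["b2"], norm_stats=stats)
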
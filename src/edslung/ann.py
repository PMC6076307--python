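"""Single-hidden-layer feedforward classifier trained with Levenberg–Marquardt.

Architecture: S = 5 inputs (VC, FEV1, FVC, Tiffeneau index, pre-classifier
disease probability, all min-max normalized), N tanh hidden neurons and a
linear output layer.  The default output encoding is a single linear neuron
whose value indexes the ten diagnostic classes

    ASTHMA1..ASTHMA4, GOLD1..GOLD4, NORMAL, INCONCLUSIVE  ->  0..9;

predictions round the scalar output to the nearest integer and clamp to
[0, 9].  An optional one-hot/argmax encoding (10 linear outputs) is
available since index regression imposes an artificial class ordering.

Training minimizes the mean squared error between network outputs and the
encoded targets with a damped Gauss–Newton (Levenberg–Marquardt) loop using
the analytic Jacobian of the per-sample residuals.  Model selection uses
k-fold cross-validation and a hidden-size search with a parsimony margin:
among candidate widths whose mean test MSE lies within the margin of the
best, the narrowest architecture wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataValidationError, DivergenceError

CLASS_NAMES = (
    "ASTHMA1",
    "ASTHMA2",
    "ASTHMA3",
    "ASTHMA4",
    "GOLD1",
    "GOLD2",
    "GOLD3",
    "GOLD4",
    "NORMAL",
    "INCONCLUSIVE",
)


@dataclass(frozen=True)
class ClassCodebook:
    """Bijective, order-stable mapping between class names and codes 0..K-1."""

    names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("class names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def code(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DataValidationError(f"unknown class name {name!r}") from None

    def name(self, code: int) -> str:
        if not 0 <= code < len(self.names):
            raise DataValidationError(f"class code {code} out of range")
        return self.names[code]


DEFAULT_CODEBOOK = ClassCodebook()


@dataclass
class NetworkWeights:
    """Iw (S×N input weights), Hb (N hidden biases), Hw (N×R output weights), Ob (R biases)."""

    Iw: np.ndarray
    Hb: np.ndarray
    Hw: np.ndarray
    Ob: np.ndarray

    def __post_init__(self) -> None:
        self.Iw = np.asarray(self.Iw, dtype=float)
        self.Hb = np.asarray(self.Hb, dtype=float)
        self.Hw = np.asarray(self.Hw, dtype=float)
        self.Ob = np.asarray(self.Ob, dtype=float)
        S, N = self.Iw.shape if self.Iw.ndim == 2 else (None, None)
        if S is None or self.Hb.shape != (N,) or self.Hw.shape[0] != N or self.Hw.ndim != 2:
            raise ConfigurationError("inconsistent weight shapes")
        R = self.Hw.shape[1]
        if self.Ob.shape != (R,):
            raise ConfigurationError("inconsistent output-bias shape")
        for arr in (self.Iw, self.Hb, self.Hw, self.Ob):
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError("weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.Iw.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.Iw.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Hw.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.Iw.size + self.Hb.size + self.Hw.size + self.Ob.size

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.Iw.ravel(), self.Hb.ravel(), self.Hw.ravel(), self.Ob.ravel()]
        )

    @classmethod
    def from_flat(cls, theta: np.ndarray, S: int, N: int, R: int) -> "NetworkWeights":
        theta = np.asarray(theta, dtype=float)
        sizes = (S * N, N, N * R, R)
        if theta.size != sum(sizes):
            raise ConfigurationError("flattened parameter vector has wrong length")
        i0, i1, i2 = np.cumsum(sizes[:-1])
        return cls(
            Iw=theta[:i0].reshape(S, N),
            Hb=theta[i0:i1].copy(),
            Hw=theta[i1:i2].reshape(N, R),
            Ob=theta[i2:].copy(),
        )


@dataclass(frozen=True)
class ForwardTrace:
    hidden: np.ndarray  # tanh activations, each in (-1, 1)
    outputs: np.ndarray


def forward_batch(w: NetworkWeights, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations (n, N) and linear outputs (n, R) for a batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != w.n_inputs:
        raise ConfigurationError(
            f"input has {X.shape[1]} features, network expects {w.n_inputs}"
        )
    if not np.all(np.isfinite(X)):
        raise DataValidationError("network input contains non-finite values")
    HO = np.tanh(X @ w.Iw + w.Hb)
    Y = HO @ w.Hw + w.Ob
    return HO, Y


def forward(w: NetworkWeights, x: Sequence[float]) -> ForwardTrace:
    """Forward pass for a single input vector."""
    HO, Y = forward_batch(w, np.asarray(x, dtype=float)[None, :])
    return ForwardTrace(hidden=HO[0], outputs=Y[0])


def predict_class(
    w: NetworkWeights,
    x: Sequence[float],
    codebook: ClassCodebook = DEFAULT_CODEBOOK,
) -> str:
    """Decode the network output into a class name.

    Index encoding (R = 1): round half up to the nearest integer, clamp to
    the codebook range.  One-hot encoding (R = len(codebook)): argmax.
    """
    y = forward(w, x).outputs
    if not np.all(np.isfinite(y)):
        raise DivergenceError("network produced a non-finite output")
    if w.n_outputs == 1:
        code = int(np.floor(y[0] + 0.5))
        code = min(max(code, 0), len(codebook) - 1)
    elif w.n_outputs == len(codebook):
        code = int(np.argmax(y))
    else:
        raise ConfigurationError(
            f"cannot decode {w.n_outputs} outputs against {len(codebook)} classes"
        )
    return codebook.name(code)


@dataclass
class TrainingBatch:
    """Normalized features, encoded real-valued targets and (optionally) predictions."""

    inputs: np.ndarray  # (n, S), entries in [0, 1]
    targets: np.ndarray  # (n,) or (n, R)
    predictions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.inputs.shape[0] < 1:
            raise DataValidationError("inputs must be a non-empty (n, S) matrix")
        if self.targets.shape[0] != self.inputs.shape[0]:
            raise DataValidationError("inputs and targets disagree on sample count")

    @property
    def n(self) -> int:
        return self.inputs.shape[0]

    def subset(self, idx: np.ndarray) -> "TrainingBatch":
        return TrainingBatch(self.inputs[idx], self.targets[idx])


def mse(batch: TrainingBatch) -> float:
    """Mean squared error over all samples (and outputs, if several)."""
    if batch.predictions is None:
        raise DataValidationError("predictions not populated")
    pred = np.asarray(batch.predictions, dtype=float)
    resid = pred.reshape(batch.n, -1) - batch.targets.reshape(batch.n, -1)
    return float(np.mean(np.sum(resid**2, axis=1)))


@dataclass(frozen=True)
class LmaSettings:
    """Damping schedule and stopping tolerances for Levenberg–Marquardt."""

    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 10.0
    lambda_max: float = 1e12
    max_iter: int = 200
    mse_tol: float = 1e-8
    grad_tol: float = 1e-10
    init_scale: float = 0.5  # weights drawn uniform in [-scale, scale]


DEFAULT_LMA = LmaSettings()


@dataclass
class TrainingHistory:
    mse_per_iteration: list[float] = field(default_factory=list)
    converged: bool = False
    stop_reason: str = ""
    restart_mses: list[float] = field(default_factory=list)


def init_weights(S: int, N: int, R: int, rng: np.random.Generator, scale: float = 0.5) -> NetworkWeights:
    return NetworkWeights(
        Iw=rng.uniform(-scale, scale, size=(S, N)),
        Hb=rng.uniform(-scale, scale, size=N),
        Hw=rng.uniform(-scale, scale, size=(N, R)),
        Ob=rng.uniform(-scale, scale, size=R),
    )


def residual_jacobian(w: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the stacked per-sample outputs w.r.t. the
    flattened parameters, shape (n*R, P) with parameter order Iw, Hb, Hw, Ob.

    With HO = tanh(X Iw + Hb) and y = HO Hw + Ob:
        dy_r/dIw_sn = Hw_nr (1 - HO_n^2) x_s
        dy_r/dHb_n  = Hw_nr (1 - HO_n^2)
        dy_r/dHw_nr = HO_n
        dy_r/dOb_r  = 1
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    S, N, R = w.n_inputs, w.n_hidden, w.n_outputs
    HO, _ = forward_batch(w, X)
    dtanh = 1.0 - HO**2  # (n, N)
    J = np.zeros((n, R, w.n_parameters))
    for r in range(R):
        back = dtanh * w.Hw[:, r]  # (n, N)
        # dIw: (n, S, N) = x_s * back_n
        J[:, r, : S * N] = (X[:, :, None] * back[:, None, :]).reshape(n, S * N)
        J[:, r, S * N : S * N + N] = back
        hw_block = np.zeros((n, N, R))
        hw_block[:, :, r] = HO
        J[:, r, S * N + N : S * N + N + N * R] = hw_block.reshape(n, N * R)
        J[:, r, S * N + N + N * R + r] = 1.0
    return J.reshape(n * R, w.n_parameters)


def _residuals(w: NetworkWeights, X: np.ndarray, T: np.ndarray) -> np.ndarray:
    _, Y = forward_batch(w, X)
    return (Y - T.reshape(Y.shape)).ravel()


def _lma_single(
    X: np.ndarray,
    T: np.ndarray,
    w: NetworkWeights,
    settings: LmaSettings,
) -> tuple[NetworkWeights, TrainingHistory]:
    n = X.shape[0]
    S, N, R = w.n_inputs, w.n_hidden, w.n_outputs
    theta = w.flatten()
    r = _residuals(w, X, T)
    sse = float(r @ r)
    lam = settings.lambda0
    hist = TrainingHistory(mse_per_iteration=[sse / n])
    eye = np.eye(theta.size)
    for it in range(settings.max_iter):
        if not np.isfinite(sse):
            raise DivergenceError("non-finite training loss", iteration=it)
        if sse / n < settings.mse_tol:
            hist.converged, hist.stop_reason = True, "mse_tol"
            break
        J = residual_jacobian(w, X)
        g = J.T @ r
        if np.max(np.abs(g)) < settings.grad_tol:
            hist.converged, hist.stop_reason = True, "grad_tol"
            break
        A = J.T @ J
        accepted = False
        while lam <= settings.lambda_max:
            try:
                delta = np.linalg.solve(A + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= settings.lambda_up
                continue
            cand_theta = theta + delta
            cand_w = NetworkWeights.from_flat(cand_theta, S, N, R)
            cand_r = _residuals(cand_w, X, T)
            cand_sse = float(cand_r @ cand_r)
            if np.isfinite(cand_sse) and cand_sse < sse:
                theta, w, r, sse = cand_theta, cand_w, cand_r, cand_sse
                lam = max(lam / settings.lambda_down, 1e-15)
                accepted = True
                break
            lam *= settings.lambda_up
        if not accepted:
            hist.converged, hist.stop_reason = True, "no_improving_step"
            break
        hist.mse_per_iteration.append(sse / n)
    else:
        hist.stop_reason = "max_iter"
    return w, hist


def encode_targets(
    labels: Sequence[str],
    codebook: ClassCodebook = DEFAULT_CODEBOOK,
    encoding: str = "index",
) -> np.ndarray:
    """Encode class names as regression targets (scalar codes or one-hot rows)."""
    codes = np.array([codebook.code(name) for name in labels], dtype=float)
    if encoding == "index":
        return codes
    if encoding == "onehot":
        T = np.zeros((len(codes), len(codebook)))
        T[np.arange(len(codes)), codes.astype(int)] = 1.0
        return T
    raise ConfigurationError(f"unknown output encoding {encoding!r}")


def lma_train(
    batch: TrainingBatch,
    hidden_size: int,
    seed: int,
    settings: LmaSettings = DEFAULT_LMA,
    restarts: int = 1,
) -> tuple[NetworkWeights, TrainingHistory]:
    """Train from ``restarts`` seeded initializations, keep the lowest-MSE fit.

    Fully deterministic for a given (batch, hidden_size, seed, settings).
    """
    if hidden_size < 1:
        raise ConfigurationError("hidden_size must be >= 1")
    if restarts < 1:
        raise ConfigurationError("restarts must be >= 1")
    X = batch.inputs
    T = batch.targets
    R = 1 if T.ndim == 1 else T.shape[1]
    S = X.shape[1]
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best: tuple[NetworkWeights, TrainingHistory] | None = None
    restart_mses = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        w0 = init_weights(S, hidden_size, R, rng, settings.init_scale)
        w, hist = _lma_single(X, T, w0, settings)
        final = hist.mse_per_iteration[-1]
        restart_mses.append(final)
        if best is None or final < best[1].mse_per_iteration[-1]:
            best = (w, hist)
    best[1].restart_mses = restart_mses
    return best


@dataclass(frozen=True)
class CrossValidationPlan:
    k: int
    fold_assignments: np.ndarray  # length n, values in 0..k-1
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


def kfold_plan(n: int, k: int, seed: int) -> CrossValidationPlan:
    """Seeded random partition of n samples into k non-empty folds."""
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ConfigurationError(f"k = {k} exceeds sample count n = {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    # balanced folds: sizes differ by at most one
    assignments[perm] = np.arange(n) % k
    return CrossValidationPlan(k=k, fold_assignments=assignments, seed=seed)


@dataclass
class CvResult:
    plan: CrossValidationPlan
    fold_test_mse: list[float]
    mean_test_mse: float
    heldout_predictions: np.ndarray  # decoded class codes, aligned with the dataset
    heldout_accuracy: float | None  # fraction correct vs integer-coded targets


def _decode_codes(Y: np.ndarray, n_classes: int) -> np.ndarray:
    if Y.shape[1] == 1:
        codes = np.floor(Y[:, 0] + 0.5).astype(int)
        return np.clip(codes, 0, n_classes - 1)
    return np.argmax(Y, axis=1)


def kfold_cross_validate(
    batch: TrainingBatch,
    k: int,
    hidden_size: int,
    seed: int,
    settings: LmaSettings = DEFAULT_LMA,
    restarts: int = 1,
    n_classes: int = len(CLASS_NAMES),
) -> CvResult:
    """Train on k−1 folds, test on the held-out fold, for every fold.

    Each sample is tested exactly once; the k test MSEs are averaged.  When
    targets are integer class codes (or one-hot rows) the pooled held-out
    classification accuracy is reported as well.
    """
    plan = kfold_plan(batch.n, k, seed)
    fold_mse: list[float] = []
    heldout = np.full(batch.n, -1, dtype=int)
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        w, _ = lma_train(
            batch.subset(tr), hidden_size, int(fold_seeds[fold]), settings, restarts
        )
        _, Y = forward_batch(w, batch.inputs[te])
        test = batch.subset(te)
        test.predictions = Y.reshape(test.targets.shape)
        fold_mse.append(mse(test))
        heldout[te] = _decode_codes(Y, n_classes)
    if batch.targets.ndim == 1:
        true_codes = batch.targets.astype(int)
        exact = np.allclose(batch.targets, true_codes)
    else:
        true_codes = np.argmax(batch.targets, axis=1)
        exact = True
    accuracy = float(np.mean(heldout == true_codes)) if exact else None
    return CvResult(
        plan=plan,
        fold_test_mse=fold_mse,
        mean_test_mse=float(np.mean(fold_mse)),
        heldout_predictions=heldout,
        heldout_accuracy=accuracy,
    )


DEFAULT_HIDDEN_SIZES = (5, 10, 12, 14, 17, 20)


@dataclass
class HiddenSizeSearchResult:
    table: list[tuple[int, float]]  # (size, mean test MSE)
    selected_size: int


def hidden_size_search(
    batch: TrainingBatch,
    sizes: Sequence[int] = DEFAULT_HIDDEN_SIZES,
    k: int = 10,
    seed: int = 0,
    settings: LmaSettings = DEFAULT_LMA,
    restarts: int = 1,
    parsimony_margin: float = 0.0,
) -> HiddenSizeSearchResult:
    """Evaluate candidate hidden widths by cross-validation and select one.

    Selection: among sizes whose mean test MSE is within ``parsimony_margin``
    of the minimum, the smallest architecture wins (ties go to the smaller).
    """
    if not sizes:
        raise ConfigurationError("hidden-size candidate list is empty")
    table = [
        (int(N), kfold_cross_validate(batch, k, int(N), seed, settings, restarts).mean_test_mse)
        for N in sizes
    ]
    return HiddenSizeSearchResult(table=table, selected_size=select_size(table, parsimony_margin))


def select_size(table: Sequence[tuple[int, float]], parsimony_margin: float = 0.0) -> int:
    """Parsimonious argmin over a (size, mean MSE) table."""
    best_mse = min(m for _, m in table)
    # small absolute slack so a margin exactly equal to the MSE gap qualifies
    eligible = [n for n, m in table if m - best_mse <= parsimony_margin + 1e-12]
    return min(eligible)
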
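"""Extreme learning machine: a single-hidden-layer network whose input weights
are random and fixed, with only the output layer solved — in closed form via
the Moore–Penrose generalized inverse.

With L hidden units, input weights W (L×d) and biases b drawn uniformly on
[−1, 1], the hidden activations are H = sin(X Wᵀ + b) and the output weights
solve the least-squares problem β = H† T.  When L ≥ n and H has full row
rank the network interpolates the training set exactly (zero training
error), which the tests assert at 1e−6 MSE.

Inputs are z-scored and divided by √d (d = feature count), with statistics
frozen at training time: the projection w·x then has spread of order one,
which keeps the sine activation out of its uninformative high-frequency
regime regardless of dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_HIDDEN = 630          # hidden sine units
PINV_RCOND = 1e-10            # relative singular-value truncation


class ELMValidationError(ValueError):
    pass


@dataclass
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X):
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        # extra sqrt(d) keeps w.x of order one for uniform [-1,1] weights
        return cls(mean=mean, sd=sd * np.sqrt(X.shape[1]))

    def transform(self, X):
        return (X - self.mean) / self.sd


@dataclass
class ELMModel:
    W: np.ndarray                 # L×d input weights (random, fixed)
    b: np.ndarray                 # L biases
    beta: np.ndarray              # L×m output weights (least-squares solution)
    standardizer: Standardizer
    seed: int
    spec_hash: str = ""           # feature-spec fingerprint, checked at predict time

    @property
    def n_hidden(self):
        return self.W.shape[0]

    @property
    def n_features(self):
        return self.W.shape[1]


def _hidden(X, W, b):
    return np.sin(X @ W.T + b)


def elm_train(X, T, n_hidden: int = DEFAULT_HIDDEN, seed: int = 0,
              standardize: bool = True, spec_hash: str = "") -> ELMModel:
    """Fit an ELM: random sine projection, pseudo-inverse output solve.

    Parameters
    ----------
    X : (n, d) feature matrix; T : (n,) or (n, m) targets.
    n_hidden : hidden-layer width L (default 630).
    seed : seeds the uniform [−1, 1] draw of W and b.
    """
    X = np.asarray(X, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if T.ndim == 1:
        T = T[:, None]
    if X.ndim != 2 or X.shape[0] != T.shape[0] or X.shape[0] < 1:
        raise ELMValidationError(f"bad shapes X {X.shape}, T {T.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ELMValidationError("non-finite training data")
    if n_hidden < 1:
        raise ELMValidationError("n_hidden must be >= 1")

    std = Standardizer.fit(X) if standardize else Standardizer(
        mean=np.zeros(X.shape[1]), sd=np.ones(X.shape[1]))
    Xs = std.transform(X)

    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = _hidden(Xs, W, b)
    beta = np.linalg.pinv(H, rcond=PINV_RCOND) @ T
    return ELMModel(W=W, b=b, beta=beta, standardizer=std, seed=seed,
                    spec_hash=spec_hash)


def elm_predict(model: ELMModel, X, chunk: int = 200_000) -> np.ndarray:
    """Real-valued scores sin(X Wᵀ + b)·β, shape (n, m); deterministic."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ELMValidationError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"model expects {model.n_features}")
    Xs = model.standardizer.transform(X)
    out = np.empty((X.shape[0], model.beta.shape[1]))
    for i in range(0, X.shape[0], chunk):
        out[i:i + chunk] = _hidden(Xs[i:i + chunk], model.W, model.b) @ model.beta
    return out


def binarize(scores, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores to {0,1}; a score exactly at threshold goes to 1."""
    return (np.asarray(scores) >= threshold).astype(np.uint8)


def save_model(model: ELMModel, path) -> None:
    """Persist the model as a single NPZ archive (arrays + scalar header)."""
    np.savez_compressed(
        path, W=model.W, b=model.b, beta=model.beta,
        std_mean=model.standardizer.mean, std_sd=model.standardizer.sd,
        seed=np.int64(model.seed), spec_hash=np.str_(model.spec_hash))


def load_model(path) -> ELMModel:
    z = np.load(path, allow_pickle=False)
    return ELMModel(W=z["W"], b=z["b"], beta=z["beta"],
                    standardizer=Standardizer(mean=z["std_mean"], sd=z["std_sd"]),
                    seed=int(z["seed"]), spec_hash=str(z["spec_hash"]))
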
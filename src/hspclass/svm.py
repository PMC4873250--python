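"""Binary soft-margin kernel classifier: the building block of both tiers.

Training is delegated to scikit-learn's libsvm-based ``SVC``; the fitted
model is immediately frozen into its support vectors, dual coefficients and
intercept, and all decision values are computed from those arrays by this
module's own kernel functions.  Freezing gives a single deterministic
scoring path that serializes to plain JSON and round-trips bit-exactly.

Kernel conventions (matching the classic SVM-light parameterization that the
hyper-parameter vocabulary comes from):

* linear:      K(x, z) = x . z
* polynomial:  K(x, z) = (x . z + 1)^d
* rbf:         K(x, z) = exp(-g ||x - z||^2)

``cost_ratio`` (the ``-j`` knob) multiplies the penalty of misclassifying
*positive* training examples relative to negatives, the standard lever
against class imbalance in one-vs-rest stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .errors import HspClassError

KERNELS = ("linear", "polynomial", "rbf")


@dataclass(frozen=True)
class KernelConfig:
    """Hyper-parameters of one binary model.

    Fields irrelevant to the chosen kernel must be ``None``: ``degree`` is
    polynomial-only, ``gamma`` is rbf-only.
    """

    kernel: str = "linear"
    degree: int | None = None
    gamma: float | None = None
    cost_ratio: float = 1.0  # -j: weight on positive-class training errors
    trade_off: float = 1.0  # C: regularization strength

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise HspClassError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.kernel == "polynomial":
            if self.degree is None or self.degree < 1:
                raise HspClassError("polynomial kernel requires degree >= 1")
            if self.gamma is not None:
                raise HspClassError("gamma is an rbf-only parameter")
        elif self.kernel == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise HspClassError("rbf kernel requires gamma > 0")
            if self.degree is not None:
                raise HspClassError("degree is a polynomial-only parameter")
        else:
            if self.degree is not None or self.gamma is not None:
                raise HspClassError("linear kernel takes neither degree nor gamma")
        if self.cost_ratio <= 0:
            raise HspClassError("cost_ratio must be > 0")
        if self.trade_off <= 0:
            raise HspClassError("trade_off must be > 0")

    @classmethod
    def linear(cls, cost_ratio: float = 1.0, trade_off: float = 1.0) -> "KernelConfig":
        return cls("linear", cost_ratio=cost_ratio, trade_off=trade_off)

    @classmethod
    def polynomial(
        cls, degree: int, cost_ratio: float = 1.0, trade_off: float = 1.0
    ) -> "KernelConfig":
        return cls("polynomial", degree=degree, cost_ratio=cost_ratio, trade_off=trade_off)

    @classmethod
    def rbf(cls, gamma: float, cost_ratio: float = 1.0, trade_off: float = 1.0) -> "KernelConfig":
        return cls("rbf", gamma=gamma, cost_ratio=cost_ratio, trade_off=trade_off)

    def describe(self) -> str:
        if self.kernel == "polynomial":
            core = f"polynomial d={self.degree}"
        elif self.kernel == "rbf":
            core = f"rbf g={self.gamma:g}"
        else:
            core = "linear"
        return f"{core} j={self.cost_ratio:g} C={self.trade_off:g}"

    def to_dict(self) -> dict[str, Any]:
        return {
            "kernel": self.kernel,
            "degree": self.degree,
            "gamma": self.gamma,
            "cost_ratio": self.cost_ratio,
            "trade_off": self.trade_off,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KernelConfig":
        return cls(**d)


def _kernel_matrix(config: KernelConfig, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if config.kernel == "linear":
        return A @ B.T
    if config.kernel == "polynomial":
        return (A @ B.T + 1.0) ** config.degree
    return np.exp(-config.gamma * cdist(A, B, "sqeuclidean"))


@dataclass
class BinaryModel:
    """A trained binary decision function, frozen to its support vectors.

    ``decision_value(x) = sum_i dual_coef_i K(sv_i, x) + intercept``; the
    sign at threshold 0 gives the predicted label, positive meaning
    ``positive_label``.
    """

    config: KernelConfig
    encoding: str  # "discrete" (20-dim) or "coupled" (400-dim)
    positive_label: str
    support_vectors: np.ndarray  # (n_sv, dim)
    dual_coef: np.ndarray  # (n_sv,), signed y_i * alpha_i
    intercept: float
    n_positive: int
    n_negative: int

    @property
    def dim(self) -> int:
        return self.support_vectors.shape[1]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise HspClassError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.dim} (encoding {self.encoding!r})"
            )
        K = _kernel_matrix(self.config, X, self.support_vectors)
        return K @ self.dual_coef + self.intercept

    def decision_value(self, vector: np.ndarray) -> float:
        return float(self.decision_values(np.asarray(vector, dtype=float)[None, :])[0])

    def predict_labels(self, X: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        """+1 where the decision value >= threshold (ties go positive), else -1."""
        d = self.decision_values(X)
        return np.where(d >= threshold, 1, -1)

    def predict_label(self, vector: np.ndarray, threshold: float = 0.0) -> int:
        return int(self.predict_labels(np.asarray(vector, dtype=float)[None, :], threshold)[0])

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config.to_dict(),
            "encoding": self.encoding,
            "positive_label": self.positive_label,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BinaryModel":
        return cls(
            config=KernelConfig.from_dict(d["config"]),
            encoding=d["encoding"],
            positive_label=d["positive_label"],
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_positive=int(d["n_positive"]),
            n_negative=int(d["n_negative"]),
        )


def train_binary(
    features: np.ndarray,
    labels: np.ndarray,
    config: KernelConfig,
    seed: int = 0,
    encoding: str = "coupled",
    positive_label: str = "positive",
) -> BinaryModel:
    """Fit a binary max-margin model on a +/-1 labelled feature matrix.

    Deterministic: identical (features, labels, config, seed) yield
    bit-identical decision functions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise HspClassError("features must be a 2-D matrix aligned with labels")
    if not np.isfinite(X).all():
        raise HspClassError("features contain non-finite values")
    uniq = set(np.unique(y).tolist())
    if uniq != {-1, 1}:
        raise HspClassError(f"labels must contain both +1 and -1, got {sorted(uniq)}")

    if config.kernel == "linear":
        svc = SVC(kernel="linear", C=config.trade_off)
    elif config.kernel == "polynomial":
        svc = SVC(kernel="poly", degree=config.degree, gamma=1.0, coef0=1.0, C=config.trade_off)
    else:
        svc = SVC(kernel="rbf", gamma=config.gamma, C=config.trade_off)
    # tight optimizer tolerance so symmetry properties of the dual hold closely
    svc.set_params(class_weight={1: config.cost_ratio, -1: 1.0},
                   random_state=seed, tol=1e-6)
    svc.fit(X, y.astype(int))

    # classes_ is sorted (-1, +1), so decision_function > 0 <=> predicted +1
    return BinaryModel(
        config=config,
        encoding=encoding,
        positive_label=positive_label,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        n_positive=int((y == 1).sum()),
        n_negative=int((y == -1).sum()),
    )
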
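"""Linear SVM training, span-rule model selection and the logistic meta-classifier.

The classifier itself is a standard soft-margin linear SVM; the network
feature selection upstream carries the method's structure.  The
regularization constant C is chosen by the span rule of Chapelle & Vapnik:
a computable estimate of the leave-one-out error obtained from the support
vectors of a single fit, so a C grid can be scanned without n retrainings
per grid point.

All standardization is fit on training data only; test data is transformed
with the stored training parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

DEFAULT_C_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1e3)


def standardize_fit_apply(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Per-feature standardization fit on training samples only.

    ``train`` and ``test`` are feature x sample matrices.  Each training
    feature is scaled to mean 0, sd 1 (population sd, as in
    sklearn.preprocessing.StandardScaler); the same parameters are applied
    to the test matrix.  Zero-variance features map to 0 in both.

    Returns ``(train_std, test_std, means, sds)``.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[1] < 2:
        raise ValueError("need at least 2 training samples to standardize")
    means = train.mean(axis=1)
    sds = train.std(axis=1)
    safe = np.where(sds > 0, sds, 1.0)
    train_std = np.where(
        (sds > 0)[:, None], (train - means[:, None]) / safe[:, None], 0.0
    )
    test_std = None
    if test is not None:
        test = np.asarray(test, dtype=float)
        test_std = np.where(
            (sds > 0)[:, None], (test - means[:, None]) / safe[:, None], 0.0
        )
    return train_std, test_std, means, sds


@dataclass
class TrainedModel:
    """A fitted linear SVM restricted to a feature signature.

    The ranking function f(x) = sum_i alpha_i y_i <x_i, x> + b is fully
    reproducible from the stored support vectors, dual coefficients and
    intercept.  ``means``/``sds`` are the training standardization
    parameters for the signature features (in signature order).
    """

    signature: list[str]
    support_vectors: np.ndarray          # (n_sv, n_features), standardized
    dual_coef: np.ndarray                # alpha_i * y_i per support vector
    intercept: float
    C: float
    means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sds: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def decision_function(self, x_new: np.ndarray) -> np.ndarray:
        """Continuous ranking scores for samples in rows of ``x_new``
        (already standardized, signature order)."""
        x_new = np.asarray(x_new, dtype=float)
        return x_new @ self.support_vectors.T @ self.dual_coef + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "stsvm-model-v1",
                "signature": self.signature,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coef": self.dual_coef.tolist(),
                "intercept": self.intercept,
                "C": self.C,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
            }
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "stsvm-model-v1":
            raise ValueError(f"{path}: not a recognized model file")
        return cls(
            signature=list(d["signature"]),
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            means=np.array(d["means"], dtype=float),
            sds=np.array(d["sds"], dtype=float),
        )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    signature: list[str] | None = None,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> TrainedModel:
    """Fit a soft-margin linear-kernel SVM.

    ``X`` is sample x feature (standardized, restricted to the signature);
    ``y`` in {+1, -1}.  Dual coefficients satisfy 0 <= alpha_i <= C and
    sum alpha_i y_i = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if C <= 0:
        raise ValueError("C must be positive")
    classes = set(np.unique(y))
    if classes != {-1, 1}:
        raise ValueError(f"need both classes (+1/-1) present, got {sorted(classes)}")
    clf = SVC(kernel="linear", C=C, tol=1e-6)
    clf.fit(X, y)
    # sklearn's dual_coef_ is alpha_i * y_i ordered by its support_ index
    return TrainedModel(
        signature=list(signature) if signature is not None else [],
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        C=float(C),
        means=np.asarray(means, dtype=float) if means is not None else np.zeros(0),
        sds=np.asarray(sds, dtype=float) if sds is not None else np.zeros(0),
    )


def ranking_function(model: TrainedModel, X_new: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i <x_i, x> + b for each row x of ``X_new``."""
    X_new = np.asarray(X_new, dtype=float)
    return X_new @ model.support_vectors.T @ model.dual_coef + model.intercept


def _extended_gram_inverse(sv: np.ndarray, jitter: float) -> np.ndarray:
    """Inverse of [[K_sv + jitter*I, 1], [1^T, 0]] (pinv on singularity)."""
    n_sv = sv.shape[0]
    ext = np.zeros((n_sv + 1, n_sv + 1))
    ext[:n_sv, :n_sv] = sv @ sv.T + jitter * np.eye(n_sv)
    ext[:n_sv, n_sv] = 1.0
    ext[n_sv, :n_sv] = 1.0
    try:
        return np.linalg.inv(ext)
    except np.linalg.LinAlgError:
        ext[:n_sv, :n_sv] += 1e-6 * np.eye(n_sv)
        return np.linalg.pinv(ext)


def span_loo_estimate(X: np.ndarray, y: np.ndarray, C: float, jitter: float = 1e-8) -> float:
    """Span estimate of the leave-one-out error of a linear SVM at C.

    After a single fit, support vector p is predicted to flip its label in
    leave-one-out iff alpha_p * S_p^2 >= y_p f(x_p), where S_p is its span
    (Chapelle-Vapnik): for an unbounded SV (alpha < C) the distance to the
    affine hull of the other unbounded SVs, S_p^2 = 1/(inv)_pp from the
    inverse of the extended Gram matrix [[K_U, 1], [1^T, 0]]; for a bounded
    SV (alpha = C) the distance to the affine hull of all unbounded SVs,
    with the margin condition already discounted by its slack through
    y_p f(x_p).  Non-support vectors are classified identically without
    themselves and contribute 0; the estimate is the flip fraction over all
    training points.

    A singular extended matrix falls back to a jittered diagonal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    model = train_svm(X, y, C)
    sv = model.support_vectors
    n_sv = sv.shape[0]
    if n_sv == 0:
        return 0.0
    alpha = np.abs(model.dual_coef)  # alpha_i = |alpha_i y_i|
    y_sv = np.sign(model.dual_coef)  # y_i, as alpha_i > 0 on support vectors
    f_sv = ranking_function(model, sv)
    bounded = alpha >= C * (1.0 - 1e-6)
    free = ~bounded
    span2 = np.empty(n_sv)
    if bounded.any():
        # the span of a box-bounded SV is constrained and expensive to
        # compute exactly; the SV-set diameter is its classical upper bound
        diff = sv[:, None, :] - sv[None, :, :]
        span2[bounded] = (diff**2).sum(axis=2).max()
    if free.any():
        svf = sv[free]
        inv = _extended_gram_inverse(svf, jitter)
        diag = np.diag(inv)[: svf.shape[0]]
        with np.errstate(divide="ignore"):
            span2[free] = np.where(np.abs(diag) > 1e-12, 1.0 / np.abs(diag), np.inf)
    flips = alpha * span2 >= y_sv * f_sv
    return float(flips.sum()) / n


def span_select_C(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] | list[float] = DEFAULT_C_GRID,
) -> float:
    """Choose C from a grid by minimizing the span estimate of the LOO error.

    Ties are broken toward the smallest C.  Grid points whose fit fails are
    skipped with a warning; if every point fails an error is raised.
    """
    if not grid:
        raise ValueError("C grid must be non-empty")
    best_c = None
    best_est = np.inf
    for c in sorted(grid):
        try:
            est = span_loo_estimate(X, y, c)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"span estimate failed at C={c}: {exc}")
            continue
        if est < best_est:
            best_est = est
            best_c = c
    if best_c is None:
        raise RuntimeError("SVM training failed at every C in the grid")
    return float(best_c)


@dataclass
class MetaModel:
    """Logistic regression combining two SVM ranking outputs.

    P(y=+1 | f1, f2) = sigmoid(w0 + w1 f1 + w2 f2).
    """

    intercept: float
    coef: np.ndarray  # (w1, w2)


def fit_meta(f1: np.ndarray, f2: np.ndarray, y: np.ndarray) -> MetaModel:
    """Maximum-likelihood logistic regression of the labels on two ranking
    score vectors (with intercept).

    Under perfect separation the likelihood has no finite maximum; the fit
    then stops at the iteration cap and a warning is issued.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (len(f1) == len(f2) == len(y)):
        raise ValueError("f1, f2 and y must be aligned")
    Z = np.column_stack([f1, f2])
    lr = LogisticRegression(penalty=None, max_iter=200)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        lr.fit(Z, y)
    model = MetaModel(intercept=float(lr.intercept_[0]), coef=lr.coef_.ravel().copy())
    z = model.intercept + Z @ model.coef
    separated = bool(np.all(np.where(y == 1, z, -z) > 0))
    if separated or any(issubclass(w.category, ConvergenceWarning) for w in caught):
        warnings.warn(
            "logistic meta-classifier scores separate the classes perfectly; "
            "coefficients are not identifiable and come from the "
            "capped-iteration fit"
        )
    return model


def predict_meta(model: MetaModel, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """P(y=+1) for each sample given its two ranking scores."""
    z = model.intercept + model.coef[0] * np.asarray(f1) + model.coef[1] * np.asarray(f2)
    return 1.0 / (1.0 + np.exp(-z))
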
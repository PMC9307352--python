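"""Six classifiers sharing the 0.9 / 0.1 target encoding.

Every classifier is trained against regression targets T_C = 0.9 (cancer)
and T_N = 0.1 (normal) and emits both a continuous score in score space and
a binary label obtained by thresholding the score at 0.5 (ties go to
normal).  The gap invariant T_C - T_N >= 0.5 is enforced by
:class:`TargetEncoding`.

Algorithms
----------
GMM
    Per-class mixture of Q diagonal-covariance Gaussians (default Q = 1)
    fitted by expectation maximization with a variance floor; the score is
    the posterior probability of cancer mapped onto [T_N, T_C].
DFA
    Each sample's feature vector (ordered by feature index) is summarized
    by its detrended-fluctuation scaling exponent alpha; the decision
    threshold is the midpoint of the training class-mean alphas and the
    score is a monotone map of alpha onto [T_N, T_C].
NLR
    Nonlinear regression: a scalar logistic curve
    T_N + (T_C - T_N) / (1 + exp(-(a + b u))) in the sample-mean feature u,
    fitted by damped Gauss-Newton least squares against the encoded targets.
BLDC
    Bayesian linear regression of the encoded targets on (features, bias)
    with prior precision alpha and noise precision beta set by evidence
    maximization (MacKay fixed-point iteration).
LR
    Ordinary least squares Z = p + q.Y via pseudo-inverse (well defined for
    d >= n).
KNN
    Euclidean K-nearest-neighbour majority vote (K odd); the score is the
    cancer vote fraction mapped onto [T_N, T_C].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DataError

__all__ = [
    "TargetEncoding",
    "encode_targets",
    "decode_scores",
    "dfa_alpha",
    "dfa_fluctuations",
    "default_box_sizes",
    "fit",
    "predict",
    "bayesian_linear_regression",
    "save_model",
    "load_model",
    "ALGORITHMS",
    "BaseClassifier",
]

ALGORITHMS = ("GMM", "DFA", "NLR", "BLDC", "LR", "KNN")


@dataclass(frozen=True)
class TargetEncoding:
    """Regression targets and decision threshold shared by all classifiers."""

    t_cancer: float = 0.9
    t_normal: float = 0.1
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.t_cancer - self.t_normal < 0.5:
            raise ConfigurationError(
                f"target gap t_cancer - t_normal = {self.t_cancer - self.t_normal} "
                "violates the >= 0.5 requirement"
            )
        if not self.t_normal < self.threshold < self.t_cancer:
            raise ConfigurationError(
                "threshold must lie strictly between t_normal and t_cancer"
            )

    @property
    def span(self) -> float:
        return self.t_cancer - self.t_normal


def encode_targets(labels: np.ndarray, encoding: TargetEncoding | None = None) -> np.ndarray:
    """Map binary labels to regression targets (1 -> 0.9, 0 -> 0.1)."""
    encoding = encoding or TargetEncoding()
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ConfigurationError("labels must be binary 0/1")
    return np.where(labels == 1, encoding.t_cancer, encoding.t_normal).astype(float)


def decode_scores(scores: np.ndarray, encoding: TargetEncoding | None = None) -> np.ndarray:
    """Threshold scores at 0.5; ties (score == threshold) go to normal."""
    encoding = encoding or TargetEncoding()
    return (np.asarray(scores, dtype=float) > encoding.threshold).astype(int)


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------


def default_box_sizes(n: int, n_sizes: int = 8) -> np.ndarray:
    """Log-spaced box sizes from 4 up to n // 4 (at least 4 distinct sizes).

    Short series (n // 4 < 7) extend the largest box to n // 2 so that at
    least 4 distinct sizes remain available.
    """
    if n < 16:
        raise DataError(f"series length {n} < 16; DFA needs length >= 4 * min box size")
    for top in (max(n // 4, 5), max(n // 2, 5)):
        sizes = np.unique(
            np.round(np.geomspace(4, top, num=max(n_sizes, 8))).astype(int)
        )
        sizes = sizes[sizes >= 4]
        if sizes.size >= 4:
            return sizes
    raise DataError(f"series length {n} admits fewer than 4 distinct box sizes")


def dfa_fluctuations(
    series: np.ndarray,
    box_sizes: Sequence[int] | None = None,
    detrend_order: int = 1,
    *,
    integrate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """RMS detrended fluctuations G(s) over box sizes s.

    With ``integrate=True`` (standard DFA) the profile is the cumulative sum
    of the mean-centered series; ``integrate=False`` treats ``series`` as
    the profile itself (so an order-1 detrend annihilates a pure linear
    ramp).  For each box size the profile is split into non-overlapping
    boxes, a polynomial of ``detrend_order`` is removed per box, and the
    RMS residual is recorded.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if box_sizes is None:
        box_sizes = default_box_sizes(n)
    sizes = np.asarray(sorted(set(int(s) for s in box_sizes)), dtype=int)
    if sizes.size < 4:
        raise ConfigurationError("DFA needs at least 4 distinct box sizes")
    if (sizes < 4).any():
        raise ConfigurationError("DFA box sizes must be >= 4")
    if n < 4 * sizes.min():
        raise DataError(f"series length {n} < 4 * min box size {sizes.min()}")

    profile = np.cumsum(x - x.mean()) if integrate else x
    fluct = np.empty(sizes.size)
    for i, s in enumerate(sizes):
        n_boxes = n // s
        seg = profile[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s, dtype=float)
        # per-box polynomial detrend via one shared Vandermonde solve
        V = np.vander(t, detrend_order + 1)
        coef, *_ = np.linalg.lstsq(V, seg.T, rcond=None)
        resid = seg.T - V @ coef
        fluct[i] = float(np.sqrt(np.mean(resid**2)))
    return sizes, fluct


def dfa_alpha(
    series: np.ndarray,
    box_sizes: Sequence[int] | None = None,
    detrend_order: int = 1,
) -> float:
    """Detrended-fluctuation scaling exponent of a series.

    Alpha is the least-squares slope of log G(s) against log s over the
    fluctuations of :func:`dfa_fluctuations` (white noise ~0.5, integrated
    white noise ~1.5).  A constant series, or one whose fluctuations vanish
    at every scale, returns 0 with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size and np.ptp(x) == 0:
        warnings.warn("constant series: DFA alpha undefined, returning 0", stacklevel=2)
        return 0.0
    sizes, fluct = dfa_fluctuations(x, box_sizes, detrend_order)
    keep = fluct > 0
    if keep.sum() < 2:
        warnings.warn(
            "fluctuations vanish at all scales; returning alpha = 0", stacklevel=2
        )
        return 0.0
    slope = np.polyfit(np.log(sizes[keep]), np.log(fluct[keep]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Classifier framework
# ---------------------------------------------------------------------------


class BaseClassifier:
    """Common fit/score contract; subclasses implement ``_fit`` and ``_score``."""

    algorithm: str = ""

    def __init__(self, encoding: TargetEncoding | None = None, seed: int = 0):
        self.encoding = encoding or TargetEncoding()
        self.seed = int(seed)
        self.fitted_ = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ConfigurationError("X rows and y length differ")
        for cls in (0, 1):
            if int(np.sum(y == cls)) < 2:
                raise DataError(f"class {cls} has fewer than 2 training samples")
        self._fit(X, y)
        self.fitted_ = True
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self.fitted_:
            raise ConfigurationError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.asarray(self._score(X), dtype=float)
        if not np.isfinite(scores).all():
            raise DataError(f"{self.algorithm}: non-finite scores produced")
        return scores, decode_scores(scores, self.encoding)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        state = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self._state().items()
        }
        return {
            "algorithm": self.algorithm,
            "encoding": {
                "t_cancer": self.encoding.t_cancer,
                "t_normal": self.encoding.t_normal,
                "threshold": self.encoding.threshold,
            },
            "seed": self.seed,
            "state": state,
        }

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def _score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _state(self) -> dict:  # pragma: no cover
        raise NotImplementedError

    def _restore(self, state: dict) -> None:  # pragma: no cover
        raise NotImplementedError


class GMMClassifier(BaseClassifier):
    """Per-class diagonal-covariance Gaussian mixture with a variance floor."""

    algorithm = "GMM"

    def __init__(
        self,
        n_components: int = 1,
        encoding: TargetEncoding | None = None,
        seed: int = 0,
        max_iter: int = 100,
        tol: float = 1e-6,
    ):
        super().__init__(encoding, seed)
        if n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        self.n_components = int(n_components)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    @staticmethod
    def _log_gauss(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
        # X: n x d, means/variances: Q x d -> n x Q log densities
        diff2 = (X[:, None, :] - means[None, :, :]) ** 2
        return -0.5 * np.sum(
            diff2 / variances[None] + np.log(2 * np.pi * variances)[None], axis=-1
        )

    def _fit_class(self, X: np.ndarray, rng: np.random.Generator) -> dict:
        n, d = X.shape
        q = self.n_components
        floor = 1e-6 * max(float(np.mean(np.var(X, axis=0))), 1e-12)
        if q == 1:
            var = np.var(X, axis=0)[None, :]
            if (var < floor).any():
                warnings.warn("degenerate covariance: variance floor applied", stacklevel=2)
            return {
                "weights": np.ones(1),
                "means": X.mean(axis=0)[None, :],
                "variances": np.maximum(var, floor),
            }
        # EM with seeded random responsibilities
        resp = rng.dirichlet(np.ones(q), size=n)
        ll_old = -np.inf
        weights = np.full(q, 1.0 / q)
        means = X[rng.choice(n, q, replace=False)]
        variances = np.tile(np.maximum(np.var(X, axis=0), floor), (q, 1))
        for _ in range(self.max_iter):
            nk = resp.sum(axis=0) + 1e-12
            weights = nk / n
            means = (resp.T @ X) / nk[:, None]
            variances = np.maximum(
                (resp.T @ (X**2)) / nk[:, None] - means**2, floor
            )
            log_p = self._log_gauss(X, means, variances) + np.log(weights + 1e-300)
            m = log_p.max(axis=1, keepdims=True)
            log_norm = m + np.log(np.exp(log_p - m).sum(axis=1, keepdims=True))
            resp = np.exp(log_p - log_norm)
            ll = float(log_norm.sum())
            if abs(ll - ll_old) < self.tol * max(abs(ll), 1.0):
                break
            ll_old = ll
        return {"weights": weights, "means": means, "variances": variances}

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        rng = np.random.default_rng(self.seed)
        self.components_ = {cls: self._fit_class(X[y == cls], rng) for cls in (0, 1)}
        self.log_priors_ = {
            cls: float(np.log(np.mean(y == cls))) for cls in (0, 1)
        }

    def _class_log_likelihood(self, X: np.ndarray, cls: int) -> np.ndarray:
        c = self.components_[cls]
        log_p = self._log_gauss(X, c["means"], c["variances"]) + np.log(
            c["weights"] + 1e-300
        )
        m = log_p.max(axis=1)
        return m + np.log(np.exp(log_p - m[:, None]).sum(axis=1))

    def _score(self, X: np.ndarray) -> np.ndarray:
        log_joint = np.stack(
            [self._class_log_likelihood(X, c) + self.log_priors_[c] for c in (0, 1)],
            axis=1,
        )
        m = log_joint.max(axis=1, keepdims=True)
        post = np.exp(log_joint - m)
        post /= post.sum(axis=1, keepdims=True)
        return self.encoding.t_normal + self.encoding.span * post[:, 1]

    def _state(self) -> dict:
        out = {"log_prior_0": self.log_priors_[0], "log_prior_1": self.log_priors_[1],
               "n_components": self.n_components}
        for cls in (0, 1):
            for key in ("weights", "means", "variances"):
                out[f"{key}_{cls}"] = self.components_[cls][key]
        return out

    def _restore(self, state: dict) -> None:
        self.n_components = int(state["n_components"])
        self.log_priors_ = {0: state["log_prior_0"], 1: state["log_prior_1"]}
        self.components_ = {
            cls: {
                key: np.asarray(state[f"{key}_{cls}"], dtype=float)
                for key in ("weights", "means", "variances")
            }
            for cls in (0, 1)
        }


class DFAClassifier(BaseClassifier):
    """Classifies by the DFA scaling exponent of each feature vector."""

    algorithm = "DFA"

    def __init__(
        self,
        box_sizes: Sequence[int] | None = None,
        detrend_order: int = 1,
        encoding: TargetEncoding | None = None,
        seed: int = 0,
    ):
        super().__init__(encoding, seed)
        self.box_sizes = None if box_sizes is None else list(box_sizes)
        self.detrend_order = int(detrend_order)

    def _alphas(self, X: np.ndarray) -> np.ndarray:
        if self.box_sizes is None and X.shape[1] < 16:
            # degenerate rule: vectors too short for DFA are summarized by
            # their mean value instead of a scaling exponent
            return X.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.array(
                [dfa_alpha(row, self.box_sizes, self.detrend_order) for row in X]
            )

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        alphas = self._alphas(X)
        self.mean_alpha_ = {cls: float(alphas[y == cls].mean()) for cls in (0, 1)}
        self.threshold_alpha_ = 0.5 * (self.mean_alpha_[0] + self.mean_alpha_[1])
        gap = self.mean_alpha_[1] - self.mean_alpha_[0]
        self.orientation_ = 1.0 if gap >= 0 else -1.0
        self.scale_ = max(abs(gap) / 4.0, 1e-6)

    def _score(self, X: np.ndarray) -> np.ndarray:
        z = self.orientation_ * (self._alphas(X) - self.threshold_alpha_) / self.scale_
        return self.encoding.t_normal + self.encoding.span / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def _state(self) -> dict:
        return {
            "mean_alpha_0": self.mean_alpha_[0],
            "mean_alpha_1": self.mean_alpha_[1],
            "threshold_alpha": self.threshold_alpha_,
            "orientation": self.orientation_,
            "scale": self.scale_,
            "box_sizes": self.box_sizes,
            "detrend_order": self.detrend_order,
        }

    def _restore(self, state: dict) -> None:
        self.mean_alpha_ = {0: state["mean_alpha_0"], 1: state["mean_alpha_1"]}
        self.threshold_alpha_ = state["threshold_alpha"]
        self.orientation_ = state["orientation"]
        self.scale_ = state["scale"]
        self.box_sizes = state["box_sizes"]
        self.detrend_order = int(state["detrend_order"])


class NLRClassifier(BaseClassifier):
    """Scalar logistic curve in the sample-mean feature, Gauss-Newton fitted."""

    algorithm = "NLR"

    def __init__(
        self,
        encoding: TargetEncoding | None = None,
        seed: int = 0,
        max_iter: int = 200,
        tol: float = 1e-8,
        projection: np.ndarray | None = None,
    ):
        super().__init__(encoding, seed)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.projection = None if projection is None else np.asarray(projection, float)

    def _u(self, X: np.ndarray) -> np.ndarray:
        if self.projection is not None:
            return X @ self.projection
        return X.mean(axis=1)

    def _curve(self, u: np.ndarray, a: float, b: float) -> np.ndarray:
        z = np.clip(a + b * u, -500, 500)
        return self.encoding.t_normal + self.encoding.span / (1.0 + np.exp(-z))

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        t = encode_targets(y, self.encoding)
        u = self._u(X)
        su = float(np.std(u))
        if su == 0:
            self.a_, self.b_ = 0.0, 0.0
            return
        # orient the initial slope with the sign of corr(u, targets)
        r = float(np.corrcoef(u, t)[0, 1]) if np.std(t) > 0 else 1.0
        b = np.sign(r) if r != 0 else 1.0
        b /= su
        a = -b * float(np.mean(u))
        sse_old = float(np.sum((self._curve(u, a, b) - t) ** 2))
        for _ in range(self.max_iter):
            f = self._curve(u, a, b)
            # d f / d z for the logistic scaled to [t_n, t_c]
            sig = (f - self.encoding.t_normal) / self.encoding.span
            dz = self.encoding.span * sig * (1 - sig)
            J = np.stack([dz, dz * u], axis=1)
            resid = t - f
            try:
                step, *_ = np.linalg.lstsq(J, resid, rcond=None)
            except np.linalg.LinAlgError:
                break
            # damped update: halve until the SSE does not increase
            lam = 1.0
            for _ in range(12):
                a_new, b_new = a + lam * step[0], b + lam * step[1]
                sse = float(np.sum((self._curve(u, a_new, b_new) - t) ** 2))
                if sse <= sse_old + 1e-15:
                    break
                lam *= 0.5
            if max(abs(lam * step[0]), abs(lam * step[1])) < self.tol:
                a, b, sse_old = a_new, b_new, sse
                break
            a, b, sse_old = a_new, b_new, sse
        self.a_, self.b_ = float(a), float(b)

    def _score(self, X: np.ndarray) -> np.ndarray:
        return self._curve(self._u(X), self.a_, self.b_)

    def _state(self) -> dict:
        return {"a": self.a_, "b": self.b_, "projection": self.projection}

    def _restore(self, state: dict) -> None:
        self.a_ = float(state["a"])
        self.b_ = float(state["b"])
        proj = state.get("projection")
        self.projection = None if proj is None else np.asarray(proj, dtype=float)


def bayesian_linear_regression(
    phi: np.ndarray,
    t: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, float]:
    """Evidence-maximized Bayesian linear regression of ``t`` on ``phi``.

    Iterates the MacKay fixed point for the prior precision alpha and noise
    precision beta, returning ``(weights, alpha, beta)``.  On noise-free
    data beta grows to its cap and the weights approach the least-squares
    solution.
    """
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float)
    n, d = phi.shape
    gram = phi.T @ phi
    eigvals = np.maximum(np.linalg.eigvalsh(gram), 0.0)
    phit = phi.T @ t

    alpha, beta = 1.0, 1.0 / max(float(np.var(t)), 1e-12)
    for _ in range(max_iter):
        m = np.linalg.solve(beta * gram + alpha * np.eye(d), beta * phit)
        lam = beta * eigvals
        gamma = float(np.sum(lam / (lam + alpha)))
        m_norm2 = float(m @ m)
        resid2 = float(np.sum((t - phi @ m) ** 2))
        alpha_new = float(np.clip(gamma / max(m_norm2, 1e-12), 1e-10, 1e10))
        beta_new = float(
            np.clip(max(n - gamma, 1e-12) / max(resid2, 1e-12), 1e-10, 1e12)
        )
        converged = (
            abs(alpha_new - alpha) <= tol * abs(alpha)
            and abs(beta_new - beta) <= tol * abs(beta)
        )
        alpha, beta = alpha_new, beta_new
        if converged:
            break
    weights = np.linalg.solve(beta * gram + alpha * np.eye(d), beta * phit)
    return weights, alpha, beta


class BLDCClassifier(BaseClassifier):
    """Bayesian linear regression on encoded targets, evidence-maximized."""

    algorithm = "BLDC"

    def __init__(
        self,
        encoding: TargetEncoding | None = None,
        seed: int = 0,
        max_iter: int = 200,
        tol: float = 1e-6,
    ):
        super().__init__(encoding, seed)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        t = encode_targets(y, self.encoding)
        phi = np.hstack([X, np.ones((X.shape[0], 1))])
        self.weights_, self.alpha_, self.beta_ = bayesian_linear_regression(
            phi, t, self.max_iter, self.tol
        )

    def _score(self, X: np.ndarray) -> np.ndarray:
        phi = np.hstack([X, np.ones((X.shape[0], 1))])
        return phi @ self.weights_

    def _state(self) -> dict:
        return {"weights": self.weights_, "alpha": self.alpha_, "beta": self.beta_}

    def _restore(self, state: dict) -> None:
        self.weights_ = np.asarray(state["weights"], dtype=float)
        self.alpha_ = float(state["alpha"])
        self.beta_ = float(state["beta"])


class LRClassifier(BaseClassifier):
    """Ordinary least squares on encoded targets (pseudo-inverse for d >= n).

    A logistic variant (``logistic=True``) replaces the linear fit with a
    ridge-stabilized IRLS logistic regression on the binary labels.
    """

    algorithm = "LR"

    def __init__(
        self,
        encoding: TargetEncoding | None = None,
        seed: int = 0,
        logistic: bool = False,
        max_iter: int = 100,
    ):
        super().__init__(encoding, seed)
        self.logistic = bool(logistic)
        self.max_iter = int(max_iter)

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        n = X.shape[0]
        phi = np.hstack([np.ones((n, 1)), X])
        if not self.logistic:
            t = encode_targets(y, self.encoding)
            self.coef_ = np.linalg.pinv(phi) @ t
        else:
            w = np.zeros(phi.shape[1])
            yy = y.astype(float)
            ridge = 1e-6
            for _ in range(self.max_iter):
                z = np.clip(phi @ w, -500, 500)
                p = 1.0 / (1.0 + np.exp(-z))
                W = np.maximum(p * (1 - p), 1e-9)
                H = phi.T @ (phi * W[:, None]) + ridge * np.eye(phi.shape[1])
                g = phi.T @ (yy - p) - ridge * w
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    break
                w = w + step
                if np.max(np.abs(step)) < 1e-10:
                    break
            self.coef_ = w

    def _score(self, X: np.ndarray) -> np.ndarray:
        phi = np.hstack([np.ones((X.shape[0], 1)), X])
        if not self.logistic:
            return phi @ self.coef_
        z = np.clip(phi @ self.coef_, -500, 500)
        p = 1.0 / (1.0 + np.exp(-z))
        return self.encoding.t_normal + self.encoding.span * p

    def _state(self) -> dict:
        return {"coef": self.coef_, "logistic": self.logistic}

    def _restore(self, state: dict) -> None:
        self.coef_ = np.asarray(state["coef"], dtype=float)
        self.logistic = bool(state["logistic"])


class KNNClassifier(BaseClassifier):
    """Euclidean K-nearest-neighbour majority vote; K must be odd."""

    algorithm = "KNN"

    def __init__(
        self,
        k: int = 3,
        encoding: TargetEncoding | None = None,
        seed: int = 0,
    ):
        super().__init__(encoding, seed)
        if k < 1 or k % 2 == 0:
            raise ConfigurationError(f"K must be an odd positive integer, got {k}")
        self.k = int(k)

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:
        if self.k > X.shape[0]:
            raise ConfigurationError(
                f"K={self.k} exceeds the {X.shape[0]} training samples"
            )
        self.train_X_ = X.copy()
        self.train_y_ = y.copy()

    def _score(self, X: np.ndarray) -> np.ndarray:
        d = cdist(X, self.train_X_, "euclidean")
        # order ties by training index for permutation-stable neighbours
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        votes = self.train_y_[order].mean(axis=1)
        return self.encoding.t_normal + self.encoding.span * votes

    def _state(self) -> dict:
        return {"train_X": self.train_X_, "train_y": self.train_y_, "k": self.k}

    def _restore(self, state: dict) -> None:
        self.train_X_ = np.asarray(state["train_X"], dtype=float)
        self.train_y_ = np.asarray(state["train_y"], dtype=int)
        self.k = int(state["k"])


_REGISTRY: dict[str, type[BaseClassifier]] = {
    "GMM": GMMClassifier,
    "DFA": DFAClassifier,
    "NLR": NLRClassifier,
    "BLDC": BLDCClassifier,
    "LR": LRClassifier,
    "KNN": KNNClassifier,
}


def fit(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    encoding: TargetEncoding | None = None,
    seed: int = 0,
    **hyperparams,
) -> BaseClassifier:
    """Construct and fit the named classifier."""
    algorithm = algorithm.upper()
    if algorithm not in _REGISTRY:
        raise ConfigurationError(
            f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
        )
    model = _REGISTRY[algorithm](encoding=encoding, seed=seed, **hyperparams)
    return model.fit(X, y)


def predict(model: BaseClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and thresholded binary labels for ``X``."""
    return model.predict(X)


def save_model(model: BaseClassifier, path: str | Path) -> None:
    """Serialize a fitted model (parameters + encoding) to JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))


def load_model(path: str | Path) -> BaseClassifier:
    """Restore a model written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    cls = _REGISTRY[payload["algorithm"]]
    model = cls.__new__(cls)
    BaseClassifier.__init__(
        model, encoding=TargetEncoding(**payload["encoding"]), seed=payload["seed"]
    )
    model._restore(payload["state"])
    model.fitted_ = True
    return model
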
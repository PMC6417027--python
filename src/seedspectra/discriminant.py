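"""Chemometric models: PCA exploration and linear discriminant analysis.

The classifier implemented here is classical LDA in its distance form. Each
class ``k`` is summarised by its centroid spectrum ``mu_k`` and all classes
share the pooled within-class covariance ``Sigma``. A spectrum ``x`` is scored
by its squared Mahalanobis distance to each centroid,

    d_k(x) = (x - mu_k)^T Sigma^{-1} (x - mu_k),

turned into a discriminant score ``g_k = -d_k/2 + ln(pi_k)`` with class prior
``pi_k``, and into a posterior membership probability by normalising
``exp(g_k)`` over classes. The assigned class is the posterior argmax — which
under equal priors is exactly the minimum-distance rule, and for two classes
coincides with the "posterior > 0.5" rule.

The module follows the statsmodels convention: :class:`LinearDiscriminant` is
the model specification, its :meth:`~LinearDiscriminant.fit` returns an
:class:`LDAResult` carrying the estimates, and prediction, scoring,
cross-validation and plotting hang off the result object. Thin functional
wrappers (:func:`lda_fit`, :func:`lda_predict`, :func:`loocv`, ...) expose the
same operations for pipeline code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import scipy.linalg

from .exceptions import CrossValidationError, FitError, ParameterError, ValidationError
from .extraction import LabelVector, SpectraMatrix

__all__ = [
    "PCAResult",
    "pca_fit",
    "LinearDiscriminant",
    "LDAResult",
    "ConfusionMatrix",
    "ClassificationReport",
    "lda_fit",
    "lda_predict",
    "loocv",
    "score_report",
    "discriminant_scores_2d",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (display convention for report tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraMatrix):
        return X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValidationError(f"expected a 2-D data matrix, got shape {X.shape}")
    return X


def _as_codes(y, class_names: Sequence[str] | None):
    if isinstance(y, LabelVector):
        return y.codes.copy(), tuple(y.class_names)
    codes = np.asarray(y, dtype=int)
    k = int(codes.max()) + 1 if codes.size else 0
    names = tuple(class_names) if class_names is not None else tuple(
        f"class_{i}" for i in range(k)
    )
    return codes, names


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Principal components of a column-mean-centred spectra matrix.

    ``explained_variance_pct`` is relative to the total variance over all
    bands, so over a full-rank decomposition the percentages sum to 100.
    """

    component_loadings: np.ndarray  # bands x k, orthonormal columns
    scores: np.ndarray  # seeds x k
    explained_variance_pct: np.ndarray  # k,
    column_means: np.ndarray  # bands,
    eigenvalues: np.ndarray  # k, sample-covariance eigenvalues


def pca_fit(X, k: int | None = None) -> PCAResult:
    """Eigendecomposition of the sample covariance of ``X`` (n-1 denominator).

    Parameters
    ----------
    X
        ``n x B`` matrix (or :class:`~seedspectra.extraction.SpectraMatrix`).
    k
        Number of components to keep; defaults to ``min(n - 1, B)``.
    """
    M = _as_matrix(X)
    n, b = M.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 observations")
    kmax = min(n - 1, b)
    k = kmax if k is None else int(k)
    if not (1 <= k <= kmax):
        raise ParameterError(f"k must lie in 1..{kmax}, got {k}")
    mu = M.mean(axis=0)
    C = np.cov(M - mu, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(
        component_loadings=evecs[:, :k],
        scores=(M - mu) @ evecs[:, :k],
        explained_variance_pct=pct[:k],
        column_means=mu,
        eigenvalues=evals[:k],
    )


# ---------------------------------------------------------------------------
# Confusion matrices and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K table of counts; rows are true classes, columns assigned classes."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.class_names)
        if c.shape != (k, k):
            raise ValidationError(f"counts shape {c.shape} vs {k} classes")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(np.int64)
            if (c < 0).any():
                raise ValidationError("confusion counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @classmethod
    def from_assignments(
        cls, true_codes, assigned_codes, class_names: Sequence[str]
    ) -> "ConfusionMatrix":
        k = len(class_names)
        counts = np.zeros((k, k), dtype=np.int64)
        for t, a in zip(np.asarray(true_codes), np.asarray(assigned_codes)):
            counts[int(t), int(a)] += 1
        return cls(counts, tuple(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def score_report(confusion: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class and overall correct-classification percentages.

    Per-class accuracy is ``100 * diagonal / row sum`` (NaN for an empty
    class); the overall correct classification is ``100 * trace / total``.
    Values are returned at full precision — round only for display
    (:func:`round_half_up` to two decimals reproduces printed report tables).
    """
    c = confusion.counts.astype(np.float64)
    if c.sum() == 0:
        raise ValidationError("empty confusion matrix")
    row = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, 100.0 * np.diag(c) / row, np.nan)
    overall = 100.0 * np.trace(c) / c.sum()
    return per_class, float(overall)


@dataclass(frozen=True)
class ClassificationReport:
    """Verdicts of a classifier over a data set, with the derived accuracies."""

    confusion: ConfusionMatrix
    per_class_accuracy_pct: np.ndarray
    overall_correct_pct: float
    assignments: np.ndarray
    posteriors: np.ndarray  # seeds x K, rows sum to 1
    squared_distances: np.ndarray  # seeds x K

    @classmethod
    def from_predictions(
        cls, confusion: ConfusionMatrix, assignments, posteriors, squared_distances
    ) -> "ClassificationReport":
        per_class, overall = score_report(confusion)
        return cls(
            confusion,
            per_class,
            overall,
            np.asarray(assignments),
            np.asarray(posteriors),
            np.asarray(squared_distances),
        )

    def summary(self) -> str:
        names = self.confusion.class_names
        width = max(12, max(len(n) for n in names) + 2)
        head = "".join(f"{n:>{width}}" for n in names)
        lines = [
            "Classification report",
            "=" * (width * (len(names) + 1) + 10),
            f"{'':>{width}}{head}{'% correct':>11}",
        ]
        for i, n in enumerate(names):
            row = "".join(f"{int(v):>{width}}" for v in self.confusion.counts[i])
            acc = self.per_class_accuracy_pct[i]
            acc_s = "n/a" if np.isnan(acc) else f"{round_half_up(acc):.2f}"
            lines.append(f"{n:>{width}}{row}{acc_s:>11}")
        lines.append(
            f"Overall correct classification: "
            f"{round_half_up(self.overall_correct_pct):.2f}%  "
            f"(n = {self.confusion.total})"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The LDA model / results pair
# ---------------------------------------------------------------------------

class LinearDiscriminant:
    """Linear discriminant model specification.

    Parameters
    ----------
    X
        ``n x B`` training spectra (array or :class:`SpectraMatrix`).
    y
        Integer class codes ``0..K-1`` (array or :class:`LabelVector`).
    class_names
        Optional labels for the codes (taken from ``y`` when it is a
        :class:`LabelVector`).
    prior_mode
        ``"proportional"`` (priors = training class frequencies; the default,
        appropriate for unbalanced lots) or ``"equal"``.
    regularization_lambda
        Ridge shrinkage of the pooled covariance:
        ``Sigma + lambda * (trace(Sigma)/B) * I``. The tiny default keeps a
        20-band covariance invertible even for small classes; 0 is allowed
        when the data permit.

    Examples
    --------
    >>> model = LinearDiscriminant(X, y, prior_mode="proportional")
    >>> res = model.fit()
    >>> report = res.score(X_val, y_val)
    >>> print(report.summary())
    """

    def __init__(
        self,
        X,
        y,
        class_names: Sequence[str] | None = None,
        prior_mode: str = "proportional",
        regularization_lambda: float = 1e-6,
    ) -> None:
        self.X = _as_matrix(X)
        self.codes, self.class_names = _as_codes(y, class_names)
        if self.codes.size != self.X.shape[0]:
            raise ValidationError(
                f"{self.X.shape[0]} rows in X vs {self.codes.size} labels"
            )
        if prior_mode not in ("proportional", "equal"):
            raise ParameterError(f"unknown prior_mode '{prior_mode}'")
        if regularization_lambda < 0:
            raise ParameterError("regularization_lambda must be >= 0")
        self.prior_mode = prior_mode
        self.regularization_lambda = float(regularization_lambda)

    @classmethod
    def from_spectra(
        cls,
        spectra: SpectraMatrix,
        labels: LabelVector,
        prior_mode: str = "proportional",
        regularization_lambda: float = 1e-6,
    ) -> "LinearDiscriminant":
        if tuple(spectra.seed_ids) != tuple(labels.seed_ids):
            raise ValidationError("spectra and labels are not aligned on seed_ids")
        return cls(
            spectra, labels,
            prior_mode=prior_mode, regularization_lambda=regularization_lambda,
        )

    def fit(self) -> "LDAResult":
        """Estimate centroids, pooled within-class covariance and priors."""
        X, codes = self.X, self.codes
        n, b = X.shape
        k = len(self.class_names)
        present = np.unique(codes)
        if len(present) < 2:
            raise FitError("LDA needs at least 2 classes present in the data")
        counts = np.array([(codes == i).sum() for i in range(k)])
        if (counts < 2).any():
            bad = [self.class_names[i] for i in range(k) if counts[i] < 2]
            raise FitError(f"every class needs >= 2 members; too small: {bad}")

        centroids = np.vstack([X[codes == i].mean(axis=0) for i in range(k)])
        scatter = np.zeros((b, b))
        for i in range(k):
            d = X[codes == i] - centroids[i]
            scatter += d.T @ d
        pooled = scatter / (n - k)
        lam = self.regularization_lambda
        if lam > 0:
            # ridge scale follows the covariance magnitude; a zero-scatter
            # (perfectly noise-free) fit falls back to unit scale so the
            # model degenerates gracefully to a nearest-centroid rule
            scale = np.trace(pooled) / b
            pooled = pooled + lam * (scale if scale > 0 else 1.0) * np.eye(b)
        try:
            cho = scipy.linalg.cho_factor(pooled)
            precision = scipy.linalg.cho_solve(cho, np.eye(b))
        except scipy.linalg.LinAlgError as e:
            raise FitError(
                "pooled covariance is not positive definite; increase "
                "regularization_lambda"
            ) from e

        if self.prior_mode == "equal":
            priors = np.full(k, 1.0 / k)
        else:
            priors = counts / counts.sum()
        return LDAResult(
            model=self,
            class_names=self.class_names,
            centroids=centroids,
            pooled_covariance=pooled,
            precision=precision,
            priors=priors,
            class_counts=counts,
            regularization_lambda=lam,
            n_obs=n,
        )

    def fit_loocv(self) -> ClassificationReport:
        """Leave-one-out cross-validation: n refits, each scoring one held-out seed.

        Every class must keep at least 2 members in every fold (so classes
        need >= 3 members overall).
        """
        X, codes = self.X, self.codes
        n = X.shape[0]
        k = len(self.class_names)
        counts = np.array([(codes == i).sum() for i in range(k)])
        if (counts < 3).any():
            bad = [self.class_names[i] for i in range(k) if counts[i] < 3]
            raise CrossValidationError(
                f"LOOCV needs >= 3 members per class; too small: {bad}"
            )
        assignments = np.empty(n, dtype=int)
        posteriors = np.empty((n, k))
        distances = np.empty((n, k))
        keep = np.ones(n, dtype=bool)
        for i in range(n):
            keep[i] = False
            res_i = LinearDiscriminant(
                X[keep], codes[keep],
                class_names=self.class_names,
                prior_mode=self.prior_mode,
                regularization_lambda=self.regularization_lambda,
            ).fit()
            keep[i] = True
            a, p, d = res_i.predict(X[i])
            assignments[i], posteriors[i], distances[i] = a[0], p[0], d[0]
        confusion = ConfusionMatrix.from_assignments(codes, assignments, self.class_names)
        return ClassificationReport.from_predictions(
            confusion, assignments, posteriors, distances
        )


@dataclass(frozen=True)
class LDAResult:
    """Fitted linear discriminant model.

    Carries the class centroids, the (regularised) pooled within-class
    covariance and its inverse, and the class priors; all prediction,
    scoring and projection methods live here.
    """

    model: LinearDiscriminant
    class_names: tuple[str, ...]
    centroids: np.ndarray  # K x B
    pooled_covariance: np.ndarray  # B x B, symmetric positive definite
    precision: np.ndarray  # B x B, inverse of pooled_covariance
    priors: np.ndarray  # K, sums to 1
    class_counts: np.ndarray  # K,
    regularization_lambda: float
    n_obs: int

    @property
    def n_bands(self) -> int:
        return self.centroids.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    # -- prediction --------------------------------------------------------

    def squared_distances(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each row to each class centroid."""
        M = _as_matrix(X)
        if M.shape[1] != self.n_bands:
            raise ValidationError(
                f"{M.shape[1]} bands in data vs {self.n_bands} in model"
            )
        d = np.empty((M.shape[0], self.n_classes))
        for k in range(self.n_classes):
            diff = M - self.centroids[k]
            d[:, k] = np.einsum("ij,jk,ik->i", diff, self.precision, diff)
        return d

    def posteriors(self, X) -> np.ndarray:
        """Posterior membership probabilities (rows sum to 1)."""
        d = self.squared_distances(X)
        g = -0.5 * d + np.log(self.priors)[None, :]
        g -= g.max(axis=1, keepdims=True)  # stabilise the softmax
        p = np.exp(g)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Assign each spectrum to the class of maximum posterior.

        Returns ``(assignments, posteriors, squared_distances)``. Under equal
        priors the argmax-posterior rule is the minimum-distance rule; for two
        classes it is the "membership probability > 0.5" rule. Exact posterior
        ties go to the lowest class index.
        """
        d = self.squared_distances(X)
        g = -0.5 * d + np.log(self.priors)[None, :]
        gs = g - g.max(axis=1, keepdims=True)
        p = np.exp(gs)
        p /= p.sum(axis=1, keepdims=True)
        return np.argmax(p, axis=1), p, d

    def score(self, X, y) -> ClassificationReport:
        """Classify ``X`` and tabulate against true labels ``y``."""
        codes, _ = _as_codes(y, self.class_names)
        a, p, d = self.predict(X)
        confusion = ConfusionMatrix.from_assignments(codes, a, self.class_names)
        return ClassificationReport.from_predictions(confusion, a, p, d)

    # -- discriminant-factor projection ------------------------------------

    def discriminant_factors(self, n_factors: int = 2):
        """Directions and explained-variance shares of the discriminant factors.

        Solves the generalized eigenproblem ``Sb v = lambda Sw v`` with ``Sw``
        the pooled within-class covariance and ``Sb`` the between-class
        scatter of the centroids; at most ``K - 1`` factors carry variance,
        and their explained percentages sum to 100 over those ``K - 1``.
        """
        k = self.n_classes
        if k == 2 and n_factors > 1:
            warnings.warn(
                "only one discriminant factor exists for 2 classes", stacklevel=2
            )
            n_factors = 1
        n_factors = min(n_factors, k - 1)
        mu = (self.class_counts / self.class_counts.sum()) @ self.centroids
        sb = np.zeros((self.n_bands, self.n_bands))
        for i in range(k):
            d = self.centroids[i] - mu
            sb += self.class_counts[i] * np.outer(d, d)
        sb /= max(self.class_counts.sum() - 1, 1)
        evals, evecs = scipy.linalg.eigh(sb, self.pooled_covariance)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
        lead = evals[: k - 1]
        pct = 100.0 * lead / lead.sum() if lead.sum() > 0 else np.zeros_like(lead)
        return evecs[:, :n_factors], pct[:n_factors], mu

    def discriminant_scores(self, X, n_factors: int = 2):
        """Project spectra onto the leading discriminant factors.

        Returns ``(scores, explained_pct)`` where ``scores`` is
        ``n x n_factors`` (centred on the training grand mean).
        """
        vecs, pct, mu = self.discriminant_factors(n_factors)
        return (_as_matrix(X) - mu) @ vecs, pct

    def plot_factor_scores(self, X, y=None, ax=None):
        """Scatter the first two discriminant factors (F1 vs F2)."""
        import matplotlib.pyplot as plt

        scores, pct = self.discriminant_scores(X, n_factors=2)
        if ax is None:
            _, ax = plt.subplots()
        codes = _as_codes(y, self.class_names)[0] if y is not None else None
        if codes is None:
            ax.scatter(scores[:, 0], scores[:, -1], s=14)
        else:
            for i, name in enumerate(self.class_names):
                sel = codes == i
                ax.scatter(scores[sel, 0], scores[sel, -1], s=14, label=name)
            ax.legend()
        ax.set_xlabel(f"F1 ({pct[0]:.2f}%)")
        ax.set_ylabel(f"F2 ({pct[1]:.2f}%)" if len(pct) > 1 else "F1")
        return ax

    def summary(self) -> str:
        lines = [
            "Linear discriminant model",
            "=" * 60,
            f"Observations: {self.n_obs}    Bands: {self.n_bands}    "
            f"Classes: {self.n_classes}",
            f"Priors ({self.model.prior_mode}): "
            + ", ".join(
                f"{n}={p:.4f}" for n, p in zip(self.class_names, self.priors)
            ),
            f"Regularization lambda: {self.regularization_lambda:g}",
            "Class counts: "
            + ", ".join(
                f"{n}={c}" for n, c in zip(self.class_names, self.class_counts)
            ),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers (pipeline surface)
# ---------------------------------------------------------------------------

def lda_fit(
    X,
    y,
    prior_mode: str = "proportional",
    regularization_lambda: float = 1e-6,
    class_names: Sequence[str] | None = None,
) -> LDAResult:
    """Fit an LDA model; see :class:`LinearDiscriminant`."""
    return LinearDiscriminant(
        X, y, class_names=class_names,
        prior_mode=prior_mode, regularization_lambda=regularization_lambda,
    ).fit()


def lda_predict(result: LDAResult, X):
    """``(assignments, posteriors, squared_distances)`` for new spectra."""
    return result.predict(X)


def loocv(
    X,
    y,
    prior_mode: str = "proportional",
    regularization_lambda: float = 1e-6,
    class_names: Sequence[str] | None = None,
) -> ClassificationReport:
    """Leave-one-out cross-validation; see :meth:`LinearDiscriminant.fit_loocv`."""
    return LinearDiscriminant(
        X, y, class_names=class_names,
        prior_mode=prior_mode, regularization_lambda=regularization_lambda,
    ).fit_loocv()


def discriminant_scores_2d(result: LDAResult, X):
    """Seeds x 2 discriminant-factor scores with explained-variance shares."""
    return result.discriminant_scores(X, n_factors=2)
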
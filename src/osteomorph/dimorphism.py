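"""Sexual dimorphism statistics on shape-model coefficients.

Quantifies the sex-shape relationship three ways: canonical correlation
between the mode weights and the binary sex factor (male = +1, female = -1;
with a single response the canonical correlation equals the multiple
correlation), partial-least-squares variance explained by sex, and
leave-one-out linear-discriminant classification accuracy per class. Effect
shapes reconstruct the amplified male/female class means through the shape
model for heat-map visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import chi2

from .model import ShapeModel, reconstruct

__all__ = [
    "CcaResult",
    "LdaLooResult",
    "DimorphismReport",
    "sex_shape_cca",
    "pls_sex_variance",
    "lda_loo_accuracy",
    "effect_shapes",
    "SexDimorphism",
    "SexDimorphismResults",
]

_LABEL_CODES = {"male": 1.0, "m": 1.0, 1: 1.0, 1.0: 1.0, "+1": 1.0,
                "female": -1.0, "f": -1.0, -1: -1.0, -1.0: -1.0, "-1": -1.0}


def encode_labels(labels: Sequence) -> np.ndarray:
    """Map male/female (or +-1) labels to the +-1 coding."""
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        key = lab.lower() if isinstance(lab, str) else lab
        if key not in _LABEL_CODES:
            raise ValueError(f"unrecognized sex label: {lab!r}")
        out[i] = _LABEL_CODES[key]
    return out


def _check_two_classes(y: np.ndarray, min_per_class: int = 1) -> None:
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    if n_pos < min_per_class or n_neg < min_per_class:
        raise ValueError(
            f"both sexes must be present with >= {min_per_class} subjects "
            f"(got {n_pos} male, {n_neg} female)"
        )


@dataclass
class CcaResult:
    """Canonical correlation of shape coefficients with the sex factor."""

    canonical_r: float
    p_value: float           # permutation p-value (authoritative)
    p_bartlett: float        # Bartlett chi-square approximation
    effect_direction: np.ndarray
    null_r: Optional[np.ndarray] = None


def sex_shape_cca(
    coeff_matrix: np.ndarray,
    labels: Sequence,
    n_permutations: int = 1000,
    rng=None,
    ridge: Optional[float] = None,
) -> CcaResult:
    """Maximal correlation between a linear combination of coefficients and sex.

    With the single +-1 response this is the multiple correlation of the sex
    factor on the mode weights. The reported effect direction is the canonical
    structure vector — the normalized cross-covariance of the coefficients
    with sex, i.e. the class-mean difference direction — which is the stable,
    interpretable quantity (the raw canonical weights are noise-amplified on
    low-variance modes). Significance comes from Bartlett's
    chi-square approximation and from a permutation test (default 1000 label
    shuffles), the latter being authoritative since mode weights need not be
    normal. When M >= n/5 the cross-covariance solve is ridge-regularized.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    y = encode_labels(labels)
    _check_two_classes(y)
    n, M = X.shape
    if n != y.size:
        raise ValueError("label count must match coefficient rows")
    Xc = X - X.mean(axis=0)

    if ridge is None:
        ridge = 0.0 if M < n / 5 else 1e-3
    G = Xc.T @ Xc
    if ridge > 0:
        G = G + ridge * np.trace(G) / M * np.eye(M)

    def _fit(yvec):
        yc = yvec - yvec.mean()
        beta = (np.linalg.solve(G, Xc.T @ yc) if ridge > 0
                else np.linalg.lstsq(Xc, yc, rcond=None)[0])
        score = Xc @ beta
        denom = np.linalg.norm(score) * np.linalg.norm(yc)
        if denom == 0:
            return 0.0, beta
        return float(abs(score @ yc) / denom), beta

    r, beta = _fit(y)
    cross_cov = Xc.T @ (y - y.mean())
    norm_cc = np.linalg.norm(cross_cov)
    direction = cross_cov / norm_cc if norm_cc > 0 else cross_cov

    lam = max(1.0 - r**2, np.finfo(float).tiny)
    stat = -(n - 1 - (M + 2) / 2) * np.log(lam)
    p_bartlett = float(chi2.sf(stat, df=M))

    generator = np.random.default_rng(rng)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _fit(generator.permutation(y))[0]
    p_perm = float((1 + (null >= r).sum()) / (1 + n_permutations))
    return CcaResult(canonical_r=r, p_value=p_perm, p_bartlett=p_bartlett,
                     effect_direction=direction, null_r=null)


def pls_sex_variance(coeff_matrix: np.ndarray, labels: Sequence) -> float:
    """Percent of total shape variance explained by the sex factor.

    One-component partial-least-squares regression of the (centered)
    coefficient matrix on the +-1 sex factor; the reported value is the
    fraction of total coefficient variance captured by the fitted prediction.
    With a single binary predictor this equals the between-class sum of
    squares as a fraction of the total.
    """
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(coeff_matrix, dtype=float)
    y = encode_labels(labels)
    _check_two_classes(y)
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum())
    if total == 0:
        return 0.0
    pls = PLSRegression(n_components=1, scale=False)
    pls.fit(y.reshape(-1, 1), Xc)
    pred = pls.predict(y.reshape(-1, 1))
    pred_c = pred - pred.mean(axis=0)
    return 100.0 * float((pred_c**2).sum()) / total


@dataclass
class LdaLooResult:
    """Per-class leave-one-out LDA accuracy (percent)."""

    accuracy_male: float
    accuracy_female: float
    predictions: np.ndarray
    overall: float = np.nan


def lda_loo_accuracy(
    coeff_matrix: np.ndarray,
    labels: Sequence,
    shrinkage: Optional[bool] = None,
) -> LdaLooResult:
    """Leave-one-subject-out linear discriminant accuracy per class.

    Uses the exact closed-form leave-one-out update of the pooled-covariance
    two-class discriminant (Sherman-Morrison downdate of the pooled scatter),
    equivalent to refitting the LDA n times but O(n M^2). Class priors are the
    training-fold class fractions. When the pooled covariance is singular or
    M >= n/5 a shrinkage discriminant (scikit-learn, Ledoit-Wolf) is used
    fold-by-fold instead, with a warning.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    y = encode_labels(labels)
    _check_two_classes(y, min_per_class=2)
    n, M = X.shape

    use_shrinkage = bool(shrinkage) if shrinkage is not None else M >= n / 5
    if not use_shrinkage:
        pred = _lda_loo_exact(X, y)
        if pred is None:
            use_shrinkage = True
    if use_shrinkage:
        warnings.warn(
            "pooled covariance ill-conditioned or high-dimensional; "
            "using shrinkage LDA per fold",
            RuntimeWarning,
        )
        pred = _lda_loo_sklearn(X, y)

    male = y > 0
    acc_male = 100.0 * float((pred[male] == 1.0).mean())
    acc_female = 100.0 * float((pred[~male] == -1.0).mean())
    return LdaLooResult(accuracy_male=acc_male, accuracy_female=acc_female,
                        predictions=pred, overall=100.0 * float((pred == y).mean()))


def _lda_loo_exact(X: np.ndarray, y: np.ndarray):
    """Closed-form LOO predictions; returns None if the scatter is singular."""
    n, M = X.shape
    male = y > 0
    n1, n2 = int(male.sum()), int((~male).sum())
    mu1 = X[male].mean(axis=0)
    mu2 = X[~male].mean(axis=0)
    d1 = X[male] - mu1
    d2 = X[~male] - mu2
    S = d1.T @ d1 + d2.T @ d2  # pooled within-class scatter
    try:
        A = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(S) > 1e12:
        return None

    pred = np.empty(n)
    for i in range(n):
        xi = X[i]
        if male[i]:
            nc = n1
            mu_c = (n1 * mu1 - xi) / (n1 - 1)
            m1, m2 = mu_c, mu2
            k1, k2 = n1 - 1, n2
            d = xi - mu1
        else:
            nc = n2
            mu_c = (n2 * mu2 - xi) / (n2 - 1)
            m1, m2 = mu1, mu_c
            k1, k2 = n1, n2 - 1
            d = xi - mu2
        kappa = nc / (nc - 1)
        Ad = A @ d
        denom = 1.0 - kappa * d @ Ad
        if abs(denom) < 1e-14:
            return None
        Ai = A + kappa * np.outer(Ad, Ad) / denom  # inv(S - kappa d d^T)
        # fold covariance = downdated scatter / (n - 3)
        w = (n - 3) * Ai @ (m1 - m2)
        delta = w @ (xi - 0.5 * (m1 + m2)) + np.log(k1 / k2)
        pred[i] = 1.0 if delta > 0 else -1.0
    return pred


def _lda_loo_sklearn(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    n = X.shape[0]
    pred = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X[train], y[train])
        pred[i] = clf.predict(X[i][None, :])[0]
    return pred


def effect_shapes(
    model: ShapeModel,
    coeff_matrix: np.ndarray,
    labels: Sequence,
    effect_direction: np.ndarray,
    amplification: float = 2.0,
):
    """Amplified male/female effect shapes reconstructed through the model.

    The class-mean canonical scores along the (unit) effect direction are
    amplified (default factor 2) around the overall mean and mapped back to
    shape space. Returns ``(shape_male, shape_female)`` as 3K vectors.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    y = encode_labels(labels)
    _check_two_classes(y)
    e = np.asarray(effect_direction, dtype=float)
    e = e / np.linalg.norm(e)
    scores = X @ e
    s_all = scores.mean()
    b_mean = X.mean(axis=0)
    shapes = []
    for cls in (1.0, -1.0):
        s_cls = scores[y == cls].mean()
        b = b_mean + amplification * (s_cls - s_all) * e
        shapes.append(reconstruct(model, b))
    return tuple(shapes)


@dataclass
class DimorphismReport:
    """Table-style record of the dimorphism statistics for one structure."""

    structure: str
    n_subjects: int
    M_used: int
    canonical_r: float
    canonical_p: float
    pct_variance_by_sex: float
    accuracy_male: float
    accuracy_female: float
    effect_direction: np.ndarray

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "n_subjects": self.n_subjects,
            "M_used": self.M_used,
            "canonical_r": self.canonical_r,
            "canonical_p": self.canonical_p,
            "pct_variance_by_sex": self.pct_variance_by_sex,
            "accuracy_male_pct": self.accuracy_male,
            "accuracy_female_pct": self.accuracy_female,
        }


class SexDimorphism:
    """Sex-dimorphism analysis of shape-model coefficients.

    Statsmodels-style model object: construct from the coefficient matrix and
    sex labels (optionally with the generating :class:`ShapeModel` so effect
    shapes can be reconstructed), then :meth:`fit` runs CCA, PLS and LOO-LDA
    and returns :class:`SexDimorphismResults`.
    """

    def __init__(self, coeff_matrix: np.ndarray, labels: Sequence,
                 model: Optional[ShapeModel] = None, structure: str = ""):
        self.coeff_matrix = np.asarray(coeff_matrix, dtype=float)
        self.labels = list(labels)
        self.model = model
        self.structure = structure or (model.structure if model else "")

    def fit(self, n_permutations: int = 1000, rng=None) -> "SexDimorphismResults":
        cca = sex_shape_cca(self.coeff_matrix, self.labels,
                            n_permutations=n_permutations, rng=rng)
        pct = pls_sex_variance(self.coeff_matrix, self.labels)
        lda = lda_loo_accuracy(self.coeff_matrix, self.labels)
        report = DimorphismReport(
            structure=self.structure,
            n_subjects=self.coeff_matrix.shape[0],
            M_used=self.coeff_matrix.shape[1],
            canonical_r=cca.canonical_r,
            canonical_p=cca.p_value,
            pct_variance_by_sex=pct,
            accuracy_male=lda.accuracy_male,
            accuracy_female=lda.accuracy_female,
            effect_direction=cca.effect_direction,
        )
        return SexDimorphismResults(report=report, cca=cca, lda=lda, parent=self)


@dataclass
class SexDimorphismResults:
    """Fitted dimorphism statistics with reporting helpers."""

    report: DimorphismReport
    cca: CcaResult
    lda: LdaLooResult
    parent: SexDimorphism

    def effect_shapes(self, amplification: float = 2.0):
        if self.parent.model is None:
            raise ValueError("effect shapes need the generating ShapeModel")
        return effect_shapes(self.parent.model, self.parent.coeff_matrix,
                             self.parent.labels, self.report.effect_direction,
                             amplification)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Sex Dimorphism Results",
            "=" * 44,
            f"{'structure':<34}{r.structure or '-'}",
            f"{'subjects':<34}{r.n_subjects}",
            f"{'coefficients used (M)':<34}{r.M_used}",
            f"{'canonical r (sex-shape)':<34}{r.canonical_r:.3f}",
            f"{'permutation p':<34}{r.canonical_p:.3g}",
            f"{'Bartlett p':<34}{self.cca.p_bartlett:.3g}",
            f"{'% variance explained by sex':<34}{r.pct_variance_by_sex:.2f}",
            f"{'% correct male (LOO LDA)':<34}{r.accuracy_male:.2f}",
            f"{'% correct female (LOO LDA)':<34}{r.accuracy_female:.2f}",
            "=" * 44,
        ]
        return "\n".join(lines)
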
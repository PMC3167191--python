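"""Fisher's linear discriminant analysis for two diagnostic groups.

The canonical discriminant direction is a ∝ S_w⁻¹(μ_excess − μ_deficient),
scaled so that the pooled within-group variance of the discriminant score is
one (the canonical convention); standardized coefficients multiply each raw
coefficient by the pooled within-group SD of its variable, matching the
"standardized canonical discriminant function coefficients" reported by the
classical statistics packages.  The cutoff between the two group centroids
is, with proportional priors, the weighted mean of the centroids with each
centroid weighted by the *other* group's size (the classical two-group rule
with unequal groups); with equal priors it is the plain midpoint.  Ties at
the cutoff are classified as excess (the "≥" convention).

Diagnostics: Wilks' Λ = |S_w|/|S_t| with Bartlett's χ² approximation, and
Box's M test of equality of the two group covariance matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import DEFICIENT, EXCESS, ConfusionTable, accuracy, confusion, mcc
from .thresholds import _as_excess_bool


def _class_split(X: np.ndarray, y_excess: np.ndarray):
    Xd, Xe = X[~y_excess], X[y_excess]
    if len(Xd) < 2 or len(Xe) < 2:
        raise ValueError("need at least 2 subjects per class")
    return Xd, Xe


def _scatter_within(Xd: np.ndarray, Xe: np.ndarray) -> np.ndarray:
    Sd = (Xd - Xd.mean(axis=0)).T @ (Xd - Xd.mean(axis=0))
    Se = (Xe - Xe.mean(axis=0)).T @ (Xe - Xe.mean(axis=0))
    return Sd + Se


def wilks_lambda(X, y) -> tuple[float, float]:
    """Wilks' Λ = |S_w|/|S_t| for the one-discriminant two-group design,
    with Bartlett's χ² approximation −(n−1−(p+g)/2)·ln Λ on p·(g−1) df."""
    X = np.asarray(X, dtype=float)
    ye = _as_excess_bool(y)
    n, p = X.shape
    Xd, Xe = _class_split(X, ye)
    Sw = _scatter_within(Xd, Xe)
    Xc = X - X.mean(axis=0)
    St = Xc.T @ Xc
    sign_t, logdet_t = np.linalg.slogdet(St)
    sign_w, logdet_w = np.linalg.slogdet(Sw)
    if sign_t <= 0 or sign_w <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix in Wilks' Lambda")
    lam = float(np.exp(logdet_w - logdet_t))
    g = 2
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam)
    pval = float(stats.chi2.sf(chi2, df=p * (g - 1)))
    return lam, pval


def box_m(X, y) -> tuple[float, float]:
    """Box's M test of equal group covariance matrices (χ² approximation)."""
    X = np.asarray(X, dtype=float)
    ye = _as_excess_bool(y)
    n, p = X.shape
    groups = _class_split(X, ye)
    g = len(groups)
    ns = np.array([len(Gk) for Gk in groups])
    pooled = _scatter_within(*groups) / (n - g)
    sign_p, logdet_p = np.linalg.slogdet(pooled)
    if sign_p <= 0:
        raise np.linalg.LinAlgError("singular pooled covariance in Box's M")
    M = (n - g) * logdet_p
    for Gk, nk in zip(groups, ns):
        Sk = np.atleast_2d(np.cov(Gk, rowvar=False, ddof=1))
        sign_k, logdet_k = np.linalg.slogdet(Sk)
        if sign_k <= 0:
            raise np.linalg.LinAlgError("singular group covariance in Box's M")
        M -= (nk - 1) * logdet_k
    c = (np.sum(1.0 / (ns - 1)) - 1.0 / (n - g)) * \
        (2 * p * p + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))
    chi2 = M * (1 - c)
    df = p * (p + 1) * (g - 1) / 2.0
    pval = float(stats.chi2.sf(chi2, df=df))
    return float(M), pval


class FisherDiscriminant:
    """Two-group Fisher discriminant model on a feature matrix.

    Parameters
    ----------
    X : (n, p) array-like
        Per-subject feature values (pulse quantities or factor scores).
    y : sequence of {"deficient", "excess"}
    priors : {"proportional", "equal"}
        Governs where the cutoff sits between the group centroids.
    feature_names : optional sequence of p names for reporting.
    """

    def __init__(self, X, y, priors: str = "proportional", feature_names=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects × features)")
        self.y = list(y)
        if priors not in ("proportional", "equal"):
            raise ValueError("priors must be 'proportional' or 'equal'")
        self.priors = priors
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{k+1}" for k in range(self.X.shape[1])])

    @classmethod
    def from_dataframe(cls, df, features, label_col: str = "label",
                       priors: str = "proportional") -> "FisherDiscriminant":
        features = list(features)
        return cls(df[features].to_numpy(dtype=float), df[label_col],
                   priors=priors, feature_names=features)

    def fit(self) -> "DiscriminantResults":
        X = self.X
        ye = _as_excess_bool(self.y)
        n, p = X.shape
        Xd, Xe = _class_split(X, ye)
        nd, ne = len(Xd), len(Xe)
        Sw = _scatter_within(Xd, Xe)
        Spw = Sw / (n - 2)                       # pooled within-group covariance
        diff = Xe.mean(axis=0) - Xd.mean(axis=0)
        try:
            a = np.linalg.solve(Sw, diff)
        except np.linalg.LinAlgError as err:
            corr_rank = np.linalg.matrix_rank(Sw)
            raise np.linalg.LinAlgError(
                f"within-class scatter is singular (rank {corr_rank} < {p}); "
                "drop collinear features") from err
        # canonical scaling: unit pooled within-group score variance
        scale = float(a @ Spw @ a)
        if scale <= 0:
            raise np.linalg.LinAlgError("degenerate discriminant direction")
        a = a / np.sqrt(scale)
        # orientation: excess centroid scores higher
        if float(Xe.mean(axis=0) @ a) < float(Xd.mean(axis=0) @ a):
            a = -a
        centroid_d = float(Xd.mean(axis=0) @ a)
        centroid_e = float(Xe.mean(axis=0) @ a)
        if self.priors == "proportional":
            cutoff = (ne * centroid_d + nd * centroid_e) / (nd + ne)
        else:
            cutoff = 0.5 * (centroid_d + centroid_e)
        constant = -float(X.mean(axis=0) @ a)    # score centered at grand mean
        std_coef = a * np.sqrt(np.diag(Spw))
        lam, lam_p = wilks_lambda(X, self.y)
        try:
            bm, bm_p = box_m(X, self.y)
        except np.linalg.LinAlgError:
            bm, bm_p = np.nan, np.nan
            warnings.warn("Box's M unavailable: singular group covariance")
        return DiscriminantResults(
            model=self, raw_coefficients=a, standardized_coefficients=std_coef,
            constant=constant, cutoff=cutoff,
            class_means={DEFICIENT: centroid_d, EXCESS: centroid_e},
            wilks_lambda=lam, wilks_p=lam_p, box_m=bm, box_m_p=bm_p,
            n_obs=n, n_per_class={DEFICIENT: nd, EXCESS: ne},
        )


@dataclass
class DiscriminantResults:
    """Fitted Fisher discriminant function and its diagnostics."""

    model: FisherDiscriminant
    raw_coefficients: np.ndarray
    standardized_coefficients: np.ndarray
    constant: float
    cutoff: float
    class_means: dict
    wilks_lambda: float
    wilks_p: float
    box_m: float
    box_m_p: float
    n_obs: int
    n_per_class: dict

    def scores(self, X=None) -> np.ndarray:
        X = self.model.X if X is None else np.atleast_2d(np.asarray(X, float))
        return X @ self.raw_coefficients

    def predict(self, X=None) -> list[str]:
        """Excess for scores at or above the cutoff, deficient below."""
        return [EXCESS if s >= self.cutoff else DEFICIENT for s in self.scores(X)]

    def training_table(self) -> ConfusionTable:
        return confusion(self.model.y, self.predict())

    def summary(self) -> str:
        names = self.model.feature_names
        lines = [
            "Fisher discriminant analysis (deficient vs excess)",
            "=" * 52,
            f"n = {self.n_obs}  (deficient {self.n_per_class[DEFICIENT]}, "
            f"excess {self.n_per_class[EXCESS]}); priors = {self.model.priors}",
            f"Wilks' Lambda = {self.wilks_lambda:.3f} (P = {self.wilks_p:.3f})",
            f"Box's M = {self.box_m:.2f} (P = {self.box_m_p:.3f})",
            "",
            f"{'variable':<12}{'raw coef':>12}{'std coef':>12}",
        ]
        for name, rc, sc in zip(names, self.raw_coefficients,
                                self.standardized_coefficients):
            lines.append(f"{name:<12}{rc:>12.4f}{sc:>12.4f}")
        lines.append(f"{'cutoff':<12}{self.cutoff:>12.4f}")
        tab = self.training_table()
        lines += ["", f"training accuracy = {accuracy(tab):.1%}   MCC = {mcc(tab):.2f}"]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "features": self.model.feature_names,
            "raw_coefficients": self.raw_coefficients.tolist(),
            "standardized_coefficients": self.standardized_coefficients.tolist(),
            "constant": self.constant,
            "cutoff": self.cutoff,
            "class_means": self.class_means,
            "priors": self.model.priors,
            "wilks_lambda": self.wilks_lambda, "wilks_p": self.wilks_p,
            "box_m": self.box_m, "box_m_p": self.box_m_p,
            "n_obs": self.n_obs,
        }, indent=2)


def fisher_lda(X, y, priors: str = "proportional",
               feature_names=None) -> DiscriminantResults:
    """Functional facade over :class:`FisherDiscriminant`."""
    return FisherDiscriminant(X, y, priors=priors,
                              feature_names=feature_names).fit()


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome."""

    table: ConfusionTable
    per_subject: list
    n_invalid: int = 0

    @property
    def accuracy(self) -> float:
        return accuracy(self.table)

    @property
    def mcc(self) -> float:
        return mcc(self.table)


def loocv(model_fitter, X, y) -> CVResult:
    """Leave-one-out cross-validation of an arbitrary fitter.

    ``model_fitter(X_train, y_train)`` must return an object with a
    ``predict(X)`` method returning labels.  Each subject is predicted by a
    model refitted on the other n−1; folds that lose a class are excluded
    with a warning and counted in ``n_invalid``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = list(y)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    preds, truths = [], []
    per_subject = []
    n_invalid = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = [y[j] for j in range(n) if j != i]
        if len(set(y_tr)) < 2:
            warnings.warn(f"fold {i} lost a class; prediction marked invalid")
            per_subject.append(None)
            n_invalid += 1
            continue
        res = model_fitter(X[mask], y_tr)
        pred = res.predict(X[i:i + 1])[0]
        per_subject.append(pred)
        preds.append(pred)
        truths.append(y[i])
    return CVResult(table=confusion(truths, preds), per_subject=per_subject,
                    n_invalid=n_invalid)
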
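"""Principal-component factor analysis with varimax rotation.

Extraction follows the principal-component method on the correlation matrix
of the 15 pulse amplitudes: factors are eigenvectors scaled by the square
root of their eigenvalues, factors with eigenvalue > 1 are retained (Kaiser
criterion), and the retained loading matrix is varimax-rotated with Kaiser
row normalization.  Per-factor % of variance is eigenvalue/p × 100.

Sampling adequacy uses the Kaiser–Meyer–Olkin index

    KMO = Σ r²_ij / (Σ r²_ij + Σ q²_ij)   (off-diagonal sums)

where q_ij are the anti-image partial correlations, and Bartlett's test of
sphericity

    χ² = −(n − 1 − (2p+5)/6)·ln|R|,   df = p(p−1)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation of a p×m loading matrix.

    Maximizes the variance of squared loadings per factor; returns the
    rotated loadings and the m×m rotation matrix.  Communalities (row sums
    of squared loadings) are preserved exactly by orthogonality.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L, np.eye(m)
    h = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        nonzero = h > 0
        L[nonzero] = L[nonzero] / h[nonzero, None]
    R = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    Lr = L @ R
    if kaiser_normalize:
        Lr = Lr * h[:, None]
    # sign convention: each factor's largest-|loading| entry positive
    signs = np.sign(Lr[np.abs(Lr).argmax(axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    return Lr * signs, R * signs


def _correlation_matrix(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = list(np.nonzero(sd == 0)[0])
        raise ValueError(f"constant columns cannot be correlated: {dead}")
    return np.corrcoef(X, rowvar=False)


def kmo(X=None, *, corr: np.ndarray | None = None) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy in [0, 1].

    Accepts a data matrix or (keyword) a precomputed correlation matrix.
    For two variables with r ≠ 0 the value is exactly 0.5, since the
    bivariate partial correlation equals the correlation itself.
    """
    R = _resolve_corr(X, corr)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular correlation matrix in KMO") from err
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)           # anti-image partial correlations
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    value = float(r2 / (r2 + q2)) if (r2 + q2) > 0 else 0.0
    if value < 0.5:
        warnings.warn(f"KMO = {value:.3f} < 0.5: factor analysis inappropriate")
    return value


def bartlett_sphericity(X=None, *, corr: np.ndarray | None = None,
                        n_obs: int | None = None) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is the identity."""
    R = _resolve_corr(X, corr)
    if n_obs is None:
        if X is None:
            raise ValueError("n_obs is required with a precomputed correlation matrix")
        n_obs = np.asarray(X).shape[0]
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix has non-positive determinant")
    chi2 = -(n_obs - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df=df))


def _resolve_corr(X, corr) -> np.ndarray:
    if (X is None) == (corr is None):
        raise ValueError("pass exactly one of X or corr")
    if corr is not None:
        R = np.asarray(corr, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        return R
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return _correlation_matrix(X)


class FactorAnalysis:
    """Principal-component factor model of a subjects × variables table.

    Either a data matrix ``X`` or a population correlation matrix ``corr``
    (with ``n_obs`` for the tests) can be supplied.
    """

    def __init__(self, X=None, *, corr=None, n_obs: int | None = None,
                 variable_names=None):
        if (X is None) == (corr is None):
            raise ValueError("pass exactly one of X or corr")
        self.X = None if X is None else np.asarray(X, dtype=float)
        if self.X is not None:
            self.n_obs = self.X.shape[0]
            self.corr = _correlation_matrix(self.X)
            if self.n_obs <= self.corr.shape[0]:
                warnings.warn("fewer subjects than variables+1: factor solution "
                              "is degenerate-prone")
        else:
            self.corr = np.asarray(corr, dtype=float)
            self.n_obs = n_obs
        p = self.corr.shape[0]
        self.variable_names = (list(variable_names) if variable_names is not None
                               else [f"v{k+1}" for k in range(p)])

    @classmethod
    def from_dataframe(cls, df, columns) -> "FactorAnalysis":
        columns = list(columns)
        return cls(df[columns].to_numpy(dtype=float), variable_names=columns)

    def fit(self, rotation_tol: float = 1e-8,
            rotation_max_iter: int = 1000) -> "FactorResults":
        R = self.corr
        p = R.shape[0]
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        if eigval[-1] <= 1e-12:
            raise np.linalg.LinAlgError(
                "singular correlation matrix: collinear variables present")
        retained = eigval > 1.0                       # Kaiser criterion
        m = int(retained.sum())
        structureless = m <= 1 and np.allclose(R, np.eye(p), atol=0.2)
        if structureless:
            warnings.warn("correlation structure is near-identity: no factors to extract")
        L_unrotated = eigvec[:, :m] * np.sqrt(eigval[:m]) if m else np.empty((p, 0))
        L_rot, rotmat = varimax(L_unrotated, tol=rotation_tol,
                                max_iter=rotation_max_iter) if m else (L_unrotated, np.eye(0))
        kmo_val = kmo(corr=R)
        bart = (bartlett_sphericity(corr=R, n_obs=self.n_obs)
                if self.n_obs is not None else (np.nan, np.nan))
        return FactorResults(
            model=self, loadings=L_rot, unrotated_loadings=L_unrotated,
            rotation=rotmat, eigenvalues=eigval[:m].copy(),
            all_eigenvalues=eigval.copy(),
            pct_variance=eigval[:m] / p * 100.0, n_factors=m,
            kmo=kmo_val, bartlett_stat=bart[0], bartlett_p=bart[1],
        )


@dataclass
class FactorResults:
    """Retained, varimax-rotated factor solution with adequacy diagnostics."""

    model: FactorAnalysis
    loadings: np.ndarray
    unrotated_loadings: np.ndarray
    rotation: np.ndarray
    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    pct_variance: np.ndarray
    n_factors: int
    kmo: float
    bartlett_stat: float
    bartlett_p: float

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings ** 2).sum(axis=1)

    def variable_assignments(self) -> list[int]:
        """Factor index (0-based) of each variable's max-|loading| factor."""
        if self.n_factors == 0:
            return [-1] * len(self.model.variable_names)
        return list(np.abs(self.loadings).argmax(axis=1))

    def factor_scores(self, X=None) -> np.ndarray:
        """Regression-method factor scores: Z R⁻¹ L on standardized data."""
        X = self.model.X if X is None else np.asarray(X, dtype=float)
        if X is None:
            raise ValueError("factor scores need a data matrix")
        mu = self.model.X.mean(axis=0) if self.model.X is not None else X.mean(axis=0)
        sd = (self.model.X.std(axis=0, ddof=1) if self.model.X is not None
              else X.std(axis=0, ddof=1))
        Z = (X - mu) / sd
        return Z @ np.linalg.solve(self.model.corr, self.loadings)

    def summary(self) -> str:
        lines = [
            "Principal-component factor analysis (varimax rotation)",
            "=" * 56,
            f"variables = {len(self.model.variable_names)}, retained factors "
            f"(eigenvalue > 1) = {self.n_factors}",
            f"KMO = {self.kmo:.3f}   Bartlett chi2 = {self.bartlett_stat:.1f} "
            f"(P = {self.bartlett_p:.3g})",
            f"cumulative % variance = {self.pct_variance.sum():.1f}",
            "",
            f"{'factor':<8}{'eigenvalue':>12}{'% variance':>12}  variables (max loading)",
        ]
        assign = self.variable_assignments()
        for f in range(self.n_factors):
            members = [self.model.variable_names[v]
                       for v in range(len(assign)) if assign[v] == f]
            lines.append(f"f{f+1:<7}{self.eigenvalues[f]:>12.3f}"
                         f"{self.pct_variance[f]:>12.3f}  {', '.join(members)}")
        return "\n".join(lines)


def factor_analysis(X=None, *, corr=None, n_obs=None,
                    variable_names=None) -> FactorResults:
    """Functional facade over :class:`FactorAnalysis`."""
    return FactorAnalysis(X, corr=corr, n_obs=n_obs,
                          variable_names=variable_names).fit()
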
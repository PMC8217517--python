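"""The statistical layer: correlation/regression, two-sample t-test and
exploratory factor analysis (EFA), implemented from first principles.

Only the chi-square and Student-t tail probabilities come from scipy;
every statistic — the product-moment correlation, the pooled/Welch
t-statistic, Bartlett's sphericity chi-square, the Kaiser–Meyer–Olkin
sampling-adequacy index, principal-component factor extraction and the
varimax rotation — is computed here explicitly.

The EFA follows the SPSS-style workflow used for the sperm-beating
variables: Pearson correlation matrix -> KMO (> 0.5 indicates sampling
adequacy) -> Bartlett's test of sphericity (alpha 0.05) -> eigenvalue
extraction (factors retained by the Kaiser eigenvalue-greater-than-1
rule by default; the scree vector is always reported so the count can
be overridden by judgment) -> varimax rotation with Kaiser row
normalization -> loadings flagged as significant when |loading| > 0.40.

The EFA is exposed statsmodels-style: build
``ExploratoryFactorAnalysis(data)`` and call ``fit()`` to obtain an
:class:`EFAResult` with the estimates, diagnostics and a ``summary()``
table. ``run_efa`` is the one-call functional wrapper.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _student_t

__all__ = [
    "CorrelationReport",
    "TTestResult",
    "EFAResult",
    "ExploratoryFactorAnalysis",
    "pearson_regression",
    "ttest2",
    "bartlett_sphericity",
    "kmo",
    "extract_factors",
    "varimax",
    "varimax_criterion",
    "run_efa",
    "p_value_stars",
]

LOADING_THRESHOLD = 0.40

# star conventions used in the reports
_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def p_value_stars(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# correlation / t-test
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    r: float
    r2: float
    slope: float
    intercept: float
    n: int
    p_two_tailed: float

    @property
    def stars(self) -> str:
        return p_value_stars(self.p_two_tailed)


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Pearson correlation R plus least-squares line; two-tailed p from
    the t-distribution with n−2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("constant input vector: correlation undefined")
    sxy = float(dx @ dy)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _student_t.sf(abs(tstat), n - 2))
    return CorrelationReport(r=r, r2=r * r, slope=float(slope),
                             intercept=intercept, n=n, p_two_tailed=p)


@dataclass
class TTestResult:
    t: float
    df: float
    p_two_tailed: float

    @property
    def stars(self) -> str:
        return p_value_stars(self.p_two_tailed)


def ttest2(x: Sequence[float], y: Sequence[float],
           welch: bool = False) -> TTestResult:
    """Unpaired two-tailed t-test (pooled-variance Student by default,
    Welch with ``welch=True``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = float(x.var(ddof=1))
    vy = float(y.var(ddof=1))
    diff = float(x.mean() - y.mean())
    if welch:
        se2 = vx / nx + vy / ny
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1.0 / nx + 1.0 / ny)
        df = nx + ny - 2
    if se2 == 0:
        tstat = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        tstat = diff / np.sqrt(se2)
    p = float(2.0 * _student_t.sf(abs(tstat), df)) if np.isfinite(tstat) else 0.0
    return TTestResult(t=float(tstat), df=float(df), p_two_tailed=p)


# ---------------------------------------------------------------------------
# EFA building blocks
# ---------------------------------------------------------------------------

def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return corr


def bartlett_sphericity(corr: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity on a correlation matrix.

    chi2 = −(n − 1 − (2p + 5)/6) · ln det(corr), df = p(p−1)/2. A
    singular matrix (det ≤ 0) yields chi2 = +inf (flagged, not silent).
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    if n <= p:
        raise ValueError("need n > p observations")
    df = p * (p - 1) // 2
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        warnings.warn("singular correlation matrix: Bartlett chi2 = +inf",
                      UserWarning, stacklevel=2)
        return float("inf"), df, 0.0
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    return float(chi2), df, float(_chi2.sf(chi2, df))


def kmo(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser–Meyer–Olkin sampling adequacy, overall and per variable.

    Partial correlations q_ij come from the inverse correlation matrix;
    KMO = Σr² / (Σr² + Σq²) over off-diagonal entries (> 0.5 indicates
    adequacy). For p = 2 the partial correlation equals the simple one,
    so the overall KMO is exactly 0.5.
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not invertible") from exc
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(p, dtype=bool)
    r2 = corr[off] ** 2
    q2 = partial[off] ** 2
    denom = r2.sum() + q2.sum()
    if denom == 0:
        raise ValueError("KMO undefined: all off-diagonal correlations and "
                         "partials are zero (identity correlation)")
    overall = float(r2.sum() / denom)
    per_var = np.empty(p)
    for j in range(p):
        mask = off[j]
        denom_j = (corr[j, mask] ** 2).sum() + (partial[j, mask] ** 2).sum()
        per_var[j] = np.nan if denom_j == 0 else \
            (corr[j, mask] ** 2).sum() / denom_j
    return overall, per_var


def _sorted_eig(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # orient each eigenvector so its largest-magnitude entry is positive
    for j in range(mat.shape[0]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return eigval, eigvec


def extract_factors(corr: np.ndarray, n_factors: int,
                    method: str = "pca", max_iter: int = 200,
                    tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Factor extraction from a correlation matrix.

    ``method="pca"`` (default): principal-component extraction, column
    j of the loading matrix = eigvec_j·sqrt(eigval_j).
    ``method="paf"``: iterated principal-axis factoring — the diagonal
    is replaced by communalities (initialized from squared multiple
    correlations) and re-estimated until convergence.

    Returns (eigenvalues of the full correlation matrix in descending
    order — the scree vector — and the p×k unrotated loadings).
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    if not 1 <= n_factors <= p:
        raise ValueError(f"n_factors must be in [1, {p}]")
    scree, eigvec = _sorted_eig(corr)
    if method == "pca":
        loadings = eigvec[:, :n_factors] * np.sqrt(
            np.clip(scree[:n_factors], 0.0, None))
        return scree, loadings
    if method != "paf":
        raise ValueError("method must be 'pca' or 'paf'")
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        eigval_r, eigvec_r = _sorted_eig(reduced)
        loadings = eigvec_r[:, :n_factors] * np.sqrt(
            np.clip(eigval_r[:n_factors], 0.0, None))
        h2_new = (loadings ** 2).sum(axis=1)
        if np.max(np.abs(h2_new - h2)) < tol:
            break
        h2 = h2_new
    return scree, loadings


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: summed per-factor variance of squared
    loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    p = L2.shape[0]
    return float(np.sum(L2 ** 2) / p - np.sum((L2.sum(axis=0) / p) ** 2))


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-12,
            kaiser_normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by iterated pairwise planar rotations.

    Kaiser row-normalization is applied before and undone after
    (the SPSS default). Returns (rotated loadings, rotation matrix R)
    with rotated = loadings @ R, R orthogonal. The rotation never
    decreases the varimax criterion and preserves communalities
    (row sums of squared loadings).
    """
    L = np.asarray(loadings, dtype=float).copy()
    if not np.isfinite(L).all():
        raise ValueError("non-finite loadings")
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        return L, R
    if kaiser_normalize:
        h = np.sqrt((L ** 2).sum(axis=1))
        h = np.where(h == 0, 1.0, h)
        L = L / h[:, None]
    for _ in range(max_iter):
        before = varimax_criterion(L)
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = L[:, i], L[:, j]
                u = a ** 2 - b ** 2
                v = 2 * a * b
                A, B = u.sum(), v.sum()
                C = (u ** 2 - v ** 2).sum()
                D = 2 * (u * v).sum()
                num = D - 2 * A * B / p
                den = C - (A ** 2 - B ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        if varimax_criterion(L) - before < tol:
            break
    if kaiser_normalize:
        L = L * h[:, None]
    return L, R


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

@dataclass
class EFAResult:
    """Estimates and diagnostics of a fitted exploratory factor analysis."""

    corr_matrix: np.ndarray
    kmo_overall: float
    kmo_per_variable: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_factors: int
    loadings_unrotated: np.ndarray
    loadings_rotated: np.ndarray
    rotation_matrix: np.ndarray
    var_names: list = field(default_factory=list)
    n_obs: int = 0
    loading_threshold: float = LOADING_THRESHOLD

    @property
    def significant_mask(self) -> np.ndarray:
        """|loading| > threshold on the rotated loadings."""
        return np.abs(self.loadings_rotated) > self.loading_threshold

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings_rotated ** 2).sum(axis=1)

    def summary(self) -> str:
        lines = ["Exploratory factor analysis",
                 "=" * 60,
                 f"observations: {self.n_obs}   variables: "
                 f"{len(self.eigenvalues)}   factors retained: "
                 f"{self.n_factors}",
                 f"KMO sampling adequacy: {self.kmo_overall:.3f} "
                 f"({'adequate' if self.kmo_overall > 0.5 else 'inadequate'})",
                 f"Bartlett sphericity: chi2({self.bartlett_df}) = "
                 f"{self.bartlett_chi2:.2f}, p = {self.bartlett_p:.3g} "
                 f"{p_value_stars(self.bartlett_p)}",
                 f"eigenvalues: " + ", ".join(
                     f"{v:.3f}" for v in self.eigenvalues[:8]) +
                 (" ..." if len(self.eigenvalues) > 8 else ""),
                 "-" * 60,
                 "varimax-rotated loadings "
                 f"(|loading| > {self.loading_threshold:.2f} marked *):"]
        names = self.var_names or [
            f"var{i+1}" for i in range(self.loadings_rotated.shape[0])]
        width = max(len(str(n)) for n in names)
        for name, row, sig in zip(names, self.loadings_rotated,
                                  self.significant_mask):
            cells = " ".join(
                f"{v:7.3f}{'*' if s else ' '}" for v, s in zip(row, sig))
            lines.append(f"  {str(name):<{width}} {cells}")
        return "\n".join(lines)


class ExploratoryFactorAnalysis:
    """EFA model over an n×p table of per-specimen variables.

    Parameters
    ----------
    data
        DataFrame or array, one row per specimen, numeric columns.
    n_factors
        Fixed factor count, or "kaiser" to retain eigenvalues > 1.
    extraction
        "pca" (principal components, the default) or "paf" (iterated
        principal-axis factoring).
    """

    def __init__(self, data, n_factors: int | str = "kaiser",
                 extraction: str = "pca",
                 loading_threshold: float = LOADING_THRESHOLD):
        if isinstance(data, pd.DataFrame):
            self.var_names = [str(c) for c in data.columns]
            mat = data.to_numpy(dtype=float)
        else:
            mat = np.asarray(data, dtype=float)
            self.var_names = [f"var{i+1}" for i in range(mat.shape[1])]
        if mat.ndim != 2:
            raise ValueError("data must be 2-D (specimens × variables)")
        n, p = mat.shape
        if n <= p:
            raise ValueError(f"need more observations than variables "
                             f"(n={n}, p={p})")
        if not np.isfinite(mat).all():
            raise ValueError("data contains non-finite values")
        self.data = mat
        self.n_factors = n_factors
        self.extraction = extraction
        self.loading_threshold = loading_threshold

    def fit(self, kaiser_normalize: bool = True) -> EFAResult:
        n, p = self.data.shape
        corr = np.corrcoef(self.data, rowvar=False)
        kmo_overall, kmo_per = kmo(corr)
        if kmo_overall <= 0.5:
            warnings.warn(f"KMO = {kmo_overall:.3f} <= 0.5: sampling "
                          "adequacy questionable", UserWarning, stacklevel=2)
        chi2, df, bart_p = bartlett_sphericity(corr, n)
        if bart_p >= 0.05:
            warnings.warn(f"Bartlett p = {bart_p:.3g} >= 0.05: variables may "
                          "be uncorrelated", UserWarning, stacklevel=2)
        eigval, _ = extract_factors(corr, p)
        if self.n_factors == "kaiser":
            k = max(1, int(np.sum(eigval > 1.0)))
        else:
            k = int(self.n_factors)
        _, loadings = extract_factors(corr, k, method=self.extraction)
        rotated, R = varimax(loadings, kaiser_normalize=kaiser_normalize)
        return EFAResult(
            corr_matrix=corr, kmo_overall=kmo_overall, kmo_per_variable=kmo_per,
            bartlett_chi2=chi2, bartlett_df=df, bartlett_p=bart_p,
            eigenvalues=eigval, n_factors=k,
            loadings_unrotated=loadings, loadings_rotated=rotated,
            rotation_matrix=R, var_names=self.var_names, n_obs=n,
            loading_threshold=self.loading_threshold)


def run_efa(data, n_factors: int | str = "kaiser") -> EFAResult:
    """One-call EFA pipeline (see :class:`ExploratoryFactorAnalysis`)."""
    return ExploratoryFactorAnalysis(data, n_factors=n_factors).fit()
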
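"""Principal axis factoring with varimax rotation and regression factor scores.

The extraction follows the classical iterated-communalities scheme: the
correlation-matrix diagonal is replaced by communality estimates (initialized
with squared multiple correlations), the reduced matrix is eigendecomposed,
loadings are the top eigenvectors scaled by the square roots of their
eigenvalues, and communalities are re-estimated until they stabilize.
Rotation is varimax with Kaiser normalization; factor scores use the
regression (Thurstone) estimator and are rescaled to unit sample variance so
they can be fed directly to the fixed-coefficient screening equations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd

from .errors import DegenerateInputError
from .reference import FACTOR_NAMES, REFERENCE_LOADINGS, REFERENCE_STARS

__all__ = [
    "Standardizer",
    "standardize",
    "PrincipalAxisFactoring",
    "FactorResults",
    "varimax_rotate",
    "tucker_congruence",
]


class Standardizer:
    """Column z-scoring with retained means/SDs (sample, ddof=1) for reuse."""

    def __init__(self) -> None:
        self.means_: pd.Series | None = None
        self.sds_: pd.Series | None = None

    def fit(self, data: pd.DataFrame) -> "Standardizer":
        data = pd.DataFrame(data)
        if len(data) < 2:
            raise DegenerateInputError("standardization needs at least 2 rows")
        sds = data.std(ddof=1)
        zero = sds[sds == 0]
        if len(zero):
            raise DegenerateInputError(
                f"zero-variance column(s): {', '.join(map(str, zero.index))}"
            )
        self.means_ = data.mean()
        self.sds_ = sds
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise RuntimeError("Standardizer must be fitted first")
        data = pd.DataFrame(data)
        return (data - self.means_) / self.sds_

    def fit_transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return self.fit(data).transform(data)


def standardize(data: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """z-score each column; returns the z matrix and the fitted transform."""
    s = Standardizer()
    return s.fit_transform(data), s


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations from the correlation-matrix inverse."""
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix: using pseudo-inverse for SMC")
        inv = np.linalg.pinv(corr)
    d = np.diag(inv)
    with np.errstate(divide="ignore"):
        smc = 1.0 - 1.0 / d
    return np.clip(smc, 0.0, 1.0)


def varimax_rotate(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation; returns (rotated loadings, rotation matrix).

    With Kaiser normalization each variable's loading row is scaled to unit
    communality before rotation and unscaled after, so every variable weighs
    equally in the criterion.  A single factor rotates by the identity.
    """
    lam = np.asarray(loadings, dtype=float)
    p, m = lam.shape
    if m < 2:
        return lam.copy(), np.eye(m)
    h = np.sqrt((lam**2).sum(axis=1))
    if kaiser_normalize:
        scale = np.where(h > 0, h, 1.0)
    else:
        scale = np.ones(p)
    a = lam / scale[:, None]
    rot = np.eye(m)
    d = 0.0
    for _ in range(max_iter):
        b = a @ rot
        u, s, vt = svd(a.T @ (b**3 - b @ np.diag((b**2).sum(axis=0)) / p))
        rot = u @ vt
        d_new = s.sum()
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    rotated = (a @ rot) * scale[:, None]
    return rotated, rot


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine (Tucker congruence) between two loading vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


@dataclass
class FactorResults:
    """Fitted factor solution: loadings, communalities, variance, scoring."""

    loadings: pd.DataFrame
    unrotated_loadings: pd.DataFrame
    communalities: pd.Series
    variance_explained: pd.Series  # percent of total variance per factor
    rotation_matrix: np.ndarray
    corr: pd.DataFrame
    n_iterations: int
    converged: bool
    heywood: bool
    standardizer: Standardizer | None = None
    factor_names: list[str] = field(default_factory=list)

    @property
    def total_variance_pct(self) -> float:
        return float(self.variance_explained.sum())

    def score(self, data: pd.DataFrame, standardized: bool = False) -> pd.DataFrame:
        """Regression-method factor scores, rescaled to unit sample variance.

        ``data`` is either raw variables (scored through the stored
        standardizer) or an already z-scored matrix (``standardized=True``).
        """
        data = pd.DataFrame(data)
        if standardized or self.standardizer is None:
            z = data[self.loadings.index].to_numpy(dtype=float)
        else:
            z = self.standardizer.transform(data)[self.loadings.index].to_numpy(dtype=float)
        r = self.corr.to_numpy(dtype=float)
        lam = self.loadings.to_numpy(dtype=float)
        try:
            w = np.linalg.solve(r, lam)
        except np.linalg.LinAlgError:
            warnings.warn("singular correlation matrix: ridge-adjusted inverse used")
            w = np.linalg.solve(r + 1e-8 * np.eye(len(r)), lam)
        # Rescale to unit variance: regression scores Zw have sample variance
        # diag(w' R w) on the estimation sample, so this division is exact there.
        sds = np.sqrt(np.clip(np.einsum("ij,ij->j", w, r @ w), 1e-12, None))
        scores = (z @ w) / sds
        return pd.DataFrame(scores, index=data.index, columns=self.loadings.columns)

    def name_factors(
        self,
        reference: pd.DataFrame = REFERENCE_LOADINGS,
        stars: pd.DataFrame = REFERENCE_STARS,
    ) -> "FactorResults":
        """Label factors by congruence with the reference starred pattern.

        Each rotated factor is matched (greedy, highest |congruence| first) to
        the reference factor it resembles most, its sign is flipped so the
        starred loadings are predominantly positive, and columns are reordered
        as trembling/speed/accuracy.  Returns self, mutated.
        """
        common = [v for v in reference.index if v in self.loadings.index]
        ref = reference.loc[common]
        lam = self.loadings.loc[common]
        n_f = lam.shape[1]
        cong = np.zeros((n_f, ref.shape[1]))
        for i in range(n_f):
            for j in range(ref.shape[1]):
                cong[i, j] = tucker_congruence(lam.iloc[:, i], ref.iloc[:, j])
        assignment: dict[int, int] = {}
        flat = sorted(
            ((abs(cong[i, j]), i, j) for i in range(n_f) for j in range(ref.shape[1])),
            reverse=True,
        )
        used_i: set[int] = set()
        used_j: set[int] = set()
        for _, i, j in flat:
            if i in used_i or j in used_j:
                continue
            assignment[i] = j
            used_i.add(i)
            used_j.add(j)
        names = list(ref.columns)
        new_cols = {}
        order = sorted(assignment, key=lambda i: assignment[i])
        signs = {}
        for i, j in assignment.items():
            starred = stars.loc[common].iloc[:, j].to_numpy()
            col = self.loadings.iloc[:, i]
            sign = 1.0 if col.loc[np.asarray(common)[starred]].sum() >= 0 else -1.0
            signs[i] = sign
            new_cols[i] = names[j]
        loadings = self.loadings.copy()
        for i, sign in signs.items():
            loadings.iloc[:, i] = loadings.iloc[:, i] * sign
        loadings = loadings.iloc[:, order]
        loadings.columns = [new_cols[i] for i in order]
        var = self.variance_explained.iloc[order]
        var.index = loadings.columns
        self.loadings = loadings
        self.variance_explained = var
        self.factor_names = list(loadings.columns)
        return self

    def plot_scree(self, ax=None):
        """Scree plot of the reduced-correlation eigenvalues."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.corr.to_numpy(dtype=float).copy()
        np.fill_diagonal(r, self.communalities.to_numpy())
        vals = np.sort(np.linalg.eigvalsh(r))[::-1]
        ax.plot(np.arange(1, len(vals) + 1), vals, "o-")
        ax.set_xlabel("factor")
        ax.set_ylabel("eigenvalue (reduced correlation)")
        ax.axhline(0.0, color="grey", lw=0.5)
        return ax

    def to_dict(self) -> dict:
        return {
            "method": "principal axis factoring, varimax rotation (Kaiser normalization)",
            "converged": self.converged,
            "heywood": self.heywood,
            "n_iterations": self.n_iterations,
            "variance_explained_pct": {
                str(k): float(v) for k, v in self.variance_explained.items()
            },
            "total_variance_pct": self.total_variance_pct,
            "communalities": {str(k): float(v) for k, v in self.communalities.items()},
            "rotated_loadings": {
                str(var): {str(f): float(self.loadings.loc[var, f]) for f in self.loadings.columns}
                for var in self.loadings.index
            },
        }

    def summary(self) -> str:
        lines = [
            "Principal axis factoring (varimax, Kaiser normalization)",
            f"  factors: {', '.join(map(str, self.loadings.columns))}",
            f"  variance explained: "
            + ", ".join(f"{k}={v:.1f}%" for k, v in self.variance_explained.items())
            + f" (total {self.total_variance_pct:.1f}%)",
            f"  converged: {self.converged} ({self.n_iterations} iterations)"
            + ("  [Heywood case clipped]" if self.heywood else ""),
            "",
            self.loadings.round(3).to_string(),
        ]
        return "\n".join(lines)


class PrincipalAxisFactoring:
    """Common-factor model extracted by iterated principal axis factoring.

    Construct from raw data (``data=``, standardized internally) or directly
    from a correlation matrix (``corr=``).
    """

    def __init__(
        self,
        data: pd.DataFrame | None = None,
        corr: pd.DataFrame | np.ndarray | None = None,
        n_factors: int = 3,
        max_iter: int = 100,
        tol: float = 1e-4,
    ) -> None:
        if (data is None) == (corr is None):
            raise ValueError("provide exactly one of data or corr")
        self.standardizer: Standardizer | None = None
        if data is not None:
            data = pd.DataFrame(data)
            z, self.standardizer = standardize(data)
            corr_df = pd.DataFrame(
                np.corrcoef(z.to_numpy(dtype=float), rowvar=False),
                index=data.columns,
                columns=data.columns,
            )
        else:
            corr_df = pd.DataFrame(corr)
            if corr_df.shape[0] != corr_df.shape[1]:
                raise ValueError("correlation matrix must be square")
            if not np.allclose(corr_df, corr_df.T, atol=1e-8):
                raise ValueError("correlation matrix must be symmetric")
        if n_factors >= corr_df.shape[0]:
            raise ValueError("n_factors must be smaller than the number of variables")
        self.corr = corr_df
        self.n_factors = n_factors
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, rotation: str | None = "varimax", kaiser_normalize: bool = True) -> FactorResults:
        r = self.corr.to_numpy(dtype=float).copy()
        p = r.shape[0]
        m = self.n_factors
        h = _smc(r)
        converged = False
        heywood = False
        it = 0
        lam = np.zeros((p, m))
        for it in range(1, self.max_iter + 1):
            reduced = r.copy()
            np.fill_diagonal(reduced, h)
            vals, vecs = eigh(reduced)
            idx = np.argsort(vals)[::-1][:m]
            top_vals = np.clip(vals[idx], 0.0, None)
            lam = vecs[:, idx] * np.sqrt(top_vals)
            h_new = (lam**2).sum(axis=1)
            if np.any(h_new > 1.0):
                heywood = True
                h_new = np.clip(h_new, 0.0, 1.0)
            if np.max(np.abs(h_new - h)) < self.tol:
                h = h_new
                converged = True
                break
            h = h_new
        unrotated = pd.DataFrame(
            lam,
            index=self.corr.index,
            columns=[f"factor{j + 1}" for j in range(m)],
        )
        if rotation == "varimax":
            rot_lam, rot = varimax_rotate(lam, kaiser_normalize=kaiser_normalize)
        elif rotation is None:
            rot_lam, rot = lam.copy(), np.eye(m)
        else:
            raise ValueError(f"unknown rotation: {rotation!r}")
        # Order rotated factors by explained variance, sign so column sums >= 0.
        var = (rot_lam**2).sum(axis=0)
        order = np.argsort(var)[::-1]
        rot_lam = rot_lam[:, order]
        rot = rot[:, order]
        signs = np.where(rot_lam.sum(axis=0) >= 0, 1.0, -1.0)
        rot_lam = rot_lam * signs
        rot = rot * signs
        loadings = pd.DataFrame(
            rot_lam,
            index=self.corr.index,
            columns=[f"factor{j + 1}" for j in range(m)],
        )
        variance = pd.Series(
            (rot_lam**2).sum(axis=0) / p * 100.0, index=loadings.columns
        )
        return FactorResults(
            loadings=loadings,
            unrotated_loadings=unrotated,
            communalities=pd.Series((rot_lam**2).sum(axis=1), index=self.corr.index),
            variance_explained=variance,
            rotation_matrix=rot,
            corr=self.corr,
            n_iterations=it,
            converged=converged,
            heywood=heywood,
            standardizer=self.standardizer,
        )
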
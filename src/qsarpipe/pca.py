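"""Correlation-based principal component analysis for descriptor selection.

PCA is fit on the autoscaled descriptor matrix, i.e. it eigendecomposes the
Pearson correlation matrix, so each principal component's explained variance is
``eigenvalue / m * 100`` percent and the eigenvalues sum to the number of
descriptors.  Loadings follow a deterministic sign convention: each component
is flipped, if necessary, so that its first nonzero entry (in descriptor
order) is positive.  Components are reported both numerically and as rendered
linear-combination equations, the form chemists use to read off which
descriptors drive the separation of potent from less potent compounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .dataset import QSARDataError

__all__ = [
    "PCAModel",
    "fit_pca",
    "variance_table",
    "project_scores",
    "render_pc_equation",
    "parse_pc_equation",
]

_SIGN_TOL = 1e-12


@dataclass
class PCAModel:
    """Eigenstructure of the correlation matrix of an autoscaled matrix.

    ``loadings`` holds orthonormal eigenvectors in columns, eigenvalues sorted
    descending; ``scores`` are the projections of the training rows.
    """

    loadings: np.ndarray  # m x m
    eigenvalues: np.ndarray  # descending
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    scores: np.ndarray  # n x m

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its first entry of non-negligible magnitude is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nonzero = np.nonzero(np.abs(col) > _SIGN_TOL)[0]
        if nonzero.size and col[nonzero[0]] < 0:
            out[:, j] = -col
    return out


def fit_pca(scaled_matrix: np.ndarray) -> PCAModel:
    """Eigendecompose the correlation matrix of an autoscaled n x m matrix.

    The input is expected column-standardized (sample n-1 convention), so
    ``X'X / (n-1)`` is the Pearson correlation matrix and the eigenvalues sum
    to m.  Scores are ``X @ loadings``.
    """
    x = np.asarray(scaled_matrix, dtype=float)
    if x.ndim != 2:
        raise QSARDataError("expected a 2-D matrix")
    if not np.all(np.isfinite(x)):
        raise QSARDataError("non-finite entries in input matrix")
    n, m = x.shape
    if n < 2 or m < 1:
        raise QSARDataError(f"need n >= 2 and m >= 1, got {n} x {m}")
    corr = x.T @ x / (n - 1)
    eigenvalues, vectors = scipy.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.maximum(eigenvalues[order], 0.0)
    loadings = _fix_signs(vectors[:, order])
    explained = eigenvalues / m * 100.0
    return PCAModel(
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        scores=x @ loadings,
    )


def variance_table(model: PCAModel, n_components: int | None = None) -> pd.DataFrame:
    """Explained and cumulative variance percentages for PC1..PCk."""
    m = model.n_features
    k = m if n_components is None else n_components
    if not 1 <= k <= m:
        raise QSARDataError(f"n_components must lie in [1, {m}], got {k}")
    return pd.DataFrame(
        {
            "pc": [f"PC{i + 1}" for i in range(k)],
            "explained_pct": model.explained_pct[:k],
            "cumulative_pct": model.cumulative_pct[:k],
        }
    )


def project_scores(model: PCAModel, scaled_new: np.ndarray) -> np.ndarray:
    """Project new autoscaled rows onto the model's components."""
    x = np.asarray(scaled_new, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if x.shape[1] != model.n_features:
        raise QSARDataError(
            f"matrix has {x.shape[1]} columns, model expects {model.n_features}"
        )
    return x @ model.loadings


def render_pc_equation(
    model: PCAModel, pc_index: int, names: list[str] | None = None
) -> str:
    """Format one component as a signed linear combination, e.g.

    ``PC1 = 0.4232*ALOGPS_logs + 0.5937*Mor29m - 0.6223*IC5 - 0.2845*GAP_energy``

    Coefficients are printed to 4 decimal places; zero loadings are retained.
    """
    m = model.n_features
    if not 0 <= pc_index < m:
        raise QSARDataError(f"pc_index must lie in [0, {m - 1}], got {pc_index}")
    if names is None:
        names = [f"x{j + 1}" for j in range(m)]
    if len(names) != m:
        raise QSARDataError(f"expected {m} names, got {len(names)}")
    parts = []
    for j, name in enumerate(names):
        coef = model.loadings[j, pc_index]
        sign = "-" if coef < 0 else "+"
        term = f"{abs(coef):.4f}*{name}"
        if j == 0:
            parts.append(term if sign == "+" else f"-{term}")
        else:
            parts.append(f"{sign} {term}")
    return f"PC{pc_index + 1} = " + " ".join(parts)


_TERM_RE = re.compile(r"([+-]?)\s*(\d+\.\d+)\*(\S+)")


def parse_pc_equation(equation: str) -> dict[str, float]:
    """Invert :func:`render_pc_equation`: name -> signed coefficient."""
    rhs = equation.split("=", 1)[1]
    out: dict[str, float] = {}
    for sign, mag, name in _TERM_RE.findall(rhs):
        out[name] = float(mag) * (-1.0 if sign == "-" else 1.0)
    return out
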
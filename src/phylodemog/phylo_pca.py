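"""Phylogenetic principal component analysis (PPCA).

Ordinary PCA treats observations as independent; for genus-level traits the
phylogeny induces correlation between rows. PPCA removes the GLS
phylogenetic mean and eigen-decomposes the evolutionary covariance

    a = (1' C^-1 1)^-1 1' C^-1 Z
    S = (Z - 1a)' C^-1 (Z - 1a) / (n - 1)

where C is the phylogenetic covariance of the genera and Z the standardized
genus x trait matrix. With C = I this reduces exactly to ordinary PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .phylo_signal import PhyloCovariance

__all__ = ["PPCAResult", "standardize_traits", "ppca"]


@dataclass
class PPCAResult:
    loadings: pd.DataFrame  # trait x axis, columns PC1..PCk, unit norm
    scores: pd.DataFrame  # genus x axis
    eigenvalues: np.ndarray  # non-increasing
    proportion_variance: np.ndarray  # sums to 1
    n_genera: int
    traits_used: tuple[str, ...]


def standardize_traits(X: pd.DataFrame) -> pd.DataFrame:
    """Scale each trait column to mean 0, unit sample variance (ddof=1).

    Requires a complete matrix: genera with any missing trait must be
    dropped upstream. Raises on a constant column.
    """
    if X.isna().any().any():
        raise ValueError("trait matrix contains missing cells; keep complete-trait genera only")
    sd = X.std(ddof=1)
    bad = sd[(sd == 0) | ~np.isfinite(sd)].index.tolist()
    if bad:
        raise ValueError(f"constant or degenerate trait column(s): {bad}")
    return (X - X.mean()) / sd


def ppca(Z: pd.DataFrame, C: PhyloCovariance) -> PPCAResult:
    """Phylogenetic PCA of standardized traits ``Z`` on covariance ``C``.

    Rows of ``Z`` are matched to C's tips by index label. Loadings columns
    are unit-norm with the sign fixed so each column's largest-magnitude
    element is positive; scores are the GLS-centred data projected on the
    loadings.
    """
    n, p = Z.shape
    if p > n:
        raise ValueError(f"more traits ({p}) than genera ({n})")
    missing = [g for g in Z.index if g not in C.labels]
    if missing:
        raise KeyError(f"genera absent from phylogeny: {missing[:5]}")
    Cm = C.subset(list(Z.index)).matrix
    try:
        fac = cho_factor(Cm, lower=True)
    except LinAlgError as err:
        raise ValueError("singular phylogenetic covariance") from err

    Zv = Z.to_numpy(dtype=float)
    ones = np.ones(n)
    Ci1 = cho_solve(fac, ones)
    s11 = ones @ Ci1
    a = (Ci1 @ Zv) / s11  # phylogenetic mean per trait
    R = Zv - a
    S = R.T @ cho_solve(fac, R) / (n - 1)

    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    V = eigvec[:, order]
    # sign convention: largest-|.| element of each column positive
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]

    axes = [f"PC{j + 1}" for j in range(p)]
    scores = R @ V
    total = eigval.sum()
    return PPCAResult(
        loadings=pd.DataFrame(V, index=Z.columns, columns=axes),
        scores=pd.DataFrame(scores, index=Z.index, columns=axes),
        eigenvalues=eigval,
        proportion_variance=eigval / total,
        n_genera=n,
        traits_used=tuple(Z.columns),
    )
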
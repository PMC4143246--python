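"""Principal coordinate analysis (classical metric MDS) of a DA matrix.

Gower double-centering of -D^2/2, eigendecomposition, coordinates scaled by
the square roots of the positive eigenvalues.  DA matrices are generally
non-Euclidean, so negative eigenvalues can occur; they are reported but
excluded from the percent-variance denominator (plain ratios of positive
eigenvalues; no Cailliez/Lingoes correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .distance import DistanceMatrix


@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray  # n x k_retained
    eigenvalues: np.ndarray  # all n, descending (negatives included)
    percent_variance: np.ndarray  # for retained axes, over positive eigenvalues

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)

    def eigen_frame(self) -> pd.DataFrame:
        pos = self.eigenvalues[self.eigenvalues > 0].sum()
        pct = np.where(self.eigenvalues > 0, 100.0 * self.eigenvalues / pos, np.nan)
        return pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "percent_variance": pct},
            index=[f"axis{i + 1}" for i in range(len(self.eigenvalues))],
        )


def pcoa(
    dm: DistanceMatrix, k: int = 3, cailliez: bool = False, eps: float = 1e-10
) -> PCoAResult:
    """Principal coordinates of a symmetric zero-diagonal distance matrix.

    Axes are ordered by descending eigenvalue; at most ``k`` axes with
    positive eigenvalues are retained.  Axis signs are fixed by making the
    largest-magnitude coordinate of each axis positive.  ``cailliez``
    applies the additive constant correction that makes the matrix
    Euclidean before decomposing.
    """
    D = np.asarray(dm.d, dtype=float)
    n = D.shape[0]
    if k > n - 1:
        raise ValueError(f"k = {k} must be <= n - 1 = {n - 1}")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distances must be non-negative with a zero diagonal")

    if cailliez:
        D = D + _cailliez_constant(D) * (1 - np.eye(n))

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps * max(abs(evals[0]), 1.0)
    n_keep = min(k, int(pos.sum()))
    coords = evecs[:, :n_keep] * np.sqrt(evals[:n_keep])
    # deterministic axis orientation
    for c in range(n_keep):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    pos_sum = evals[pos].sum()
    pct = 100.0 * evals[:n_keep] / pos_sum if pos_sum > 0 else np.zeros(n_keep)
    return PCoAResult(
        labels=list(dm.labels),
        coordinates=coords,
        eigenvalues=evals,
        percent_variance=pct,
    )


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D Euclidean (Cailliez 1983)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    F1 = -0.5 * J @ (D ** 2) @ J
    F2 = -0.5 * J @ D @ J
    zero = np.zeros((n, n))
    eye = np.eye(n)
    M = np.block([[zero, 2 * F1], [-eye, -4 * F2]])
    evals = np.linalg.eigvals(M)
    return float(max(evals.real.max(), 0.0))
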
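"""Shannon and von Neumann entropy machinery.

The similarity-aware mutual-information score of a column pair (k, l) is

    U_vNE(k, l) = (vNE(rho_k) + vNE(rho_l) - vNE(rho_kl)) / (vNE(rho_k) + vNE(rho_l))

where rho_kl = sqrt(P) A sqrt(P) is a 400x400 density matrix built from the
joint pair probabilities P = diag(p_1 … p_400) and the pair-similarity
matrix A, and rho_k, rho_l are its 20x20 partial traces. With A = I the
density matrix is diagonal and every von Neumann entropy reduces to the
Shannon entropy of the corresponding distribution.

All entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import ColumnPairDistribution
from .errors import MatrixValidationError
from .pair_similarity import SimilarityMatrix

#: Eigenvalues above this negative tolerance are treated as rounding noise.
EIG_TOL = 1e-8

_TRACE_TOL = 1e-10
_SYM_TOL = 1e-10


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability vector summing to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _entropy_of_eigenvalues(lam: np.ndarray) -> float:
    low = lam.min() if lam.size else 0.0
    if low < -EIG_TOL:
        raise MatrixValidationError(
            f"density matrix has eigenvalue {low:.3e} < -{EIG_TOL:.0e}; "
            "the similarity matrix is not positive semi-definite"
        )
    lam = np.clip(lam, 0.0, 1.0)
    nz = lam[lam > 0]
    return float(-(nz * np.log(nz)).sum())


class DensityMatrix:
    """A 400x400 density matrix rho_kl with cached eigenvalues."""

    dim = 400

    def __init__(self, matrix: np.ndarray, check: bool = True):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.dim, self.dim):
            raise MatrixValidationError(
                f"expected {self.dim}x{self.dim} matrix, got {matrix.shape}"
            )
        if check:
            if abs(np.trace(matrix) - 1.0) > _TRACE_TOL:
                raise MatrixValidationError(
                    f"trace {np.trace(matrix)!r} deviates from 1"
                )
            if np.abs(matrix - matrix.T).max() > _SYM_TOL:
                raise MatrixValidationError("matrix is not symmetric")
        self.matrix = matrix
        self._eigenvalues: np.ndarray | None = None

    @property
    def eigenvalues(self) -> np.ndarray:
        if self._eigenvalues is None:
            self._eigenvalues = np.linalg.eigvalsh(self.matrix)
        return self._eigenvalues


class MarginalDensity(DensityMatrix):
    """A 20x20 partial-trace density matrix (rho_k or rho_l)."""

    dim = 20

    def __init__(self, matrix: np.ndarray, position: str, check: bool = True):
        super().__init__(matrix, check=check)
        if position not in ("first", "second"):
            raise ValueError("position must be 'first' or 'second'")
        self.position = position


@dataclass
class EntropyReport:
    """All entropy terms of one column pair, in nats."""

    k: int
    l: int
    h_k: float
    h_l: float
    h_kl: float
    u_shannon: float
    vne_k: float
    vne_l: float
    vne_kl: float
    u_vne: float


def u_shannon(dist: ColumnPairDistribution) -> float:
    """Normalized Shannon mutual information 2(H(k)+H(l)-H(k,l))/(H(k)+H(l)).

    Returns 0 by convention when both columns are fully conserved.
    """
    pk, pl = dist.marginals()
    h_k, h_l = shannon_entropy(pk), shannon_entropy(pl)
    if h_k + h_l == 0.0:
        return 0.0
    h_kl = shannon_entropy(dist.p)
    return 2.0 * (h_k + h_l - h_kl) / (h_k + h_l)


def density_matrix(dist: ColumnPairDistribution, A: SimilarityMatrix) -> DensityMatrix:
    """rho_kl = sqrt(P) A sqrt(P) with P = diag of the pair probabilities."""
    A.validate()
    sp = np.sqrt(dist.p)
    return DensityMatrix(sp[:, None] * A.values * sp[None, :])


def partial_trace(rho: DensityMatrix, position: str) -> MarginalDensity:
    """Trace out one column of a joint density matrix.

    ``position='first'`` keeps the first column's subsystem:
    s_ij = sum_u r[(i,u),(j,u)]; ``'second'`` keeps the second:
    t_ij = sum_u r[(u,i),(u,j)].
    """
    r4 = rho.matrix.reshape(20, 20, 20, 20)
    if position == "first":
        out = np.einsum("iuju->ij", r4)
    elif position == "second":
        out = np.einsum("uiuj->ij", r4)
    else:
        raise ValueError("position must be 'first' or 'second'")
    return MarginalDensity(out, position)


def von_neumann_entropy(rho: DensityMatrix | np.ndarray) -> float:
    """-sum lambda ln lambda over the eigenvalues of a density matrix."""
    if isinstance(rho, DensityMatrix):
        lam = rho.eigenvalues
    else:
        lam = np.linalg.eigvalsh(np.asarray(rho, dtype=float))
    return _entropy_of_eigenvalues(lam)


def renyi_entropy(rho: DensityMatrix, alpha: float) -> float:
    """alpha-Renyi entropy (1/(1-alpha)) ln sum lambda^alpha.

    For alpha = 2 the eigenvalue decomposition is bypassed: the sum of
    squared eigenvalues equals trace(rho^2), i.e. the squared Frobenius
    norm of the symmetric matrix.
    """
    if alpha <= 0 or alpha == 1:
        raise ValueError("alpha must be positive and different from 1")
    if alpha == 2:
        purity = float(np.sum(rho.matrix * rho.matrix))
        return -float(np.log(purity))
    lam = np.clip(rho.eigenvalues, 0.0, 1.0)
    lam = lam[lam > 0]
    return float(np.log(np.sum(lam**alpha)) / (1.0 - alpha))


def _vne_terms(p: np.ndarray, a_values: np.ndarray) -> tuple[float, float, float]:
    """(vNE(rho_kl), vNE(rho_k), vNE(rho_l)) via the support of p.

    States with zero probability contribute zero rows/columns to rho_kl,
    so the spectrum is that of the submatrix restricted to the support —
    this keeps the eigensolve at the number of observed pair states
    instead of 400.
    """
    support = np.flatnonzero(p > 0.0)
    sp = np.sqrt(p[support])
    rho = sp[:, None] * a_values[np.ix_(support, support)] * sp[None, :]
    v_joint = _entropy_of_eigenvalues(np.linalg.eigvalsh(rho))

    i_idx = support // 20
    u_idx = support % 20
    s = np.zeros((20, 20))
    t = np.zeros((20, 20))
    rows, cols = np.nonzero(u_idx[:, None] == u_idx[None, :])
    np.add.at(s, (i_idx[rows], i_idx[cols]), rho[rows, cols])
    rows, cols = np.nonzero(i_idx[:, None] == i_idx[None, :])
    np.add.at(t, (u_idx[rows], u_idx[cols]), rho[rows, cols])
    v_k = _entropy_of_eigenvalues(np.linalg.eigvalsh(s))
    v_l = _entropy_of_eigenvalues(np.linalg.eigvalsh(t))
    return v_joint, v_k, v_l


def _u_vne_from_terms(v_joint: float, v_k: float, v_l: float) -> float:
    denom = v_k + v_l
    if denom == 0.0:
        return 0.0
    u = (denom - v_joint) / denom
    if u < 0.0:
        # subadditivity guarantees u >= 0; tiny negatives are rounding noise
        if u < -EIG_TOL:
            raise MatrixValidationError(f"U_vNE = {u:.3e} violates subadditivity")
        u = 0.0
    return u


def u_vne_value(p: np.ndarray, a_values: np.ndarray) -> float:
    """U_vNE from a 400-vector of pair probabilities and raw matrix values."""
    return _u_vne_from_terms(*_vne_terms(p, a_values))


def u_vne(dist: ColumnPairDistribution, A: SimilarityMatrix) -> EntropyReport:
    """Full entropy report for one column pair under similarity matrix A."""
    A.validate()
    v_joint, v_k, v_l = _vne_terms(dist.p, A.values)
    pk, pl = dist.marginals()
    h_k, h_l = shannon_entropy(pk), shannon_entropy(pl)
    h_kl = shannon_entropy(dist.p)
    u_sh = 0.0 if h_k + h_l == 0 else 2.0 * (h_k + h_l - h_kl) / (h_k + h_l)
    return EntropyReport(
        k=dist.k, l=dist.l,
        h_k=h_k, h_l=h_l, h_kl=h_kl, u_shannon=u_sh,
        vne_k=v_k, vne_l=v_l, vne_kl=v_joint,
        u_vne=_u_vne_from_terms(v_joint, v_k, v_l),
    )
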
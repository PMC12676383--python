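"""Distance-based decoding of reconstructed bit sequences.

The K-bit reconstruction network outputs a vector ``y_hat in [0,1]^K`` per
trial; the decoded class is the code-bank row closest to it under one of
four dissimilarities:

* squared Euclidean distance (the square root is omitted — it does not
  change the argmin);
* Mahalanobis distance under a shrinkage-regularized covariance
  ``Sigma_reg = (1 - lambda) Sigma + lambda alpha I`` with ``lambda = 0.1``
  and ``alpha`` the mean diagonal of ``Sigma``;
* 1-D Earth Mover's Distance in its cumulative-distribution form,
  ``d = mean_k |CDF_p(k) - CDF_q(k)|``, after clipping/normalizing both
  vectors to probability mass functions;
* radius-constrained EMD: the minimum-cost transport plan with mass
  movement forbidden beyond ``R`` bit positions, solved as a linear
  program (dual simplex).  An infeasible problem means no admissible local
  transport exists and yields distance +inf, not an error.

Both Euclidean and Mahalanobis accept the raw sigmoid outputs by default;
a 0.5-threshold option binarizes first (ranking-equivalent in the clean
case, lossy otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, sparse

from .codes import CodeBank
from .nets import Reconstruction

__all__ = [
    "DistanceMatrix",
    "ShrinkageConfig",
    "TransportPlan",
    "euclidean_decode",
    "mahalanobis_decode",
    "normalize_pmf",
    "emd_cdf",
    "emd_decode",
    "constrained_emd",
    "cemd_decode",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Trials x classes dissimilarities; +inf marks infeasible transport."""

    D: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=np.float64)
        if np.isnan(D).any():
            raise ValueError("distance matrix contains NaN")
        if (D < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "D", np.maximum(D, 0.0))

    def labels(self) -> np.ndarray:
        """Argmin labels (1-based); ties broken toward the lowest class index."""
        return np.argmin(self.D, axis=1) + 1


@dataclass(frozen=True)
class ShrinkageConfig:
    """Covariance shrinkage: Sigma_reg = (1-lambda) Sigma + lambda alpha I."""

    lambda_shrink: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_shrink <= 1.0:
            raise ValueError("lambda_shrink must lie in [0, 1]")


@dataclass(frozen=True)
class TransportPlan:
    """A K x K nonnegative flow matrix satisfying both marginals."""

    X: np.ndarray
    radius: int
    cost: float


def _prep(recon: Reconstruction | np.ndarray) -> np.ndarray:
    y = recon.y_hat if isinstance(recon, Reconstruction) else np.asarray(recon, float)
    return np.atleast_2d(y)


def euclidean_decode(
    recon: Reconstruction | np.ndarray,
    bank: CodeBank,
    threshold: bool = False,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Squared Euclidean distance to each code row; argmin labels."""
    Y = _prep(recon)
    if Y.shape[1] != bank.K:
        raise ValueError(f"reconstruction K={Y.shape[1]} != bank K={bank.K}")
    if threshold:
        Y = (Y >= 0.5).astype(np.float64)
    C = bank.codes.astype(np.float64)
    D = ((Y[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    dm = DistanceMatrix(D=D, metric="euclidean")
    return dm, dm.labels()


def mahalanobis_decode(
    recon: Reconstruction | np.ndarray,
    bank: CodeBank,
    cfg: ShrinkageConfig = ShrinkageConfig(),
    cov_source: Reconstruction | np.ndarray | None = None,
    threshold: bool = False,
    sigma: np.ndarray | None = None,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Shrinkage-Mahalanobis distance to each code row.

    The covariance is estimated from ``cov_source`` (default: the decoded
    reconstructions themselves, which is transductive, so callers normally
    pass training-set reconstructions here) and regularized as
    ``(1-lambda) Sigma + lambda alpha I`` with alpha = mean(diag(Sigma)).
    ``sigma`` injects a known covariance directly, bypassing estimation.
    """
    Y = _prep(recon)
    if threshold:
        Y = (Y >= 0.5).astype(np.float64)
    if sigma is not None:
        Sigma = np.asarray(sigma, dtype=np.float64)
    else:
        src = _prep(cov_source) if cov_source is not None else Y
        if src.shape[0] < 2:
            raise ValueError("covariance source needs >= 2 rows")
        Sigma = np.cov(src, rowvar=False)
    alpha = float(np.mean(np.diag(Sigma)))
    K = Y.shape[1]
    Sigma_reg = (1.0 - cfg.lambda_shrink) * Sigma + cfg.lambda_shrink * alpha * np.eye(K)
    try:
        L = np.linalg.cholesky(Sigma_reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized covariance is numerically singular"
        ) from exc
    C = bank.codes.astype(np.float64)
    diffs = Y[:, None, :] - C[None, :, :]  # (n, classes, K)
    sol = np.linalg.solve(L, diffs.reshape(-1, K).T)  # (K, n*classes)
    D = (sol**2).sum(axis=0).reshape(Y.shape[0], bank.n_classes)
    dm = DistanceMatrix(D=D, metric="mahalanobis")
    return dm, dm.labels()


def normalize_pmf(v: np.ndarray) -> np.ndarray:
    """Clip at zero and normalize to a probability mass function."""
    v = np.asarray(v, dtype=np.float64)
    pos = np.maximum(v, 0.0)
    total = pos.sum()
    if total <= 0:
        raise ValueError("degenerate PMF: no positive mass after clipping")
    return pos / total


def emd_cdf(p: np.ndarray, q: np.ndarray) -> float:
    """1-D EMD in CDF form, normalized by K: mean_k |CDF_p(k) - CDF_q(k)|."""
    return float(np.mean(np.abs(np.cumsum(p - q))))


def emd_decode(
    recon: Reconstruction | np.ndarray, bank: CodeBank
) -> tuple[DistanceMatrix, np.ndarray]:
    """Unconstrained EMD between trial PMFs and code-row PMFs; argmin labels."""
    Y = _prep(recon)
    Q = np.stack([normalize_pmf(row) for row in bank.codes.astype(np.float64)])
    D = np.empty((Y.shape[0], bank.n_classes))
    for i in range(Y.shape[0]):
        p = normalize_pmf(Y[i])
        for c in range(bank.n_classes):
            D[i, c] = emd_cdf(p, Q[c])
    dm = DistanceMatrix(D=D, metric="emd")
    return dm, dm.labels()


def constrained_emd(
    p: np.ndarray, q: np.ndarray, R: int
) -> tuple[float, TransportPlan | None]:
    """Minimum-cost transport between PMFs with movement limited to R bits.

    Minimizes sum_{k,j} |k-j| X_kj subject to row sums = p, column sums = q
    and X_kj = 0 for |k-j| > R, via linear programming (dual simplex).
    Returns (cost, plan); infeasible problems return (inf, None) — mass
    would have to move farther than R, so the pair is deemed maximally
    dissimilar.  Cost is normalized by the total flow (1 for PMFs).
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if R < 0:
        raise ValueError("R must be >= 0")
    K = p.size
    if q.size != K:
        raise ValueError("PMFs must share length")
    # variables: banded entries X_kj with |k-j| <= R only
    rows_k, cols_j = [], []
    for k in range(K):
        lo, hi = max(0, k - R), min(K - 1, k + R)
        for j in range(lo, hi + 1):
            rows_k.append(k)
            cols_j.append(j)
    rows_k = np.array(rows_k)
    cols_j = np.array(cols_j)
    n_var = rows_k.size
    cost_vec = np.abs(rows_k - cols_j).astype(np.float64)
    # equality constraints: K row-marginals + K column-marginals
    var_idx = np.arange(n_var)
    A = sparse.coo_matrix(
        (
            np.ones(2 * n_var),
            (
                np.concatenate([rows_k, K + cols_j]),
                np.concatenate([var_idx, var_idx]),
            ),
        ),
        shape=(2 * K, n_var),
    ).tocsr()
    b = np.concatenate([p, q])
    res = optimize.linprog(
        cost_vec, A_eq=A, b_eq=b, bounds=(0, None), method="highs-ds"
    )
    if not res.success:
        return float("inf"), None
    X = np.zeros((K, K))
    X[rows_k, cols_j] = res.x
    total_flow = X.sum()
    cost = float(res.fun / total_flow) if total_flow > 0 else 0.0
    return cost, TransportPlan(X=X, radius=R, cost=cost)


def cemd_decode(
    recon: Reconstruction | np.ndarray,
    bank: CodeBank,
    R: int = 8,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Constrained-EMD decoding; +inf classes are excluded from the argmin.

    If every class is infeasible for a trial the decoder falls back to the
    unconstrained EMD for that trial (logged).
    """
    Y = _prep(recon)
    Q = np.stack([normalize_pmf(row) for row in bank.codes.astype(np.float64)])
    D = np.empty((Y.shape[0], bank.n_classes))
    labels = np.empty(Y.shape[0], dtype=np.int64)
    for i in range(Y.shape[0]):
        p = normalize_pmf(Y[i])
        for c in range(bank.n_classes):
            D[i, c], _ = constrained_emd(p, Q[c], R)
        if np.isinf(D[i]).all():
            logger.warning(
                "trial %d: all classes infeasible at R=%d; "
                "falling back to unconstrained EMD", i, R,
            )
            labels[i] = int(np.argmin([emd_cdf(p, Q[c]) for c in range(bank.n_classes)])) + 1
        else:
            labels[i] = int(np.argmin(D[i])) + 1
    return DistanceMatrix(D=D, metric=f"cemd(R={R})"), labels
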
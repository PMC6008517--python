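"""Probability-of-superiority (PS) statistics and PS-based moment matrices.

The probability of superiority between two paired continuous variables is
the probability that an observation falling above the mean on one variable
also falls above the mean on the other (or below on both).  A value of 0.5
encodes no association; 0 and 1 encode perfect discordance/concordance.
For a bivariate normal pair with correlation ``r`` the population PS is the
orthant probability ``asin(r)/pi + 0.5``.

This module provides the r<->PS conversions, the sample PS statistic with
its half-count tie rule, the group (common-language) PS, and construction
of Pearson- and PS-based observed moment matrices suitable as input to the
SEM estimators in :mod:`pssem.sem_engine`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PSDomainError",
    "SampleMatrix",
    "GroupSummary",
    "r_to_ps",
    "ps_to_r",
    "sample_ps",
    "sign_pattern",
    "group_ps",
    "pearson_matrix",
    "ps_matrix",
    "ensure_estimable",
    "write_matrix",
    "read_matrix",
]

#: Relative tolerance (times the column SD) below which a centered score is
#: treated as lying exactly at the mean when counting ties.
TIE_RTOL = 1e-12

#: Default eigenvalue floor used by :func:`ensure_estimable`.
EIGEN_FLOOR = 1e-6


class PSDomainError(ValueError):
    """Raised when an argument lies outside the PS/correlation domain."""


@dataclass
class GroupSummary:
    """Sufficient statistics of two independent groups on one variable."""

    mean1: float
    mean2: float
    var1: float
    var2: float


@dataclass
class SampleMatrix:
    """A symmetric observed moment matrix with provenance.

    ``kind`` is ``"pearson"`` for a conventional covariance/correlation
    matrix and ``"ps"`` for a PS-based matrix whose off-diagonal elements
    are ``pi_jk * sqrt(Var_j * Var_k)`` with ``pi_jk`` in [0, 1].
    """

    values: np.ndarray
    n: int
    kind: str
    labels: list[str]
    as_correlation: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("diagonal variances must be positive")
        if self.kind not in ("pearson", "ps"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_correlation(self) -> "SampleMatrix":
        """Rescale to unit diagonal (PS off-diagonals become raw pi values)."""
        d = np.sqrt(self.variances)
        vals = self.values / np.outer(d, d)
        np.fill_diagonal(vals, 1.0)
        return SampleMatrix(vals, self.n, self.kind, list(self.labels),
                            as_correlation=True, warnings=list(self.warnings))


def r_to_ps(r):
    """Convert Pearson's correlation to a probability of superiority.

    Uses the arcsine law ``pi_r = asin(r)/pi + 0.5``, the orthant
    probability of a bivariate normal pair: e.g. r = 0.40 -> 0.631.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise PSDomainError("correlation must lie in [-1, 1]")
    out = np.arcsin(r) / np.pi + 0.5
    return float(out) if out.ndim == 0 else out


def ps_to_r(ps):
    """Analytic inverse of :func:`r_to_ps`: ``r = sin(pi * (ps - 0.5))``."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise PSDomainError("PS must lie in [0, 1]")
    out = np.sin(np.pi * (ps - 0.5))
    return float(out) if out.ndim == 0 else out


def sign_pattern(x: np.ndarray) -> np.ndarray:
    """Column-wise sign of deviations from the column mean.

    Deviations within ``TIE_RTOL * sd`` of zero are coded 0 (a tie).  This
    relative guard matters for discrete scores where centering in floating
    point need not be exact.
    """
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=0)
    sd = x.std(axis=0)
    tol = TIE_RTOL * np.where(sd > 0, sd, 1.0)
    s = np.sign(centered)
    s[np.abs(centered) <= tol] = 0.0
    return s


def sample_ps(x, y) -> float:
    """Sample probability of superiority between two paired vectors.

    Counts pairs on the same side of their respective means, plus half a
    count for pairs at both means exactly; pairs with exactly one
    coordinate at its mean contribute nothing.  Division is by the total
    number of pairs ``n``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: every pair ties, PS = 0.5", stacklevel=2)
        return 0.5
    s = sign_pattern(np.column_stack([x, y]))
    sx, sy = s[:, 0], s[:, 1]
    concordant = np.count_nonzero(sx * sy > 0)
    double_tie = np.count_nonzero((sx == 0) & (sy == 0))
    return (concordant + 0.5 * double_tie) / n


def group_ps(g: GroupSummary) -> float:
    """Common-language effect size P(X1 > X2) for two normal groups.

    ``Phi((mean1 - mean2) / sqrt(var1 + var2))``.
    """
    if g.var1 <= 0 or g.var2 <= 0:
        raise ValueError("group variances must be positive")
    return float(norm.cdf((g.mean1 - g.mean2) / np.sqrt(g.var1 + g.var2)))


def _as_frame(data, columns=None) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data if columns is None else data[list(columns)]
    else:
        arr = np.asarray(data, dtype=float)
        df = pd.DataFrame(arr, columns=[f"y{j + 1}" for j in range(arr.shape[1])])
    return df


def _check_table(df: pd.DataFrame) -> None:
    n, p = df.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 observations on at least 2 columns")
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant column(s): {const}")


def pearson_matrix(data, columns=None) -> SampleMatrix:
    """Conventional covariance matrix (n-1 denominator) of a data table."""
    df = _as_frame(data, columns)
    _check_table(df)
    cov = np.cov(df.to_numpy(dtype=float), rowvar=False, ddof=1)
    return SampleMatrix(cov, len(df), "pearson", list(map(str, df.columns)))


def ps_matrix(data, as_correlation: bool = False, columns=None) -> SampleMatrix:
    """PS-based observed moment matrix.

    Diagonal holds the (n-1) sample variances; off-diagonal (j, k) holds
    ``sample_ps(col_j, col_k) * sqrt(Var_j * Var_k)``.  With
    ``as_correlation=True`` the variances are rescaled to 1 so the
    off-diagonals are the raw PS values.  Note that under independence the
    off-diagonals sit near ``0.5 * sqrt(Var_j * Var_k)``, not zero.
    """
    df = _as_frame(data, columns)
    _check_table(df)
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    s = sign_pattern(x)
    pos = (s > 0).astype(float)
    neg = (s < 0).astype(float)
    tie = (s == 0).astype(float)
    # pairwise counts in one pass: concordant + half the double ties
    pi = (pos.T @ pos + neg.T @ neg + 0.5 * (tie.T @ tie)) / n
    var = x.var(axis=0, ddof=1)
    if as_correlation:
        vals = pi.copy()
        np.fill_diagonal(vals, 1.0)
    else:
        scale = np.sqrt(np.outer(var, var))
        vals = pi * scale
        np.fill_diagonal(vals, var)
    return SampleMatrix(vals, n, "ps", list(map(str, df.columns)),
                        as_correlation=as_correlation)


def ensure_estimable(m: SampleMatrix, floor: float = EIGEN_FLOOR) -> SampleMatrix:
    """Clip eigenvalues to ``floor`` so the matrix is safely invertible.

    Returns the input unchanged when it is already positive-definite with
    smallest eigenvalue >= ``floor``; otherwise reconstructs the nearest
    symmetric matrix with clipped spectrum, restores the original diagonal,
    and records a warning flag.
    """
    vals = np.asarray(m.values, dtype=float)
    eig = np.linalg.eigvalsh(vals)
    if eig[0] >= floor:
        return m
    w, v = np.linalg.eigh(vals)
    fixed = (v * np.maximum(w, floor)) @ v.T
    fixed = 0.5 * (fixed + fixed.T)
    np.fill_diagonal(fixed, np.diag(vals))
    if np.linalg.eigvalsh(fixed)[0] < floor:
        # restoring the diagonal broke definiteness again: shrink the
        # off-diagonal block toward the diagonal just enough instead
        diag = np.diag(np.diag(vals))
        lo, hi = 0.0, 1.0
        for _ in range(60):
            t = 0.5 * (lo + hi)
            cand = t * vals + (1.0 - t) * diag
            if np.linalg.eigvalsh(cand)[0] >= floor:
                lo = t
            else:
                hi = t
        fixed = lo * vals + (1.0 - lo) * diag
    out = SampleMatrix(fixed, m.n, m.kind, list(m.labels),
                       as_correlation=m.as_correlation,
                       warnings=list(m.warnings) + [
                           f"eigenvalues clipped to {floor:g} "
                           f"(smallest was {eig[0]:.3g})"])
    return out


def write_matrix(m: SampleMatrix, path) -> None:
    """Write a matrix CSV (labelled) plus a JSON sidecar with provenance."""
    path = Path(path)
    pd.DataFrame(m.values, index=m.labels, columns=m.labels).to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "kind": m.kind,
        "n": int(m.n),
        "as_correlation": bool(m.as_correlation),
        "warnings": list(m.warnings),
    }, indent=2))


def read_matrix(path) -> SampleMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SampleMatrix(df.to_numpy(dtype=float), meta["n"], meta["kind"],
                        list(df.columns), as_correlation=meta["as_correlation"],
                        warnings=list(meta.get("warnings", [])))
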
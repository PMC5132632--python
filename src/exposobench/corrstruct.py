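"""Exposure correlation structure: build, repair, rescale, summarize, serialize.

The simulation study draws exposome matrices from a multivariate normal
distribution whose correlation matrix mimics a real cohort exposome: most
pairwise correlations are weak (|r| < 0.2) yet most variables have at least
one strongly correlated partner (|r| > 0.6).  This module houses the
correlation-matrix container and everything needed to obtain such a matrix:
reading a deposited one from CSV/XLSX, repairing an indefinite estimate to
the nearest correlation matrix, rescaling off-diagonals to study the effect
of overall correlation strength, and generating a surrogate matrix with a
prescribed summary structure when no deposited matrix is at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConvergenceError, GenerationError, ValidationError

#: eigenvalues above this (negative) tolerance count as positive semidefinite
PSD_TOL = 1e-8

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationMatrix:
    """A validated p x p correlation matrix.

    Parameters
    ----------
    values
        Square symmetric matrix with unit diagonal, entries in [-1, 1] and
        smallest eigenvalue >= -1e-8.
    labels
        Variable names, length p.  Defaults to ``X001 ... Xp``.
    """

    values: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError(f"correlation matrix must be square, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("correlation matrix contains non-finite entries")
        if np.max(np.abs(values - values.T)) > _SYM_TOL:
            raise ValidationError("correlation matrix is not symmetric (tolerance 1e-10)")
        if np.max(np.abs(np.diag(values) - 1.0)) > 1e-8:
            i = int(np.argmax(np.abs(np.diag(values) - 1.0)))
            raise ValidationError(f"diagonal entry ({i},{i}) = {values[i, i]!r} differs from 1")
        if np.max(np.abs(values)) > 1.0 + 1e-12:
            raise ValidationError("correlation entries must lie in [-1, 1]")
        lam_min = float(np.linalg.eigvalsh(values)[0])
        if lam_min < -PSD_TOL:
            raise ValidationError(
                f"matrix is not positive semidefinite within tolerance "
                f"(min eigenvalue {lam_min:.3e} < {-PSD_TOL:.0e})"
            )
        # symmetrize exactly and clip rounding overshoot
        values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(values, 1.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        labels = tuple(self.labels) if self.labels else tuple(
            f"X{i + 1:03d}" for i in range(values.shape[0])
        )
        if len(labels) != values.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels for a {values.shape[0]}-variable matrix"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass(frozen=True)
class CorrelationSummary:
    """Summary of the off-diagonal correlation structure.

    ``frac_below_02``: proportion of unordered off-diagonal pairs with
    |r| < 0.2.  ``frac_with_strong_partner``: proportion of variables whose
    largest off-diagonal |r| exceeds 0.6.  ``hist_counts``/``hist_edges``:
    histogram of |r| over unordered pairs.
    """

    frac_below_02: float
    frac_with_strong_partner: float
    hist_counts: tuple[int, ...] = ()
    hist_edges: tuple[float, ...] = ()

    def __post_init__(self):
        for name in ("frac_below_02", "frac_with_strong_partner"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")


def summarize_correlation(
    sigma: CorrelationMatrix,
    *,
    weak_threshold: float = 0.2,
    strong_threshold: float = 0.6,
    bins: Sequence[float] | int = 20,
) -> CorrelationSummary:
    """Summarize the off-diagonal structure of a correlation matrix.

    Proportions are computed over unordered off-diagonal pairs (each pair
    counted once); the strong-partner proportion is computed per variable.
    """
    r = np.abs(sigma.values)
    iu = np.triu_indices(sigma.p, k=1)
    off = r[iu]
    frac_below = float(np.mean(off < weak_threshold)) if off.size else 1.0
    masked = r - 2.0 * np.eye(sigma.p)  # push the diagonal below any threshold
    strong = float(np.mean(masked.max(axis=1) > strong_threshold))
    counts, edges = np.histogram(off, bins=bins, range=(0.0, 1.0) if np.isscalar(bins) else None)
    return CorrelationSummary(
        frac_below_02=frac_below,
        frac_with_strong_partner=strong,
        hist_counts=tuple(int(c) for c in counts),
        hist_edges=tuple(float(e) for e in edges),
    )


def nearest_positive_definite(
    A: np.ndarray | CorrelationMatrix,
    tol: float = PSD_TOL,
    *,
    max_iter: int = 500,
    labels: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Nearest correlation matrix by Higham's alternating projections.

    Projects alternately onto the positive-semidefinite cone and the
    unit-diagonal affine set, with Dykstra's correction so the iteration
    converges to the nearest (Frobenius-norm) correlation matrix.  Already
    valid inputs are returned unchanged (fixed point).

    Raises
    ------
    ValidationError
        If ``A`` is not square symmetric with unit diagonal and entries in
        [-1, 1].
    ConvergenceError
        If successive iterates still differ by more than 1e-9 (Frobenius)
        after ``max_iter`` sweeps.
    """
    if isinstance(A, CorrelationMatrix):
        labels = labels or A.labels
        A = A.values
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"input must be square, got shape {A.shape}")
    if np.max(np.abs(A - A.T)) > 1e-8:
        raise ValidationError("input must be symmetric")
    if np.max(np.abs(np.diag(A) - 1.0)) > 1e-8:
        raise ValidationError("input must have unit diagonal")

    # out-of-range entries (e.g. from rescaling) are clamped before projection
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    if np.linalg.eigvalsh(A)[0] >= -tol:
        return CorrelationMatrix(A, tuple(labels) if labels else ())

    Y = A.copy()
    dS = np.zeros_like(A)
    diff = np.inf
    for _ in range(max_iter):
        R = Y - dS
        lam, Q = np.linalg.eigh((R + R.T) / 2.0)
        X = (Q * np.clip(lam, 0.0, None)) @ Q.T
        dS = X - R
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        np.clip(Y_new, -1.0, 1.0, out=Y_new)
        diff = float(np.linalg.norm(Y_new - Y, "fro"))
        Y = Y_new
        if diff < 1e-9 and np.linalg.eigvalsh((Y + Y.T) / 2.0)[0] >= -tol:
            break
    else:
        raise ConvergenceError(
            f"alternating projections did not converge in {max_iter} iterations "
            f"(last Frobenius step {diff:.3e})",
            residual=diff,
        )
    Y = (Y + Y.T) / 2.0
    np.fill_diagonal(Y, 1.0)
    return CorrelationMatrix(np.clip(Y, -1.0, 1.0), tuple(labels) if labels else ())


def scale_correlations(sigma: CorrelationMatrix, factor: float) -> CorrelationMatrix:
    """Multiply all off-diagonal correlations by ``factor``.

    Entries are clamped to [-1, 1] afterwards; if the rescaled matrix is no
    longer positive semidefinite it is repaired with
    :func:`nearest_positive_definite`.  The diagonal is untouched.  Halving
    (factor 0.5) and doubling-then-capping (factor 2) produce the weaker and
    stronger correlation regimes of the study.
    """
    if not np.isscalar(factor) or factor <= 0:
        raise ValidationError(f"factor must be a positive scalar, got {factor!r}")
    out = sigma.values * float(factor)
    np.fill_diagonal(out, 1.0)
    out = np.clip(out, -1.0, 1.0)
    if np.linalg.eigvalsh(out)[0] < -PSD_TOL:
        return nearest_positive_definite(out, labels=sigma.labels)
    return CorrelationMatrix(out, sigma.labels)


def _surrogate_draw(
    p: int,
    frac_below: float,
    frac_strong: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One attempt at a structured correlation matrix (pre-repair).

    Strong cliques (|r| ~ 0.65-0.85) cover the strong-partner fraction of
    variables; medium within-community correlations (~0.3-0.45) bring the
    share of pairs with |r| >= 0.2 up to target; everything else is weak
    background noise well below 0.2.
    """
    n_pairs = p * (p - 1) // 2
    A = np.zeros((p, p))

    # weak background
    bg = rng.normal(0.0, 0.02, size=(p, p))
    bg = np.clip((bg + bg.T) / 2.0, -0.1, 0.1)
    A += bg

    # medium communities sized so that community pairs ~= pairs above 0.2
    need_ge_02 = int(round((1.0 - frac_below) * n_pairs))
    if need_ge_02 > 0 and p >= 4:
        g = max(2, int(round(1 + 2 * need_ge_02 / p)))
        g = min(g, p)
        order = rng.permutation(p)
        groups = [order[i:i + g] for i in range(0, p, g)]
        for members in groups:
            if len(members) < 2:
                continue
            level = rng.uniform(0.30, 0.45)
            A[np.ix_(members, members)] = level
    else:
        groups = [rng.permutation(p)]

    # strong cliques nested inside communities
    taken = np.zeros(p, dtype=bool)
    budget = int(round(frac_strong * p))
    gi = 0
    # one large clique first, emulating a homogeneous measurement panel
    if budget >= 8 and len(groups[0]) >= 8:
        panel = rng.choice(np.asarray(groups[0]), size=min(12, budget, len(groups[0])), replace=False)
        A[np.ix_(panel, panel)] = rng.uniform(0.65, 0.8)
        taken[panel] = True
        budget -= len(panel)
    while budget >= 2 and groups and gi < 4 * p:
        members = np.asarray(groups[gi % len(groups)])
        gi += 1
        free = members[~taken[members]]
        if len(free) < 2:
            continue
        size = int(rng.choice([2, 2, 3])) if budget >= 3 else 2
        size = min(size, len(free), budget)
        clique = rng.choice(free, size=size, replace=False)
        level = rng.uniform(0.65, 0.85)
        A[np.ix_(clique, clique)] = level
        taken[clique] = True
        budget -= size

    np.fill_diagonal(A, 1.0)
    return A


def surrogate_sigma(
    p: int,
    target: CorrelationSummary | tuple[float, float] = (0.83, 0.78),
    seed: int = 0,
    *,
    max_retries: int = 20,
    tol_pp: float = 0.03,
) -> CorrelationMatrix:
    """Generate a correlation matrix matching a target summary structure.

    A stand-in for a real cohort exposome correlation matrix: random cliques
    of highly correlated variables embedded in weakly correlated communities,
    followed by a positive-semidefinite repair.  The summary of the output
    matches ``target`` within ``tol_pp`` (3 percentage points) on both
    proportions; generation is deterministic given ``seed``.

    Raises
    ------
    GenerationError
        If no attempt matches the target within ``max_retries``.
    """
    if p < 2:
        raise ValidationError("surrogate matrix needs p >= 2")
    if isinstance(target, CorrelationSummary):
        f_below, f_strong = target.frac_below_02, target.frac_with_strong_partner
    else:
        f_below, f_strong = map(float, target)
    if not (0.0 <= f_below <= 1.0 and 0.0 <= f_strong <= 1.0):
        raise ValidationError("target proportions must lie in [0, 1]")

    best = None
    for attempt in range(max_retries):
        rng = substream(seed, "surrogate-sigma", attempt)
        A = _surrogate_draw(p, f_below, f_strong, rng)
        sigma = nearest_positive_definite(A)
        s = summarize_correlation(sigma)
        err = max(
            abs(s.frac_below_02 - f_below),
            abs(s.frac_with_strong_partner - f_strong),
        )
        if best is None or err < best[0]:
            best = (err, sigma)
        if err <= tol_pp:
            return sigma
    raise GenerationError(
        f"no surrogate matrix within {tol_pp:.0%} of target "
        f"({f_below:.2f}, {f_strong:.2f}) after {max_retries} attempts; "
        f"best deviation {best[0]:.3f}"
    )


# ---------------------------------------------------------------------------
# serialization


def _frame_to_matrix(df: pd.DataFrame, path) -> CorrelationMatrix:
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"{path}: correlation table must be square, got {df.shape[0]} rows x "
            f"{df.shape[1]} columns"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [
            (i, j)
            for i in range(df.shape[0])
            for j in range(df.shape[1])
            if not isinstance(df.iat[i, j], (int, float, np.integer, np.floating))
        ]
        where = f" at (row, col) {bad[0]}" if bad else ""
        raise ValidationError(f"{path}: non-numeric cell{where}") from exc
    labels = tuple(str(c) for c in df.columns)
    bad_diag = np.flatnonzero(np.abs(np.diag(values) - 1.0) > 1e-8)
    if bad_diag.size:
        i = int(bad_diag[0])
        raise ValidationError(
            f"{path}: diagonal entry at (row {i}, col {i}) is {values[i, i]}, expected 1"
        )
    return CorrelationMatrix(values, labels)


def read_matrix(path: str | Path, dialect: str | None = None) -> CorrelationMatrix:
    """Read a correlation matrix from CSV or XLSX.

    Layout: header row and index column of variable labels around a square
    numeric table.  ``dialect`` is inferred from the file suffix when not
    given.  The matrix is validated on read.
    """
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).lower()
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
    elif dialect in ("xlsx", "xls"):
        df = pd.read_excel(path, sheet_name=0, index_col=0)
    else:
        raise ValidationError(f"unsupported dialect {dialect!r} (expected csv or xlsx)")
    return _frame_to_matrix(df, path)


def write_matrix(sigma: CorrelationMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write a correlation matrix to CSV or XLSX (labels as header + index)."""
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).lower()
    df = pd.DataFrame(sigma.values, index=list(sigma.labels), columns=list(sigma.labels))
    if dialect == "csv":
        df.to_csv(path)
    elif dialect in ("xlsx", "xls"):
        df.to_excel(path, sheet_name="Sigma")
    else:
        raise ValidationError(f"unsupported dialect {dialect!r} (expected csv or xlsx)")
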
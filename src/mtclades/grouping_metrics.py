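"""Diagnostics for comparing grouping schemes.

Given a per-sample table of population labels and one or more grouping
columns (nomenclature-based SC/SCL/custom, or tree-based cluster ids), this
module computes the quantities used to judge a grouping:

* population × group contingency tables and relative frequencies,
* correspondence analysis (CA) of the contingency table — the SVD of the
  standardized residuals ``S = D_r^{-1/2} (P - r cᵀ) D_c^{-1/2}`` with
  ``P = N/n`` and masses ``r``, ``c``; total inertia equals χ²/n,
* classical (Torgerson) multidimensional scaling of a distance matrix —
  eigendecomposition of ``B = -½ J D∘D J`` with the centering operator
  ``J = I - 11ᵀ/n``,
* within-group pairwise-distance summaries (the violin-plot numbers), and
* reduction to a minimal set of representative samples covering every
  distinct combination of grouping labels.

Axis signs in CA and MDS are not identifiable; consumers should compare
configurations up to sign and rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MtCladesError

__all__ = [
    "CaResult",
    "MdsResult",
    "frequency_table",
    "correspondence_analysis",
    "classical_mds",
    "within_group_distances",
    "representative_reduction",
]

logger = logging.getLogger(__name__)


def frequency_table(
    gt: pd.DataFrame, scheme: str, population_col: str = "population"
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Population × group counts and per-population relative frequencies.

    Returns ``(counts, frequencies)``; each frequency row sums to 1.
    """
    for col in (population_col, scheme):
        if col not in gt.columns:
            raise MtCladesError(f"column {col!r} not in grouping table")
    if gt[scheme].isna().any() or gt[population_col].isna().any():
        raise MtCladesError("grouping table contains missing labels")
    counts = pd.crosstab(gt[population_col], gt[scheme])
    counts.index.name = "population"
    counts.columns.name = scheme
    freqs = counts.div(counts.sum(axis=1), axis=0)
    return counts, freqs


@dataclass(frozen=True)
class CaResult:
    """Correspondence analysis output in principal coordinates."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    inertia: np.ndarray          # per-dimension, = singular value squared
    inertia_pct: np.ndarray
    total_inertia: float         # = chi-squared / n

    @property
    def n_dimensions(self) -> int:
        return len(self.singular_values)


def correspondence_analysis(ct: pd.DataFrame, eps: float = 1e-12) -> CaResult:
    """Correspondence analysis of a population × group contingency table.

    Zero rows/columns are pruned (masses must be positive; a notice is
    logged).  Dimensions with singular value ≤ ``eps`` are dropped, so an
    exactly independent table yields zero retained dimensions and zero
    inertia.  CA is invariant to scaling the whole table, so counts and
    relative frequencies give identical coordinates.
    """
    ct = ct.astype(float)
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise MtCladesError("CA needs at least a 2x2 table")
    if (ct.values < 0).any():
        raise MtCladesError("contingency table must be non-negative")
    keep_rows = ct.sum(axis=1) > 0
    keep_cols = ct.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.info(
            "pruning %d zero rows and %d zero columns before CA",
            int((~keep_rows).sum()), int((~keep_cols).sum()),
        )
        ct = ct.loc[keep_rows, keep_cols]
    n = ct.values.sum()
    if n <= 0:
        raise MtCladesError("contingency table has zero grand total")
    P = ct.values / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > eps
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    inertia = sv**2
    total = float(inertia.sum())
    pct = 100 * inertia / total if total > 0 else np.zeros_like(inertia)
    dims = [f"dim{i + 1}" for i in range(len(sv))]
    return CaResult(
        row_coords=pd.DataFrame(row_coords, index=ct.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=ct.columns, columns=dims),
        singular_values=sv,
        inertia=inertia,
        inertia_pct=pct,
        total_inertia=total,
    )


@dataclass(frozen=True)
class MdsResult:
    """Classical-scaling embedding plus the full Gram-matrix eigenvalues."""

    coords: pd.DataFrame
    eigenvalues: np.ndarray  # all of them, sorted descending; negatives reported


def classical_mds(d: pd.DataFrame, k: int = 2) -> MdsResult:
    """Torgerson classical scaling of a symmetric zero-diagonal distance matrix.

    Coordinates come from the top-``k`` eigenpairs of the double-centered
    Gram matrix with non-negative eigenvalues; if fewer than ``k`` exist,
    ``k`` is truncated with a warning.  Negative eigenvalues — expected for
    non-Euclidean inputs such as tree metrics — are reported unmodified.
    """
    ids = list(d.index)
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise MtCladesError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise MtCladesError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-9):
        raise MtCladesError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-9 * abs(evals[0])) if n > 1 else evals > 0
    n_pos = int(pos.sum())
    if k > n_pos:
        import warnings

        warnings.warn(
            f"requested k={k} but only {n_pos} non-negative eigenpairs; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    cols = [f"mds{i + 1}" for i in range(k)]
    return MdsResult(coords=pd.DataFrame(coords, index=ids, columns=cols), eigenvalues=evals)


def within_group_distances(
    d: pd.DataFrame, gt: pd.DataFrame, scheme: str, sample_col: str = "sample_id"
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray]]:
    """Pairwise distances among members of each group of one scheme.

    Returns a per-group summary frame (member count, pair count, mean, max)
    and the full distance lists keyed by group.  Singleton groups contribute
    an empty distribution.
    """
    missing = [s for s in gt[sample_col] if s not in d.index]
    if missing:
        raise MtCladesError(f"samples absent from distance matrix: {missing[:5]}")
    summaries = []
    dists: Dict[str, np.ndarray] = {}
    for group, sub in gt.groupby(scheme, sort=True):
        members = list(sub[sample_col])
        sub_d = d.loc[members, members].values
        iu = np.triu_indices(len(members), k=1)
        vals = sub_d[iu]
        dists[str(group)] = vals
        summaries.append(
            {
                "group": group,
                "n_members": len(members),
                "n_pairs": len(vals),
                "mean_distance": float(vals.mean()) if len(vals) else np.nan,
                "max_distance": float(vals.max()) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(summaries), dists


def representative_reduction(
    gt: pd.DataFrame, schemes: Sequence[str], sample_col: str = "sample_id"
) -> Tuple[List[str], pd.DataFrame]:
    """Minimal sample set covering every distinct combination of grouping labels.

    One representative per distinct label tuple across ``schemes``; ties are
    broken by the lexicographically smallest sample id.  Returns the sorted
    representative ids and the reduced table (representatives only).
    """
    for s in schemes:
        if s not in gt.columns:
            raise MtCladesError(f"scheme column {s!r} not in grouping table")
    reps: Dict[tuple, str] = {}
    for _, row in gt.iterrows():
        key = tuple(row[s] for s in schemes)
        sid = row[sample_col]
        if key not in reps or sid < reps[key]:
            reps[key] = sid
    rep_ids = sorted(reps.values())
    reduced = gt[gt[sample_col].isin(rep_ids)].reset_index(drop=True)
    return rep_ids, reduced
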
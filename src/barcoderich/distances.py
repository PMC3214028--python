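"""Complete-deletion filtering and pooled (composite-likelihood) TN93 distances.

Distances are expressed as base substitutions per site.  The rate structure
(two transition classes relative to transversions, unequal base frequencies)
is estimated once from substitution counts pooled over every unordered
sequence pair, then each pair's distance is evaluated with those shared
frequencies and its own mismatch proportions.  Rows that are identical over
the retained columns get a distance of exactly ``0.0``; that exact-zero
relation is what the delimitation stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, DegenerateAlignmentError, InputError
from .io_formats import LocusAlignment, decode

# Base order throughout: A=0, C=1, G=2, T=3.  Purines {A,G}, pyrimidines {C,T}.
_TRANSVERSION_PAIRS = ((0, 1), (0, 3), (1, 2), (2, 3))


@dataclass(frozen=True)
class PooledParams:
    """Shared substitution parameters estimated from pooled pair counts.

    ``kappa1`` is the purine-transition rate and ``kappa2`` the
    pyrimidine-transition rate, both relative to the transversion rate.
    A ``*_fallback`` flag marks a kappa that could not be estimated (its
    substitution class was unobserved) and defaulted to 1.0.
    """

    pi: np.ndarray  # base frequencies, order A C G T
    kappa1: float
    kappa2: float
    kappa1_fallback: bool = False
    kappa2_fallback: bool = False


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix plus the pooled parameters.

    Saturated pairs (log-domain violations in the distance transform) hold
    ``nan`` and are listed in ``saturated_pairs``; downstream consumers must
    refuse to operate on them rather than silently propagate ``nan``.
    """

    sample_ids: tuple[str, ...]
    d: np.ndarray
    pooled: PooledParams
    n_sites: int
    n_columns_removed: int = 0
    saturated_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def is_zero(self, a: str, b: str) -> bool:
        return self.get(a, b) == 0.0

    def to_phylip(self, path: str | Path) -> None:
        """Export in square PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_samples}\n")
            for sid, row in zip(self.sample_ids, self.d):
                cells = " ".join(f"{v:.8f}" for v in row)
                fh.write(f"{sid}  {cells}\n")


def complete_deletion(alignment: LocusAlignment) -> LocusAlignment:
    """Drop every column where any row has a gap or ambiguous/missing base.

    Retained original column indices are carried on the result.  If no column
    survives, the (empty) result carries a degenerate-alignment warning and
    distance computation will refuse it.
    """
    if alignment.n_samples == 0:
        raise InputError("empty alignment")
    codes = alignment.encode()
    keep = np.all(codes >= 0, axis=0)
    kept_codes = codes[:, keep]
    original = (
        np.asarray(alignment.column_indices)
        if alignment.column_indices is not None
        else np.arange(alignment.n_columns)
    )
    warnings = alignment.warnings
    if kept_codes.shape[1] == 0:
        rows = tuple("" for _ in alignment.rows)
        warnings = warnings + (
            "degenerate-alignment: no columns survive complete deletion",
        )
    else:
        rows = decode(kept_codes)
    return LocusAlignment(
        locus_id=alignment.locus_id,
        sample_ids=alignment.sample_ids,
        rows=rows,
        binary_chars=alignment.binary_chars,
        column_indices=tuple(int(i) for i in original[keep]),
        boundaries=alignment.boundaries,
        warnings=warnings,
    )


def is_degenerate(alignment: LocusAlignment) -> bool:
    return any(w.startswith("degenerate-alignment") for w in alignment.warnings)


def pool_substitution_counts(alignment: LocusAlignment) -> np.ndarray:
    """4x4 substitution count matrix pooled over all unordered pairs and sites.

    Counts are kept in both orders (the matrix is symmetric); entry ``[a, b]``
    with ``a != b`` is the number of (pair, site) observations with bases
    ``a``/``b``, and the diagonal counts identical-base observations.
    Requires a complete-deletion alignment (no missing states).
    """
    if alignment.n_samples < 2:
        raise InputError("need at least 2 sequences to pool substitution counts")
    codes = alignment.encode()
    if np.any(codes < 0):
        raise AlignmentError("pooling requires a complete-deletion alignment")
    return _pooled_counts_from_codes(codes)


def _pooled_counts_from_codes(codes: np.ndarray) -> np.ndarray:
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)]).astype(np.float64)
    F = counts @ counts.T
    np.fill_diagonal(F, np.diag(F) - counts.sum(axis=1))
    return F


def estimate_pooled_params(F: np.ndarray) -> PooledParams:
    """Estimate shared TN93 parameters from the pooled count matrix.

    Frequencies come straight from the pooled marginals; the two transition
    rates are recovered from the log-corrected pooled mismatch proportions.
    Unobserved substitution classes force the affected kappa to a flagged 1.0.
    """
    F = np.asarray(F, dtype=np.float64)
    total = F.sum()
    if total <= 0:
        raise InputError("all-zero pooled counts")
    pi = F.sum(axis=1) / total
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    P1 = (F[0, 2] + F[2, 0]) / total
    P2 = (F[1, 3] + F[3, 1]) / total
    Q = sum(F[a, b] + F[b, a] for a, b in _TRANSVERSION_PAIRS) / total
    k1 = 2.0 * piA * piG / piR if piR > 0 else 0.0
    k2 = 2.0 * piC * piT / piY if piY > 0 else 0.0

    kappa1 = kappa2 = 1.0
    f1 = f2 = True
    if Q > 0 and piR > 0 and piY > 0:
        w3 = 1.0 - Q / (2.0 * piR * piY)
        if w3 > 0:
            b3 = -np.log(w3)
            if P1 > 0 and k1 > 0:
                w1 = 1.0 - P1 / k1 - Q / (2.0 * piR)
                if w1 > 0:
                    b1 = -np.log(w1)
                    est = (b1 - piY * b3) / (piR * b3)
                    if est > 0:
                        kappa1, f1 = float(est), False
            if P2 > 0 and k2 > 0:
                w2 = 1.0 - P2 / k2 - Q / (2.0 * piY)
                if w2 > 0:
                    b2 = -np.log(w2)
                    est = (b2 - piR * b3) / (piY * b3)
                    if est > 0:
                        kappa2, f2 = float(est), False
    return PooledParams(
        pi=pi, kappa1=kappa1, kappa2=kappa2, kappa1_fallback=f1, kappa2_fallback=f2
    )


def _tn93_coefficients(pi: np.ndarray) -> tuple[float, float, float, float, float]:
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    k1 = 2.0 * piA * piG / piR if piR > 0 else 0.0
    k2 = 2.0 * piC * piT / piY if piY > 0 else 0.0
    k3 = 2.0 * (piR * piY - (piA * piG * piY / piR if piR > 0 else 0.0)
                - (piC * piT * piR / piY if piY > 0 else 0.0))
    return k1, k2, k3, piR, piY


def tn93_from_proportions(
    P1: float, P2: float, Q: float, params: PooledParams
) -> tuple[float, bool]:
    """Closed-form TN93 distance from mismatch proportions and shared params.

    Returns ``(distance, saturated)``; a saturated pair (argument of a log
    non-positive) yields ``(nan, True)``.
    """
    k1, k2, k3, piR, piY = _tn93_coefficients(params.pi)
    if P1 == 0.0 and P2 == 0.0 and Q == 0.0:
        return 0.0, False
    w1 = 1.0 - (P1 / k1 if k1 > 0 else 0.0) - (Q / (2.0 * piR) if piR > 0 else 0.0)
    w2 = 1.0 - (P2 / k2 if k2 > 0 else 0.0) - (Q / (2.0 * piY) if piY > 0 else 0.0)
    w3 = 1.0 - (Q / (2.0 * piR * piY) if piR > 0 and piY > 0 else 0.0)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return float("nan"), True
    d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
    return float(max(d, 0.0)), False


def pairwise_distance(
    row_i: str, row_j: str, params: PooledParams
) -> tuple[float, bool]:
    """Distance between two clean equal-length rows under the pooled model."""
    if len(row_i) == 0 or len(row_j) == 0:
        raise InputError("zero-length rows")
    if len(row_i) != len(row_j):
        raise InputError("rows differ in length")
    if row_i == row_j:
        return 0.0, False
    a = np.frombuffer(row_i.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_j.encode("ascii"), dtype=np.uint8)
    ca = _encode_clean(a)
    cb = _encode_clean(b)
    L = len(row_i)
    P1 = float(np.sum(((ca == 0) & (cb == 2)) | ((ca == 2) & (cb == 0)))) / L
    P2 = float(np.sum(((ca == 1) & (cb == 3)) | ((ca == 3) & (cb == 1)))) / L
    diff = float(np.sum(ca != cb)) / L
    Q = diff - P1 - P2
    return tn93_from_proportions(P1, P2, Q, params)


def _encode_clean(ascii_codes: np.ndarray) -> np.ndarray:
    from .io_formats import _CODE_TABLE

    coded = _CODE_TABLE[ascii_codes]
    if np.any(coded < 0):
        raise InputError("rows must be complete-deletion clean (A/C/G/T only)")
    return coded


def _pair_proportions(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair mismatch proportion matrices (P1, P2, Q) from clean codes."""
    n, L = codes.shape
    ind = [(codes == b).astype(np.float64) for b in range(4)]

    def sym(a: int, b: int) -> np.ndarray:
        m = ind[a] @ ind[b].T
        return m + m.T

    P1 = sym(0, 2) / L
    P2 = sym(1, 3) / L
    Q = sum(sym(a, b) for a, b in _TRANSVERSION_PAIRS) / L
    return P1, P2, Q


def distances_from_codes(
    codes: np.ndarray, params: Optional[PooledParams] = None
) -> tuple[np.ndarray, np.ndarray, PooledParams]:
    """Vectorized pipeline core: codes -> (d matrix, saturation mask, params)."""
    n, L = codes.shape
    if n < 2:
        raise InputError("need at least 2 sequences")
    if L == 0:
        raise DegenerateAlignmentError("no columns available for distances")
    if params is None:
        params = estimate_pooled_params(_pooled_counts_from_codes(codes))
    P1, P2, Q = _pair_proportions(codes)
    k1, k2, k3, piR, piY = _tn93_coefficients(params.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = 1.0 - (P1 / k1 if k1 > 0 else 0.0) - (Q / (2.0 * piR) if piR > 0 else 0.0)
        w2 = 1.0 - (P2 / k2 if k2 > 0 else 0.0) - (Q / (2.0 * piY) if piY > 0 else 0.0)
        w3 = 1.0 - (Q / (2.0 * piR * piY) if piR > 0 and piY > 0 else 0.0)
        saturated = (w1 <= 0.0) | (w2 <= 0.0) | (w3 <= 0.0)
        d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
    identical = (P1 + P2 + Q) == 0.0
    d = np.where(identical, 0.0, d)
    d = np.where(saturated & ~identical, np.nan, np.maximum(d, 0.0))
    saturated = saturated & ~identical
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(saturated, False)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    d = np.where(identical, 0.0, d)
    np.fill_diagonal(d, 0.0)
    return d, saturated, params


def distance_matrix(
    alignment: LocusAlignment, params: Optional[PooledParams] = None
) -> DistanceMatrix:
    """Complete deletion -> pooled parameter estimation -> per-pair distances."""
    if alignment.n_samples < 2:
        raise InputError("need at least 2 sequences for a distance matrix")
    n_before = alignment.n_columns
    clean = complete_deletion(alignment)
    if is_degenerate(clean):
        raise DegenerateAlignmentError(
            f"locus {alignment.locus_id!r}: no columns survive complete deletion"
        )
    codes = clean.encode()
    d, saturated, params = distances_from_codes(codes, params)
    sat_pairs = tuple(
        (clean.sample_ids[i], clean.sample_ids[j])
        for i, j in zip(*np.where(np.triu(saturated, 1)))
    )
    return DistanceMatrix(
        sample_ids=clean.sample_ids,
        d=d,
        pooled=params,
        n_sites=clean.n_columns,
        n_columns_removed=n_before - clean.n_columns,
        saturated_pairs=sat_pairs,
    )
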
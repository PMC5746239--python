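"""Pregnancy-level concomitant-medication distance.

The distance between two pregnancies is the sum over the ten canonical
windows of a set-to-set dissimilarity between the medications reported
in that window.  The default window aggregator is a *symmetric
best-match mean*:

    contribution(A -> B) = mean over a in A of min over b in B of s(a, b)
    window dissimilarity  = contribution(A -> B) + contribution(B -> A)

with the conventions min over an empty B = 3 (nothing to match against)
and mean over an empty A = 0.  Since the per-medication score s is
bounded by 3, each window contributes at most 6 and the total distance
lies in [0, 60] — the range of the pairwise-distance heatmap this
pipeline is built to reproduce.

Two alternative aggregators are provided for sensitivity analysis:
``best_match_sum`` (unnormalized, unbounded in the set sizes) and
``hausdorff`` (max-based, window range [0, 3]).

The triangle inequality is *not* guaranteed by best-match set measures
and is deliberately not asserted anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import squareform

from .atc import atc_dissimilarity, parse_atc, validate_score_map
from .errors import ConfigError, DataError
from .exposure import ExposureProfile, N_WINDOWS

__all__ = [
    "DistanceMatrix",
    "AGGREGATORS",
    "score_matrix",
    "window_set_dissimilarity",
    "profile_distance",
    "distance_matrix",
    "write_distance_matrix",
    "read_distance_matrix",
]

AGGREGATORS = ("best_match_mean", "best_match_sum", "hausdorff")

#: score of a medication with no counterpart to match against
_UNMATCHED = 3.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with an ordered id axis.

    Stored in condensed (upper-triangle) form, following the scipy
    convention; :meth:`square` materializes the full matrix.
    """

    ids: tuple[str, ...]
    condensed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise DataError("duplicate ids in distance matrix")
        expected = n * (n - 1) // 2
        if self.condensed.shape != (expected,):
            raise DataError(
                f"condensed length {self.condensed.shape} does not match "
                f"{n} ids (expected {expected})"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def square(self) -> np.ndarray:
        return squareform(self.condensed, checks=False)

    @classmethod
    def from_square(cls, ids: Sequence[str], sq: np.ndarray) -> "DistanceMatrix":
        sq = np.asarray(sq, dtype=float)
        if sq.ndim != 2 or sq.shape[0] != sq.shape[1]:
            raise DataError("distance matrix must be square")
        if not np.allclose(sq, sq.T, rtol=1e-12, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(sq), 0.0, atol=1e-12):
            raise DataError("distance matrix must have a zero diagonal")
        return cls(tuple(str(i) for i in ids), squareform(sq, checks=False))


def score_matrix(
    catalog: Sequence[str], score_map: Optional[Mapping[int, int]] = None
) -> np.ndarray:
    """Dense medication-by-medication dissimilarity over a code catalog."""
    if score_map is not None:
        validate_score_map(score_map)
    codes = [parse_atc(c) for c in catalog]
    n = len(codes)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = atc_dissimilarity(codes[i], codes[j], score_map)
    return S


def _contribution(
    A: Iterable[str], B: Iterable[str], score_map, reduce: str
) -> float:
    """One-sided best-match term: mean/max/sum over A of min over B."""
    A, B = list(A), list(B)
    if not A:
        return 0.0
    vals = [
        min((atc_dissimilarity(a, b, score_map) for b in B), default=_UNMATCHED)
        for a in A
    ]
    if reduce == "mean":
        return sum(vals) / len(vals)
    if reduce == "max":
        return max(vals)
    return float(sum(vals))


def window_set_dissimilarity(
    A: Iterable[str],
    B: Iterable[str],
    score_map: Optional[Mapping[int, int]] = None,
    aggregator: str = "best_match_mean",
) -> float:
    """Set-to-set dissimilarity between two windows' medication sets."""
    if aggregator == "best_match_mean":
        return _contribution(A, B, score_map, "mean") + _contribution(
            B, A, score_map, "mean"
        )
    if aggregator == "best_match_sum":
        return _contribution(A, B, score_map, "sum") + _contribution(
            B, A, score_map, "sum"
        )
    if aggregator == "hausdorff":
        return max(
            _contribution(A, B, score_map, "max"),
            _contribution(B, A, score_map, "max"),
        )
    raise ConfigError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")


def profile_distance(
    p: ExposureProfile,
    q: ExposureProfile,
    score_map: Optional[Mapping[int, int]] = None,
    aggregator: str = "best_match_mean",
) -> float:
    """Sum of per-window set dissimilarities between two pregnancies."""
    return float(
        sum(
            window_set_dissimilarity(p.windows[w], q.windows[w], score_map, aggregator)
            for w in range(N_WINDOWS)
        )
    )


def _factorize_window(sets: list[frozenset[str]]):
    uid_of: dict[frozenset[str], int] = {}
    inv = np.empty(len(sets), dtype=np.intp)
    uniq: list[frozenset[str]] = []
    for i, s in enumerate(sets):
        u = uid_of.get(s)
        if u is None:
            u = uid_of[s] = len(uniq)
            uniq.append(s)
        inv[i] = u
    return uniq, inv


def _window_lookup(
    uniq: list[frozenset[str]],
    code_index: Mapping[str, int],
    S: np.ndarray,
    aggregator: str,
) -> np.ndarray:
    """Dissimilarity between every pair of distinct window sets."""
    U, C = len(uniq), S.shape[0]
    M = np.zeros((U, C))
    Mmin = np.full((U, C), _UNMATCHED)
    sizes = np.zeros(U)
    for u, s in enumerate(uniq):
        if not s:
            continue
        idx = [code_index[c] for c in s]
        M[u, idx] = 1.0
        Mmin[u] = S[:, idx].min(axis=1)
        sizes[u] = len(idx)
    if aggregator in ("best_match_mean", "best_match_sum"):
        weights = M / np.maximum(sizes, 1.0)[:, None] if aggregator == "best_match_mean" else M
        G = weights @ Mmin.T  # G[u, v] = contribution(set u -> set v)
        return G + G.T
    if aggregator == "hausdorff":
        F = np.empty((U, U))
        neg = np.where(M.astype(bool), 0.0, -np.inf)
        for v in range(U):
            vals = (neg + Mmin[v][None, :]).max(axis=1)  # max over a of min-match
            vals[sizes == 0] = 0.0
            F[:, v] = vals
        return np.maximum(F, F.T)
    raise ConfigError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")


def distance_matrix(
    profiles: Sequence[ExposureProfile],
    score_map: Optional[Mapping[int, int]] = None,
    aggregator: str = "best_match_mean",
) -> DistanceMatrix:
    """All pairwise profile distances, in input order.

    Computation is blocked per window over *distinct* window sets, so
    cohorts where many pregnancies share the same reported set (the
    typical case) cost far less than n^2 set comparisons.  Entries are
    accumulated in double precision and are reproducible bit-for-bit
    for a fixed input order.
    """
    if len(profiles) < 2:
        raise DataError("distance_matrix requires at least 2 profiles")
    ids = [p.pregnancy_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate pregnancy ids: {dupes}")
    if aggregator not in AGGREGATORS:
        raise ConfigError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")

    catalog = sorted(set().union(*(p.all_codes() for p in profiles)))
    code_index = {c: i for i, c in enumerate(catalog)}
    S = score_matrix(catalog, score_map) if catalog else np.zeros((0, 0))

    n = len(profiles)
    D = np.zeros((n, n))
    for w in range(N_WINDOWS):
        uniq, inv = _factorize_window([p.windows[w] for p in profiles])
        W = _window_lookup(uniq, code_index, S, aggregator)
        D += W[np.ix_(inv, inv)]
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(tuple(ids), squareform(D, checks=False))


# ---------------------------------------------------------------------------
# Delimited-text IO: id-list header, then one row per leading index with the
# distances to all later ids.
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path, delimiter: str = ",") -> None:
    sq = dm.square()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(dm.ids) + "\n")
        for i in range(dm.n - 1):
            fh.write(delimiter.join(repr(float(v)) for v in sq[i, i + 1 :]) + "\n")


def read_distance_matrix(path, delimiter: str = ",") -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise DataError(f"{path}: empty distance matrix file")
    ids = tuple(lines[0].split(delimiter))
    n = len(ids)
    sq = np.zeros((n, n))
    if len(lines) - 1 != n - 1:
        raise DataError(f"{path}: expected {n - 1} distance rows, found {len(lines) - 1}")
    for i, ln in enumerate(lines[1:]):
        vals = [float(v) for v in ln.split(delimiter)] if ln else []
        if len(vals) != n - i - 1:
            raise DataError(f"{path}: row {i} has {len(vals)} values, expected {n - i - 1}")
        sq[i, i + 1 :] = vals
        sq[i + 1 :, i] = vals
    return DistanceMatrix(ids, squareform(sq, checks=False))
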
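"""Covariation networks from ternary variation-call strings.

Each probe set carries an ordered string of calls over a fixed series of
condition-vs-condition comparisons: I (increased), D (decreased) or
N (not changed).  Two probe sets covary positively when their calls agree in
sign (II or DD) and negatively when they disagree (ID or DI); positions where
both probe sets are N carry no information.  The positive (CORR) and negative
(ANTI) correlation of a pair are the percentages of concordant and discordant
positions among the informative ones.  Pair values are kept in a network only
when they beat an empirical null built from random probe-set pairs.

Calls are stored internally as int8 codes: I=+1, D=-1, N=0, which turns the
concordance counts into matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CALL_TO_CODE = {"I": 1, "D": -1, "N": 0}
CODE_TO_CALL = {1: "I", -1: "D", 0: "N"}


def encode_calls(calls: Iterable[str]) -> np.ndarray:
    """Encode an iterable of call strings into an int8 matrix (I=1, D=-1, N=0)."""
    rows = []
    for s in calls:
        row = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        out = np.zeros(row.size, dtype=np.int8)
        out[row == ord("I")] = 1
        out[row == ord("D")] = -1
        bad = ~np.isin(row, (ord("I"), ord("D"), ord("N")))
        if bad.any():
            pos = int(np.nonzero(bad)[0][0])
            raise ValueError(f"illegal call symbol {chr(row[pos])!r} at position {pos}")
        rows.append(out)
    return np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.int8)


def decode_calls(codes: np.ndarray) -> list[str]:
    lut = np.array(["D", "N", "I"])  # index by code+1
    return ["".join(lut[row + 1]) for row in np.asarray(codes, dtype=np.int8)]


@dataclass
class VariationCallMatrix:
    """Probe sets x comparisons matrix of ternary I/D/N calls."""

    probe_set_ids: list[str]
    comparison_ids: list[str]
    codes: np.ndarray  # int8, shape (n_probe_sets, n_comparisons)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        n, m = self.codes.shape
        if n != len(self.probe_set_ids) or m != len(self.comparison_ids):
            raise ValueError("call matrix dimensions do not match identifier lists")
        if len(set(self.probe_set_ids)) != n:
            raise ValueError("duplicate probe-set identifiers")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("call codes must be in {-1, 0, +1} (D, N, I)")
        self._index = {ps: i for i, ps in enumerate(self.probe_set_ids)}

    @classmethod
    def from_strings(
        cls, probe_set_ids: Sequence[str], calls: Sequence[str],
        comparison_ids: Sequence[str] | None = None,
    ) -> "VariationCallMatrix":
        codes = encode_calls(calls)
        if comparison_ids is None:
            comparison_ids = [f"c{i + 1}" for i in range(codes.shape[1])]
        return cls(list(probe_set_ids), list(comparison_ids), codes)

    @property
    def n_probe_sets(self) -> int:
        return self.codes.shape[0]

    @property
    def n_comparisons(self) -> int:
        return self.codes.shape[1]

    def index_of(self, ps: str) -> int:
        try:
            return self._index[ps]
        except KeyError:
            raise KeyError(f"unknown probe set {ps!r}") from None

    def call_string(self, ps: str) -> str:
        return decode_calls(self.codes[self.index_of(ps)][None, :])[0]


def corr_anti(s1, s2) -> tuple[float, float, int]:
    """Positive/negative correlation (percent) of two call strings.

    Informative positions are those where at least one call is not N.
    corr = 100 * #(II or DD) / informative, anti = 100 * #(ID or DI) /
    informative.  A pair with no informative position is degenerate and
    reports (0, 0, 0).

    Accepts call strings or int8 code vectors; returns
    (corr, anti, n_informative).
    """
    x = encode_calls([s1])[0] if isinstance(s1, str) else np.asarray(s1, np.int8)
    y = encode_calls([s2])[0] if isinstance(s2, str) else np.asarray(s2, np.int8)
    if x.shape != y.shape:
        raise ValueError(f"call strings differ in length: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("call strings must have length >= 1")
    prod = x.astype(np.int32) * y
    conc = int((prod == 1).sum())
    disc = int((prod == -1).sum())
    informative = int(((x != 0) | (y != 0)).sum())
    if informative == 0:
        return 0.0, 0.0, 0
    return 100.0 * conc / informative, 100.0 * disc / informative, informative


def pairwise_corr_anti(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs corr/anti/informative matrices from an int8 code matrix.

    conc - disc = X @ X.T and conc + disc = |X| @ |X|.T, so both counts come
    from two symmetric matrix products; informative counts come from the
    complement of the joint-N product.
    """
    x = np.asarray(codes, dtype=np.float64)
    ax = np.abs(x)
    signed = x @ x.T
    total = ax @ ax.T
    conc = (total + signed) / 2.0
    disc = (total - signed) / 2.0
    both_n = (1.0 - ax) @ (1.0 - ax).T
    informative = codes.shape[1] - both_n
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(informative > 0, 100.0 * conc / informative, 0.0)
        anti = np.where(informative > 0, 100.0 * disc / informative, 0.0)
    return corr, anti, informative.astype(np.int64)


@dataclass
class NullDistribution:
    """Empirical null of corr/anti values over random probe-set pairs."""

    corr_null: np.ndarray  # sorted ascending
    anti_null: np.ndarray  # sorted ascending
    n_samples: int
    seed: int
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.corr_null = np.sort(np.asarray(self.corr_null, dtype=float))
        self.anti_null = np.sort(np.asarray(self.anti_null, dtype=float))


def _pair_from_linear(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices over the strict upper triangle to (i, j) pairs."""
    counts = np.arange(n - 1, -1, -1)  # pairs starting at row i
    offsets = np.concatenate(([0], np.cumsum(counts)))
    i = np.searchsorted(offsets, k, side="right") - 1
    j = i + 1 + (k - offsets[i])
    return i, j


def build_null(calls: VariationCallMatrix, n_samples: int, seed: int) -> NullDistribution:
    """Corr/anti null from uniformly random distinct unordered probe-set pairs.

    Sampling is without replacement; when ``n_samples`` exceeds the number of
    distinct pairs, all pairs are used exhaustively.
    """
    n = calls.n_probe_sets
    if n < 2:
        raise ValueError("need at least 2 probe sets to build a null")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    total = n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    exhaustive = n_samples >= total
    if exhaustive:
        k = np.arange(total)
    else:
        k = rng.choice(total, size=n_samples, replace=False)
    i, j = _pair_from_linear(np.asarray(k), n)
    x = calls.codes[i].astype(np.int32)
    y = calls.codes[j].astype(np.int32)
    prod = x * y
    conc = (prod == 1).sum(axis=1)
    disc = (prod == -1).sum(axis=1)
    informative = ((x != 0) | (y != 0)).sum(axis=1)
    ok = informative > 0
    corr = np.zeros(len(k))
    anti = np.zeros(len(k))
    corr[ok] = 100.0 * conc[ok] / informative[ok]
    anti[ok] = 100.0 * disc[ok] / informative[ok]
    return NullDistribution(corr, anti, n_samples=len(k), seed=seed, exhaustive=exhaustive)


def empirical_pvalue(value: float, null: np.ndarray) -> float:
    """Upper-tail add-one empirical p-value: (#null >= value + 1) / (n + 1)."""
    arr = np.asarray(null, dtype=float)
    if arr.size == 0:
        raise ValueError("empty null distribution")
    count = arr.size - np.searchsorted(arr, value, side="left")
    return (count + 1.0) / (arr.size + 1.0)


@dataclass
class CovariationNetwork:
    """Significance-filtered CORR/ANTI matrices over a probe-set universe.

    ``corr``/``anti`` hold percent values; ``stored_corr``/``stored_anti``
    flag which entries passed the empirical-null filter.  Entries that are
    not stored are treated as 0 downstream.
    """

    probe_set_ids: list[str]
    corr: np.ndarray
    anti: np.ndarray
    stored_corr: np.ndarray
    stored_anti: np.ndarray
    alpha: float
    n_comparisons: int
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {ps: i for i, ps in enumerate(self.probe_set_ids)}

    @property
    def n_probe_sets(self) -> int:
        return len(self.probe_set_ids)

    def index_of(self, ps: str) -> int:
        try:
            return self._index[ps]
        except KeyError:
            raise KeyError(f"unknown probe set {ps!r}") from None

    def pair_values(self, ps_a: str, ps_b: str) -> tuple[float, float]:
        """(corr, anti) with absent/filtered values reported as 0."""
        i, j = self.index_of(ps_a), self.index_of(ps_b)
        c = float(self.corr[i, j]) if self.stored_corr[i, j] else 0.0
        a = float(self.anti[i, j]) if self.stored_anti[i, j] else 0.0
        return c, a

    def has_positive_edge(self, ps_a: str, ps_b: str) -> bool:
        i, j = self.index_of(ps_a), self.index_of(ps_b)
        return bool(self.stored_corr[i, j] and self.corr[i, j] > 0)

    def edges(self):
        """Yield (ps_a, ps_b, corr, anti) for pairs with any stored value."""
        either = self.stored_corr | self.stored_anti
        ii, jj = np.nonzero(np.triu(either, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            c = float(self.corr[i, j]) if self.stored_corr[i, j] else 0.0
            a = float(self.anti[i, j]) if self.stored_anti[i, j] else 0.0
            yield self.probe_set_ids[i], self.probe_set_ids[j], c, a


def build_network(
    calls: VariationCallMatrix, null: NullDistribution, alpha: float = 0.05
) -> CovariationNetwork:
    """Assemble the significance-filtered covariation network.

    A pair's corr (resp. anti) value is stored iff its add-one empirical
    p-value against the corr (resp. anti) null is <= alpha.  Pairs with no
    informative position are excluded entirely.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    corr, anti, informative = pairwise_corr_anti(calls.codes)
    n = calls.n_probe_sets

    def tail_p(values: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
        m = null_sorted.size
        count = m - np.searchsorted(null_sorted, values.ravel(), side="left")
        return ((count + 1.0) / (m + 1.0)).reshape(values.shape)

    nondegenerate = informative > 0
    offdiag = ~np.eye(n, dtype=bool)
    stored_corr = (tail_p(corr, null.corr_null) <= alpha) & nondegenerate & offdiag
    stored_anti = (tail_p(anti, null.anti_null) <= alpha) & nondegenerate & offdiag
    return CovariationNetwork(
        probe_set_ids=list(calls.probe_set_ids),
        corr=corr,
        anti=anti,
        stored_corr=stored_corr,
        stored_anti=stored_anti,
        alpha=alpha,
        n_comparisons=calls.n_comparisons,
    )
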
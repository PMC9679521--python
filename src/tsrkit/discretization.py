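"""Adaptive equal-frequency discretization of MaxDist and Theta.

The key formula needs each triangle's MaxDist and Theta as small bin
indices (default bin counts 35 and 29 respectively).  Boundaries are
fitted so that bin populations are as equal as possible subject to the
hard constraint that all occurrences of the same value land in the same
bin: cuts may only be placed between *distinct* sorted values.

The fitted objective is the minimax deviation ``max_b |pop_b − N/B|``.
For up to 512 distinct values the optimum is found exactly by dynamic
programming over contiguous partitions; beyond that, greedy quantile
cuts are refined by a deterministic local search.  Published boundary
tables can be loaded from file instead, so key integers produced with
the original binning can be reproduced verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BinBoundaries",
    "fit_bins",
    "assign_bin",
    "assign_bins",
    "read_boundaries",
    "write_boundaries",
    "AdaptiveFrequencyBinner",
    "THETA_BIN_COUNT",
    "MAXDIST_BIN_COUNT",
]

#: default bin counts for the two triangle descriptors
THETA_BIN_COUNT = 29
MAXDIST_BIN_COUNT = 35

_DP_MAX_DISTINCT = 512


@dataclass(frozen=True)
class BinBoundaries:
    """Cut points of one discretized variable.

    ``boundaries`` has ``bin_count + 1`` strictly increasing entries;
    bin *i* (1-based) is the half-open interval
    ``[boundaries[i-1], boundaries[i])``, except the last bin which is
    closed on the right.  Values outside the outer boundaries are
    clamped to the first/last bin (with a warning).
    """

    variable: str
    boundaries: np.ndarray = field(repr=False)
    bin_count: int

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or len(b) != self.bin_count + 1:
            raise ValueError(
                f"expected {self.bin_count + 1} boundaries, got {len(b)}"
            )
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        object.__setattr__(self, "boundaries", b)


def _objective(prefix, cuts, target):
    """(max deviation, sum of deviations) of the partition given by cuts.

    ``cuts`` are indices into the distinct-value array: cumulative counts
    of distinct values per bin boundary, ending at len(prefix)-1 implicit.
    """
    pops = np.diff(np.concatenate([[0.0], prefix[cuts], [prefix[-1]]]))
    dev = np.abs(pops - target)
    return float(dev.max()), float(dev.sum())


def _fit_exact(prefix, n_bins, target):
    """Exact minimax contiguous partition via DP; O(B · D²)."""
    d = len(prefix)  # number of distinct values
    # f[i] = best achievable max-deviation covering distinct values 0..i
    # (inclusive) with the current number of bins.
    cum = prefix
    f = np.abs(cum - target)
    back = np.zeros((n_bins, d), dtype=np.int64)
    for j in range(1, n_bins):
        # candidate: last bin spans (i'+1 .. i); cost |cum[i]-cum[i']-t|
        cost = np.abs(cum[None, :] - cum[:, None] - target)  # [i', i]
        combined = np.maximum(f[:, None], cost)
        # bins must be nonempty: only i' < i is admissible
        combined[np.tril_indices(d)] = np.inf
        back[j] = np.argmin(combined, axis=0)
        f = combined[back[j], np.arange(d)]
    # reconstruct cuts
    cuts = []
    i = d - 1
    for j in range(n_bins - 1, 0, -1):
        i = int(back[j, i])
        cuts.append(i)
    return np.array(cuts[::-1], dtype=np.int64)


def _fit_greedy(prefix, n_bins, target):
    """Greedy quantile cuts + local search on the minimax objective."""
    d = len(prefix)
    cuts = []
    for j in range(1, n_bins):
        idx = int(np.argmin(np.abs(prefix - j * target)))
        cuts.append(idx)
    cuts = np.array(cuts, dtype=np.int64)
    # enforce strictly increasing interior cuts with room for all bins
    for j in range(len(cuts)):
        cuts[j] = max(cuts[j], j)
        cuts[j] = min(cuts[j], d - (len(cuts) - j) - 1)
    for j in range(1, len(cuts)):
        cuts[j] = max(cuts[j], cuts[j - 1] + 1)

    best = _objective(prefix, cuts, target)
    improved = True
    passes = 0
    while improved and passes < 200:
        improved = False
        passes += 1
        for j in range(len(cuts)):
            for step in (-1, 1):
                cand = cuts.copy()
                cand[j] += step
                lo = cand[j - 1] + 1 if j > 0 else 0
                hi = cand[j + 1] - 1 if j + 1 < len(cand) else d - 2
                if not (lo <= cand[j] <= hi):
                    continue
                obj = _objective(prefix, cand, target)
                if obj < best:
                    best, cuts, improved = obj, cand, True
    return cuts


def fit_bins(values, bin_count, variable="") -> BinBoundaries:
    """Fit adaptive equal-frequency bin boundaries.

    Parameters
    ----------
    values : array-like
        Observed values (duplicates allowed and meaningful).
    bin_count : int
        Number of bins; must not exceed the number of distinct values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot fit bins on empty data")
    distinct, counts = np.unique(values, return_counts=True)
    if bin_count > len(distinct):
        raise ValueError(
            f"bin_count={bin_count} exceeds {len(distinct)} distinct values"
        )
    if bin_count == len(distinct):
        cuts = np.arange(bin_count - 1, dtype=np.int64)
    else:
        prefix = np.cumsum(counts).astype(float)
        target = values.size / bin_count
        if len(distinct) <= _DP_MAX_DISTINCT:
            cuts = _fit_exact(prefix, bin_count, target)
        else:
            cuts = _fit_greedy(prefix, bin_count, target)
    inner = 0.5 * (distinct[cuts] + distinct[cuts + 1])
    boundaries = np.concatenate([[distinct[0]], inner, [distinct[-1]]])
    return BinBoundaries(variable=variable, boundaries=boundaries, bin_count=int(bin_count))


def assign_bins(values, bins: BinBoundaries, warn_out_of_range=True) -> np.ndarray:
    """Vectorized bin assignment; returns 1-based indices."""
    values = np.asarray(values, dtype=float)
    inner = bins.boundaries[1:-1]
    idx = np.searchsorted(inner, values, side="right") + 1
    if warn_out_of_range:
        n_out = int(
            np.sum(values < bins.boundaries[0]) + np.sum(values > bins.boundaries[-1])
        )
        if n_out:
            warnings.warn(
                f"{n_out} value(s) outside the fitted range of "
                f"'{bins.variable}'; clamped to the outer bins",
                stacklevel=2,
            )
    return idx


def assign_bin(value, bins: BinBoundaries) -> int:
    """Bin index (1..bin_count) for a single value."""
    return int(assign_bins(np.asarray([value]), bins)[0])


def write_boundaries(bins: BinBoundaries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{bins.variable}\t{bins.bin_count}\n")
        for b in bins.boundaries:
            fh.write(f"{float(b)!r}\n")


def read_boundaries(path) -> BinBoundaries:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise ValueError(f"{path}: expected header 'variable<TAB>bin_count'")
        variable, bin_count = header[0], int(header[1])
        boundaries = [float(line) for line in fh if line.strip()]
    return BinBoundaries(variable=variable, boundaries=np.asarray(boundaries),
                         bin_count=bin_count)


class AdaptiveFrequencyBinner(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper around :func:`fit_bins`/:func:`assign_bins`.

    Parameters
    ----------
    n_bins : int
        Number of bins.
    variable : str
        Name recorded in the fitted :class:`BinBoundaries`.
    """

    def __init__(self, n_bins=10, variable=""):
        self.n_bins = n_bins
        self.variable = variable

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        self.bins_ = fit_bins(X, self.n_bins, variable=self.variable)
        self.boundaries_ = self.bins_.boundaries
        return self

    def transform(self, X):
        check_is_fitted(self, "bins_")
        X = np.asarray(X, dtype=float)
        return assign_bins(X.ravel(), self.bins_).reshape(X.shape)
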
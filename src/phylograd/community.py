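"""Community statistics: richness, mean pairwise distance, independent-swap
nulls and the net relatedness index (NRI).

The community table is a plots x species :class:`pandas.DataFrame` of
non-negative counts; incidence (0/1) data are the degenerate case in which
abundance weighting has no effect. Phylogenetic distances come from
:func:`phylograd.phylo.cophenetic_matrix`.

NRI follows the convention ``NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)``
so that a *positive* value means co-occurring species are more closely related
than expected (phylogenetic clustering) and a negative value means
overdispersion. Null communities are produced by the independent-swap
algorithm, a Markov chain over 2x2 checkerboard submatrix swaps that exactly
preserves each species' occurrence frequency (column sums) and each plot's
richness (row sums).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["richness", "mpd", "independent_swap", "nri", "NullEnsemble",
           "SwapChain", "nri_table"]

logger = logging.getLogger(__name__)


def richness(row, q: int = 0) -> float:
    """Hill-number diversity of one community row; only q = 0 is in scope.

    At q = 0 the effective species number weights common and rare species
    equally, i.e. it is the count of species with a positive entry.
    """
    if q != 0:
        raise NotImplementedError("only Hill order q = 0 is supported")
    x = np.asarray(row, dtype=float)
    if (x < 0).any():
        raise ValueError("community entries must be non-negative")
    return float((x > 0).sum())


def _align(row: pd.Series | np.ndarray, D: pd.DataFrame,
           species=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(row, pd.Series):
        species = row.index
        x = row.to_numpy(dtype=float)
    else:
        x = np.asarray(row, dtype=float)
        if species is None:
            if len(x) != D.shape[0]:
                raise ValueError("unlabeled row length does not match matrix")
            species = D.index
    missing = [s for s in species if s not in D.index]
    if missing:
        raise KeyError(f"species absent from distance matrix: {missing[:10]}")
    dm = D.loc[species, species].to_numpy(dtype=float)
    return x, dm


def mpd(row, D: pd.DataFrame, weighted: bool = False, species=None) -> float:
    """Mean pairwise patristic distance among the species present in a row.

    Unweighted: the mean of d(i, j) over unordered pairs of distinct present
    species. Weighted: sum_{i<j} f_i f_j d(i, j) / sum_{i<j} f_i f_j with f
    the abundances, which reduces to the unweighted form on incidence data.
    Fewer than two present species yields NaN (propagated, never 0).
    """
    x, dm = _align(row, D, species)
    present = x > 0
    if present.sum() < 2:
        return float("nan")
    f = x[present] if weighted else np.ones(int(present.sum()))
    sub = dm[np.ix_(present, present)]
    num = f @ sub @ f  # ordered pairs; diagonal is zero
    den = f.sum() ** 2 - (f ** 2).sum()
    return float(num / den)


def _mpd_all_rows(M: np.ndarray, dm: np.ndarray, weighted: bool) -> np.ndarray:
    """Vectorized MPD for every row of a plots x species matrix."""
    F = M.astype(float) if weighted else (M > 0).astype(float)
    num = np.einsum("ij,jk,ik->i", F, dm, F)
    den = F.sum(axis=1) ** 2 - (F ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[(M > 0).sum(axis=1) < 2] = np.nan
    return out


class SwapChain:
    """Independent-swap Markov chain over a community matrix.

    A step picks a random 2x2 submatrix (two plots, two species); if its
    occupancy pattern is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) the
    two occupied cells are swapped diagonally, carrying their abundances with
    them. Row and column occupancy sums are invariant under every step.
    """

    def __init__(self, matrix: np.ndarray, rng: np.random.Generator):
        self.m = np.array(matrix, copy=True)
        self.rng = rng
        self.n_rows, self.n_cols = self.m.shape

    def step(self, n_attempts: int) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            return
        m = self.m
        # draw attempt coordinates in batch; the swap itself is sequential
        rows = self.rng.integers(0, self.n_rows, size=(n_attempts, 2))
        cols = self.rng.integers(0, self.n_cols, size=(n_attempts, 2))
        for k in range(n_attempts):
            r1, r2 = rows[k]
            c1, c2 = cols[k]
            if r1 == r2 or c1 == c2:
                continue
            a, b, c, d = m[r1, c1], m[r1, c2], m[r2, c1], m[r2, c2]
            if a > 0 and d > 0 and b == 0 and c == 0:
                m[r1, c1], m[r2, c2] = 0, 0
                m[r1, c2], m[r2, c1] = a, d
            elif b > 0 and c > 0 and a == 0 and d == 0:
                m[r1, c2], m[r2, c1] = 0, 0
                m[r1, c1], m[r2, c2] = b, c


def independent_swap(table: pd.DataFrame, n_attempts: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """One randomized matrix after ``n_attempts`` attempted checkerboard swaps.

    Occupancy row and column sums are preserved exactly; with count data the
    cell values travel with the occupancy. A matrix with no checkerboard
    submatrix is returned unchanged.
    """
    if table.size == 0:
        raise ValueError("empty community table")
    chain = SwapChain(table.to_numpy(), np.random.default_rng(seed))
    chain.step(n_attempts)
    return pd.DataFrame(chain.m, index=table.index, columns=table.columns)


@dataclass
class NullEnsemble:
    """Per-plot null MPD distribution from the swap chain."""

    samples: np.ndarray   # n_null x n_plots
    n_null: int
    seed: int

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.samples, axis=0)

    @property
    def sd(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.samples, axis=0, ddof=1)


def nri(table: pd.DataFrame, D: pd.DataFrame, n_null: int = 1000,
        weighted: bool = True, seed: int = 0, burn_in: int | None = None,
        thin: int = 1000) -> tuple[pd.Series, NullEnsemble]:
    """Net relatedness index per plot against independent-swap nulls.

    The chain is burned in for ``burn_in`` attempted swaps (default 10x the
    number of occupied cells) and one null matrix is taken every ``thin``
    attempts; null MPD uses the same ``weighted`` flag as the observed MPD.
    Plots with fewer than two species, or whose null MPD has zero spread
    (e.g. a star phylogeny), yield NaN with a logged warning.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 plots and >= 2 species")
    sp = list(table.columns)
    missing = [s for s in sp if s not in D.index]
    if missing:
        raise KeyError(f"species absent from distance matrix: {missing[:10]}")
    dm = D.loc[sp, sp].to_numpy(dtype=float)
    M = table.to_numpy()
    obs = _mpd_all_rows(M, dm, weighted)

    rng = np.random.default_rng(seed)
    chain = SwapChain(M, rng)
    if burn_in is None:
        burn_in = 10 * int((M > 0).sum())
    chain.step(burn_in)
    samples = np.empty((n_null, len(table)))
    for b in range(n_null):
        chain.step(thin)
        samples[b] = _mpd_all_rows(chain.m, dm, weighted)
    ens = NullEnsemble(samples=samples, n_null=n_null, seed=seed)

    sd = ens.sd
    with np.errstate(invalid="ignore", divide="ignore"):
        values = -(obs - ens.mean) / sd
    degenerate = (sd == 0) & np.isfinite(obs)
    if degenerate.any():
        logger.warning("null MPD spread is zero for %d plots; NRI set to NaN",
                       int(degenerate.sum()))
        values[degenerate] = np.nan
    return pd.Series(values, index=table.index, name="nri"), ens


def nri_table(table: pd.DataFrame, D: pd.DataFrame, n_null: int = 1000,
              weighted: bool = True, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Per-plot summary: richness, observed MPD, null mean/sd and NRI."""
    values, ens = nri(table, D, n_null=n_null, weighted=weighted, seed=seed,
                      **kwargs)
    sp = list(table.columns)
    dm = D.loc[sp, sp].to_numpy(dtype=float)
    obs = _mpd_all_rows(table.to_numpy(), dm, weighted)
    return pd.DataFrame({
        "richness": (table.to_numpy() > 0).sum(axis=1),
        "mpd_obs": obs,
        "null_mean": ens.mean,
        "null_sd": ens.sd,
        "nri": values.to_numpy(),
    }, index=table.index)
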
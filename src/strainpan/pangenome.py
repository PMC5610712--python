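"""Core/pan/new-gene rarefaction and the Heaps-law openness test.

Starting from a binary strain x gene-family matrix, genomes are added
one at a time in permuted orders; at each step the core (families in
every genome so far), pan (families in any genome so far) and new
(families first seen at this step) counts are recorded.  Medians across
permutations summarise the curves.  Fitting log10(new-gene median)
against log10(genome number) gives the Heaps exponent alpha = -slope;
alpha < 1 indicates an open pan-genome that keeps acquiring novel genes
as strains are added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GeneModel
from .orthology import PresenceAbsenceMatrix


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, PresenceAbsenceMatrix):
        return matrix.df
    return matrix


def core_genome(matrix, strains: Sequence[str] | None = None) -> list[str]:
    """Columns (families and singletons) present in every listed strain."""
    df = _as_frame(matrix)
    if strains is None:
        strains = list(df.index)
    strains = list(strains)
    if not strains:
        raise ValueError("strain subset must be non-empty")
    unknown = [s for s in strains if s not in df.index]
    if unknown:
        raise ValueError(f"unknown strains {unknown}")
    sub = df.loc[strains].to_numpy(dtype=bool)
    keep = sub.all(axis=0)
    return [c for c, k in zip(df.columns, keep) if k]


@dataclass
class RarefactionResult:
    """Per-permutation core/pan/new counts for k = 1..N genomes.

    ``core[p, k-1]`` is the core size after the first k genomes of
    permutation p (for k = 1 this is the gene count of the opening
    genome); ``new[p, 0]`` equals that same opening count.
    """

    core: np.ndarray           # (n_permutations, N)
    pan: np.ndarray
    new: np.ndarray
    n_permutations: int
    seed: int | None

    @property
    def n_genomes(self) -> int:
        return self.core.shape[1]

    def medians(self) -> pd.DataFrame:
        k = np.arange(1, self.n_genomes + 1)
        return pd.DataFrame(
            {
                "k": k,
                "core": np.median(self.core, axis=0),
                "pan": np.median(self.pan, axis=0),
                "new": np.median(self.new, axis=0),
            }
        )

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for p in range(self.core.shape[0]):
            for k in range(self.n_genomes):
                rows.append((k + 1, p, self.core[p, k], self.pan[p, k], self.new[p, k]))
        return pd.DataFrame(rows, columns=["k", "permutation", "core", "pan", "new"])


def rarefaction(
    matrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    orders: Sequence[Sequence[int]] | None = None,
) -> RarefactionResult:
    """Permutation rarefaction of core/pan/new gene counts.

    Genome addition orders are sampled uniformly (with replacement from
    the N! orders) using *seed*; passing *orders* forces an explicit
    permutation set instead, e.g. the full enumeration on a small panel.
    """
    df = _as_frame(matrix)
    values = df.to_numpy(dtype=bool)
    n = values.shape[0]
    if n < 2:
        raise ValueError("rarefaction requires at least two strains")
    if orders is None:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        order_arr = np.stack([rng.permutation(n) for _ in range(n_permutations)])
    else:
        order_arr = np.asarray(orders, dtype=int)
        if order_arr.ndim != 2 or order_arr.shape[1] != n:
            raise ValueError("each forced order must list every strain index once")
        n_permutations = order_arr.shape[0]

    core = np.empty((n_permutations, n), dtype=np.int64)
    pan = np.empty_like(core)
    new = np.empty_like(core)
    for p in range(n_permutations):
        rows = values[order_arr[p]]
        cum_and = np.logical_and.accumulate(rows, axis=0)
        cum_or = np.logical_or.accumulate(rows, axis=0)
        core[p] = cum_and.sum(axis=1)
        pan[p] = cum_or.sum(axis=1)
        new[p, 0] = pan[p, 0]
        new[p, 1:] = np.diff(pan[p])
    return RarefactionResult(core, pan, new, n_permutations, seed)


@dataclass
class HeapsFit:
    """Power-law fit new(k) ~ kappa * k^(-alpha) on log10 scales."""

    alpha: float
    kappa: float
    slope: float
    intercept: float
    fit_range: tuple[int, int]
    r_squared: float

    @property
    def open(self) -> bool:
        return self.alpha < 1.0


def fit_heaps(
    new_medians: Mapping[int, float] | pd.Series,
    fit_range: tuple[int, int] | None = None,
) -> HeapsFit:
    """OLS of log10(median new genes) on log10(k); alpha = -slope.

    *new_medians* maps genome number k to the median new-gene count.
    The default range is k = 2..N: the first genome contributes its
    whole gene complement rather than a discovery increment.
    """
    series = pd.Series(dict(new_medians)).sort_index()
    if fit_range is None:
        fit_range = (2, int(series.index.max()))
    lo, hi = fit_range
    window = series[(series.index >= lo) & (series.index <= hi)]
    if len(window) < 3:
        raise ValueError("need at least 3 points in the fit range")
    if (window <= 0).any():
        bad = list(window[window <= 0].index)
        raise ValueError(
            f"non-positive new-gene medians at k={bad}; narrow fit_range "
            f"to exclude them"
        )
    res = stats.linregress(np.log10(window.index.to_numpy(dtype=float)),
                           np.log10(window.to_numpy(dtype=float)))
    return HeapsFit(
        alpha=-float(res.slope),
        kappa=float(10.0 ** res.intercept),
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_range=(lo, hi),
        r_squared=float(res.rvalue**2),
    )


def leave_one_out_core(matrix) -> dict[str, int]:
    """Core size of the panel after excluding each strain in turn."""
    df = _as_frame(matrix)
    if len(df.index) < 3:
        raise ValueError("leave-one-out requires at least 3 strains")
    out = {}
    for strain in df.index:
        rest = [s for s in df.index if s != strain]
        out[str(strain)] = len(core_genome(df, rest))
    return out


@dataclass
class RepliconGeneSummary:
    """Median and quartiles of genes-per-genome for each replicon class."""

    stats: pd.DataFrame  # index: replicon class; columns: n_strains, q1, median, q3

    def as_tuple(self, replicon_class: str) -> tuple[float, float, float]:
        row = self.stats.loc[replicon_class]
        return float(row["median"]), float(row["q1"]), float(row["q3"])


def replicon_gene_summary(genes: Sequence[GeneModel]) -> RepliconGeneSummary:
    """Per-class distribution of per-strain gene totals.

    Quartiles use linear interpolation between order statistics (the
    convention that yields fractional medians such as 47.5).  Strains
    carrying no replicon of a class do not contribute a zero to that
    class's distribution.
    """
    counts: dict[tuple[str, str], int] = {}
    for g in genes:
        if g.replicon_class is None:
            raise ValueError(f"gene {g.gene_id!r} lacks a replicon class")
        key = (g.replicon_class, g.strain_id)
        counts[key] = counts.get(key, 0) + 1
    per_class: dict[str, list[int]] = {}
    for (cls, _strain), c in sorted(counts.items()):
        per_class.setdefault(cls, []).append(c)
    rows = {}
    for cls, vals in sorted(per_class.items()):
        arr = np.asarray(vals, dtype=float)
        rows[cls] = {
            "n_strains": len(arr),
            "q1": np.percentile(arr, 25),
            "median": np.percentile(arr, 50),
            "q3": np.percentile(arr, 75),
        }
    return RepliconGeneSummary(pd.DataFrame(rows).T)


def plot_rarefaction(result: RarefactionResult, path: str) -> None:
    """Four-panel figure: core, pan, new, and log10(new) medians vs k."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med = result.medians()
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("core", "core genes", axes[0, 0], False),
        ("pan", "total genes", axes[0, 1], False),
        ("new", "new genes", axes[1, 0], False),
        ("new", "log10 new genes", axes[1, 1], True),
    ]
    for col, title, ax, logscale in panels:
        ax.plot(med["k"], med[col], "ko-", ms=3)
        if logscale:
            ax.set_yscale("log")
            ax.set_xscale("log")
        ax.set_xlabel("genomes added")
        ax.set_ylabel(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
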
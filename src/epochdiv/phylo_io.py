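"""Readers, writers and containers for trees, clade-sampling tables and
environmental series.

Conventions
-----------
Ages are in Myr before present with 0 = the present; node ages increase
toward the root.  The likelihood works in forward time from the start of the
epoch grid; :func:`to_forward_time` converts between the two (it is its own
inverse).  Epoch intervals are half-open ``(older, younger]`` in age, so an
observation sitting exactly on a boundary belongs to the *younger* epoch.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "CladeSamplingTable",
    "EnvSeries",
    "read_tree",
    "resolve_clades",
    "bin_environment",
    "to_forward_time",
    "write_trace",
    "read_trace",
]


def to_forward_time(t: float | np.ndarray, span: float):
    """Convert an age (Myr before present) to forward time from the start of
    a span, or back again — the map ``t -> span - t`` is an involution."""
    return span - np.asarray(t) if np.ndim(t) else span - t


class TimeTree:
    """A rooted, ultrametric, binary time-calibrated tree.

    Wraps a :class:`dendropy.Tree`; node ages are computed from root-to-tip
    path sums and validated on construction.

    Parameters
    ----------
    tree:
        A rooted dendropy tree with branch lengths in Myr.
    tol_factor:
        Relative ultrametricity tolerance; tips must sit within
        ``tol_factor * root_age`` of the present.
    """

    def __init__(self, tree: dendropy.Tree, tol_factor: float = 1e-6):
        tree.is_rooted = True
        self._tree = tree
        self._tol_factor = tol_factor
        self._index()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        t = dendropy.Tree.get(data=newick, schema="newick")
        return cls(t)

    # -- internals ------------------------------------------------------

    def _index(self) -> None:
        tree = self._tree
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValueError(
                f"root must have exactly two children, found "
                f"{len(root.child_nodes())}"
            )
        # root-to-node path lengths
        depth: dict = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            el = node.edge.length if node.edge.length is not None else 0.0
            depth[node] = depth[node.parent_node] + el
        leaves = [nd for nd in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise ValueError("tree must have at least two tips")
        span = max(depth[lf] for lf in leaves)
        tol = self._tol_factor * span
        for lf in leaves:
            if abs(span - depth[lf]) > tol:
                label = lf.taxon.label if lf.taxon is not None else "<unnamed>"
                raise ValueError(
                    f"tree is not ultrametric: tip {label!r} ends "
                    f"{span - depth[lf]:.6g} Myr short of the present "
                    f"(tolerance {tol:.3g})"
                )
        ages: dict = {}
        for node in tree.preorder_node_iter():
            age = span - depth[node]
            ages[node] = 0.0 if node.is_leaf() else age
            if not node.is_leaf():
                if len(node.child_nodes()) != 2:
                    raise ValueError("tree must be fully bifurcating")
                if age <= 0.0:
                    raise ValueError("internal node ages must be positive")
        for node in tree.preorder_node_iter():
            if node is not root and not node.is_leaf():
                if ages[node] >= ages[node.parent_node] + tol:
                    raise ValueError("child node older than its parent")
        self._ages = ages
        self._root_age = span
        self._tips = sorted(
            lf.taxon.label for lf in leaves if lf.taxon is not None
        )
        self._taxon_by_label = {
            lf.taxon.label: lf.taxon for lf in leaves if lf.taxon is not None
        }
        internal = np.array(
            sorted(ages[nd] for nd in tree.preorder_internal_node_iter())
        )
        self._internal_ages = internal

    # -- accessors ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tips(self) -> list:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def root_age(self) -> float:
        return self._root_age

    @property
    def internal_ages(self) -> np.ndarray:
        """All internal-node ages (root included), ascending."""
        return self._internal_ages.copy()

    @property
    def non_root_internal_ages(self) -> np.ndarray:
        """Branching ages excluding the root split, ascending."""
        return self._internal_ages[:-1].copy()

    def node_age(self, node) -> float:
        return self._ages[node]

    def mrca(self, taxon_a: str, taxon_b: str):
        missing = [t for t in (taxon_a, taxon_b) if t not in self._taxon_by_label]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        node = self._tree.mrca(
            taxa=[self._taxon_by_label[taxon_a], self._taxon_by_label[taxon_b]]
        )
        return node

    def mrca_age(self, taxon_a: str, taxon_b: str) -> float:
        return self._ages[self.mrca(taxon_a, taxon_b)]

    def stem_age(self, taxon_a: str, taxon_b: str) -> float:
        """Age of the parent of the MRCA; the root's stem age is the root age."""
        node = self.mrca(taxon_a, taxon_b)
        if node.parent_node is None:
            return self._root_age
        return self._ages[node.parent_node]

    # -- output ---------------------------------------------------------

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        ).strip()

    def write(self, path, format: str = "newick") -> None:
        if format not in ("newick", "nexus"):
            raise ValueError(f"unsupported tree format {format!r}")
        self._tree.write(
            path=str(path),
            schema=format,
            real_value_format_specifier=".17g",
            **({"suppress_rooting": True} if format == "newick" else {}),
        )


def read_tree(path, format: str = "newick") -> TimeTree:
    """Read a rooted ultrametric tree (branch lengths in Myr)."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    tree = dendropy.Tree.get(path=str(path), schema=format)
    return TimeTree(tree)


@dataclass
class CladeRow:
    clade: str
    taxon_a: str
    taxon_b: str
    missing: int
    crown_age: float | None = None
    stem_age: float | None = None


@dataclass
class CladeSamplingTable:
    """Named clades with known numbers of missing (unsampled) species.

    Each clade is identified by two sampled tips whose MRCA defines it;
    ``missing`` is the count of extant species of the clade absent from the
    tree.  After :func:`resolve_clades` the crown/stem ages and the global
    sampling summary (n sampled, m total, rho = n/m) are populated.
    """

    rows: list = field(default_factory=list)
    n_sampled: int | None = None

    def __post_init__(self):
        for r in self.rows:
            if r.missing < 0:
                raise ValueError(f"clade {r.clade!r}: missing count < 0")

    @classmethod
    def from_csv(cls, path) -> "CladeSamplingTable":
        df = pd.read_csv(path)
        required = {"clade", "taxonA", "taxonB", "missing"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"clade table must have columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        rows = [
            CladeRow(str(r.clade), str(r.taxonA), str(r.taxonB), int(r.missing))
            for r in df.itertuples()
        ]
        return cls(rows)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "clade": [r.clade for r in self.rows],
                "taxonA": [r.taxon_a for r in self.rows],
                "taxonB": [r.taxon_b for r in self.rows],
                "missing": [r.missing for r in self.rows],
            }
        ).to_csv(path, index=False)

    @property
    def total_missing(self) -> int:
        return int(sum(r.missing for r in self.rows))

    @property
    def m_total(self) -> int:
        if self.n_sampled is None:
            raise ValueError("table not resolved against a tree yet")
        return self.n_sampled + self.total_missing

    @property
    def rho(self) -> float:
        return self.n_sampled / self.m_total

    def crown_ages(self) -> np.ndarray:
        return np.array([r.crown_age for r in self.rows], dtype=float)

    def stem_ages(self) -> np.ndarray:
        return np.array([r.stem_age for r in self.rows], dtype=float)

    def missing_counts(self) -> np.ndarray:
        return np.array([r.missing for r in self.rows], dtype=float)


def resolve_clades(tree: TimeTree, table: CladeSamplingTable) -> CladeSamplingTable:
    """Resolve each clade's MRCA on ``tree``, recording crown and stem ages.

    Raises if any defining taxon is absent or two clades resolve to the same
    MRCA node.
    """
    tip_set = set(tree.tips)
    missing_labels = sorted(
        {
            t
            for r in table.rows
            for t in (r.taxon_a, r.taxon_b)
            if t not in tip_set
        }
    )
    if missing_labels:
        raise KeyError(f"taxa not in tree: {missing_labels}")
    seen_nodes = {}
    resolved = []
    for r in table.rows:
        node = tree.mrca(r.taxon_a, r.taxon_b)
        if id(node) in seen_nodes:
            raise ValueError(
                f"clades {seen_nodes[id(node)]!r} and {r.clade!r} resolve to "
                f"the same MRCA"
            )
        seen_nodes[id(node)] = r.clade
        stem = (
            tree.root_age
            if node.parent_node is None
            else tree.node_age(node.parent_node)
        )
        resolved.append(
            CladeRow(
                r.clade,
                r.taxon_a,
                r.taxon_b,
                r.missing,
                crown_age=tree.node_age(node),
                stem_age=stem,
            )
        )
    return CladeSamplingTable(resolved, n_sampled=tree.n_tips)


@dataclass
class EnvSeries:
    """An environmental time series as age-value pairs, optionally binned
    onto an epoch grid.

    ``ages`` are Myr before present; any input ordering is normalised to
    ascending age.  After :func:`bin_environment`, ``epoch_means`` holds the
    arithmetic mean per epoch (present epoch first), ``epoch_deltas`` the
    first differences ``E_i - E_{i-1}`` (zero for the present epoch) and
    ``epoch_counts`` the number of raw observations per epoch.
    """

    ages: np.ndarray
    values: np.ndarray
    epoch_means: np.ndarray | None = None
    epoch_deltas: np.ndarray | None = None
    epoch_counts: np.ndarray | None = None
    epoch_breaks: np.ndarray | None = None

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be 1-D and equal length")
        order = np.argsort(ages, kind="stable")
        ages, values = ages[order], values[order]
        if np.any(np.diff(ages) == 0.0):
            raise ValueError("ages must be unique")
        self.ages, self.values = ages, values

    @classmethod
    def from_csv(cls, path) -> "EnvSeries":
        df = pd.read_csv(path)
        if not {"age_mya", "value"}.issubset(df.columns):
            raise ValueError(
                "environment CSV must have columns 'age_mya' and 'value'"
            )
        return cls(df["age_mya"].to_numpy(float), df["value"].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_mya": self.ages, "value": self.values}).to_csv(
            path, index=False, float_format="%.17g"
        )


def _epoch_index(ages: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    # half-open (older, younger]: a boundary observation joins the younger
    # epoch; age 0 joins epoch 0.
    idx = np.searchsorted(breaks, ages, side="left") - 1
    return np.clip(idx, 0, len(breaks) - 2)


def bin_environment(env: EnvSeries, grid) -> EnvSeries:
    """Arithmetic per-epoch means of an environmental series on ``grid``.

    ``grid`` is anything with a ``breaks`` attribute of ascending epoch
    boundary ages (present first).  Observations older than the grid span
    are ignored.  Epochs with no observations are filled by linear
    interpolation of neighbouring epoch means (with a warning).
    """
    breaks = np.asarray(grid.breaks, dtype=float)
    k = len(breaks) - 1
    inside = env.ages <= breaks[-1] + 1e-12
    ages, values = env.ages[inside], env.values[inside]
    if ages.size == 0:
        raise ValueError("environmental series does not overlap the grid span")
    idx = _epoch_index(ages, breaks)
    counts = np.bincount(idx, minlength=k).astype(int)
    sums = np.bincount(idx, weights=values, minlength=k)
    means = np.full(k, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    if not np.all(nz):
        mids = 0.5 * (breaks[:-1] + breaks[1:])
        empty = np.flatnonzero(~nz)
        warnings.warn(
            f"{empty.size} epoch(s) contain no environmental observations; "
            "filling by linear interpolation of neighbouring epoch means",
            stacklevel=2,
        )
        means[~nz] = np.interp(mids[~nz], mids[nz], means[nz])
    deltas = np.zeros(k)
    deltas[1:] = np.diff(means)
    return EnvSeries(
        env.ages.copy(),
        env.values.copy(),
        epoch_means=means,
        epoch_deltas=deltas,
        epoch_counts=counts,
        epoch_breaks=breaks.copy(),
    )


# -- posterior traces ---------------------------------------------------

_TRACE_LEAD = ["iteration", "lnPosterior", "lnLikelihood", "lnPrior"]


def write_trace(trace, path) -> None:
    """Write a posterior trace as full-precision TSV (one row per retained
    sample; header mandatory)."""
    df = trace.df if hasattr(trace, "df") else trace
    cols = _TRACE_LEAD + [c for c in df.columns if c not in _TRACE_LEAD]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for c in _TRACE_LEAD:
        if c not in df.columns:
            raise ValueError(f"trace file missing required column {c!r}")
    return df
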
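"""Forward simulation of episodic and environment-linked birth-death trees.

Provides the generative side of the package: complete-process simulation with
piecewise-constant rates (Gillespie with exact epoch-boundary handling),
uniform pruning, the "add missing species, redraw divergence times, prune"
protocol that mimics empirical (clade-biased) taxon sampling, a fast
replicated sampler of reconstructed branching times used as a Monte-Carlo
oracle for the speciation-time CDF, and deterministic fixture generation.

Conditioning on survival (at least two sampled tips) is implemented by
rejection, which is simple and exact; a warning is emitted when the
acceptance rate falls below 1%.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field

import numpy as np

from .env_link import fixed_env_rates
from .likelihood import EpochGrid, njit, speciation_time_cdf
from .phylo_io import (
    CladeRow,
    CladeSamplingTable,
    EnvSeries,
    TimeTree,
    bin_environment,
    resolve_clades,
)

__all__ = [
    "SimConfig",
    "simulate_tree",
    "prune_uniform",
    "simulate_empirical_sampling",
    "make_fixture_suite",
    "sample_reconstructed_branching_ages",
    "cenozoic_co2_curve",
    "env_linked_grid",
]

sys.setrecursionlimit(max(sys.getrecursionlimit(), 100_000))


@dataclass
class SimConfig:
    """Settings for one batch of forward simulations.

    Exactly one stop condition must be set: ``root_age`` (the process starts
    with two lineages that far in the past) or ``n_taxa`` (the clock stops
    when the extant count first reaches the target; constant rates only).
    """

    grid: EpochGrid
    seed: int
    root_age: float | None = None
    n_taxa: int | None = None
    rho: float = 1.0
    min_sampled: int = 2
    max_rejections: int = 10_000
    #: with "root_split" both root children must leave sampled descendants
    #: (the reconstructed root age equals the starting age), matching the
    #: likelihood's S(2, t1, T) conditioning exactly; "sampled2" only asks
    #: for two sampled tips overall.
    condition: str = "sampled2"

    def __post_init__(self):
        if (self.root_age is None) == (self.n_taxa is None):
            raise ValueError("set exactly one of root_age or n_taxa")
        if self.n_taxa is not None and self.grid.k != 1:
            raise ValueError("taxon-count stop requires constant (1-epoch) rates")
        if self.seed is None:
            raise ValueError("seed is mandatory")


class _Lineage:
    __slots__ = ("birth_age", "end_age", "children", "sampled", "label")

    def __init__(self, birth_age):
        self.birth_age = birth_age
        self.end_age = None
        self.children = None
        self.sampled = False
        self.label = None


def _rate_index(breaks: np.ndarray, age: float) -> int:
    idx = int(np.searchsorted(breaks, age, side="left")) - 1
    return min(max(idx, 0), len(breaks) - 2)


def _simulate_complete(grid: EpochGrid, root_age: float, rng, cap: int = 100_000):
    """One realisation of the complete process from two lineages at
    ``root_age``; returns (root lineage pair, extant lineages) or None when
    the lineage cap is exceeded."""
    breaks, lam, mu = grid.breaks, grid.lam, grid.mu
    left, right = _Lineage(root_age), _Lineage(root_age)
    active = [left, right]
    n_created = 2
    a = root_age
    while active and a > 0.0:
        i = _rate_index(breaks, a)
        total = len(active) * (lam[i] + mu[i])
        w = rng.exponential(1.0 / total)
        if a - w <= breaks[i]:
            if i == 0:
                break
            a = breaks[i]
            continue
        a -= w
        u = rng.integers(len(active))
        lin = active[u]
        if rng.random() < lam[i] / (lam[i] + mu[i]):
            lin.end_age = a
            c1, c2 = _Lineage(a), _Lineage(a)
            lin.children = (c1, c2)
            active[u] = c1
            active.append(c2)
            n_created += 2
            if n_created > cap:
                return None
        else:
            lin.end_age = a
            active[u] = active[-1]
            active.pop()
    for lin in active:
        lin.end_age = 0.0
    return (left, right), active


def _simulate_count_stop(grid: EpochGrid, n_taxa: int, rng, cap: int = 100_000):
    """Constant-rate simulation from two lineages, stopping the clock when
    the extant count first reaches ``n_taxa``; returns the elapsed time and
    the lineage pair, in *elapsed* coordinates (birth ages as time since the
    root; converted to ages by the caller)."""
    lam, mu = float(grid.lam[0]), float(grid.mu[0])

    class _L:
        __slots__ = ("t0", "t1", "children", "sampled", "label")

        def __init__(self, t0):
            self.t0 = t0
            self.t1 = None
            self.children = None
            self.sampled = False
            self.label = None

    left, right = _L(0.0), _L(0.0)
    active = [left, right]
    t = 0.0
    n_created = 2
    while active:
        if len(active) >= n_taxa:
            break
        total = len(active) * (lam + mu)
        t += rng.exponential(1.0 / total)
        u = rng.integers(len(active))
        lin = active[u]
        if rng.random() < lam / (lam + mu):
            lin.t1 = t
            c1, c2 = _L(t), _L(t)
            lin.children = (c1, c2)
            active[u] = c1
            active.append(c2)
            n_created += 2
            if n_created > cap:
                return None
        else:
            lin.t1 = t
            active[u] = active[-1]
            active.pop()
    if len(active) < n_taxa:
        return None
    # the count first reaches the target exactly at a speciation event; place
    # the present uniformly inside the waiting interval to the next event so
    # the youngest node has a positive age
    total = len(active) * (lam + mu)
    t += rng.uniform(0.0, 1.0) * rng.exponential(1.0 / total)
    # convert elapsed times to ages with the present at t
    def conv(lin):
        out = _Lineage(t - lin.t0)
        out.end_age = 0.0 if lin.t1 is None else t - lin.t1
        if lin.children is not None:
            out.children = tuple(conv(c) for c in lin.children)
        return out

    return (conv(left), conv(right)), t


def _mark_sampled(extant, rho, rng) -> int:
    n = 0
    for lin in extant:
        lin.sampled = bool(rng.random() < rho) if rho < 1.0 else True
        n += lin.sampled
    return n


def _collect_extant(lin, out):
    if lin.children is None:
        if lin.end_age == 0.0:
            out.append(lin)
    else:
        for c in lin.children:
            _collect_extant(c, out)


def _reduce(lin):
    """Reconstructed-tree reduction: returns (newick fragment, top age) of the
    subtree with unsampled/extinct lineages pruned and unifurcations
    collapsed, or None when the lineage has no sampled descendant."""
    if lin.children is None:
        if not lin.sampled:
            return None
        return (lin.label, 0.0)
    kept = [r for r in (_reduce(c) for c in lin.children) if r is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    (sa, aa), (sb, ab) = kept
    split = lin.end_age
    return (f"({sa}:{split - aa:.12f},{sb}:{split - ab:.12f})", split)


def _to_timetree(pair) -> TimeTree | None:
    left, right = pair
    extant = []
    _collect_extant(left, extant)
    _collect_extant(right, extant)
    idx = 1
    for lin in sorted(extant, key=lambda l: l.birth_age, reverse=True):
        if lin.sampled:
            lin.label = f"t{idx}"
            idx += 1
    ra = left.birth_age
    ka = _reduce(left)
    kb = _reduce(right)
    if ka is None or kb is None:
        return None
    (sa, aa), (sb, ab) = ka, kb
    newick = f"({sa}:{ra - aa:.12f},{sb}:{ra - ab:.12f});"
    return TimeTree.from_newick(newick)


def simulate_tree(config: SimConfig) -> tuple:
    """Simulate one reconstructed tree; returns (TimeTree, truth record).

    Conditions on at least ``min_sampled`` sampled tips surviving, by
    rejection (an error after ``max_rejections`` failed attempts suggests the
    parameters cannot produce surviving trees of the requested size).
    """
    rng = np.random.default_rng(config.seed)
    attempts = 0
    while attempts < config.max_rejections:
        attempts += 1
        if config.root_age is not None:
            sim = _simulate_complete(config.grid, config.root_age, rng)
            if sim is None:
                continue
            pair, extant = sim
            root_age = config.root_age
        else:
            sim = _simulate_count_stop(config.grid, config.n_taxa, rng)
            if sim is None:
                continue
            pair, root_age = sim
            extant = []
            _collect_extant(pair[0], extant)
            _collect_extant(pair[1], extant)
        n_sampled = _mark_sampled(extant, config.rho, rng)
        if n_sampled < config.min_sampled:
            continue
        tree = _to_timetree(pair)
        if tree is None or tree.n_tips < config.min_sampled:
            continue
        if config.condition == "root_split" and abs(
            tree.root_age - root_age
        ) > 1e-9 * max(1.0, root_age):
            continue
        if attempts > 100:
            warnings.warn(
                f"simulation acceptance rate below 1% ({attempts} attempts)",
                stacklevel=2,
            )
        truth = {
            "breaks": config.grid.breaks.tolist(),
            "lambda": config.grid.lam.tolist(),
            "mu": config.grid.mu.tolist(),
            "rho": config.rho,
            "root_age": float(root_age),
            "n_tips": tree.n_tips,
            "attempts": attempts,
        }
        return tree, truth
    raise RuntimeError(
        f"no surviving simulation in {config.max_rejections} attempts; "
        "consider different rates or a smaller tree"
    )


def prune_uniform(tree: TimeTree, rho: float, seed: int) -> TimeTree:
    """Keep each tip independently with probability rho; retries with a fresh
    substream (and a warning) when fewer than two tips survive."""
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must be in (0, 1]")
    if rho == 1.0:
        return tree
    rng = np.random.default_rng(seed)
    for attempt in range(1000):
        keep = [t for t in tree.tips if rng.random() < rho]
        if len(keep) >= 2:
            if attempt > 0:
                warnings.warn(
                    f"pruning retried {attempt} time(s) to keep >= 2 tips",
                    stacklevel=2,
                )
            pruned = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=keep)
            return TimeTree(pruned)
    raise RuntimeError("could not retain two tips after 1000 pruning attempts")


# -- empirical-sampling protocol -----------------------------------------


def _ages_by_node(dtree):
    depth = {dtree.seed_node: 0.0}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    span = max(depth[lf] for lf in dtree.leaf_node_iter())
    return {nd: (0.0 if nd.is_leaf() else span - depth[nd]) for nd in depth}, span


def _cdf_inverse_sampler(grid: EpochGrid, root_age: float, n_grid: int = 4096):
    t1 = grid.span - root_age  # forward time of the root
    ts = np.linspace(t1, grid.span, n_grid)
    F = np.array([speciation_time_cdf(grid, t, t_origin=t1) for t in ts])
    F[-1] = F[-1] if grid.rho < 1.0 else 1.0

    def inv(u):
        return grid.span - np.interp(u * F[-1], F, ts)  # ages

    return inv


def simulate_empirical_sampling(
    base_tree: TimeTree,
    clades: CladeSamplingTable,
    rate_source,
    seed: int,
) -> tuple:
    """The prune protocol: graft each clade's missing species onto the tree
    at uniformly chosen positions, redraw all divergence times from the
    requested process conditional on the (ranked) topology, then prune the
    grafted tips again.

    ``rate_source`` is an :class:`EpochGrid` (rho must be 1; use a one-epoch
    grid for the constant-rate protocol).  Returns
    (pruned TimeTree, resolved CladeSamplingTable, complete TimeTree).
    """
    grid = rate_source
    if grid.rho != 1.0:
        raise ValueError("the redraw process is a complete-tree process; rho must be 1")
    rng = np.random.default_rng(seed)
    resolved = resolve_clades(base_tree, clades)
    dtree = base_tree.dendropy_tree.clone(depth=1)
    taxon_ns = dtree.taxon_namespace
    ages, root_age = _ages_by_node(dtree)
    if grid.span + 1e-9 < root_age:
        raise ValueError("rate grid must span the root age")

    label_to_leaf = {
        lf.taxon.label: lf for lf in dtree.leaf_node_iter() if lf.taxon is not None
    }
    def _mrca_node(leaf_a, leaf_b):
        anc = set()
        nd = leaf_a
        while nd is not None:
            anc.add(id(nd))
            nd = nd.parent_node
        nd = leaf_b
        while nd is not None:
            if id(nd) in anc:
                return nd
            nd = nd.parent_node
        raise RuntimeError("disconnected tree")

    added_labels = []
    counter = 0
    for row in resolved.rows:
        if row.taxon_a not in label_to_leaf or row.taxon_b not in label_to_leaf:
            raise ValueError(f"clade {row.clade!r} has no sampled members")
        for _ in range(row.missing):
            mrca = _mrca_node(
                label_to_leaf[row.taxon_a], label_to_leaf[row.taxon_b]
            )
            edges = [
                nd
                for nd in mrca.preorder_iter()
                if nd is not mrca
            ]
            target = edges[rng.integers(len(edges))]
            hi, lo = ages[target.parent_node], ages[target]
            attach_age = float(rng.uniform(lo, hi))
            parent = target.parent_node
            parent.remove_child(target)
            mid = parent.new_child(edge_length=hi - attach_age)
            mid.add_child(target)
            target.edge.length = attach_age - lo
            counter += 1
            label = f"missing{counter}"
            taxon = taxon_ns.new_taxon(label)
            tip = mid.new_child(taxon=taxon, edge_length=attach_age)
            ages[mid] = attach_age
            ages[tip] = 0.0
            added_labels.append(label)

    # redraw all non-root divergence times from the process, rank-preserving
    internal = [
        nd
        for nd in dtree.preorder_internal_node_iter()
        if nd is not dtree.seed_node
    ]
    if internal:
        inv = _cdf_inverse_sampler(grid, root_age)
        draws = np.sort(inv(rng.uniform(size=len(internal))))[::-1]  # ages desc
        for nd, new_age in zip(
            sorted(internal, key=lambda x: ages[x], reverse=True), draws
        ):
            ages[nd] = float(new_age)
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = ages[nd.parent_node] - ages[nd]

    complete = TimeTree(dtree)
    if added_labels:
        pruned_d = complete.dendropy_tree.extract_tree_with_taxa_labels(
            labels=base_tree.tips
        )
        pruned = TimeTree(pruned_d)
    else:
        pruned = complete
    out_table = resolve_clades(
        pruned, CladeSamplingTable([CladeRow(r.clade, r.taxon_a, r.taxon_b, r.missing) for r in resolved.rows])
    )
    return pruned, out_table, complete


# -- Monte-Carlo oracle for reconstructed branching times ----------------


@njit(cache=False)
def _branching_ages_kernel(breaks, lam, mu, rho, t1_age, n_reps, seed, cap,
                           one_per_tree):
    np.random.seed(seed)
    out = np.empty(n_reps * 8, dtype=np.float64)
    n_out = 0
    k_top = breaks.shape[0] - 2
    for _ in range(n_reps):
        end_type = np.zeros(cap, dtype=np.uint8)  # 0 open, 1 extinct, 2 split
        end_ev = np.full(cap, -1, dtype=np.int32)
        ev_time = np.empty(cap, dtype=np.float64)
        ev_a = np.empty(cap, dtype=np.int32)
        ev_b = np.empty(cap, dtype=np.int32)
        active = np.empty(cap, dtype=np.int32)
        active[0] = 0
        n_active = 1
        n_lin = 1
        n_ev = 0
        a = t1_age
        overflow = False
        while n_active > 0 and a > 0.0:
            i = np.searchsorted(breaks, a) - 1
            if i < 0:
                i = 0
            if i > k_top:
                i = k_top
            total = n_active * (lam[i] + mu[i])
            w = np.random.exponential(1.0 / total)
            if a - w <= breaks[i]:
                if i == 0:
                    break
                a = breaks[i]
                continue
            a -= w
            u = np.random.randint(n_active)
            lin = active[u]
            if np.random.random() < lam[i] / (lam[i] + mu[i]):
                if n_lin + 2 > cap or n_ev + 1 > cap:
                    overflow = True
                    break
                end_type[lin] = 2
                end_ev[lin] = n_ev
                ev_time[n_ev] = a
                ev_a[n_ev] = n_lin
                ev_b[n_ev] = n_lin + 1
                active[u] = n_lin
                active[n_active] = n_lin + 1
                n_active += 1
                n_lin += 2
                n_ev += 1
            else:
                end_type[lin] = 1
                active[u] = active[n_active - 1]
                n_active -= 1
        if overflow:
            continue
        good = np.zeros(n_lin, dtype=np.uint8)
        for u in range(n_active):
            if np.random.random() < rho:
                good[active[u]] = 1
        for lin in range(n_lin - 1, -1, -1):
            if end_type[lin] == 2:
                ev = end_ev[lin]
                if good[ev_a[ev]] == 1 or good[ev_b[ev]] == 1:
                    good[lin] = 1
        if good[0] == 0:
            continue
        if one_per_tree:
            # reservoir-sample a single reconstructed event per replicate so
            # pooled draws are independent
            kept = -1.0
            n_good = 0
            for ev in range(n_ev):
                if good[ev_a[ev]] == 1 and good[ev_b[ev]] == 1:
                    n_good += 1
                    if np.random.random() < 1.0 / n_good:
                        kept = ev_time[ev]
            if n_good > 0 and n_out < out.shape[0]:
                out[n_out] = kept
                n_out += 1
        else:
            for ev in range(n_ev):
                if good[ev_a[ev]] == 1 and good[ev_b[ev]] == 1:
                    if n_out < out.shape[0]:
                        out[n_out] = ev_time[ev]
                        n_out += 1
    return out[:n_out]


def sample_reconstructed_branching_ages(
    grid: EpochGrid,
    t1_age: float,
    n_reps: int,
    seed: int,
    cap: int = 4096,
    one_per_tree: bool = False,
) -> np.ndarray:
    """Ages of reconstructed-tree branching events pooled over ``n_reps``
    forward simulations, each starting from a single lineage at age
    ``t1_age`` and thinned by the grid's sampling fraction at the present.
    The empirical distribution of these ages is the Monte-Carlo counterpart
    of :func:`epochdiv.likelihood.speciation_time_cdf` (normalised by its
    value at the present, which is below one when rho < 1).  With
    ``one_per_tree`` a single uniformly chosen event per surviving replicate
    is returned, giving independent draws."""
    return _branching_ages_kernel(
        grid.breaks,
        grid.lam,
        grid.mu,
        float(grid.rho),
        float(t1_age),
        int(n_reps),
        int(seed) % (2**31 - 1),
        int(cap),
        one_per_tree,
    )


# -- environment helpers and fixtures ------------------------------------


def cenozoic_co2_curve(ages) -> np.ndarray:
    """A smooth synthetic Cenozoic-like CO2 curve (ppm): high Palaeogene
    values declining through a steep Oligocene-like step (~34 Mya) to modern
    levels, with mild long-period wiggles."""
    a = np.asarray(ages, dtype=float)
    step = 420.0 / (1.0 + np.exp(-(a - 33.5) / 2.2))
    ramp = 3.2 * a
    wiggle = 25.0 * np.sin(a / 4.5) * np.exp(-((a - 15.0) / 25.0) ** 2)
    return 280.0 + step + ramp + wiggle


def env_linked_grid(
    env: EnvSeries,
    root_age: float,
    n_epochs: int,
    lam0: float,
    mu0: float,
    beta_lam: float,
    beta_mu: float,
    sigma_lam: float,
    sigma_mu: float,
    seed: int,
    rho: float = 1.0,
) -> tuple:
    """Generate a GMRF-env rate grid: log rates follow the environmental
    trend ``beta * dE`` plus Normal(0, sigma) innovations per epoch (the
    sigma = 0 case is the fixed-linkage model).  Returns (EpochGrid, truth).
    """
    rng = np.random.default_rng(seed)
    breaks = np.linspace(0.0, root_age, n_epochs + 1)
    shell = EpochGrid(breaks, np.ones(n_epochs), np.zeros(n_epochs), rho)
    binned = bin_environment(env, shell)
    d = binned.epoch_deltas
    ln_lam = np.log(fixed_env_rates(lam0, beta_lam, d))
    ln_mu = np.log(fixed_env_rates(mu0, beta_mu, d))
    if sigma_lam > 0:
        ln_lam[1:] += np.cumsum(rng.normal(0.0, sigma_lam, n_epochs - 1))
    if sigma_mu > 0:
        ln_mu[1:] += np.cumsum(rng.normal(0.0, sigma_mu, n_epochs - 1))
    grid = EpochGrid(breaks, np.exp(ln_lam), np.exp(ln_mu), rho)
    truth = {
        "lam0": lam0,
        "mu0": mu0,
        "beta_lambda": beta_lam,
        "beta_mu": beta_mu,
        "sigma_lambda": sigma_lam,
        "sigma_mu": sigma_mu,
        "delta_env": d.tolist(),
        "lambda": grid.lam.tolist(),
        "mu": grid.mu.tolist(),
    }
    return grid, truth


def _pick_clades(tree: TimeTree, rng, n_clades: int, total_missing: int):
    """Disjoint named clades with young-biased missing counts summing to
    ``total_missing``."""
    dtree = tree.dendropy_tree
    candidates = []
    for nd in dtree.preorder_internal_node_iter():
        if nd is dtree.seed_node:
            continue
        tips = [lf.taxon.label for lf in nd.leaf_iter()]
        if 2 <= len(tips) <= max(3, tree.n_tips // 4):
            candidates.append((nd, tips))
    order = rng.permutation(len(candidates))
    used: set = set()
    chosen = []
    for j in order:
        nd, tips = candidates[j]
        if used.intersection(tips):
            continue
        used.update(tips)
        chosen.append((nd, tips))
        if len(chosen) == n_clades:
            break
    if len(chosen) < 2:
        raise RuntimeError("tree too small to carve clades from")
    weights = []
    for nd, tips in chosen:
        age = tree.node_age(nd)
        weights.append(len(tips) * (1.0 + 3.0 * np.exp(-age / 10.0)))
    w = np.array(weights) / np.sum(weights)
    ks = np.floor(w * total_missing).astype(int)
    ks[int(np.argmax(ks))] += total_missing - int(ks.sum())
    rows = []
    for (nd, tips), k in zip(chosen, ks):
        rows.append(
            CladeRow(f"clade{len(rows) + 1}", tips[0], tips[-1], int(k))
        )
    return CladeSamplingTable(rows)


def make_fixture_suite(out_dir, seed: int) -> dict:
    """Write a deterministic fixture set: three trees (50/200/500 tips), a
    synthetic Cenozoic-like CO2 CSV, clade-sampling tables with clade-biased
    missing counts, and truth JSONs.  Returns the paths written."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {}

    env_ages = np.arange(0.0, 60.25, 0.25)
    env = EnvSeries(env_ages, cenozoic_co2_curve(env_ages))
    env_path = out / "co2_synthetic.csv"
    env.to_csv(env_path)
    paths["env"] = env_path

    def write_tree(name, tree, truth):
        tpath = out / f"{name}.nwk"
        tree.write(tpath, format="newick")
        table = _pick_clades(
            tree,
            np.random.default_rng(int(rng.integers(2**31 - 1))),
            n_clades=min(11, max(5, tree.n_tips // 18)),
            total_missing=2 * tree.n_tips,
        )
        cpath = out / f"{name}_clades.csv"
        table.to_csv(cpath)
        jpath = out / f"{name}_truth.json"
        jpath.write_text(json.dumps(truth, sort_keys=True, indent=1))
        paths[name] = tpath
        paths[f"{name}_clades"] = cpath
        paths[f"{name}_truth"] = jpath

    g50 = EpochGrid.regular(1.0, [0.12], [0.04])
    tree50, truth50 = simulate_tree(
        SimConfig(grid=g50, seed=int(rng.integers(2**31 - 1)), n_taxa=50)
    )
    write_tree("tree50", tree50, truth50)

    best = None
    for _ in range(3000):
        sub = int(rng.integers(2**31 - 1))
        grid200, truth200 = env_linked_grid(
            env, 45.0, 10, lam0=0.28, mu0=0.10, beta_lam=-0.005,
            beta_mu=-0.002, sigma_lam=0.02, sigma_mu=0.02, seed=sub,
        )
        try:
            tr, tt = simulate_tree(
                SimConfig(grid=grid200, seed=sub, root_age=45.0, max_rejections=50)
            )
        except RuntimeError:
            continue
        if best is None or abs(tr.n_tips - 200) < abs(best[0].n_tips - 200):
            best = (tr, {**tt, **truth200})
        if tr.n_tips == 200:
            break
    write_tree("tree200", best[0], best[1])

    g500 = EpochGrid.regular(1.0, [0.15], [0.05])
    tree500, truth500 = simulate_tree(
        SimConfig(grid=g500, seed=int(rng.integers(2**31 - 1)), n_taxa=500)
    )
    write_tree("tree500", tree500, truth500)
    return paths
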
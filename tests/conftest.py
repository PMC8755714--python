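"""Shared fixtures and independent oracles for the test suite.

The constant-rate (Nee et al.) reconstructed-process formulas and the
conjugate normal-mean model are coded here directly from their classical
closed forms, independent of the package's episodic machinery, so they can
serve as oracles.
"""

import math

import numpy as np
import pytest

import epochdiv as ed
from epochdiv.inference import BayesianModel, ParamBlock

# -- constant-rate closed forms (independent oracle) ---------------------


def nee_survival(lam, mu, rho, t):
    """P(>=1 sampled descendant) for a lineage t Myr before present."""
    r = lam - mu
    return rho * r / (rho * lam + (lam * (1 - rho) - mu) * math.exp(-r * t))


def nee_p1(lam, mu, rho, t):
    """P(exactly one sampled descendant lineage) at age t."""
    r = lam - mu
    den = rho * lam + (lam * (1 - rho) - mu) * math.exp(-r * t)
    return rho * r * r * math.exp(-r * t) / (den * den)


def nee_tree_loglik(tree, lam, mu, rho):
    """Constant-rate reconstructed-process log density, conditioned on both
    root lineages surviving, with the labelled-history constant."""
    n = tree.n_tips
    ll = (n - 1) * math.log(2.0) - math.lgamma(n + 1.0)
    ll += 2.0 * (
        math.log(nee_p1(lam, mu, rho, tree.root_age))
        - math.log(nee_survival(lam, mu, rho, tree.root_age))
    )
    for a in tree.non_root_internal_ages:
        ll += math.log(lam) + math.log(nee_p1(lam, mu, rho, a))
    return ll


def yule_tree_loglik(tree, lam):
    """Pure-birth closed form (mu = 0, rho = 1): survival is certain and
    p1(t) = exp(-lam t)."""
    n = tree.n_tips
    ll = (n - 1) * math.log(2.0) - math.lgamma(n + 1.0)
    ll += -2.0 * lam * tree.root_age
    for a in tree.non_root_internal_ages:
        ll += math.log(lam) - lam * a
    return ll


# -- conjugate normal-mean model (engine oracle) -------------------------


class NormalMeanModel(BayesianModel):
    """y_i ~ Normal(mu, s_known); mu ~ Normal(m0, s0): closed-form posterior
    and marginal likelihood."""

    def __init__(self, y, s_known=1.0, m0=0.0, s0=2.0):
        self.y = np.asarray(y, dtype=float)
        self.s, self.m0, self.s0 = float(s_known), float(m0), float(s0)
        self.blocks = [ParamBlock("mu")]
        self.joint_moves = []
        self.meta = {}

    def log_prior(self, p):
        z = (p["mu"][0] - self.m0) / self.s0
        return -0.5 * z * z - math.log(self.s0) - 0.5 * math.log(2 * math.pi)

    def log_likelihood(self, p):
        z = (self.y - p["mu"][0]) / self.s
        return float(
            np.sum(-0.5 * z * z - math.log(self.s) - 0.5 * math.log(2 * math.pi))
        )

    def draw_from_prior(self, rng):
        return {"mu": np.array([rng.normal(self.m0, self.s0)])}

    def posterior_mean_var(self):
        prec = 1.0 / self.s0**2 + len(self.y) / self.s**2
        mean = (self.m0 / self.s0**2 + np.sum(self.y) / self.s**2) / prec
        return mean, 1.0 / prec

    def log_evidence(self):
        from scipy import stats

        n = len(self.y)
        cov = self.s**2 * np.eye(n) + self.s0**2 * np.ones((n, n))
        return float(
            stats.multivariate_normal.logpdf(self.y, mean=np.full(n, self.m0), cov=cov)
        )


# -- fixtures ------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_tree():
    """4-tip ultrametric tree: root 10, cherries at ages 3 and 6."""
    return ed.TimeTree.from_newick("((A:3,B:3):7,(C:6,D:6):4);")


@pytest.fixture(scope="session")
def toy_trees():
    """Three small fixed trees used by the constant-rate reduction checks."""
    return [
        ed.TimeTree.from_newick("((A:3,B:3):7,(C:6,D:6):4);"),
        ed.TimeTree.from_newick("(((A:1,B:1):4,C:5):5,(D:8,E:8):2);"),
        ed.TimeTree.from_newick("((A:2.5,B:2.5):9.5,C:12);"),
    ]


@pytest.fixture(scope="session")
def cenozoic_env():
    ages = np.arange(0.0, 45.25, 0.25)
    return ed.EnvSeries(ages, ed.cenozoic_co2_curve(ages))


@pytest.fixture(scope="session")
def sim_tree_200():
    """A simulated ~200-tip constant-rate tree (shared across tests)."""
    grid = ed.EpochGrid.regular(1.0, [0.12], [0.04])
    tree, _ = ed.simulate_tree(ed.SimConfig(grid=grid, seed=97, n_taxa=200))
    return tree
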
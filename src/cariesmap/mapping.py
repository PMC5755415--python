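"""Bayesian disease mapping of parish-level caries risk.

Fits the BYM (convolution) model — Poisson counts with an ICAR spatially
structured effect plus exchangeable heterogeneity — to a parish table of
observed and expected cases, and summarizes the posterior as smoothed
relative risks (SmRR), credible intervals, exceedance probabilities
Pr(RR > 1 | data), and the red/yellow/green certainty classification used
on caries risk maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._bym_sampler import ChainDraws, run_chain

logger = logging.getLogger(__name__)

RHAT_WARN = 1.1

#: certainty-map color per classification
CATEGORY_COLORS = {"elevated": "red", "lowered": "green", "uncertain": "yellow"}


# ---------------------------------------------------------------------------
# adjacency


def load_edge_list(path, *, delimiter: str = ",") -> nx.Graph:
    """Read a two-column parish edge list into an undirected graph."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two columns")
    g = nx.Graph()
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a == b:
            raise ValueError(f"self-loop on parish {a!r}")
        g.add_edge(str(a).strip(), str(b).strip())
    return g


def write_edge_list(graph: nx.Graph, path, *, delimiter: str = ",") -> None:
    pd.DataFrame(sorted(graph.edges()), columns=["parish_id_a", "parish_id_b"]).to_csv(
        path, sep=delimiter, index=False
    )


def validate_graph(graph: nx.Graph, parish_ids) -> None:
    """Check the adjacency graph against a parish count table."""
    if any(a == b for a, b in graph.edges()):
        raise ValueError("adjacency graph contains a self-loop")
    missing = [p for p in parish_ids if p not in graph]
    if missing:
        raise ValueError(f"parishes absent from adjacency graph: {missing}")


def connectivity_report(graph: nx.Graph) -> dict:
    """Connected components and isolated parishes — ICAR needs one
    sum-to-zero constraint per component, and islands get no spatial effect."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    islands = sorted(n for n in graph if graph.degree(n) == 0)
    return {
        "n_components": len(comps),
        "components": comps,
        "islands": islands,
        "connected": len(comps) == 1,
    }


# ---------------------------------------------------------------------------
# configuration and results


@dataclass
class MCMCConfig:
    """Sampler settings for :func:`fit_bym`.

    ``sigma_u_fixed``/``sigma_v_fixed``/``alpha_fixed`` pin a hyperparameter
    instead of sampling it (e.g. ``sigma_u_fixed=0`` disables the spatial
    effect entirely, reducing the model to independent Poisson-lognormal).
    """

    n_chains: int = 4
    n_iterations: int = 5000
    n_burnin: int = 2500
    thinning: int = 1
    seed: int = 0
    sigma_u_scale: float = 1.0
    sigma_v_scale: float = 1.0
    alpha_sd: float = 10.0
    sigma_u_fixed: float | None = None
    sigma_v_fixed: float | None = None
    alpha_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


@dataclass
class PosteriorSummary:
    """Per-parish posterior summaries plus global diagnostics."""

    table: pd.DataFrame          # parish_id, smrr, ci bounds, pr_exceed, category
    alpha: dict                  # posterior summary of the intercept
    sigma_u: dict
    sigma_v: dict
    rhat: dict                   # per monitored quantity
    rhat_warning: bool
    theta_draws: np.ndarray = field(repr=False)   # (n_total_draws, n_parishes)
    parish_ids: list = field(default_factory=list)

    def draws_for(self, parish_id) -> np.ndarray:
        return self.theta_draws[:, self.parish_ids.index(parish_id)]


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor sqrt(1 + B_n/W) for one quantity.

    ``chains`` is (n_chains, n_draws).  B_n is the variance of the chain
    means and W the mean within-chain variance, so identical chains give
    exactly 1.0 and chains exploring disjoint regions blow up.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if chains.shape[1] < 2:
        raise ValueError("chains too short")
    W = chains.var(axis=1, ddof=1).mean()
    B_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B_n == 0.0 else float("inf")
    return float(np.sqrt(1.0 + B_n / W))


def check_convergence(chains_by_quantity: dict) -> dict:
    """Gelman–Rubin R-hat per monitored quantity.

    Values stacked as (n_chains, n_draws); ragged chain lengths are an error.
    """
    out = {}
    for name, chains in chains_by_quantity.items():
        arr = [np.asarray(c, dtype=float) for c in chains]
        if len({a.shape for a in arr}) != 1:
            raise ValueError(f"{name}: chains of unequal retained length")
        out[name] = gelman_rubin(np.stack(arr))
    return out


def exceedance(draws: np.ndarray) -> float:
    """Pr(RR > 1 | data): the fraction of posterior draws above 1."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError(f"need >= 100 retained draws, got {draws.size}")
    return float((draws > 1.0).mean())


def classify_certainty(pr_exceed: float, threshold: float = 0.95) -> str:
    """Three-color certainty rule for one parish.

    ``elevated`` (red) when Pr(RR > 1 | data) > threshold, ``lowered``
    (green) when Pr(RR < 1 | data) > threshold, else ``uncertain``
    (yellow).  Inequalities are strict, so 0.95 exactly is uncertain.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0.5, 1), got {threshold}")
    if not 0.0 <= pr_exceed <= 1.0:
        raise ValueError(f"pr_exceed must be in [0, 1], got {pr_exceed}")
    if pr_exceed > threshold:
        return "elevated"
    if (1.0 - pr_exceed) > threshold:
        return "lowered"
    return "uncertain"


# ---------------------------------------------------------------------------
# the estimator


class BYMMapper(BaseEstimator):
    """BYM convolution-model smoother for parish-level morbidity ratios.

    Parameters mirror :class:`MCMCConfig`.  ``fit`` takes the parish count
    table produced by :func:`cariesmap.cohort.expected_counts` plus the
    parish adjacency graph; fitted results live in ``summary_`` (one row
    per parish: smoothed relative risk ``smrr`` as the posterior median,
    90%/95% equal-tailed credible intervals, ``pr_exceed`` and the
    certainty ``category``/``color``).

    The sampler is Metropolis-within-Gibbs with graph-coloring block
    updates; identical data, parameters and seed give bit-identical output.
    """

    def __init__(
        self,
        n_chains: int = 4,
        n_iterations: int = 5000,
        n_burnin: int = 2500,
        thinning: int = 1,
        seed: int = 0,
        sigma_u_scale: float = 1.0,
        sigma_v_scale: float = 1.0,
        alpha_sd: float = 10.0,
        sigma_u_fixed: float | None = None,
        sigma_v_fixed: float | None = None,
        alpha_fixed: float | None = None,
        certainty_threshold: float = 0.95,
    ):
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.thinning = thinning
        self.seed = seed
        self.sigma_u_scale = sigma_u_scale
        self.sigma_v_scale = sigma_v_scale
        self.alpha_sd = alpha_sd
        self.sigma_u_fixed = sigma_u_fixed
        self.sigma_v_fixed = sigma_v_fixed
        self.alpha_fixed = alpha_fixed
        self.certainty_threshold = certainty_threshold

    # -- internals ---------------------------------------------------------

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            n_burnin=self.n_burnin,
            thinning=self.thinning,
            seed=self.seed,
            sigma_u_scale=self.sigma_u_scale,
            sigma_v_scale=self.sigma_v_scale,
            alpha_sd=self.alpha_sd,
            sigma_u_fixed=self.sigma_u_fixed,
            sigma_v_fixed=self.sigma_v_fixed,
            alpha_fixed=self.alpha_fixed,
        )

    def fit(self, counts: pd.DataFrame, graph: nx.Graph):
        """Run the MCMC on a parish count table.

        ``counts`` needs columns parish_id, observed, expected (expected
        strictly positive); ``graph`` must cover every parish.
        """
        cfg = self._config()
        counts = counts.reset_index(drop=True)
        ids = [str(p) for p in counts["parish_id"]]
        O = counts["observed"].to_numpy(dtype=float)
        E = counts["expected"].to_numpy(dtype=float)
        if np.any(E <= 0):
            bad = [ids[i] for i in np.nonzero(E <= 0)[0]]
            raise ValueError(f"non-positive expected count for parish(es): {bad}")
        validate_graph(graph, ids)

        sub = graph.subgraph(ids)
        index = {p: i for i, p in enumerate(ids)}
        n = len(ids)
        A = np.zeros((n, n))
        for a, b in sub.edges():
            A[index[a], index[b]] = A[index[b], index[a]] = 1.0

        comps_all = [np.array(sorted(index[p] for p in c)) for c in
                     nx.connected_components(sub)]
        components = [c for c in comps_all if c.size >= 2]
        islands = [ids[c[0]] for c in comps_all if c.size == 1]
        if islands:
            logger.warning(
                "parishes with no neighbours get only the unstructured effect: %s",
                islands,
            )
        coloring = nx.greedy_color(sub, strategy="largest_first")
        n_colors = 1 + max(coloring.values(), default=0)
        color_classes = [
            np.array(sorted(index[p] for p, c in coloring.items() if c == k))
            for k in range(n_colors)
        ]
        color_classes = [c for c in color_classes if c.size]

        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains: list[ChainDraws] = []
        for s in seeds:
            chains.append(
                run_chain(
                    O, E, A, color_classes, components,
                    n_iter=cfg.n_iterations,
                    n_burnin=cfg.n_burnin,
                    thin=cfg.thinning,
                    rng=np.random.default_rng(s),
                    sigma_u_scale=cfg.sigma_u_scale,
                    sigma_v_scale=cfg.sigma_v_scale,
                    alpha_sd=cfg.alpha_sd,
                    alpha_fixed=cfg.alpha_fixed,
                    sigma_u_fixed=cfg.sigma_u_fixed,
                    sigma_v_fixed=cfg.sigma_v_fixed,
                )
            )

        theta = np.concatenate([c.theta for c in chains], axis=0)
        log_theta_chains = np.stack([np.log(c.theta) for c in chains])  # (m, k, n)

        rhat: dict[str, float] = {}
        for j, p in enumerate(ids):
            rhat[f"log_theta[{p}]"] = gelman_rubin(log_theta_chains[:, :, j])
        if cfg.alpha_fixed is None:
            rhat["alpha"] = gelman_rubin(np.stack([c.alpha for c in chains]))
        if cfg.sigma_u_fixed is None and components:
            rhat["sigma_u"] = gelman_rubin(np.stack([c.sigma_u for c in chains]))
        if cfg.sigma_v_fixed is None:
            rhat["sigma_v"] = gelman_rubin(np.stack([c.sigma_v for c in chains]))
        rhat_warning = any(r > RHAT_WARN for r in rhat.values())
        if rhat_warning:
            worst = max(rhat, key=rhat.get)
            warnings.warn(
                f"MCMC convergence suspect: max R-hat {rhat[worst]:.3f} ({worst})",
                RuntimeWarning,
                stacklevel=2,
            )

        q = np.quantile(theta, [0.025, 0.05, 0.5, 0.95, 0.975], axis=0)
        pr = (theta > 1.0).mean(axis=0)
        cats = [classify_certainty(p, self.certainty_threshold) for p in pr]
        self.summary_ = pd.DataFrame(
            {
                "parish_id": ids,
                "observed": O.astype(int),
                "expected": E,
                "smr": O / E,
                "smrr": q[2],
                "ci90_low": q[1],
                "ci90_high": q[3],
                "ci95_low": q[0],
                "ci95_high": q[4],
                "pr_exceed": pr,
                "category": cats,
                "color": [CATEGORY_COLORS[c] for c in cats],
            }
        )

        def _summ(x: np.ndarray) -> dict:
            return {
                "median": float(np.median(x)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
            }

        self.alpha_ = _summ(np.concatenate([c.alpha for c in chains]))
        self.sigma_u_ = _summ(np.concatenate([c.sigma_u for c in chains]))
        self.sigma_v_ = _summ(np.concatenate([c.sigma_v for c in chains]))
        self.rhat_ = rhat
        self.rhat_warning_ = rhat_warning
        self.theta_draws_ = theta
        self.parish_ids_ = ids
        self.connectivity_ = connectivity_report(sub)
        return self

    def posterior_summary(self) -> PosteriorSummary:
        return PosteriorSummary(
            table=self.summary_,
            alpha=self.alpha_,
            sigma_u=self.sigma_u_,
            sigma_v=self.sigma_v_,
            rhat=self.rhat_,
            rhat_warning=self.rhat_warning_,
            theta_draws=self.theta_draws_,
            parish_ids=self.parish_ids_,
        )


def fit_bym(
    parish_counts: pd.DataFrame, graph: nx.Graph, config: MCMCConfig | None = None
) -> PosteriorSummary:
    """Functional wrapper around :class:`BYMMapper`."""
    config = config or MCMCConfig()
    mapper = BYMMapper(
        n_chains=config.n_chains,
        n_iterations=config.n_iterations,
        n_burnin=config.n_burnin,
        thinning=config.thinning,
        seed=config.seed,
        sigma_u_scale=config.sigma_u_scale,
        sigma_v_scale=config.sigma_v_scale,
        alpha_sd=config.alpha_sd,
        sigma_u_fixed=config.sigma_u_fixed,
        sigma_v_fixed=config.sigma_v_fixed,
        alpha_fixed=config.alpha_fixed,
    )
    mapper.fit(parish_counts, graph)
    return mapper.posterior_summary()
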
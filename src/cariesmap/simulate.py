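"""Synthetic regions and child cohorts with the structure the analysis assumes.

The study region this emulates: ~58 administrative parishes with
heterogeneous child populations, an overall caries prevalence (dmfs > 0)
near 10.5-10.6% among 3-6-year-olds, parish relative risks that are
spatially correlated and coupled to socio-economic composition, and a
small newly-arrived migrant subgroup with roughly four-fold prevalence
(3.1% of the cohort at 36% prevalence in the early year; 6.4% at 45% in
the later year).  The later-year profile also shifts the age distribution
toward 3- and 6-year-olds, mimicking extended recall intervals for
low-risk children, and attenuates the log-risk surface so the true
polarization narrows between years.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CHILD_COLUMNS


def make_lattice(rows: int, cols: int) -> nx.Graph:
    """Rook-contiguity lattice with string parish ids (row-major).

    Edge count is rows*(cols-1) + cols*(rows-1).  Node attribute ``pos``
    holds the (row, col) grid coordinate for map export.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    if rows * cols < 2:
        raise ValueError("lattice needs at least 2 cells")

    def pid(r: int, c: int) -> str:
        return f"P{r * cols + c + 1:02d}"

    g = nx.Graph()
    for r in range(rows):
        for c in range(cols):
            g.add_node(pid(r, c), pos=(r, c))
            if c + 1 < cols:
                g.add_edge(pid(r, c), pid(r, c + 1))
            if r + 1 < rows:
                g.add_edge(pid(r, c), pid(r + 1, c))
    return g


def _trimmed_lattice(n: int, cols: int) -> nx.Graph:
    """First ``n`` row-major cells of a lattice — stays connected."""
    rows = -(-n // cols)
    g = make_lattice(rows, cols)
    keep = [f"P{k + 1:02d}" for k in range(n)]
    return g.subgraph(keep).copy()


@dataclass(frozen=True)
class YearProfile:
    """Cohort profile for one examination year."""

    exam_year: int
    age_weights: dict = field(default_factory=lambda: {3: 0.25, 4: 0.25, 5: 0.25, 6: 0.25})
    migrant_fraction: float = 0.031
    migrant_prevalence: float = 0.36
    cohort_scale: float = 1.0     # multiplies parish child counts
    rr_scale: float = 1.0         # multiplies the true log-risk surface


#: early year: yearly recalls, even age mix, few newly arrived migrants
PROFILE_2010 = YearProfile(exam_year=2010)
#: later year: fewer 4-5-year-olds (extended recalls), larger migrant
#: subgroup with higher prevalence, attenuated risk surface
PROFILE_2016 = YearProfile(
    exam_year=2016,
    age_weights={3: 0.31, 4: 0.19, 5: 0.19, 6: 0.31},
    migrant_fraction=0.064,
    migrant_prevalence=0.45,
    cohort_scale=0.74,
    rr_scale=0.88,
)


@dataclass
class SimConfig:
    """Ground-truth generator settings.  ``seed`` is mandatory."""

    seed: int
    n_parishes: int = 58
    grid_cols: int = 8
    base_prevalence: float = 0.106
    mean_children_per_parish: float = 188.0
    size_heterogeneity: float = 0.5      # lognormal sd of parish population sizes
    ses_coupling: float = 0.25           # log-RR per SD of the SES risk composite
    spatial_sd: float = 0.40             # sd of the ICAR-correlated log-RR term
    noise_sd: float = 0.10               # sd of the unstructured log-RR term
    rr_range: tuple | None = None        # optionally pin the exact true RR span
    spatial_structure: str = "icar"      # "icar" (well-specified) or "independent"
    sex_rate_ratio: float = 1.15         # boy/girl caries rate ratio
    dmfs_geometric_p: float = 0.4        # zero-truncated geometric for case dmfs
    year_profiles: dict = field(
        default_factory=lambda: {2010: PROFILE_2010, 2016: PROFILE_2016}
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if not 0.0 <= self.base_prevalence <= 1.0:
            raise ValueError("base_prevalence must be a probability")
        if self.n_parishes < 2:
            raise ValueError("need at least 2 parishes")


@dataclass
class RegionTruth:
    """Synthetic ground truth for one region."""

    config: SimConfig
    graph: nx.Graph
    parish_ids: list
    coords: dict                  # parish_id -> (row, col)
    n_children: np.ndarray        # base-year children per parish
    ses: pd.DataFrame             # parish_id + SES proportions + composite
    log_rr_covariate: np.ndarray
    log_rr_spatial: np.ndarray
    log_rr_noise: np.ndarray
    base_rate: float

    @property
    def log_rr(self) -> np.ndarray:
        return self.log_rr_covariate + self.log_rr_spatial + self.log_rr_noise

    @property
    def true_rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def true_rr_for(self, profile: YearProfile) -> np.ndarray:
        return np.exp(profile.rr_scale * self.log_rr)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parish_id": self.parish_ids,
                "n_children": self.n_children,
                "true_rr": self.true_rr,
                "log_rr_covariate": self.log_rr_covariate,
                "log_rr_spatial": self.log_rr_spatial,
                "log_rr_noise": self.log_rr_noise,
            }
        )


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _icar_sample(graph: nx.Graph, order: list, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic CAR distribution (unit scale) by spectral
    decomposition of the graph Laplacian, zero-mean per construction."""
    L = nx.laplacian_matrix(graph, nodelist=order).toarray().astype(float)
    evals, evecs = np.linalg.eigh(L)
    pos = evals > 1e-9
    z = rng.standard_normal(int(pos.sum()))
    u = evecs[:, pos] @ (z / np.sqrt(evals[pos]))
    sd = u.std()
    return u / sd if sd > 0 else u


def simulate_region(config: SimConfig) -> RegionTruth:
    """Generate adjacency, populations, SES and a true log-risk surface.

    log RR_i = coupling * SES-composite_i + spatial_i + noise_i, centered to
    mean zero so the mean true RR is ~1; with ``rr_range`` set, the surface
    is affinely rescaled so its exponential spans exactly that interval.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    graph = _trimmed_lattice(config.n_parishes, config.grid_cols)
    order = sorted(graph.nodes())
    coords = {p: graph.nodes[p]["pos"] for p in order}
    n = config.n_parishes

    sizes = config.mean_children_per_parish * np.exp(
        config.size_heterogeneity * rng.standard_normal(n)
        - config.size_heterogeneity**2 / 2.0
    )
    n_children = np.maximum(np.round(sizes).astype(int), 10)

    edu = rng.beta(*_beta_params(0.21, 50.0), size=n)
    fbg = rng.beta(*_beta_params(0.082, 100.0), size=n)
    ppw = rng.beta(*_beta_params(0.215, 60.0), size=n)

    def z(x: np.ndarray) -> np.ndarray:
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    composite = z(-z(edu) + z(fbg) + z(ppw))
    covariate = config.ses_coupling * composite

    if config.spatial_structure == "icar":
        spatial = config.spatial_sd * _icar_sample(graph, order, rng)
    elif config.spatial_structure == "independent":
        spatial = config.spatial_sd * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown spatial_structure {config.spatial_structure!r}")
    if config.spatial_sd == 0:
        spatial = np.zeros(n)
    noise = config.noise_sd * rng.standard_normal(n)

    log_rr = covariate + spatial + noise
    log_rr = log_rr - log_rr.mean()
    if config.rr_range is not None:
        lo, hi = np.log(config.rr_range[0]), np.log(config.rr_range[1])
        span = log_rr.max() - log_rr.min()
        if span > 0:
            log_rr = lo + (log_rr - log_rr.min()) * (hi - lo) / span
        else:
            log_rr = np.full(n, (lo + hi) / 2.0)
    shift = log_rr - (covariate + spatial + noise)

    ses = pd.DataFrame(
        {
            "parish_id": order,
            "prop_higher_education": edu,
            "prop_foreign_background": fbg,
            "prop_low_purchasing_power": ppw,
            "ses_risk_composite": composite,
        }
    )
    return RegionTruth(
        config=config,
        graph=graph,
        parish_ids=order,
        coords=coords,
        n_children=n_children,
        ses=ses,
        log_rr_covariate=covariate + shift,  # absorb centering/rescaling here
        log_rr_spatial=spatial,
        log_rr_noise=noise,
        base_rate=config.base_prevalence,
    )


def simulate_cohort(
    truth: RegionTruth,
    profile: YearProfile | int = 2010,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one year's child-level examination records from a region truth.

    Case indicators are Bernoulli(clamp(base_rate * RR_i * sex_mult)); a
    case's dmfs is zero-truncated geometric, a non-case's is 0.  Migrant
    (foreign-born) children are added at the profile's fraction of the
    total cohort with the profile's flat prevalence, allocated to parishes
    proportionally to population.
    """
    if isinstance(profile, int):
        profile = truth.config.year_profiles[profile]
    cfg = truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 211, profile.exam_year])
    )
    ages = np.array(sorted(profile.age_weights))
    age_p = np.array([profile.age_weights[a] for a in ages], dtype=float)
    age_p = age_p / age_p.sum()
    r = cfg.sex_rate_ratio
    sex_mult = {"M": 2.0 * r / (1.0 + r), "F": 2.0 / (1.0 + r)}
    rr = truth.true_rr_for(profile)

    rows: list[dict] = []
    serial = 0

    def draw_children(parish: str, n: int, p_case: float, birth_class: str) -> None:
        nonlocal serial
        if n <= 0:
            return
        sex = np.where(rng.random(n) < 0.512, "M", "F")
        age = rng.choice(ages, size=n, p=age_p)
        mult = np.where(sex == "M", sex_mult["M"], sex_mult["F"])
        p = np.clip(p_case * mult, 0.0, 1.0)
        case = rng.random(n) < p
        dmfs = np.where(case, rng.geometric(cfg.dmfs_geometric_p, size=n), 0)
        for j in range(n):
            serial += 1
            rows.append(
                {
                    "child_id": f"{profile.exam_year}-{serial:06d}",
                    "exam_year": profile.exam_year,
                    "age": int(age[j]),
                    "sex": sex[j],
                    "parish_id": parish,
                    "birth_class": birth_class,
                    "dmfs": int(dmfs[j]),
                }
            )

    n_dom = np.maximum(np.round(truth.n_children * profile.cohort_scale).astype(int), 1)
    for i, parish in enumerate(truth.parish_ids):
        draw_children(parish, int(n_dom[i]), cfg.base_prevalence * rr[i], "domestic")

    total_dom = int(n_dom.sum())
    n_mig = int(round(profile.migrant_fraction / (1.0 - profile.migrant_fraction) * total_dom))
    if n_mig > 0:
        alloc = rng.multinomial(n_mig, n_dom / n_dom.sum())
        for i, parish in enumerate(truth.parish_ids):
            draw_children(parish, int(alloc[i]), profile.migrant_prevalence, "foreign_born")

    return pd.DataFrame(rows, columns=list(CHILD_COLUMNS))


def null_config(seed: int, **overrides) -> SimConfig:
    """A region whose true relative risks are all exactly 1."""
    base = SimConfig(seed=seed, ses_coupling=0.0, spatial_sd=0.0, noise_sd=0.0)
    return replace(base, **overrides) if overrides else base
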
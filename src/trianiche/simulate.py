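"""Synthetic data emulating every input of the comparative pipeline.

Generators for: ultrametric pure-birth (Yule) trees; continuous traits
with tunable phylogenetic signal λ; regression datasets whose residuals
carry phylogenetic autocorrelation; spatially clustered occurrence
clouds over bioclim rasters with a latitudinal climate gradient
(constructed so bio5 >= bio6 and bio16 >= bio17 hold at every cell); and
blood-meal tables with pure and mixed meals over a nested host taxonomy,
together with ground-truth diet breadths.

Every generator is deterministic given its seed. One global seed expands
to per-component substreams through fixed component keys (a
counter-based scheme), so adding a generator never shifts the streams of
existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .niche import AMERICAS_BBOX, HABITAT_COLUMNS, RANKS, HostTaxonomy, RasterGrid
from .phylo import RootedTree, TopologySet, brownian_covariance, lambda_transform, parse_newick

# fixed substream keys: never renumber, only append
_STREAMS = {
    "yule": 1,
    "bm": 2,
    "regression": 3,
    "landscape": 4,
    "bloodmeals": 5,
    "topologies": 6,
    "habitat": 7,
}


def _rng(seed: int, component: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[component], *map(int, extra)])
    )


@dataclass
class SimulationConfig:
    """Knobs for the occurrence-landscape generator.

    The defaults emulate the structure of the real inputs: a few dozen
    species, occurrence clouds of a few tight clusters inside an
    Americas-like bounding box, and rasters whose temperature declines
    with latitude while precipitation peaks at the equator.
    """

    seed: int
    n_species: int = 40
    points_per_species: int = 60
    n_clusters: int = 2
    cluster_sd_deg: float = 2.0
    region: tuple[float, float, float, float] = AMERICAS_BBOX
    cellsize_deg: float = 0.5
    # injected dirty records (totals across the table), to exercise cleaning
    n_duplicates: int = 3
    n_out_of_region: int = 2
    n_missing: int = 1
    # climate gradient: bio5 = t_base − t_slope·|lat| + noise (°C)
    t_base: float = 38.0
    t_slope: float = 0.3
    t_noise: float = 1.0
    t_offset_min: float = 8.0  # bio5 − bio6 lower bound, °C
    t_offset_max: float = 25.0
    # precipitation: bio16 = p_base − p_slope·|lat| + noise (mm), floored at p_floor
    p_base: float = 1200.0
    p_slope: float = 12.0
    p_noise: float = 100.0
    p_floor: float = 30.0
    species: list[str] = field(default_factory=list)

    def species_names(self) -> list[str]:
        if self.species:
            return list(self.species)
        return [f"sp{i:03d}" for i in range(1, self.n_species + 1)]


# ---------------------------------------------------------------------------
# trees and traits

def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, labels: list[str] | None = None
) -> RootedTree:
    """Ultrametric pure-birth tree.

    Starting from the crown (2 lineages), the waiting time to the next
    split at k lineages is Exp(k·birth_rate); after the n-th lineage
    appears one further Exp(n·birth_rate) stretch runs to the present,
    so terminal branches are positive and the expected root height is
    Σ_{k=2..n} 1/(k·birth_rate).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    if labels is None:
        labels = [f"sp{i:03d}" for i in range(1, n_tips + 1)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    rng = _rng(seed, "yule")
    t = 0.0

    class _Node:
        __slots__ = ("birth", "children")

        def __init__(self, birth: float):
            self.birth = birth
            self.children: list["_Node"] = []

    root = _Node(0.0)
    a, b = _Node(0.0), _Node(0.0)
    root.children = [a, b]
    active = [a, b]
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(len(active)))
        parent = active[i]
        c1, c2 = _Node(t), _Node(t)
        parent.children = [c1, c2]
        active[i] = c1
        active.append(c2)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    label_iter = iter(rng.permutation(labels))

    def newick(node: _Node) -> str:
        # a node's edge runs from its birth to its end (split time or present)
        if not node.children:
            return f"{next(label_iter)}:{t - node.birth:.12f}"
        split = node.children[0].birth
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{split - node.birth:.12f}"

    inner = ",".join(newick(c) for c in root.children)
    return parse_newick(f"({inner});")


def simulate_topology_set(
    n_topologies: int, n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> TopologySet:
    """Independent Yule trees over one shared tip-label set."""
    labels = [f"sp{i:03d}" for i in range(1, n_tips + 1)]
    sub = np.random.SeedSequence([int(seed), _STREAMS["topologies"]]).generate_state(
        n_topologies
    )
    return TopologySet(
        [
            simulate_yule_tree(n_tips, birth_rate, seed=int(s), labels=labels)
            for s in sub
        ]
    )


def simulate_bm_traits(
    tree: RootedTree,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    mu: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Trait draw from MVN(μ1, σ²·C(λ)) via Cholesky of the λ-rescaled C."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C = lambda_transform(brownian_covariance(tree), lambda_true)
    rng = _rng(seed, "bm")
    n = len(C.tip_order)
    L = np.linalg.cholesky(sigma2 * C.matrix + 1e-12 * np.eye(n)) if sigma2 > 0 else None
    z = rng.standard_normal(n)
    vals = mu + (L @ z if L is not None else np.zeros(n))
    return pd.Series(vals, index=list(C.tip_order), name="trait")


# ---------------------------------------------------------------------------
# regression datasets

#: Habitat-combination probabilities (dom, peri, syl patterns), echoing the
#: observed composition of the real assemblage.
HABITAT_COMPOSITION = {
    (True, True, True): 0.60,
    (True, True, False): 0.16,
    (False, False, True): 0.12,
    (True, False, False): 0.04,
    (False, True, False): 0.04,
    (True, False, True): 0.02,
    (False, True, True): 0.02,
}


def simulate_regression_dataset(
    tree: RootedTree,
    betas: tuple[float, float, float, float] = (1.0, 0.0, 0.5, 0.3),
    lambda_resid: float = 0.0,
    sigma2_resid: float = 1.0,
    seed: int = 0,
    dbr_mean: float = 6.0,
    tnb_log_mu: float = 3.2,
    tnb_log_sd: float = 0.35,
    pnb_log_mu: float = 7.0,
    pnb_log_sd: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Species trait table generated by inverting the regression model.

    ln(area) = β₀ + β₁·ln(DBR) + β₂·√TNB + β₃·√PNB + ε with
    ε ~ MVN(0, σ²·C(λ_resid)). DBR at species rank is 1 + Poisson;
    coarser ranks shrink deterministically toward 1. TNB/PNB are
    log-normal on scales echoing the real system (tens of °C, hundreds
    to thousands of mm). Habitat flags follow the overlapping
    composition of the real assemblage. Returns (table, ground truth).
    """
    if len(betas) != 4:
        raise ValueError("betas must have length 4 (intercept + 3 slopes)")
    rng = _rng(seed, "regression")
    C = brownian_covariance(tree)
    species = list(C.tip_order)
    n = len(species)

    dbr_sp = 1 + rng.poisson(max(dbr_mean - 1, 0.0), size=n)
    tnb = np.exp(rng.normal(tnb_log_mu, tnb_log_sd, size=n))
    pnb = np.exp(rng.normal(pnb_log_mu, pnb_log_sd, size=n))

    Xcols = np.column_stack([np.ones(n), np.log(dbr_sp), np.sqrt(tnb), np.sqrt(pnb)])
    mean = Xcols @ np.asarray(betas, dtype=float)
    if sigma2_resid > 0:
        V = lambda_transform(C, lambda_resid).matrix * sigma2_resid
        eps = np.linalg.cholesky(V + 1e-12 * np.eye(n)) @ rng.standard_normal(n)
    else:
        eps = np.zeros(n)
    ln_area = mean + eps

    # coarser ranks: deterministic shrinkage toward 1, preserving monotonicity
    shrink = {"species": 1.0, "genus": 0.8, "family": 0.6, "order": 0.35, "class": 0.15}
    table = pd.DataFrame({"species": species, "area_km2": np.exp(ln_area),
                          "tnb": tnb, "pnb": pnb})
    for rank in RANKS:
        table[f"dbr_{rank}"] = np.maximum(
            1, np.round(dbr_sp * shrink[rank]).astype(int)
        )

    hab_rng = _rng(seed, "habitat")
    patterns = list(HABITAT_COMPOSITION)
    probs = np.array(list(HABITAT_COMPOSITION.values()))
    picks = hab_rng.choice(len(patterns), size=n, p=probs / probs.sum())
    for j, col in enumerate(HABITAT_COLUMNS):
        table[col] = [patterns[k][j] for k in picks]

    truth = {
        "betas": tuple(float(b) for b in betas),
        "lambda_resid": float(lambda_resid),
        "sigma2_resid": float(sigma2_resid),
        "residuals": eps,
    }
    return table, truth


# ---------------------------------------------------------------------------
# occurrence landscape

def _make_rasters(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, RasterGrid]:
    lo, hi, s, n = cfg.region
    ncols = int(np.ceil((hi - lo) / cfg.cellsize_deg))
    nrows = int(np.ceil((n - s) / cfg.cellsize_deg))
    lat_centers = s + (np.arange(nrows) + 0.5) * cfg.cellsize_deg
    lat_grid = np.tile(lat_centers[::-1][:, None], (1, ncols))  # row 0 = north

    bio5 = cfg.t_base - cfg.t_slope * np.abs(lat_grid) + rng.normal(
        0, cfg.t_noise, size=lat_grid.shape
    )
    offset = rng.uniform(cfg.t_offset_min, cfg.t_offset_max, size=lat_grid.shape)
    bio6 = bio5 - offset
    bio16 = np.maximum(
        cfg.p_floor,
        cfg.p_base - cfg.p_slope * np.abs(lat_grid)
        + rng.normal(0, cfg.p_noise, size=lat_grid.shape),
    )
    bio17 = bio16 * rng.uniform(0.05, 0.6, size=lat_grid.shape)
    assert np.all(bio5 >= bio6) and np.all(bio16 >= bio17)
    make = lambda v: RasterGrid(xll=lo, yll=s, cellsize=cfg.cellsize_deg, values=v)
    return {"bio5": make(bio5), "bio6": make(bio6), "bio16": make(bio16),
            "bio17": make(bio17)}


def simulate_occurrence_landscape(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, RasterGrid], dict]:
    """Clustered occurrence clouds over gradient rasters, plus dirty records.

    Each species gets Gaussian clusters of points inside the region;
    configurable numbers of duplicate, out-of-region, and
    missing-coordinate records are appended (round-robin over species)
    so the cleaning stage has something to do. Returns
    (occurrence table, rasters, bookkeeping truth).
    """
    rng = _rng(cfg.seed, "landscape")
    rasters = _make_rasters(cfg, rng)
    lo, hi, s, n = cfg.region
    pad = 3 * cfg.cluster_sd_deg + cfg.cellsize_deg
    rows = []
    for sp in cfg.species_names():
        centers = np.column_stack(
            [
                rng.uniform(lo + pad, hi - pad, size=cfg.n_clusters),
                rng.uniform(s + pad, n - pad, size=cfg.n_clusters),
            ]
        )
        assign = rng.integers(cfg.n_clusters, size=cfg.points_per_species)
        pts = centers[assign] + rng.normal(
            0, cfg.cluster_sd_deg, size=(cfg.points_per_species, 2)
        )
        pts[:, 0] = np.clip(pts[:, 0], lo, hi)
        pts[:, 1] = np.clip(pts[:, 1], s, n)
        for lon, lat in pts:
            rows.append({"species": sp, "lon": lon, "lat": lat})
    clean = pd.DataFrame(rows)

    dirty = []
    names = cfg.species_names()
    for i in range(cfg.n_duplicates):
        src = clean[clean["species"] == names[i % len(names)]].iloc[0]
        dirty.append(dict(src))
    for i in range(cfg.n_out_of_region):
        dirty.append(
            {"species": names[i % len(names)], "lon": 120.0 + i, "lat": 10.0}
        )
    for i in range(cfg.n_missing):
        dirty.append({"species": names[i % len(names)], "lon": np.nan, "lat": np.nan})
    raw = pd.concat([clean, pd.DataFrame(dirty)], ignore_index=True)
    truth = {
        "n_clean": len(clean),
        "n_duplicates": cfg.n_duplicates,
        "n_out_of_region": cfg.n_out_of_region,
        "n_missing": cfg.n_missing,
    }
    return raw, rasters, truth


# ---------------------------------------------------------------------------
# blood meals

_DEFAULT_HOSTS = [
    # host, class, order, family, genus, species
    ("Homo sapiens", "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens"),
    ("Canis familiaris", "Mammalia", "Carnivora", "Canidae", "Canis", "Canis familiaris"),
    ("Felis catus", "Mammalia", "Carnivora", "Felidae", "Felis", "Felis catus"),
    ("Gallus gallus", "Aves", "Galliformes", "Phasianidae", "Gallus", "Gallus gallus"),
    ("Columba livia", "Aves", "Columbiformes", "Columbidae", "Columba", "Columba livia"),
    ("Rattus rattus", "Mammalia", "Rodentia", "Muridae", "Rattus", "Rattus rattus"),
    ("Mus musculus", "Mammalia", "Rodentia", "Muridae", "Mus", "Mus musculus"),
    ("Didelphis marsupialis", "Mammalia", "Didelphimorphia", "Didelphidae",
     "Didelphis", "Didelphis marsupialis"),
    ("Bos taurus", "Mammalia", "Artiodactyla", "Bovidae", "Bos", "Bos taurus"),
    ("Capra hircus", "Mammalia", "Artiodactyla", "Bovidae", "Capra", "Capra hircus"),
    ("Dasypus novemcinctus", "Mammalia", "Cingulata", "Dasypodidae", "Dasypus",
     "Dasypus novemcinctus"),
    # a host resolved only to family, to exercise the unresolved-rank rule
    ("Cricetidae sp.", "Mammalia", "Rodentia", "Cricetidae", None, None),
]


def default_host_taxonomy() -> HostTaxonomy:
    """A small nested host taxonomy of typical triatomine blood sources."""
    df = pd.DataFrame(
        _DEFAULT_HOSTS, columns=["host", "class", "order", "family", "genus", "species"]
    )
    return HostTaxonomy(df)


def simulate_bloodmeals(
    n_individuals: int,
    tax: HostTaxonomy | None = None,
    mixing_prob: float = 0.2,
    seed: int = 0,
    species: str = "sp001",
    n_hosts_available: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Blood-meal records for one triatomine species plus ground-truth DBR.

    Each individual feeds on one host with probability 1 − mixing_prob,
    otherwise on two distinct hosts. ``n_hosts_available`` restricts the
    pool (a random subset) to give species distinct diet breadths.
    Ground truth counts distinct resolved taxa at each rank among the
    hosts actually drawn.
    """
    if not (0 <= mixing_prob <= 1):
        raise ValueError("mixing_prob must be in [0, 1]")
    if tax is None:
        tax = default_host_taxonomy()
    pool = tax.hosts()
    rng = _rng(seed, "bloodmeals")
    if n_hosts_available is not None:
        k = max(1, min(n_hosts_available, len(pool)))
        pool = list(rng.choice(pool, size=k, replace=False))
    records: dict[tuple[str, ...], int] = {}
    drawn: set[str] = set()
    for _ in range(n_individuals):
        if len(pool) >= 2 and rng.random() < mixing_prob:
            hosts = tuple(sorted(rng.choice(pool, size=2, replace=False)))
        else:
            hosts = (str(rng.choice(pool)),)
        drawn.update(hosts)
        records[hosts] = records.get(hosts, 0) + 1
    table = pd.DataFrame(
        [
            {"species": species, "hosts": ";".join(h), "count": c}
            for h, c in sorted(records.items())
        ]
    )
    truth = {
        rank: len({tax.rank_of(h, rank) for h in drawn if tax.rank_of(h, rank)})
        for rank in RANKS
    }
    return table, truth


def simulate_bloodmeal_dataset(
    species: list[str],
    n_individuals: int = 30,
    mixing_prob: float = 0.2,
    seed: int = 0,
    tax: HostTaxonomy | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blood-meal tables for many species (varying host-pool sizes)."""
    if tax is None:
        tax = default_host_taxonomy()
    tables, truths = [], []
    for i, sp in enumerate(species):
        pool_size = 2 + (i % (len(tax.hosts()) - 1))
        tbl, truth = simulate_bloodmeals(
            n_individuals,
            tax=tax,
            mixing_prob=mixing_prob,
            seed=int(np.random.SeedSequence([seed, _STREAMS["bloodmeals"], i]).generate_state(1)[0]),
            species=sp,
            n_hosts_available=pool_size,
        )
        tables.append(tbl)
        truths.append({"species": sp, **{f"dbr_{r}": truth[r] for r in RANKS}})
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truths)
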
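"""Synthetic data with the exact generative structure of both models.

``simulate_region`` draws pooled allele counts for M sites whose log-balances
drift from a regional ancestral balance with tree-structured covariance and
binomial sampling on top — the hierarchical dispersal model's own process.
``simulate_admixture`` draws population balance matrices from an admixture
graph by sampling each independent variance component (branch and own-
variance) as a Gaussian increment, so the sample covariance converges to the
graph's V.

Default sizes and rates are chosen as realistic desk-scale study conditions:
50 pooled calls per site per SNP, ancestral frequencies Beta(2, 2) (away from
fixation), and a per-SNP drift scale with mean 0.05 — comparable to a
within-region F_ST of ~5%, typical for crop landraces sampled within one
geographic region.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_covariance import DispersalCovariance, DistanceSpec, heuristic_covariance, linear_distances
from .io_geno import (
    SiteSet,
    SnpMeta,
    VariantCounts,
    write_counts,
    write_frequencies,
    write_sites,
)
from .migadmi_model import AdmixtureGraph, BalanceMatrix
from .popdisp_model import balance, inverse_balance

__all__ = [
    "RegionConfig",
    "SimulatedRegion",
    "simulate_region",
    "random_dispersal_tree",
    "simulate_admixture",
    "make_fixture",
]


@dataclass
class RegionConfig:
    """Study conditions for one simulated region."""

    seed: int = 0
    n_sites: int = 8
    n_snps: int = 100
    n_calls: int = 50  # pooled allele calls per site per SNP
    scenario: str = "routes"  # "routes" (random path tree) | "linear" (geodesic)
    s_mean: float = 0.05  # mean per-SNP drift scale (~ within-region F_ST)
    beta: tuple[float, float] = (2.0, 2.0)  # ancestral frequency prior
    variance_mode: str = "delta"
    bbox: tuple[float, float, float, float] = (40.0, 35.0, 55.0, 45.0)  # lon0, lat0, lon1, lat1


@dataclass
class SimulatedRegion:
    """Simulated counts plus every latent needed for recovery checks."""

    counts: VariantCounts
    sites: SiteSet
    center: tuple[float, float]
    dist: DistanceSpec
    V: DispersalCovariance
    truth: dict


def random_dispersal_tree(
    m: int, rng: np.random.Generator, branch_mean: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random rooted additive binary tree over ``m`` leaves.

    Leaves are joined in random order with exponential branch lengths.
    Returns ``(d_center, d_pair, shared)``: root-to-leaf path lengths,
    additive leaf-to-leaf path distances, and the exact shared root-to-fork
    path matrix (diagonal = d_center).
    """
    return _random_tree_distances(m, rng, branch_mean)


def _random_tree_distances(m: int, rng: np.random.Generator, branch_mean: float = 0.5):
    # Build an explicit node tree by random joins, then measure paths.
    nodes = [{"leaves": [j], "children": []} for j in range(m)]
    active = list(range(m))
    edges_len: dict[int, float] = {}
    parent: dict[int, int] = {}
    next_id = m
    while len(active) > 1:
        pick = rng.choice(len(active), size=2, replace=False)
        i, j = int(pick[0]), int(pick[1])
        a, b = active[i], active[j]
        nodes.append({"leaves": nodes[a]["leaves"] + nodes[b]["leaves"], "children": [a, b]})
        parent[a] = next_id
        parent[b] = next_id
        edges_len[a] = float(rng.exponential(branch_mean))
        edges_len[b] = float(rng.exponential(branch_mean))
        active = [v for idx, v in enumerate(active) if idx not in (i, j)] + [next_id]
        next_id += 1
    root = active[0]

    def root_path(node: int) -> list[int]:
        path = []
        while node != root:
            path.append(node)
            node = parent[node]
        return path

    leaf_paths = {}
    for node, info in enumerate(nodes):
        if not info["children"]:
            leaf_paths[info["leaves"][0]] = root_path(node)
    d_center = np.array([sum(edges_len[e] for e in leaf_paths[j]) for j in range(m)])
    shared = np.zeros((m, m))
    for j in range(m):
        pj = set(leaf_paths[j])
        for k in range(m):
            common = pj.intersection(leaf_paths[k])
            shared[j, k] = sum(edges_len[e] for e in common)
    d_pair = d_center[:, None] + d_center[None, :] - 2 * shared
    np.fill_diagonal(d_pair, 0.0)
    return d_center, d_pair, shared


def simulate_region(config: RegionConfig | None = None, **kwargs) -> SimulatedRegion:
    """Draw a region dataset under the hierarchical dispersal model.

    Ancestral frequency ``fA_i ~ Beta(a, b)``; site balances
    ``x_i ~ MvN(xA_i 1, s_i V g(fA_i))`` with ``s_i`` exponential; observed
    counts ``y_ji ~ Binomial(n_calls, f_ji)``. Per-SNP draws come from
    sub-streams spawned off the master seed, so results are reproducible and
    independent of SNP evaluation order.
    """
    if config is None:
        config = RegionConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    master = np.random.SeedSequence(config.seed)
    layout_seed, snp_root = master.spawn(2)
    rng = np.random.default_rng(layout_seed)

    m = config.n_sites
    lon0, lat0, lon1, lat1 = config.bbox
    sites = SiteSet(
        [f"site{j:02d}" for j in range(m)],
        rng.uniform(lon0, lon1, size=m),
        rng.uniform(lat0, lat1, size=m),
    )
    center = (float(rng.uniform(lon0, lon1)), float(rng.uniform(lat0, lat1)))
    if config.scenario == "routes":
        d_center, d_pair, _ = _random_tree_distances(m, rng)
        dist = DistanceSpec(d_center, d_pair, "routes")
    elif config.scenario == "linear":
        dist = linear_distances(sites, center)
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    V = heuristic_covariance(dist)
    chol = np.linalg.cholesky(V.V + 1e-10 * np.eye(m))

    n_snps = config.n_snps
    a, b = config.beta
    fA = rng.beta(a, b, size=n_snps)
    fA = np.clip(fA, 1e-4, 1 - 1e-4)
    xA = balance(fA)
    s = rng.exponential(config.s_mean, size=n_snps)
    if config.variance_mode == "literal":
        g = fA * (1 - fA)
    else:
        g = 1.0 / (fA * (1 - fA))

    x = np.empty((m, n_snps))
    y = np.empty((m, n_snps), dtype=np.int64)
    n = np.full((m, n_snps), config.n_calls, dtype=np.int64)
    for i, child in enumerate(snp_root.spawn(n_snps)):
        ri = np.random.default_rng(child)
        x[:, i] = xA[i] + np.sqrt(s[i] * g[i]) * (chol @ ri.standard_normal(m))
        y[:, i] = ri.binomial(n[:, i], inverse_balance(x[:, i]))
    f = inverse_balance(x)
    counts = VariantCounts(
        sites.site_ids, [f"snp{i:04d}" for i in range(n_snps)], y, n
    )
    truth = {"fA": fA, "xA": xA, "s": s, "x": x, "f": f}
    return SimulatedRegion(counts, sites, center, dist, V, truth)


def simulate_admixture(
    graph: AdmixtureGraph,
    params: np.ndarray,
    n_snps: int = 500,
    seed: int = 0,
    chrom: str = "1",
    chrom_len: int = 12_000_000,
) -> tuple[BalanceMatrix, SnpMeta, dict]:
    """Draw a balance matrix from an admixture graph.

    Each independent variance component of the graph (tree branches, shared/
    private own-variance parts, target own variances) receives a Gaussian
    increment per SNP; population balances are the graph's linear mixture of
    those increments plus a Beta(2, 2) ancestral balance. SNP positions are
    laid uniformly (without replacement) on one chromosome.
    """
    master = np.random.SeedSequence(seed)
    layout_seed, snp_root = master.spawn(2)
    rng = np.random.default_rng(layout_seed)
    load, comp_var, _, _ = graph._components(np.asarray(params, dtype=float))
    pops = graph.pop_ids
    ncomp = len(comp_var)
    L = np.zeros((len(pops), ncomp))
    for pi, pop in enumerate(pops):
        for c, coef in load[pop].items():
            L[pi, c] = coef
    sd = np.sqrt(comp_var)

    x0 = balance(np.clip(rng.beta(2, 2, size=n_snps), 1e-4, 1 - 1e-4))
    X = np.empty((len(pops), n_snps))
    for i, child in enumerate(snp_root.spawn(n_snps)):
        ri = np.random.default_rng(child)
        X[:, i] = x0[i] + L @ (sd * ri.standard_normal(ncomp))

    # anchor the last SNP at chrom_len so the chromosome span (hence the
    # number of candidate windows) is set by chrom_len, not by sampling
    pos = np.sort(
        np.concatenate(
            [rng.choice(np.arange(1, chrom_len), size=n_snps - 1, replace=False), [chrom_len]]
        )
    )
    snp_ids = [f"snp{i:04d}" for i in range(n_snps)]
    meta = SnpMeta(snp_ids, np.array([chrom] * n_snps, dtype=object), pos)
    V, D = graph.covariance(np.asarray(params, dtype=float))
    truth = {"params": np.asarray(params, dtype=float), "V": V, "D": D, "x0": x0}
    return BalanceMatrix(list(pops), snp_ids, X, meta), meta, truth


def two_source_admixture_design() -> tuple[AdmixtureGraph, np.ndarray]:
    """Canonical two-source admixture study design.

    Three diverged population pairs (cherry stems 1.5, terminal branches 0.3
    in balance-variance units — strongly diverged regions with modest local
    drift); the target mixes one member of two pairs with weights (0.7, 0.3),
    fully shared precursor variance (alpha = 1) and own variance 0.1. Mixture
    weights are only identifiable through cross-covariances between the
    target and the sources' relatives, which is why every source keeps an
    unadmixed sister population in the design.
    """
    from .migadmi_model import AdmixtureEvent

    newick = "((s1:0.3,r1:0.3):1.5,(s2:0.3,r2:0.3):1.5,(o1:0.3,o2:0.3):1.5);"
    graph = AdmixtureGraph(newick, [AdmixtureEvent("y", ["s1", "s2"])])
    names = graph.param_names()
    truth = graph.default_params().copy()
    truth[names.index("y.w[s1]")] = 0.7
    truth[names.index("y.w[s2]")] = 0.3
    truth[names.index("y.t_own")] = 0.1
    truth[names.index("y.alpha[s1]")] = 1.0
    truth[names.index("y.alpha[s2]")] = 1.0
    return graph, truth


def make_fixture(name: str, outdir: str, seed: int | None = None) -> dict[str, str]:
    """Write a named TSV fixture set; returns the mapping of file roles to
    paths. Regeneration from the same seed is byte-identical.

    Known names: "small" (5 sites x 50 SNPs region), "recovery"
    (10 sites x 200 SNPs region with the true ancestral frequencies), and
    "maf" (20 SNPs with pooled minor-allele frequencies 0.00..0.19).
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(fname: str) -> str:
        path = os.path.join(outdir, fname)
        return path

    if name == "small":
        sim = simulate_region(RegionConfig(seed=7 if seed is None else seed, n_sites=5, n_snps=50))
        write_counts(sim.counts, p("counts.tsv"))
        write_sites(sim.sites, p("sites.tsv"))
        paths = {"counts": p("counts.tsv"), "sites": p("sites.tsv")}
    elif name == "recovery":
        sim = simulate_region(
            RegionConfig(seed=11 if seed is None else seed, n_sites=10, n_snps=200, n_calls=50)
        )
        write_counts(sim.counts, p("counts.tsv"))
        write_sites(sim.sites, p("sites.tsv"))
        truth = pd.DataFrame(
            [sim.truth["fA"]], index=pd.Index(["truth"], name="pop"), columns=sim.counts.snp_ids
        )
        write_frequencies(truth, p("truth_fA.tsv"))
        paths = {
            "counts": p("counts.tsv"),
            "sites": p("sites.tsv"),
            "truth": p("truth_fA.tsv"),
        }
    elif name == "maf":
        n_snps = 20
        snp_ids = [f"snp{i:02d}" for i in range(n_snps)]
        y = np.zeros((2, n_snps), dtype=np.int64)
        n = np.full((2, n_snps), 50, dtype=np.int64)
        for i in range(n_snps):
            y[0, i] = i  # pooled alt frequency i / 100 => MAF 0.00 .. 0.19
        counts = VariantCounts(["siteA", "siteB"], snp_ids, y, n)
        write_counts(counts, p("counts.tsv"))
        paths = {"counts": p("counts.tsv")}
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return paths
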
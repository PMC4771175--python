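"""Synthetic RPPA-style studies with known ground-truth networks.

Real tumor cohorts come with no known truth, so benchmarking the inference
stack end to end requires data generated from a stated model.  We use a
Gaussian graphical model: a sparse symmetric positive-definite precision
matrix whose off-diagonal support *is* the true edge set.  Cohorts are drawn
i.i.d. from the corresponding multivariate normal (plus independent
measurement noise), which automatically produces the transitive
fan-in/fan-out/cascade correlations that network inference must prune:
marginal correlation propagates along paths while the partial correlation of
non-adjacent pairs is exactly zero.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset, GoldStandardNetwork, make_annotation
from .genelists import GeneListCollection, HierarchyIndex

__all__ = [
    "GroundTruth",
    "SyntheticStudy",
    "generate_ground_truth",
    "sample_cohorts",
    "generate_genelist_hierarchy",
]

# ~30% of true couplings are negative so that downstream sign-based edge
# grouping (negative-dominant vs positive-dominant) is exercised.
NEGATIVE_EDGE_FRACTION = 0.3
# Coupling magnitudes: strong enough that partial correlations clear
# estimation noise at the sample sizes used in tests.
COUPLING_RANGE = (0.4, 0.9)


@dataclass
class GroundTruth:
    """A known network: antibodies, true edges, and the GGM precision matrix."""

    antibodies: list[str]
    edges: frozenset[tuple[str, str]]
    precision: np.ndarray
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        p = len(self.antibodies)
        if self.precision.shape != (p, p):
            raise ValueError("precision matrix shape mismatch")
        if not np.allclose(self.precision, self.precision.T):
            raise ValueError("precision matrix must be symmetric")
        np.linalg.cholesky(self.precision)  # raises if not positive definite
        idx = {a: i for i, a in enumerate(self.antibodies)}
        support = {
            (self.antibodies[i], self.antibodies[j])
            for i in range(p)
            for j in range(i + 1, p)
            if self.precision[i, j] != 0.0
        }
        canon = {tuple(sorted(e)) for e in self.edges}
        if {tuple(sorted(e)) for e in support} != canon:
            raise ValueError("off-diagonal support of precision must equal the edge set")
        if any(a == b for a, b in canon):
            raise ValueError("self edges are not allowed")
        self.edges = frozenset(canon)
        self._index = idx

    @property
    def n_antibodies(self) -> int:
        return len(self.antibodies)

    @property
    def density(self) -> float:
        p = self.n_antibodies
        return len(self.edges) / (p * (p - 1) / 2)

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def to_gold_standard(self) -> GoldStandardNetwork:
        """True edges as a benchmark set; universe = all antibodies."""
        return GoldStandardNetwork.from_edges(self.edges, universe=self.antibodies)


@dataclass
class SyntheticStudy:
    """Ground truth plus sampled expression cohorts."""

    ground_truth: GroundTruth
    cohorts: dict[str, pd.DataFrame]
    seed: int
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        abs_order = self.ground_truth.antibodies
        for name, mat in self.cohorts.items():
            if list(mat.columns) != abs_order:
                raise ValueError(f"cohort {name!r} does not share the antibody order")
            if not np.isfinite(mat.to_numpy()).all():
                raise ValueError(f"cohort {name!r} contains non-finite entries")

    def to_expression_dataset(self) -> ExpressionDataset:
        matrix = pd.concat(self.cohorts.values(), axis=0)
        labels = pd.Series(
            np.repeat(list(self.cohorts), [len(m) for m in self.cohorts.values()]),
            index=matrix.index,
            name="cohort",
        )
        return ExpressionDataset(matrix=matrix, cohorts=labels, annotation=self.ground_truth.annotation)


def _build_precision(p: int, edge_idx: list[tuple[int, int]], rng: np.random.Generator) -> np.ndarray:
    """Sparse precision with the given support, PD by diagonal dominance."""
    P = np.zeros((p, p))
    lo, hi = COUPLING_RANGE
    for i, j in edge_idx:
        c = rng.uniform(lo, hi)
        if rng.uniform() < NEGATIVE_EDGE_FRACTION:
            c = -c
        # negative precision entry <-> positive partial correlation
        P[i, j] = P[j, i] = -c
    row_abs = np.abs(P).sum(axis=1)
    np.fill_diagonal(P, 1.0 + row_abs)
    return P


def generate_ground_truth(
    n_antibodies: int,
    density: float = 0.0929,
    phospho_fraction: float = 51 / 187,
    multi_gene_fraction: float = 0.15,
    seed: int = 0,
) -> GroundTruth:
    """Generate a sparse ground-truth network with a GGM parameterization.

    The edge set is Erdos-Renyi-style: ``round(density * C(n, 2))`` distinct
    pairs drawn uniformly.  Edge couplings get random magnitudes (~30%
    negative) and the diagonal is dominated to guarantee positive
    definiteness.  A ``multi_gene_fraction`` of antibodies map to two gene
    symbols (paralogs); antibody 2 shares the gene of antibody 1 (as a
    phospho/total antibody pair against the same protein would), so that
    gene-level self-interaction skipping is exercised downstream.
    """
    if n_antibodies < 4:
        raise ValueError("need at least 4 antibodies")
    if not 0.0 < density < 0.5:
        raise ValueError("density must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    p = n_antibodies
    n_pairs = p * (p - 1) // 2
    m = round(density * n_pairs)

    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = rng.choice(n_pairs, size=m, replace=False) if m else np.empty(0, dtype=int)
    edge_idx = [all_pairs[k] for k in sorted(chosen)]

    last_err: Exception | None = None
    for _ in range(5):
        P = _build_precision(p, edge_idx, rng)
        try:
            np.linalg.cholesky(P)
            break
        except np.linalg.LinAlgError as err:  # pragma: no cover - dominance guarantees PD
            last_err = err
    else:  # pragma: no cover
        raise ValueError(f"could not construct a positive-definite precision: {last_err}")

    antibodies = [f"AB{k + 1:03d}" for k in range(p)]
    n_multi = round(multi_gene_fraction * p)
    multi = set(rng.choice(p, size=n_multi, replace=False)) if n_multi else set()
    genes: dict[str, list[str]] = {}
    for k, ab in enumerate(antibodies):
        gs = [f"GENE{k + 1:03d}"]
        if k in multi:
            gs.append(f"GENE{k + 1:03d}B")
        genes[ab] = gs
    # antibodies 1 and 2 target the same protein -> shared gene symbol
    genes[antibodies[1]] = [genes[antibodies[0]][0]]

    n_phospho = round(phospho_fraction * p)
    phospho_idx = set(rng.choice(p, size=n_phospho, replace=False)) if n_phospho else set()
    phospho = {ab: (k in phospho_idx) for k, ab in enumerate(antibodies)}
    sites = {ab: (f"pS{100 + k}" if k in phospho_idx else "") for k, ab in enumerate(antibodies)}
    annotation = make_annotation(antibodies, genes, phospho, sites)

    edges = frozenset((antibodies[i], antibodies[j]) for i, j in edge_idx)
    return GroundTruth(antibodies=antibodies, edges=edges, precision=P, annotation=annotation)


def sample_cohorts(
    gt: GroundTruth,
    cohort_sizes: dict[str, int],
    noise_sd: float = 0.1,
    seed: int = 0,
    edge_rescale_fraction: float = 0.0,
    edge_rescale_range: tuple[float, float] = (0.25, 1.75),
) -> SyntheticStudy:
    """Draw expression cohorts from the ground-truth GGM.

    Each cohort is i.i.d. zero-mean multivariate normal with covariance
    ``inv(precision)`` plus independent N(0, noise_sd^2) measurement noise.
    With ``edge_rescale_fraction > 0`` a per-cohort random subset of edge
    couplings is rescaled (support unchanged), emulating tumor-type
    heterogeneity in interaction strength.
    """
    if not cohort_sizes:
        raise ValueError("cohort_sizes must be nonempty")
    if any(n < 3 for n in cohort_sizes.values()):
        raise ValueError("every cohort needs at least 3 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    p = gt.n_antibodies
    idx = gt._index
    edge_list = sorted(gt.edges)
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = ss.spawn(len(cohort_sizes))

    cohorts: dict[str, pd.DataFrame] = {}
    for (name, n), child in zip(cohort_sizes.items(), child_seeds):
        rng = np.random.default_rng(child)
        P = gt.precision.copy()
        if edge_rescale_fraction > 0 and edge_list:
            k = max(1, round(edge_rescale_fraction * len(edge_list)))
            sel = rng.choice(len(edge_list), size=k, replace=False)
            for e in sel:
                a, b = edge_list[e]
                i, j = idx[a], idx[b]
                P[i, j] = P[j, i] = P[i, j] * rng.uniform(*edge_rescale_range)
            off = P.copy()
            np.fill_diagonal(off, 0.0)
            np.fill_diagonal(P, 1.0 + np.abs(off).sum(axis=1))
        cov = np.linalg.inv(P)
        if not np.isfinite(cov).all():
            raise ValueError("singular precision matrix")
        L = np.linalg.cholesky(cov)
        X = rng.standard_normal((n, p)) @ L.T
        if noise_sd > 0:
            X = X + noise_sd * rng.standard_normal((n, p))
        index = pd.Index([f"{name}_S{i + 1:04d}" for i in range(n)], name="sample")
        cohorts[name] = pd.DataFrame(X, index=index, columns=gt.antibodies)

    return SyntheticStudy(ground_truth=gt, cohorts=cohorts, seed=seed, noise_sd=noise_sd)


def generate_genelist_hierarchy(
    genes: list[str],
    n_lists: int = 40,
    n_top_level: int = 6,
    seed: int = 0,
) -> tuple[GeneListCollection, HierarchyIndex]:
    """Generate a forest of gene lists where each child is a subset of its parent.

    ``n_top_level`` roots get large random gene subsets; every further list
    attaches under a uniformly chosen existing list and takes a random
    nonempty subset of its parent's genes.  Defaults are desk scale; the real
    collection this emulates has ~1669 human lists under 24 top-level
    processes.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    if n_top_level > n_lists:
        raise ValueError("n_top_level cannot exceed n_lists")
    if n_top_level < 1:
        raise ValueError("need at least one top-level list")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_genes = len(genes)

    lists: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    relations: list[tuple[str, str]] = []
    ids: list[str] = []
    for k in range(n_lists):
        lid = f"GL-HSA-{k + 1:04d}"
        if k < n_top_level:
            size = max(2, math.ceil(rng.uniform(0.4, 0.8) * n_genes))
            members = rng.choice(n_genes, size=min(size, n_genes), replace=False)
            lists[lid] = frozenset(genes[i] for i in members)
            names[lid] = f"Top-level process {k + 1}"
        else:
            parent = ids[rng.integers(len(ids))]
            pool = sorted(lists[parent])
            size = max(1, math.ceil(rng.uniform(0.3, 0.9) * len(pool)))
            members = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
            lists[lid] = frozenset(pool[i] for i in members)
            names[lid] = f"Process {k + 1} (child of {parent})"
            relations.append((parent, lid))
        ids.append(lid)

    collection = GeneListCollection(lists=lists, names=names)
    hierarchy = HierarchyIndex(relations, all_ids=ids)
    return collection, hierarchy
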
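"""Gene-set extraction and enrichment testing with randomization calibration.

Each fitted hidden variable (column of Lambda) and each TF (column of W)
defines a gene set: the genes with exactly nonzero weight. Every gene set is
scored against a category collection by the minimum one-sided Fisher exact
p-value over categories; that minimum is then calibrated by re-running the
same scan on size-matched uniformly random gene sets, and calibrated
p-values are converted to FDR q-values by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .model_core import ModelParameters

__all__ = [
    "GeneSet",
    "CategoryCollection",
    "EnrichmentResult",
    "extract_gene_sets",
    "fisher_enrichment",
    "min_category_p",
    "calibrate_p",
    "bh_fdr",
    "enrich_gene_sets",
    "write_enrichment_table",
]

# GSEA-conventional category size window applied within the universe.
MIN_CATEGORY_SIZE = 5
MAX_CATEGORY_SIZE = 5000


@dataclass
class GeneSet:
    """Genes attached to one upper-layer node (hidden factor or TF)."""

    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CategoryCollection:
    """Named categories over a gene universe (GMT-style collection)."""

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        for name, members in self.categories.items():
            if not members <= self.universe:
                raise ValueError(f"category {name!r} has members outside the universe")

    def restricted(self, universe) -> "CategoryCollection":
        """Intersect categories and universe with another gene universe."""
        uni = self.universe & frozenset(universe)
        cats = {k: v & uni for k, v in self.categories.items()}
        return CategoryCollection(categories=cats, universe=uni)

    def size_filtered(
        self, min_size: int = MIN_CATEGORY_SIZE, max_size: int = MAX_CATEGORY_SIZE
    ) -> "CategoryCollection":
        cats = {
            k: v
            for k, v in self.categories.items()
            if min_size <= len(v) <= max_size
        }
        return CategoryCollection(categories=cats, universe=self.universe)


@dataclass
class EnrichmentResult:
    gene_set: GeneSet
    set_size: int
    best_category: str
    raw_p: float
    calibrated_p: float
    fdr_q: float = float("nan")


def extract_gene_sets(
    model: ModelParameters, gene_ids: list[str] | None = None
) -> list[GeneSet]:
    """One gene set per hidden variable and one per TF.

    Membership is the exact-zero test on the corresponding column — OWL-QN
    produces literal zeros, so no threshold is involved. Empty sets are
    returned (callers typically skip them for testing).
    """
    ids = list(gene_ids) if gene_ids is not None else list(model.gene_ids or [])
    if len(ids) != model.p:
        raise ValueError("gene_ids length does not match model")
    ids_arr = np.asarray(ids, dtype=object)
    sets: list[GeneSet] = []
    for k in range(model.q):
        nz = model.Lambda[:, k] != 0
        sets.append(GeneSet(source=f"hidden_{k}", members=frozenset(ids_arr[nz])))
    tf_ids = model.tf_ids if model.tf_ids is not None else [
        f"tf_{j}" for j in range(model.d)
    ]
    for j in range(model.d):
        nz = model.W[:, j] != 0
        sets.append(GeneSet(source=str(tf_ids[j]), members=frozenset(ids_arr[nz])))
    return sets


def fisher_enrichment(gene_set, category, universe) -> float:
    """One-sided (over-representation) Fisher exact p-value.

    Equals the hypergeometric upper tail P(overlap >= observed) for drawing
    |gene_set| genes from the universe with |category| marked.
    """
    gene_set = set(gene_set)
    category = set(category)
    universe = set(universe)
    if not gene_set <= universe or not category <= universe:
        raise ValueError("gene set and category must be subsets of the universe")
    if len(universe) < 1:
        raise ValueError("universe must be nonempty")
    if not gene_set:
        return 1.0
    k = len(gene_set & category)
    return float(hypergeom.sf(k - 1, len(universe), len(category), len(gene_set)))


def min_category_p(
    gene_set: GeneSet, collection: CategoryCollection
) -> tuple[str, float]:
    """Best-matching category: the one minimizing the Fisher p-value, ties
    broken lexicographically by category name."""
    if not collection.categories:
        raise ValueError("empty category collection")
    best_name, best_p = None, np.inf
    for name in sorted(collection.categories):
        p = fisher_enrichment(
            gene_set.members & collection.universe,
            collection.categories[name],
            collection.universe,
        )
        if p < best_p:
            best_name, best_p = name, p
    return best_name, float(best_p)


def _null_min_pvalues(
    set_size: int, collection: CategoryCollection, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Min-over-categories Fisher p for B uniform random sets of set_size."""
    universe = sorted(collection.universe)
    n_univ = len(universe)
    index = {g: i for i, g in enumerate(universe)}
    # B random subsets drawn as the first set_size entries of random orders.
    picks = np.argsort(rng.random((B, n_univ)), axis=1)[:, :set_size]
    membership = np.zeros((B, n_univ), dtype=bool)
    np.put_along_axis(membership, picks, True, axis=1)
    null_min = np.full(B, np.inf)
    for name, members in collection.categories.items():
        ind = np.zeros(n_univ, dtype=np.int64)
        ind[[index[g] for g in members]] = 1
        overlaps = membership.astype(np.int64) @ ind
        pvals = hypergeom.sf(overlaps - 1, n_univ, int(ind.sum()), set_size)
        null_min = np.minimum(null_min, pvals)
    return null_min


def calibrate_p(
    set_size: int,
    observed_min_p: float,
    collection: CategoryCollection,
    B: int = 1000,
    seed=0,
    conservative: bool = False,
) -> float:
    """Randomization-calibrated p-value for a best-category enrichment.

    Draws B uniform gene sets of the same size from the universe, scans each
    against the collection, and returns the fraction whose minimum p-value is
    at least as extreme as the observed one. The plain r/B estimate can be
    exactly 0; ``conservative`` switches to (r+1)/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if set_size > len(collection.universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(seed)
    null_min = _null_min_pvalues(set_size, collection, B, rng)
    r = int(np.sum(null_min <= observed_min_p + 1e-12))
    if conservative:
        return (r + 1) / (B + 1)
    return r / B


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_gene_sets(
    gene_sets: list[GeneSet],
    collection: CategoryCollection,
    B: int = 1000,
    seed: int = 0,
    min_size: int = MIN_CATEGORY_SIZE,
    max_size: int = MAX_CATEGORY_SIZE,
    conservative: bool = False,
    gene_universe=None,
) -> list[EnrichmentResult]:
    """Full enrichment pass over a list of gene sets.

    When ``gene_universe`` (e.g. the model's gene_ids) is given, the working
    universe is its intersection with the collection's — genes present in
    both the expression data and the annotation. Categories outside the
    [min_size, max_size] window within that universe are skipped. Each gene
    set's randomization uses an independent substream derived from
    (seed, set index), so results do not depend on evaluation order. FDR
    q-values are computed across the calibrated p-values of the tested
    (nonempty) sets.
    """
    working = (
        collection.restricted(gene_universe) if gene_universe is not None
        else collection
    )
    working = working.size_filtered(min_size, max_size)
    if not working.categories:
        return []
    results: list[EnrichmentResult] = []
    for i, gs in enumerate(gene_sets):
        members = gs.members & working.universe
        if not members:
            continue
        trimmed = GeneSet(source=gs.source, members=members)
        best_name, raw_p = min_category_p(trimmed, working)
        cal_p = calibrate_p(
            len(members), raw_p, working, B=B, seed=[seed, i],
            conservative=conservative,
        )
        results.append(
            EnrichmentResult(
                gene_set=gs,
                set_size=len(members),
                best_category=best_name,
                raw_p=raw_p,
                calibrated_p=cal_p,
            )
        )
    qvals = bh_fdr([r.calibrated_p for r in results])
    for r, q in zip(results, qvals):
        r.fdr_q = float(q)
    return results


def write_enrichment_table(results: list[EnrichmentResult], path) -> None:
    """Tab-delimited report: set size, raw p, calibrated p, FDR q, category."""
    with open(path, "w") as fh:
        fh.write("source\tset_size\traw_p\tcalibrated_p\tfdr_q\tbest_category\n")
        for r in results:
            fh.write(
                f"{r.gene_set.source}\t{r.set_size}\t{r.raw_p:.6g}\t"
                f"{r.calibrated_p:.6g}\t{r.fdr_q:.6g}\t{r.best_category}\n"
            )
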
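"""Synthetic data from the model's own generative process.

Draws TF expression and latent factors as independent standard normals,
plants sparse W and Lambda with fixed-magnitude (+/- effect_scale) nonzeros
at uniformly random positions, and assembles expression as

    X = R W' + Z Lambda' + 1 mu' + sigma * noise.

Fixed magnitudes make "support recovery" unambiguous. A companion generator
builds a category collection with one planted category per hidden factor
(an 80% subsample of its true support) plus random noise categories, so the
enrichment pipeline can be exercised end to end without downloads.

Defaults are the desk-scale study conditions used throughout the test suite:
5% TF-edge density, 20% loading density, unit effects, noise sigma 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import CategoryCollection
from .model_core import ExpressionDataset

__all__ = ["SyntheticTruth", "generate_dataset", "generate_category_collection",
           "write_dataset_files"]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters and latents behind a generated dataset."""

    W: np.ndarray
    Lambda: np.ndarray
    mu: np.ndarray
    sigma2: float
    Z: np.ndarray  # N x q latent draws
    w_support: np.ndarray  # boolean p x d
    lambda_support: np.ndarray  # boolean p x q
    planted_categories: dict[str, frozenset[str]] = field(default_factory=dict)


def _sparse_signed(
    shape: tuple[int, int], density: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Matrix with round(density*size) nonzeros of magnitude scale, signs
    uniform, positions uniform without replacement."""
    size = shape[0] * shape[1]
    k = int(round(density * size))
    out = np.zeros(size)
    if k > 0:
        pos = rng.choice(size, size=k, replace=False)
        out[pos] = scale * rng.choice([-1.0, 1.0], size=k)
    return out.reshape(shape)


def generate_dataset(
    p: int,
    d: int,
    q: int,
    N: int,
    w_density: float = 0.05,
    lambda_density: float = 0.2,
    effect_scale: float = 1.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Sample a dataset from the two-layer model; fully seeded."""
    for name, val in (("w_density", w_density), ("lambda_density", lambda_density)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    W = _sparse_signed((p, d), w_density, effect_scale, rng)
    Lam = _sparse_signed((p, q), lambda_density, effect_scale, rng)
    mu = rng.standard_normal(p)
    R = rng.standard_normal((N, d))
    Z = rng.standard_normal((N, q))
    noise = sigma * rng.standard_normal((N, p))
    X = Z @ Lam.T + mu + noise
    if d > 0:
        X = X + R @ W.T
    width_g = max(4, len(str(p)))
    width_t = max(3, len(str(d)))
    width_s = max(4, len(str(N)))
    gene_ids = [f"G{i + 1:0{width_g}d}" for i in range(p)]
    tf_ids = [f"TF{j + 1:0{width_t}d}" for j in range(d)]
    sample_ids = [f"S{n + 1:0{width_s}d}" for n in range(N)]
    data = ExpressionDataset(
        X=X, R=R, gene_ids=gene_ids, tf_ids=tf_ids, sample_ids=sample_ids
    )
    truth = SyntheticTruth(
        W=W,
        Lambda=Lam,
        mu=mu,
        sigma2=sigma**2,
        Z=Z,
        w_support=W != 0,
        lambda_support=Lam != 0,
    )
    return data, truth


def generate_category_collection(
    gene_ids: list[str],
    truth: SyntheticTruth,
    n_noise_categories: int = 20,
    seed: int = 0,
    planted_fraction: float = 0.8,
) -> CategoryCollection:
    """Planted categories (one per hidden factor) plus random noise ones.

    Each planted category is a seeded ``planted_fraction`` subsample of the
    factor's true support, so enrichment of recovered gene sets against it is
    detectable but not a tautological identity. The universe is all gene_ids.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(gene_ids, dtype=object)
    p = len(gene_ids)
    cats: dict[str, frozenset[str]] = {}
    q = truth.lambda_support.shape[1]
    for k in range(q):
        support = np.flatnonzero(truth.lambda_support[:, k])
        n_keep = max(1, math.ceil(planted_fraction * support.size)) if support.size else 0
        if n_keep == 0:
            continue
        chosen = rng.choice(support, size=n_keep, replace=False)
        cats[f"PLANTED_{k}"] = frozenset(ids[chosen])
    max_noise = max(6, p // 5)
    for j in range(n_noise_categories):
        size = int(rng.integers(5, max_noise + 1))
        size = min(size, p)
        chosen = rng.choice(p, size=size, replace=False)
        cats[f"NOISE_{j:03d}"] = frozenset(ids[chosen])
    collection = CategoryCollection(categories=cats, universe=frozenset(gene_ids))
    truth.planted_categories = {
        k: v for k, v in cats.items() if k.startswith("PLANTED_")
    }
    return collection


def write_dataset_files(
    data: ExpressionDataset,
    truth: SyntheticTruth,
    out_dir,
    collection: CategoryCollection | None = None,
) -> dict[str, Path]:
    """Write the same file formats the real pipeline reads.

    expression.tsv holds TF and gene columns together (samples x features);
    tf_list.txt names which columns are TFs; categories.gmt holds the
    collection; truth.npz archives the generating parameters.
    """
    from .io_formats import write_expression_tsv, write_gmt  # local import: avoid cycle
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        np.hstack([data.R, data.X]),
        index=data.sample_ids,
        columns=list(data.tf_ids) + list(data.gene_ids),
    )
    paths = {
        "expression": out / "expression.tsv",
        "tf_list": out / "tf_list.txt",
        "truth": out / "truth.npz",
    }
    write_expression_tsv(frame, paths["expression"])
    paths["tf_list"].write_text(
        "# synthetic TF identifiers\n" + "\n".join(data.tf_ids) + "\n"
    )
    meta = {
        "sigma2": truth.sigma2,
        "planted_categories": {k: sorted(v) for k, v in truth.planted_categories.items()},
    }
    np.savez(
        paths["truth"],
        W=truth.W,
        Lambda=truth.Lambda,
        mu=truth.mu,
        Z=truth.Z,
        meta=json.dumps(meta),
    )
    if collection is not None:
        paths["gmt"] = out / "categories.gmt"
        write_gmt(collection, paths["gmt"])
    return paths
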
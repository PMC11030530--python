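"""Seedable synthetic single-cell data with planted ground truth.

Every task in the benchmark is exercised on synthetic data carrying the
statistical structure its evaluation assumes:

* cell-type-structured counts — gamma-Poisson (negative binomial)
  counts with per-type mean profiles, log-normal baseline gene means,
  log-normal differential-expression fold changes on a fraction of
  genes per type, and gamma-distributed per-cell library sizes;
* multiplicative per-(batch, gene) batch effects, applied by Poisson
  resampling so counts stay integer;
* Dirichlet spot mixtures summing sampled reference cells (spatial
  deconvolution ground truth);
* linked modality views of the same cells through a shared latent
  space, with a shared feature block (matching ground truth);
* planted ligand-receptor interactions, scaled into the counts by
  Poisson resampling (cell-cell communication ground truth).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import CellByGeneDataset

__all__ = [
    "SyntheticConfig",
    "LRDatabase",
    "CCCTruth",
    "make_celltype_counts",
    "add_batch_effect",
    "make_spatial_mixture",
    "make_paired_modalities",
    "shuffle_pairing",
    "build_lr_database",
    "make_ccc_truth",
]


@dataclasses.dataclass
class SyntheticConfig:
    """Parameter bundle for the count generator.

    Defaults describe a small but realistically structured droplet-style
    experiment: 2,000 cells, 500 genes, 4 cell types with 10% of genes
    differentially expressed per type at log-normal(sd=1) fold changes,
    gamma-distributed library sizes averaging 2,000 UMIs, and (when
    batches are added) two batches with log-normal(sd=1) per-gene batch
    factors.
    """

    n_cells: int = 2000
    n_genes: int = 500
    n_types: int = 4
    n_batches: int = 2
    de_fraction: float = 0.1
    de_strength: float = 1.0
    library_size_mean: float = 2000.0
    library_size_shape: float = 2.0
    batch_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for f in ("n_cells", "n_genes", "n_types", "n_batches"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be a positive integer")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        for f in ("de_strength", "library_size_mean", "library_size_shape"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.batch_strength < 0:
            raise ValueError("batch_strength must be non-negative")


def test_scale(cfg: SyntheticConfig) -> SyntheticConfig:
    """The down-scaled variant used when a dataset runs in test mode."""
    return dataclasses.replace(
        cfg,
        n_cells=min(cfg.n_cells, 300),
        n_genes=min(cfg.n_genes, 120),
        library_size_mean=min(cfg.library_size_mean, 1000.0),
    )


def make_celltype_counts(cfg: SyntheticConfig) -> CellByGeneDataset:
    """Gamma-Poisson counts with per-type mean profiles.

    Baseline gene means are log-normal; for each type a ``de_fraction``
    subset of genes has its mean multiplied by log-normal
    (sd=``de_strength``) fold changes. Per-cell library sizes are gamma
    with shape ``library_size_shape`` and mean ``library_size_mean``,
    and counts are Poisson around library x (type profile), i.e. a
    negative-binomial marginal. ``cell_meta["label"]`` carries the type.
    """
    if cfg.n_types > cfg.n_cells:
        raise ValueError("n_types cannot exceed n_cells")
    rng = np.random.default_rng(cfg.seed)
    base = rng.lognormal(0.0, 1.0, cfg.n_genes)
    profiles = np.tile(base, (cfg.n_types, 1))
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    for t in range(cfg.n_types):
        idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
        profiles[t, idx] = profiles[t, idx] * rng.lognormal(
            0.0, cfg.de_strength, n_de
        )
    profiles /= profiles.sum(axis=1, keepdims=True)
    # near-balanced type assignment, shuffled
    types = np.tile(np.arange(cfg.n_types), cfg.n_cells // cfg.n_types + 1)[
        : cfg.n_cells
    ]
    rng.shuffle(types)
    lib = rng.gamma(
        cfg.library_size_shape,
        cfg.library_size_mean / cfg.library_size_shape,
        cfg.n_cells,
    )
    counts = rng.poisson(lib[:, None] * profiles[types]).astype(np.int64)
    cell_meta = pd.DataFrame(
        {"label": pd.Categorical([f"type_{t}" for t in types])},
        index=[f"cell_{i:05d}" for i in range(cfg.n_cells)],
    )
    gene_meta = pd.DataFrame(index=[f"gene_{j:04d}" for j in range(cfg.n_genes)])
    return CellByGeneDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def add_batch_effect(
    ds: CellByGeneDataset,
    n_batches: int,
    batch_strength: float,
    seed: int,
) -> CellByGeneDataset:
    """Assign batches (stratified by type) and apply per-(batch, gene) effects.

    Multiplicative log-normal(sd=``batch_strength``) factors scale the
    count means; counts are Poisson-resampled around the scaled means so
    they stay integer. Zero strength leaves the counts untouched.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if "label" not in ds.cell_meta:
        raise ValueError("dataset lacks cell-type labels")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    labels = np.asarray(out.cell_meta["label"])
    batches = np.empty(out.n_cells, dtype=np.int64)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        # round-robin within each type keeps per-batch type frequencies flat
        batches[idx] = (np.arange(idx.size) + rng.integers(n_batches)) % n_batches
    out.cell_meta["batch"] = pd.Categorical([f"batch_{b}" for b in batches])
    if batch_strength > 0:
        factors = rng.lognormal(0.0, batch_strength, (n_batches, out.n_genes))
        counts = np.asarray(out.counts, dtype=np.float64)
        out.counts = rng.poisson(counts * factors[batches]).astype(np.int64)
    return out


def make_spatial_mixture(
    reference: CellByGeneDataset,
    n_spots: int,
    cells_per_spot_mean: float,
    dirichlet_alpha: float,
    seed: int,
) -> CellByGeneDataset:
    """Dirichlet spot mixtures of reference cells, with true proportions.

    Each spot draws type proportions from a symmetric
    Dirichlet(``dirichlet_alpha``), a cell count from
    Poisson(``cells_per_spot_mean``) (at least one), samples that many
    reference cells (with replacement, per type), and sums their
    counts. ``truth["proportions"]`` holds the Dirichlet draws (rows sum
    to one) with type order in ``truth["type_order"]``.
    """
    if "label" not in reference.cell_meta:
        raise ValueError("reference lacks cell-type labels")
    labels = np.asarray(reference.cell_meta["label"])
    type_order = sorted(np.unique(labels).tolist())
    if len(type_order) < 2:
        raise ValueError("reference must contain at least two cell types")
    rng = np.random.default_rng(seed)
    by_type = {t: np.flatnonzero(labels == t) for t in type_order}
    props = rng.dirichlet(np.full(len(type_order), dirichlet_alpha), n_spots)
    ref_counts = np.asarray(reference.counts)
    spot_counts = np.zeros((n_spots, reference.n_genes), dtype=np.int64)
    for s in range(n_spots):
        n_cells = max(1, rng.poisson(cells_per_spot_mean))
        per_type = rng.multinomial(n_cells, props[s])
        for t, k in zip(type_order, per_type):
            if k == 0:
                continue
            chosen = rng.choice(by_type[t], size=k, replace=True)
            spot_counts[s] += ref_counts[chosen].sum(axis=0)
    cell_meta = pd.DataFrame(index=[f"spot_{i:04d}" for i in range(n_spots)])
    return CellByGeneDataset(
        counts=spot_counts,
        cell_meta=cell_meta,
        gene_meta=reference.gene_meta.copy(),
        truth={"proportions": props, "type_order": type_order},
    )


def make_paired_modalities(
    n_cells: int,
    d_latent: int,
    d1: int,
    d2: int,
    n_shared_features: int,
    noise_sd: float,
    seed: int,
) -> Tuple[CellByGeneDataset, CellByGeneDataset]:
    """Two linked modality views of the same cells.

    A shared standard-normal latent ``Z`` (n_cells x d_latent) is mapped
    through random linear maps into each modality; the first
    ``n_shared_features`` columns of both views use the *same* map, so
    they measure the same underlying features up to noise. Row ``i`` of
    both outputs is the same cell; ``truth["pairing"]`` on the first
    dataset is the identity permutation. The real-valued views live in
    ``layers["data"]`` (the counts slot is an all-zero placeholder).
    """
    if min(d1, d2) < d_latent:
        raise ValueError("modality dimensions must be >= d_latent")
    if n_shared_features > min(d1, d2):
        raise ValueError("n_shared_features exceeds a modality dimension")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_cells, d_latent))
    w_shared = rng.standard_normal((d_latent, n_shared_features))
    views = []
    for d in (d1, d2):
        w = rng.standard_normal((d_latent, d))
        w[:, :n_shared_features] = w_shared
        views.append(z @ w + noise_sd * rng.standard_normal((n_cells, d)))
    out = []
    for m, (x, d) in enumerate(zip(views, (d1, d2)), start=1):
        ds = CellByGeneDataset(
            counts=np.zeros((n_cells, d), dtype=np.int64),
            cell_meta=pd.DataFrame(
                index=[f"cell_{i:05d}" for i in range(n_cells)]
            ),
            gene_meta=pd.DataFrame(
                index=[f"mod{m}_feat_{j:04d}" for j in range(d)]
            ),
            layers={"data": x},
            truth={"n_shared_features": int(n_shared_features)},
        )
        out.append(ds)
    out[0].truth["pairing"] = np.arange(n_cells, dtype=np.int64)
    return out[0], out[1]


def shuffle_pairing(
    ds1: CellByGeneDataset, ds2: CellByGeneDataset, permutation: np.ndarray
) -> Tuple[CellByGeneDataset, CellByGeneDataset]:
    """Reorder modality-2 rows by ``permutation`` and update the pairing.

    After shuffling, row ``permutation[i]`` of the new modality 2 is the
    cell paired with row ``i`` of modality 1.
    """
    perm = np.asarray(permutation)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    ds2_new = ds2.copy()
    ds2_new.counts = ds2.counts[inv]
    ds2_new.cell_meta = ds2.cell_meta.iloc[inv].copy()
    ds2_new.layers = {k: v[inv] for k, v in ds2.layers.items()}
    ds1_new = ds1.copy()
    ds1_new.truth["pairing"] = perm[ds1.truth["pairing"]]
    return ds1_new, ds2_new


@dataclasses.dataclass(frozen=True)
class LRDatabase:
    """Catalogue of (ligand gene, receptor gene) pairs."""

    pairs: Tuple[Tuple[str, str], ...]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ligand-receptor pairs")

    def ligands(self) -> List[str]:
        return sorted({p[0] for p in self.pairs})


@dataclasses.dataclass(frozen=True)
class CCCTruth:
    """Planted positive sets at the two evaluation levels."""

    positive_st: frozenset  # {(source_type, target_type)}
    positive_lt: frozenset  # {(ligand_gene, target_type)}


def build_lr_database(
    gene_names: Sequence[str], n_pairs: int = 50, seed: int = 0
) -> LRDatabase:
    """Draw ``n_pairs`` disjoint ligand-receptor gene pairs from a panel."""
    if 2 * n_pairs > len(gene_names):
        raise ValueError("gene panel too small for requested pair count")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_names), size=2 * n_pairs, replace=False)
    names = [str(gene_names[i]) for i in chosen]
    pairs = tuple(zip(names[:n_pairs], names[n_pairs:]))
    return LRDatabase(pairs=pairs)


def make_ccc_truth(
    ds: CellByGeneDataset,
    lr_db: LRDatabase,
    n_true_pairs: int,
    effect_fold: float,
    seed: int,
) -> Tuple[CellByGeneDataset, CCCTruth]:
    """Plant ligand-receptor interactions between cell-type pairs.

    ``n_true_pairs`` (source type, target type, LR pair) triples are
    drawn uniformly without replacement; for each, the ligand gene's
    counts in source-type cells and the receptor gene's counts in
    target-type cells are scaled ``effect_fold``-fold by Poisson
    resampling around the scaled mean (counts stay integer). A fold of
    exactly 1 leaves the counts untouched.
    """
    if "label" not in ds.cell_meta:
        raise ValueError("dataset lacks cell-type labels")
    labels = np.asarray(ds.cell_meta["label"])
    types = sorted(np.unique(labels).tolist())
    if len(types) < 2:
        raise ValueError("dataset must contain at least two cell types")
    gene_index = {g: j for j, g in enumerate(ds.gene_meta.index)}
    usable = [p for p in lr_db.pairs if p[0] in gene_index and p[1] in gene_index]
    if not usable:
        raise ValueError("no ligand-receptor pair resolvable in the dataset")
    combos = [
        (s, t, pair) for s, t in itertools.product(types, types) for pair in usable
    ]
    if n_true_pairs > len(combos):
        raise ValueError(
            f"n_true_pairs={n_true_pairs} exceeds {len(combos)} available combinations"
        )
    rng = np.random.default_rng(seed)
    chosen = [combos[i] for i in rng.choice(len(combos), n_true_pairs, replace=False)]
    out = ds.copy()
    counts = np.asarray(out.counts, dtype=np.int64)
    for s, t, (lig, rec) in chosen:
        if effect_fold != 1:
            for gene, cell_type in ((lig, s), (rec, t)):
                j = gene_index[gene]
                rows = np.flatnonzero(labels == cell_type)
                counts[rows, j] = rng.poisson(counts[rows, j] * float(effect_fold))
    out.counts = counts
    truth = CCCTruth(
        positive_st=frozenset((s, t) for s, t, _ in chosen),
        positive_lt=frozenset((pair[0], t) for _, t, pair in chosen),
    )
    return out, truth
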
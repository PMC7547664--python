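"""Gene selection, bounded per-type cell subsampling and library sizes.

No normalization or transformation is applied anywhere: the count model
operates on raw integers, with sequencing depth absorbed by per-cell
library-size scaling factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data_io import Annotation, ExpressionMatrix, ValidationError


@dataclass
class SubsampleBounds:
    """Global lower/upper bounds on cells kept per type."""

    lower: int
    upper: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lower < 1:
            raise ValueError("lower bound must be >= 1")
        if self.upper < self.lower:
            raise ValueError("upper bound must be >= lower bound")


def select_top_genes(sc: ExpressionMatrix, n: int) -> list[str]:
    """Top ``n`` genes by total expression summed over all cells.

    Genes with zero total count are never selected; ties are broken by
    ascending lexicographic gene id for determinism.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = np.asarray(sc.counts.sum(axis=0)).ravel()
    order = sorted(range(sc.n_genes), key=lambda i: (-totals[i], sc.gene_ids[i]))
    return [sc.gene_ids[i] for i in order if totals[i] > 0][:n]


def subsample_cells(
    sc: ExpressionMatrix, ann: Annotation, bounds: SubsampleBounds
) -> tuple[ExpressionMatrix, Annotation]:
    """Bounded per-type subsampling of the single-cell data.

    Types with fewer than ``lower`` cells are dropped entirely; types within
    the bounds are kept whole; types above ``upper`` are downsampled to
    exactly ``upper`` cells uniformly without replacement. Deterministic for
    a given ``bounds.seed`` (dedicated RNG stream, not the global one).
    """
    labels = ann.subset(sc.obs_ids)
    rng = np.random.default_rng(bounds.seed)
    keep: list[str] = []
    by_type: dict[str, list[str]] = {}
    for cell, lab in zip(labels.cell_ids, labels.labels):
        by_type.setdefault(lab, []).append(cell)
    for lab in sorted(by_type):
        cells = by_type[lab]
        n_z = len(cells)
        if n_z < bounds.lower:
            continue
        if n_z > bounds.upper:
            chosen = rng.choice(n_z, size=bounds.upper, replace=False)
            cells = [cells[i] for i in sorted(chosen)]
        keep.extend(cells)
    if not keep:
        raise ValidationError("no cell type survives the subsampling bounds")
    kept_set = set(keep)
    ordered = [c for c in sc.obs_ids if c in kept_set]
    return sc.subset_obs(ordered), labels.subset(ordered)


def library_sizes(X: ExpressionMatrix) -> np.ndarray:
    """Per-observation total count s = sum over genes (the scaling factor)."""
    return np.asarray(X.counts.sum(axis=1), dtype=float).ravel()


def drop_zero_observations(
    X: ExpressionMatrix, what: str = "observations"
) -> ExpressionMatrix:
    """Remove observations with zero total count, warning when any are found."""
    s = library_sizes(X)
    if (s > 0).all():
        return X
    n0 = int((s == 0).sum())
    warnings.warn(f"dropping {n0} {what} with zero total count", stacklevel=2)
    keep = [o for o, tot in zip(X.obs_ids, s) if tot > 0]
    if not keep:
        raise ValidationError(f"all {what} have zero total count")
    return X.subset_obs(keep)


def drop_zero_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes never observed (their rate is unidentifiable)."""
    totals = np.asarray(X.counts.sum(axis=0)).ravel()
    if (totals > 0).all():
        return X
    keep = [g for g, tot in zip(X.gene_ids, totals) if tot > 0]
    if not keep:
        raise ValidationError("all genes have zero total count")
    return X.subset_genes(keep)
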
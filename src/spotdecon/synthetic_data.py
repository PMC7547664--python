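"""Synthetic data: semi-synthetic spots from real cells, and NB single cells.

The spot generator composes capture locations by sampling real annotated
cells and summing (a scaled copy of) their expression rows, so the ground
truth proportions are known exactly. It is deliberately not based on the NB
model, to avoid favoring the deconvolution model under test. A fully
synthetic NB single-cell generator is also provided so parameter-recovery
tests need no external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import Annotation, ExpressionMatrix, ProportionMatrix, ValidationError


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Nearest integer, halves rounded away from zero (not banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class SpotMembers:
    """Cells drawn for one spot: type label -> (cell ids, cell count)."""

    spot_id: str
    composition: dict[str, tuple[list[str], int]]


@dataclass
class SyntheticDataset:
    spots: ExpressionMatrix
    truth: ProportionMatrix
    members: list[SpotMembers]
    config: dict = field(default_factory=dict)


def generate_spots(
    sc: ExpressionMatrix,
    ann: Annotation,
    S: int,
    lb: int,
    ub: int,
    alpha: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Assemble ``S`` synthetic capture locations from annotated cells.

    Per spot: the cell budget C_s ~ Unif{lb..ub}; the number of contributing
    types |Z_s| ~ Unif{1..|Z|}; types drawn without replacement; unadjusted
    proportions from a flat Dirichlet over Z_s; per-type cell counts are the
    nearest integers of proportion * C_s (if all round to zero the
    largest-proportion type gets one cell; a count exceeding the type's
    available cells is capped). The adjusted (ground-truth) proportions are
    the per-spot normalization of the realized counts. Spot expression is
    the sum over sampled cells of round(alpha * y_cg), cells drawn uniformly
    without replacement within each (spot, type).
    """
    if lb < 1 or ub < lb:
        raise ValueError("bounds must satisfy 1 <= lb <= ub")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if S < 1:
        raise ValueError("S must be >= 1")
    ann = ann.subset(sc.obs_ids)
    types = ann.types
    cells_of: dict[str, list[int]] = {t: [] for t in types}
    for i, lab in enumerate(ann.labels):
        cells_of[lab].append(i)
    for t in types:
        if not cells_of[t]:
            raise ValidationError(f"type {t!r} has no cells")

    Y = np.asarray(sc.dense(), dtype=float)
    Ys = round_half_away(alpha * Y)
    rng = np.random.default_rng(seed)
    Z = len(types)

    X = np.zeros((S, sc.n_genes))
    W = np.zeros((S, Z))
    members: list[SpotMembers] = []
    for si in range(S):
        C_s = int(rng.integers(lb, ub + 1))
        k = int(rng.integers(1, Z + 1))
        chosen = rng.choice(Z, size=k, replace=False)
        props = rng.dirichlet(np.ones(k))
        n = round_half_away(props * C_s).astype(int)
        if n.sum() == 0:
            n[int(np.argmax(props))] = 1
        # cap at the available cells of each type (sampling is w/o replacement)
        avail = np.array([len(cells_of[types[zi]]) for zi in chosen])
        np.minimum(n, avail, out=n)
        if n.sum() == 0:
            raise ValidationError("spot ended up with zero cells after capping")
        # repair rounding/capping drift so the realized total stays in [lb, ub]
        while n.sum() > ub:
            n[int(np.argmax(n))] -= 1
        while n.sum() < lb:
            room = (n < avail)
            if not room.any():
                warnings.warn(
                    "not enough cells to reach the lower bound at a spot",
                    stacklevel=2,
                )
                break
            masked = np.where(room, props, -np.inf)
            n[int(np.argmax(masked))] += 1
        comp: dict[str, tuple[list[str], int]] = {}
        for j, zi in enumerate(chosen):
            if n[j] == 0:
                continue
            t = types[zi]
            picked = rng.choice(cells_of[t], size=n[j], replace=False)
            X[si] += Ys[picked].sum(axis=0)
            W[si, zi] = n[j]
            comp[t] = ([sc.obs_ids[c] for c in picked], int(n[j]))
        W[si] /= W[si].sum()
        members.append(SpotMembers(f"spot_{si}", comp))

    spot_ids = [m.spot_id for m in members]
    spots = ExpressionMatrix(spot_ids, list(sc.gene_ids), X)
    truth = ProportionMatrix(spot_ids, types, W)
    return SyntheticDataset(
        spots, truth, members,
        config={"S": S, "lb": lb, "ub": ub, "alpha": alpha, "seed": seed},
    )


def split_generation_validation(
    sc: ExpressionMatrix, ann: Annotation, seed: int = 0
) -> tuple[tuple[ExpressionMatrix, Annotation], tuple[ExpressionMatrix, Annotation]]:
    """Stratified half/half split into disjoint generation and validation sets.

    Odd type counts put the extra cell in the generation set; a type with a
    single cell goes to the generation set only, with a warning.
    """
    ann = ann.subset(sc.obs_ids)
    rng = np.random.default_rng(seed)
    gen_cells: list[str] = []
    val_cells: list[str] = []
    by_type: dict[str, list[str]] = {}
    for cell, lab in zip(ann.cell_ids, ann.labels):
        by_type.setdefault(lab, []).append(cell)
    for lab in sorted(by_type):
        cells = by_type[lab]
        if len(cells) == 1:
            warnings.warn(
                f"type {lab!r} has a single cell; assigned to generation set only",
                stacklevel=2,
            )
            gen_cells.extend(cells)
            continue
        perm = rng.permutation(len(cells))
        n_gen = (len(cells) + 1) // 2
        gen_cells.extend(cells[i] for i in perm[:n_gen])
        val_cells.extend(cells[i] for i in perm[n_gen:])
    order = {c: i for i, c in enumerate(sc.obs_ids)}
    gen_cells.sort(key=order.__getitem__)
    val_cells.sort(key=order.__getitem__)
    gen = (sc.subset_obs(gen_cells), ann.subset(gen_cells))
    val = (sc.subset_obs(val_cells), ann.subset(val_cells))
    return gen, val


@dataclass
class NBGroundTruth:
    """True parameters for the fully synthetic NB single-cell generator."""

    gene_ids: list[str]
    type_labels: list[str]
    rates: np.ndarray  # |G| x |Z|, > 0
    probs: np.ndarray  # |G| in (0, 1)
    lib_sizes: np.ndarray  # nominal per-cell scaling factors, > 0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if (self.rates <= 0).any():
            raise ValidationError("rates must be positive")
        if (self.probs <= 0).any() or (self.probs >= 1).any():
            raise ValidationError("probs must lie in (0, 1)")
        if (self.lib_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")

    @classmethod
    def random(
        cls,
        n_genes: int,
        n_types: int,
        seed: int = 0,
        rate_log_mean: float = 0.7,
        rate_log_sd: float = 1.0,
        p_low: float = 0.2,
        p_high: float = 0.8,
        lib_log_mean: float = np.log(5.0),
        lib_log_sd: float = 0.3,
        n_lib: int = 512,
    ) -> "NBGroundTruth":
        """Draw a realistic truth: log-normal rates, uniform success probs,
        log-normal scaling-factor pool sized for well-covered (top-expressed)
        genes — a few to a few dozen counts per gene and cell."""
        rng = np.random.default_rng(seed)
        rates = rng.lognormal(rate_log_mean, rate_log_sd, size=(n_genes, n_types))
        probs = rng.uniform(p_low, p_high, size=n_genes)
        libs = rng.lognormal(lib_log_mean, lib_log_sd, size=n_lib)
        return cls(
            gene_ids=[f"g{i}" for i in range(n_genes)],
            type_labels=[f"type{j}" for j in range(n_types)],
            rates=rates,
            probs=probs,
            lib_sizes=libs,
        )


def generate_nb_sc(
    truth: NBGroundTruth, cells_per_type: int, seed: int = 0
) -> tuple[ExpressionMatrix, Annotation]:
    """Sample labeled single cells from y_gc ~ NB(s_c r_gz, p_g).

    Nominal scaling factors s_c are cycled from ``truth.lib_sizes``; numpy's
    negative_binomial(n, q) counts failures before n successes, so our
    success probability p maps to q = 1 - p.
    """
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    G, Z = truth.rates.shape
    rows, cells, labels = [], [], []
    for z, lab in enumerate(truth.type_labels):
        for i in range(cells_per_type):
            s = truth.lib_sizes[(z * cells_per_type + i) % truth.lib_sizes.size]
            mu = s * truth.rates[:, z]
            rows.append(rng.negative_binomial(mu, 1.0 - truth.probs))
            cells.append(f"{lab}_c{i}")
            labels.append(lab)
    em = ExpressionMatrix(cells, list(truth.gene_ids), np.asarray(rows))
    return em, Annotation(cells, labels)
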
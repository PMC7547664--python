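"""Count-matrix, annotation and proportion I/O plus gene alignment.

Count matrices are oriented observations x genes (rows = cells or capture
locations, columns = genes) in both the TSV and Matrix Market dialects.
Gene identifiers are matched by exact, case-sensitive string equality.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """File could not be parsed in the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Observation x gene table of raw (non-negative integer) counts.

    ``counts`` may be a dense ndarray or a scipy sparse matrix; rows follow
    ``obs_ids`` and columns follow ``gene_ids``.
    """

    obs_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray | sp.spmatrix

    def __post_init__(self) -> None:
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.obs_ids, "observation ids")
        _check_unique(self.gene_ids, "gene ids")
        shape = self.counts.shape
        if shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValidationError(
                f"count matrix shape {shape} does not match "
                f"{len(self.obs_ids)} observations x {len(self.gene_ids)} genes"
            )
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        data = np.asarray(data)
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValidationError("counts contain NaN or infinite entries")
            if (data < 0).any():
                raise ValidationError("counts contain negative entries")
            if np.any(data != np.round(data)):
                raise ValidationError("counts contain non-integer entries")

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes``, in the given order."""
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(genes)
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise ValidationError(f"genes not present: {missing[:5]}")
        counts = self.counts.tocsc()[:, pos] if sp.issparse(self.counts) else self.counts[:, pos]
        return ExpressionMatrix(list(self.obs_ids), list(genes), counts)

    def subset_obs(self, obs: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.obs_ids)
        pos = idx.get_indexer(obs)
        if (pos < 0).any():
            missing = [o for o, p in zip(obs, pos) if p < 0]
            raise ValidationError(f"observations not present: {missing[:5]}")
        counts = self.counts.tocsr()[pos] if sp.issparse(self.counts) else self.counts[pos]
        return ExpressionMatrix(list(obs), list(self.gene_ids), counts)


@dataclass
class Annotation:
    """Per-cell type labels; order parallels ``cell_ids``."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        _check_unique(self.cell_ids, "cell ids")
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("one label required per cell")
        for lab in self.labels:
            if lab == "" or lab.lower() == "nan":
                raise ValidationError("empty or missing type label")

    @property
    def types(self) -> list[str]:
        """Sorted unique type labels."""
        return sorted(set(self.labels))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="label")

    def subset(self, cells: list[str]) -> "Annotation":
        s = self.as_series()
        missing = [c for c in cells if c not in s.index]
        if missing:
            raise ValidationError(f"cells without annotation: {missing[:5]}")
        return Annotation(list(cells), s.loc[cells].tolist())


@dataclass
class ProportionMatrix:
    """Per-spot cell-type proportions on the simplex.

    The noise-absorbing dummy type is never a column here; its unnormalized
    weight, when available, is carried separately in ``dummy_share``.
    """

    spot_ids: list[str]
    type_labels: list[str]
    w: np.ndarray
    dummy_share: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.type_labels = [str(t) for t in self.type_labels]
        _check_unique(self.spot_ids, "spot ids")
        _check_unique(self.type_labels, "type labels")
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.spot_ids), len(self.type_labels)):
            raise ValidationError("proportion matrix shape mismatch")
        if (self.w < -1e-12).any() or (self.w > 1 + 1e-12).any():
            raise ValidationError("proportions outside [0, 1]")
        sums = self.w.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValidationError("proportion rows must sum to 1 within 1e-6")
        if self.dummy_share is not None:
            self.dummy_share = np.asarray(self.dummy_share, dtype=float)
            if self.dummy_share.shape != (len(self.spot_ids),):
                raise ValidationError("dummy_share length mismatch")


def read_counts(path: str, fmt: str = "tsv", transpose: bool = False) -> ExpressionMatrix:
    """Read a raw count matrix.

    TSV: header row of gene ids, first column observation ids.
    MTX: MatrixMarket coordinate file with sidecars ``<prefix>.obs.txt`` and
    ``<prefix>.genes.txt`` (one id per line).
    """
    if fmt not in ("tsv", "mtx"):
        raise ValueError(f"unknown format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "tsv":
        if os.path.getsize(path) == 0:
            raise FormatError(f"{path} is empty")
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n")
        raw_cols = header.split("\t")[1:]  # pandas silently renames duplicates
        _check_unique(raw_cols, "gene ids")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"could not parse {path} as TSV: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path} has no gene columns")
        if df.isna().any().any():
            raise ValidationError(f"{path} contains missing values")
        obs_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]
        counts = df.to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise ValidationError(f"{path} contains non-numeric entries")
        counts = np.asarray(counts, dtype=float)
    else:
        prefix = path[:-4] if path.endswith(".mtx") else path
        try:
            counts = scipy.io.mmread(path if path.endswith(".mtx") else prefix + ".mtx")
        except Exception as exc:
            raise FormatError(f"could not parse {path} as MatrixMarket: {exc}") from exc
        counts = sp.csr_matrix(counts)
        obs_ids = _read_id_list(prefix + ".obs.txt")
        gene_ids = _read_id_list(prefix + ".genes.txt")
    if transpose:
        counts = counts.T
        obs_ids, gene_ids = gene_ids, obs_ids
    return ExpressionMatrix(obs_ids, gene_ids, counts)


def _read_id_list(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FormatError(f"missing sidecar id file {path}")
    with open(path, encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise FormatError(f"empty sidecar id file {path}")
    return ids


def write_counts(em: ExpressionMatrix, path: str, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        df = pd.DataFrame(em.dense(), index=em.obs_ids, columns=em.gene_ids)
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        prefix = path[:-4] if path.endswith(".mtx") else path
        scipy.io.mmwrite(prefix + ".mtx", sp.coo_matrix(em.counts))
        for name, ids in (("obs", em.obs_ids), ("genes", em.gene_ids)):
            with open(f"{prefix}.{name}.txt", "w", encoding="utf-8") as fh:
                fh.write("\n".join(ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_annotation(path: str, header: bool = False, join_columns: bool = False) -> Annotation:
    """Read a two-column TSV of (cell id, type label).

    With ``join_columns`` any additional label columns are concatenated with
    ``_`` into a single label, e.g. a broad class joined with a cluster id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path} is empty")
    df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path} must have at least two columns")
    cells = df.iloc[:, 0].tolist()
    if join_columns and df.shape[1] > 2:
        labels = df.iloc[:, 1:].agg("_".join, axis=1).tolist()
    else:
        labels = df.iloc[:, 1].tolist()
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ValidationError(f"{path} has missing labels")
    return Annotation(cells, labels)


def write_annotation(ann: Annotation, path: str) -> None:
    pd.DataFrame({"cell": ann.cell_ids, "label": ann.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def intersect_genes(
    sc: ExpressionMatrix, sp_data: ExpressionMatrix, selected: list[str]
) -> list[str]:
    """Intersect a selected single-cell gene list with the spatial genes.

    Returns ``selected ∩ sp_data.gene_ids`` preserving the order of
    ``selected``; errors when the intersection is empty.
    """
    sc_set = set(sc.gene_ids)
    unknown = [g for g in selected if g not in sc_set]
    if unknown:
        raise ValidationError(f"selected genes absent from single-cell data: {unknown[:5]}")
    sp_set = set(sp_data.gene_ids)
    out = [g for g in selected if g in sp_set]
    if not out:
        raise ValidationError("no genes shared between single-cell selection and spatial data")
    return out


def write_proportions(pm: ProportionMatrix, path: str) -> None:
    """Write proportions as TSV (spots x types); refuses invalid rows."""
    # re-validate: callers may have mutated w in place
    ProportionMatrix(pm.spot_ids, pm.type_labels, pm.w, pm.dummy_share)
    df = pd.DataFrame(pm.w, index=pm.spot_ids, columns=pm.type_labels)
    if pm.dummy_share is not None:
        df = df.assign(**{"__dummy_share__": pm.dummy_share})
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_proportions(path: str) -> ProportionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dummy = None
    if "__dummy_share__" in df.columns:
        dummy = df.pop("__dummy_share__").to_numpy()
    return ProportionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(), dummy
    )


def write_sc_params(params, directory: str) -> None:
    """Serialize fitted single-cell NB parameters as portable TSV tables.

    Writes ``rates.tsv`` (genes x types, the positive rates) and
    ``logits.tsv`` (per-gene success-probability logits and probabilities),
    so spatial fits can reuse them without re-estimation.
    """
    os.makedirs(directory, exist_ok=True)
    rates = pd.DataFrame(params.rates, index=params.gene_ids, columns=params.type_labels)
    rates.to_csv(os.path.join(directory, "rates.tsv"), sep="\t", float_format="%.12g")
    logits = pd.DataFrame(
        {"logit": params.p_logits, "p": params.p}, index=params.gene_ids
    )
    logits.to_csv(os.path.join(directory, "logits.tsv"), sep="\t", float_format="%.12g")


def read_sc_params(directory: str):
    from .sc_model import SCParams, _inv_softplus

    rates = pd.read_csv(os.path.join(directory, "rates.tsv"), sep="\t", index_col=0)
    logits = pd.read_csv(os.path.join(directory, "logits.tsv"), sep="\t", index_col=0)
    if not rates.index.equals(logits.index):
        raise ValidationError("rates.tsv and logits.tsv gene ids disagree")
    return SCParams(
        type_labels=[str(c) for c in rates.columns],
        gene_ids=[str(i) for i in rates.index],
        log_rates=_inv_softplus(rates.to_numpy()),
        p_logits=logits["logit"].to_numpy(),
        loss_history=np.array([]),
    )
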
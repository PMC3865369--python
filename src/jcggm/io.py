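"""File I/O and domain containers.

Tabular files are TSV by default (comma accepted by sniffing the header
line), UTF-8, with the first column holding row identifiers.  Expression
matrices are stored samples x genes or genes x samples; loading always
returns samples x genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class LoadError(ValueError):
    """A data file failed validation (missing value, duplicate id, ...)."""


@dataclass
class GeneticMap:
    """Marker map: list of ``(marker_id, chromosome_id, position_cM)``.

    Positions must be non-decreasing within a chromosome and marker ids
    unique.
    """

    markers: list

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.markers]
        if len(set(ids)) != len(ids):
            raise LoadError("duplicate marker ids in genetic map")
        last: dict[str, float] = {}
        for mid, chrom, pos in self.markers:
            if pos < 0:
                raise LoadError(f"negative position for marker {mid}")
            if chrom in last and pos < last[chrom]:
                raise LoadError(
                    f"positions not non-decreasing on chromosome {chrom} at {mid}")
            last[chrom] = pos

    @property
    def marker_ids(self) -> list:
        return [m[0] for m in self.markers]


@dataclass
class CovariateMatrix:
    """Covariates (e.g. marker genotypes): samples x markers.

    ``coding='backcross01'`` enforces 0/1 entries; ``q = 0`` columns means
    the unconditional model.
    """

    X: np.ndarray
    marker_ids: list
    sample_ids: list
    coding: str = "backcross01"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise LoadError("X must be 2-dimensional")
        if self.X.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise LoadError("X shape does not match sample/marker id lengths")
        if np.isnan(self.X).any():
            raise LoadError("missing values in covariate matrix")
        if self.coding == "backcross01" and self.X.size and \
                not np.isin(self.X, (0.0, 1.0)).all():
            raise LoadError("backcross01 coding requires all entries in {0, 1}")

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def subset(self, marker_ids) -> "CovariateMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return CovariateMatrix(self.X[:, idx], list(marker_ids),
                               self.sample_ids, self.coding)


@dataclass
class ConditionPanel:
    """T condition-specific expression matrices over a shared gene set.

    All conditions carry identical ``gene_ids`` in identical order; each
    condition may have its own samples.  Missing values are a load-time
    error.
    """

    conditions: list
    Ys: list
    gene_ids: list
    sample_ids: list  # per condition

    def __post_init__(self) -> None:
        if not (len(self.conditions) == len(self.Ys) == len(self.sample_ids)):
            raise LoadError("conditions, Ys and sample_ids must have equal length")
        p = len(self.gene_ids)
        if p < 2:
            raise LoadError("need at least 2 genes")
        for label, Y, sids in zip(self.conditions, self.Ys, self.sample_ids):
            Y = np.asarray(Y, dtype=float)
            if Y.shape != (len(sids), p):
                raise LoadError(f"condition {label}: matrix shape {Y.shape} does not "
                                f"match {len(sids)} samples x {p} genes")
            if Y.shape[0] < 2:
                raise LoadError(f"condition {label}: need at least 2 samples")
            if np.isnan(Y).any():
                raise LoadError(f"condition {label}: missing values in expression matrix")
        self.Ys = [np.asarray(Y, dtype=float) for Y in self.Ys]

    @property
    def T(self) -> int:
        return len(self.conditions)

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    @property
    def n_ts(self) -> list:
        return [Y.shape[0] for Y in self.Ys]


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     encoding="utf-8", na_values=["NA", "NaN", ""])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise LoadError(f"{path}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise LoadError(f"{path}: duplicate column id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise LoadError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise LoadError(f"{path}: missing value at row {row!r}, column {col!r}")
        df[col] = vals
    return df


def read_expression(path, orientation: str = "samples_rows"):
    """Load one condition's expression matrix.

    Returns ``(Y, sample_ids, gene_ids)`` with ``Y`` samples x genes
    regardless of the on-disk orientation.
    """
    df = _read_table(path)
    if orientation == "genes_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError("orientation must be 'samples_rows' or 'genes_rows'")
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def read_genotypes(path, coding: str = "backcross01") -> CovariateMatrix:
    """Load a samples x markers genotype/covariate table."""
    df = _read_table(path)
    return CovariateMatrix(df.to_numpy(dtype=float), list(df.columns),
                           list(df.index), coding)


def read_map(path) -> GeneticMap:
    """Load a genetic map TSV with columns marker, chromosome, position (cM)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), encoding="utf-8")
    if df.shape[1] < 3:
        raise LoadError(f"{path}: map needs columns marker, chromosome, position")
    markers = [(str(r.iloc[0]), str(r.iloc[1]), float(r.iloc[2]))
               for _, r in df.iterrows()]
    return GeneticMap(markers)


def load_panel(paths: dict, orientation: str = "samples_rows") -> ConditionPanel:
    """Load several condition files into a panel, checking the shared gene set."""
    conditions, Ys, sample_ids = [], [], []
    gene_ids = None
    for label, path in paths.items():
        Y, sids, gids = read_expression(path, orientation)
        if gene_ids is None:
            gene_ids = gids
        elif gids != gene_ids:
            raise LoadError(f"condition {label}: gene ids differ from first condition")
        conditions.append(label)
        Ys.append(Y)
        sample_ids.append(sids)
    return ConditionPanel(conditions, Ys, gene_ids, sample_ids)


def align_samples(panel: ConditionPanel, covariates: CovariateMatrix):
    """Per-condition covariate matrices row-aligned to each condition by id.

    Alignment is by sample id, never by row order; a sample present in a
    condition but absent from the covariate table is an error.
    """
    pos = {sid: i for i, sid in enumerate(covariates.sample_ids)}
    out = []
    for label, sids in zip(panel.conditions, panel.sample_ids):
        missing = [s for s in sids if s not in pos]
        if missing:
            raise LoadError(f"condition {label}: samples {missing[:5]} absent "
                            "from covariate table")
        out.append(covariates.X[[pos[s] for s in sids], :])
    return out


def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial correlation matrix ``-omega_ij / sqrt(omega_ii omega_jj)``."""
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("invalid precision matrix: non-positive diagonal")
    denom = np.sqrt(np.outer(d, d))
    pc = -omega / denom
    np.fill_diagonal(pc, 1.0)
    return pc


def write_edge_list(precisions, gene_ids, out_dir, conditions=None,
                    threshold: float = 1e-6) -> list:
    """Write one edge-list TSV per condition plus a combined presence table.

    Rows are pairs ``(gene_i, gene_j)`` with ``i < j`` and
    ``|omega_ij| > threshold``; the value column is the partial correlation
    ``-omega_ij / sqrt(omega_ii omega_jj)``.
    """
    omegas = precisions.omegas if hasattr(precisions, "omegas") else list(precisions)
    conditions = conditions or [f"condition{t + 1}" for t in range(len(omegas))]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = len(gene_ids)
    iu = np.triu_indices(p, 1)
    written = []
    presence = {}
    for label, om in zip(conditions, omegas):
        pc = partial_correlations(om)
        keep = np.abs(om[iu]) > threshold
        df = pd.DataFrame({
            "gene_i": [gene_ids[i] for i in iu[0][keep]],
            "gene_j": [gene_ids[j] for j in iu[1][keep]],
            "partial_correlation": pc[iu][keep],
        })
        path = out_dir / f"edges_{label}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
        presence[label] = {(gene_ids[i], gene_ids[j])
                           for i, j in zip(iu[0][keep], iu[1][keep])}
    all_pairs = sorted(set().union(*presence.values())) if presence else []
    comb = pd.DataFrame({
        "gene_i": [a for a, _ in all_pairs],
        "gene_j": [b for _, b in all_pairs],
        **{label: [int((a, b) in presence[label]) for a, b in all_pairs]
           for label in conditions},
    })
    comb_path = out_dir / "edges_combined.tsv"
    comb.to_csv(comb_path, sep="\t", index=False)
    written.append(comb_path)
    return written


def write_precisions(precisions, gene_ids, out_dir, conditions=None) -> list:
    """Write each fitted precision matrix as a dense TSV."""
    omegas = precisions.omegas if hasattr(precisions, "omegas") else list(precisions)
    conditions = conditions or [f"condition{t + 1}" for t in range(len(omegas))]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, om in zip(conditions, omegas):
        df = pd.DataFrame(om, index=gene_ids, columns=gene_ids)
        path = out_dir / f"precision_{label}.tsv"
        df.to_csv(path, sep="\t", float_format="%.12g")
        written.append(path)
    return written


def read_precision(path) -> np.ndarray:
    df = _read_table(path)
    return df.to_numpy(dtype=float)


def write_run_metadata(path, **meta) -> None:
    """Serialize run metadata (selected lambda, BIC path, seed, ...) as JSON."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(meta, indent=2, default=_default),
                          encoding="utf-8")
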
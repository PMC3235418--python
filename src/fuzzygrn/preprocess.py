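"""Bounded transforms and the time-series expression container.

Raw data are log2 expression ratios (genes x time points) plus an optional
phenotype track (fraction of budding cells in [0, 1]).  The fuzzy machinery
works on a symmetric bounded scale, so expression is normalized as

    x = arctan(log2 ratio) / (pi / 2)        in (-1, 1)

and predictions are inverted with tan(x * pi/2).  Defuzzified phenotype
predictions are pushed through a logistic (steepness C = 6, centered at 0.5)
to undo the sigmoidal compression the arctangent introduces:

    p = 1 / (1 + exp(-6 * (2x - 1)))

Missing expression values are carried as NaN and dropped listwise at fit
time; infinities are rejected up front with the offending cell named.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError, DomainError

__all__ = [
    "ExpressionDataset",
    "normalize_expression",
    "denormalize_expression",
    "phenotype_backtransform",
    "phenotype_backtransform_inverse",
    "read_expression_matrix",
    "read_phenotype_series",
    "write_expression_matrix",
    "write_phenotype_series",
]

_LOGISTIC_STEEPNESS = 6.0


def normalize_expression(log2_ratio, *, allow_nan: bool = False) -> np.ndarray:
    """arctan normalization of a log2 expression ratio onto (-1, 1).

    Odd-symmetric and strictly increasing; 0 -> 0 and 1 -> 0.5.
    NaN (missing) passes through only when ``allow_nan`` is set.
    """
    v = np.asarray(log2_ratio, dtype=float)
    bad = np.isinf(v) | (~allow_nan & np.isnan(v))
    if np.any(bad):
        raise DomainError("normalize_expression: non-finite log2 ratio")
    return np.arctan(v) / (np.pi / 2.0)


def denormalize_expression(x) -> np.ndarray:
    """Inverse of :func:`normalize_expression`: ``tan(x * pi/2)`` for |x| < 1."""
    v = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(np.abs(v) >= 1.0):
        raise DomainError(
            "denormalize_expression: |x| >= 1 hits the tangent pole (or x is non-finite)"
        )
    return np.tan(v * (np.pi / 2.0))


def phenotype_backtransform(x) -> np.ndarray:
    """Logistic back-transform of a defuzzified phenotype value in [0, 1].

    ``1 / (1 + exp(-6 * (2x - 1)))``: monotone, fixes 0.5, and spreads the
    centroid output over (0, 1).
    """
    v = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(v)) or np.any((v < 0.0) | (v > 1.0)):
        raise DomainError("phenotype_backtransform: value outside [0, 1]")
    return 1.0 / (1.0 + np.exp(-_LOGISTIC_STEEPNESS * (2.0 * v - 1.0)))


def phenotype_backtransform_inverse(p) -> np.ndarray:
    """Inverse logistic: maps an observed budding fraction in (0, 1) back to
    the defuzzified (centroid) scale.  Used only to seed simulations from
    observed phenotype values; observed phenotype is never forward-fuzzified."""
    v = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(v)) or np.any((v <= 0.0) | (v >= 1.0)):
        raise DomainError("phenotype_backtransform_inverse: value outside (0, 1)")
    return (np.log(v / (1.0 - v)) / _LOGISTIC_STEEPNESS + 1.0) / 2.0


@dataclass
class ExpressionDataset:
    """A gene x time matrix of log2 ratios with an optional phenotype track.

    Attributes
    ----------
    gene_ids : list of node labels (rows of the matrix, order preserved).
    times : strictly increasing time points in minutes.
    log2_matrix : (n_genes, n_times) log2 expression ratios; NaN = missing.
    phenotype : optional (n_times,) fraction of budding cells in [0, 1].
    normalized_matrix : arctan-normalized matrix, computed on construction;
        values lie strictly within (-1, 1) (NaN where missing).
    """

    gene_ids: list[str]
    times: np.ndarray
    log2_matrix: np.ndarray
    phenotype: np.ndarray | None = None
    normalized_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.log2_matrix = np.asarray(self.log2_matrix, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("duplicate gene ids")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise DataValidationError("times must be 1-D and strictly increasing")
        if self.log2_matrix.shape != (len(self.gene_ids), self.times.size):
            raise DataValidationError(
                f"matrix shape {self.log2_matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.times.size} time points"
            )
        inf = np.argwhere(np.isinf(self.log2_matrix))
        if inf.size:
            g, t = inf[0]
            raise DataValidationError(
                f"non-finite log2 ratio for gene {self.gene_ids[g]!r} "
                f"at time {self.times[t]:g}"
            )
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (self.times.size,):
                raise DataValidationError("phenotype length does not match time points")
            ok = np.isnan(self.phenotype) | (
                (self.phenotype >= 0.0) & (self.phenotype <= 1.0)
            )
            if not np.all(ok):
                t = int(np.argmin(ok))
                raise DataValidationError(
                    f"phenotype value {self.phenotype[t]} at time {self.times[t]:g} "
                    "outside [0, 1]"
                )
        self.normalized_matrix = normalize_expression(self.log2_matrix, allow_nan=True)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise DataValidationError(f"unknown gene {gene!r}") from None

    def normalized_row(self, gene: str) -> np.ndarray:
        return self.normalized_matrix[self.gene_index(gene)]

    def log2_row(self, gene: str) -> np.ndarray:
        return self.log2_matrix[self.gene_index(gene)]


# ---------------------------------------------------------------------------
# Delimited-table IO (tab-separated; first column gene label, header = time
# in minutes; phenotype as a two-column time/fraction table).

def read_expression_matrix(path, *, sep: str = "\t") -> ExpressionDataset:
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise DataValidationError(
            f"{path}: header must be numeric time points in minutes"
        ) from exc
    return ExpressionDataset(
        gene_ids=[str(g) for g in df.index],
        times=times,
        log2_matrix=df.to_numpy(dtype=float),
    )


def read_phenotype_series(path, dataset: ExpressionDataset | None = None, *,
                          sep: str = "\t") -> np.ndarray:
    """Read a (time, fraction) table; if *dataset* is given, align to its
    time grid (every dataset time point must be present)."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected two columns (time, fraction)")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    frac = df.iloc[:, 1].to_numpy(dtype=float)
    if dataset is None:
        return frac
    lookup = {t: f for t, f in zip(times, frac)}
    try:
        return np.array([lookup[t] for t in dataset.times])
    except KeyError as exc:
        raise DataValidationError(
            f"{path}: missing phenotype value for time point {exc.args[0]:g}"
        ) from None


def write_expression_matrix(dataset: ExpressionDataset, path, *, sep: str = "\t") -> None:
    df = pd.DataFrame(
        dataset.log2_matrix,
        index=pd.Index(dataset.gene_ids, name="gene"),
        columns=[f"{t:g}" for t in dataset.times],
    )
    df.to_csv(path, sep=sep)


def write_phenotype_series(dataset: ExpressionDataset, path, *, sep: str = "\t") -> None:
    if dataset.phenotype is None:
        raise DataValidationError("dataset has no phenotype track")
    pd.DataFrame({"time": dataset.times, "fraction_budding": dataset.phenotype}).to_csv(
        path, sep=sep, index=False
    )
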
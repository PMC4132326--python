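"""Expression-matrix input/output, validation and per-gene standardization.

Matrices are delimited text: row 1 holds sample ids, column 1 holds gene
ids, the body is numeric expression with a configurable missing token
(default ``NA``). Genes are rows, samples are columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKEN = "NA"
DEFAULT_MIN_SAMPLES = 20

_SEPARATORS = {"tsv": "\t", "csv": ","}


@dataclass
class ExpressionMatrix:
    """Genes × samples real-valued expression table.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``; missing measurements are NaN.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValidationError(f"duplicate {name} id {i!r}")
                seen.add(i)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(gene) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ValidationReport:
    n_genes: int
    n_samples: int
    n_missing: int
    warnings: list[str] = field(default_factory=list)


def load_matrix(
    path,
    dialect: str = "tsv",
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> ExpressionMatrix:
    """Read a genes × samples matrix from delimited text.

    Non-numeric body cells that are not ``missing_token`` raise
    :class:`ParseError`; duplicated ids raise :class:`ValidationError`.
    """
    sep = _dialect_sep(dialect)
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str,
                         keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: header row defines no sample columns")

    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dupes:
            raise ValidationError(f"duplicate {name} id {dupes[0]!r} in {path}")

    raw = df.to_numpy(dtype=object)
    flat = np.array([str(c).strip() for c in raw.ravel()], dtype=object)
    missing = flat == missing_token
    numeric = pd.to_numeric(pd.Series(flat), errors="coerce").to_numpy()
    bad = np.isnan(numeric) & ~missing & (flat != "nan")
    if bad.any():
        i = int(np.argmax(bad))
        r, c = divmod(i, len(sample_ids))
        raise ParseError(
            f"{path}: non-numeric cell {flat[i]!r} at gene {gene_ids[r]!r}, "
            f"sample {sample_ids[c]!r} (missing token is {missing_token!r})"
        )
    values = numeric.reshape(raw.shape)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def save_matrix(
    m: ExpressionMatrix,
    path,
    dialect: str = "tsv",
    missing_token: str = DEFAULT_MISSING_TOKEN,
    float_format: str = "%.12g",
) -> None:
    """Write a matrix in the same layout :func:`load_matrix` reads."""
    sep = _dialect_sep(dialect)
    m.to_frame().to_csv(path, sep=sep, na_rep=missing_token, float_format=float_format)


def validate(m: ExpressionMatrix, min_samples: int = DEFAULT_MIN_SAMPLES) -> ValidationReport:
    """Report matrix shape, missing values and analysis-readiness warnings."""
    warnings: list[str] = []
    n_missing = int(np.isnan(m.values).sum())
    if m.n_samples < min_samples:
        warnings.append(
            f"low sample count: {m.n_samples} samples < recommended minimum "
            f"{min_samples}; curve fits will be unreliable"
        )
    with np.errstate(all="ignore"):
        stds = np.nanstd(m.values, axis=1)
    constant = [g for g, s in zip(m.gene_ids, stds) if not np.isfinite(s) or s == 0.0]
    if constant:
        warnings.append(
            f"{len(constant)} constant or empty gene row(s) will be excluded: "
            + ", ".join(constant[:10])
        )
    if not np.isfinite(m.values[~np.isnan(m.values)]).all():
        warnings.append("matrix contains non-finite values other than missing cells")
    return ValidationReport(m.n_genes, m.n_samples, n_missing, warnings)


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (mean 0, unit sample variance, ddof=1).

    Zero-variance rows are dropped with a logged warning; missing cells stay
    missing. Idempotent up to floating-point round-off.
    """
    with np.errstate(all="ignore"):
        means = np.nanmean(m.values, axis=1, keepdims=True)
        stds = np.nanstd(m.values, axis=1, ddof=1, keepdims=True)
    keep = np.isfinite(stds[:, 0]) & (stds[:, 0] > 0)
    if not keep.any():
        raise ValidationError("no analysable genes: every row is constant or empty")
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    if dropped:
        logger.warning("excluding %d zero-variance gene(s): %s",
                       len(dropped), ", ".join(dropped[:10]))
    z = (m.values[keep] - means[keep]) / stds[keep]
    return ExpressionMatrix([g for g, k in zip(m.gene_ids, keep) if k],
                            list(m.sample_ids), z)


def _dialect_sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ParameterErrorDialect(dialect) from None


class ParameterErrorDialect(ParseError):
    def __init__(self, dialect: str):
        super().__init__(f"unknown dialect {dialect!r}; expected one of {sorted(_SEPARATORS)}")
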
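"""Readers and writers for the tabular formats consumed by the pipeline.

All genomic coordinates are held internally as 1-based inclusive intervals,
matching the convention of GWAS summary statistics. BED input (0-based,
half-open) is converted on read. Chromosome labels are normalized (leading
``chr`` stripped, case-folded) before any comparison, because annotation and
summary-statistic files routinely disagree on the dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "SnpAssociation",
    "GeneAnnotation",
    "RawExpressionTable",
    "normalize_chrom",
    "read_snp_associations",
    "read_gene_annotation",
    "read_expression_matrix",
    "write_expression_matrix",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(ValueError):
    """Parsed values violate a documented invariant."""


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` and case-fold."""
    c = str(chrom).strip().lower()
    if c.startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP-QT association record from GWAS summary statistics."""

    snp_id: str
    chrom: str
    pos: int  # 1-based base-pair position
    qt_id: str
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"p-value for {self.snp_id}/{self.qt_id} must be in (0, 1], "
                f"got {self.p_value!r}"
            )
        if self.pos < 1:
            raise ValidationError(
                f"position for {self.snp_id} must be >= 1, got {self.pos}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus as a 1-based inclusive interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start must be >= 1")


@dataclass
class RawExpressionTable:
    """A labelled numeric matrix straight off disk.

    ``row_kind`` / ``col_kind`` record whether rows are probes or genes and
    whether columns are tissue samples or ROIs; probe rows and sample columns
    may carry duplicate labels (they are merged later), gene rows and ROI
    columns may not.
    """

    frame: pd.DataFrame
    row_kind: str = "gene"  # {"probe", "gene"}
    col_kind: str = "roi"  # {"sample", "roi"}

    def __post_init__(self) -> None:
        if self.row_kind not in ("probe", "gene"):
            raise ValidationError(f"unknown row_kind {self.row_kind!r}")
        if self.col_kind not in ("sample", "roi"):
            raise ValidationError(f"unknown col_kind {self.col_kind!r}")
        if self.row_kind == "gene" and self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene row ids: {list(dupes)[:5]}")
        if self.col_kind == "roi" and self.frame.columns.has_duplicates:
            dupes = self.frame.columns[self.frame.columns.duplicated()].unique()
            raise ValidationError(f"duplicate ROI column ids: {list(dupes)[:5]}")
        if not np.all(np.isfinite(self.frame.to_numpy(dtype=float))):
            raise ValidationError("expression values must all be finite")

    @property
    def row_ids(self) -> list[str]:
        return [str(r) for r in self.frame.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


_LONG_COLUMNS = ("SNP", "CHR", "BP", "QT", "P")


def _parse_snp_rows(
    df: pd.DataFrame, qt_from: str | None, source: str
) -> tuple[list[SnpAssociation], int]:
    """Turn a string-typed frame with SNP/CHR/BP/P (+QT) columns into records."""
    records: list[SnpAssociation] = []
    n_skipped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        p_raw = str(getattr(row, "P")).strip()
        if p_raw in ("", "NA", "NaN", "nan", "."):
            n_skipped += 1
            continue
        try:
            p = float(p_raw)
        except ValueError as exc:
            raise ParseError(f"{source}, line {idx}: unparseable p-value {p_raw!r}") from exc
        if np.isnan(p):
            n_skipped += 1
            continue
        try:
            pos = int(str(getattr(row, "BP")).strip())
        except ValueError as exc:
            raise ParseError(
                f"{source}, line {idx}: unparseable position {getattr(row, 'BP')!r}"
            ) from exc
        qt = qt_from if qt_from is not None else str(getattr(row, "QT")).strip()
        records.append(
            SnpAssociation(
                snp_id=str(getattr(row, "SNP")).strip(),
                chrom=str(getattr(row, "CHR")).strip(),
                pos=pos,
                qt_id=qt,
                p_value=p,
            )
        )
    return records, n_skipped


def read_snp_associations(
    path: str | Path | Sequence[str | Path],
    dialect: str = "long_tsv",
) -> list[SnpAssociation]:
    """Read SNP-level GWAS summary statistics.

    Parameters
    ----------
    path
        For ``long_tsv``: one tab-separated file with header columns
        SNP, CHR, BP, QT, P. For ``per_qt_qassoc``: a whitespace-delimited
        PLINK-qassoc-like file (or a directory / list of them), with header
        columns including CHR, SNP, BP and P; the QT id is the file name stem.
    dialect
        ``"long_tsv"`` or ``"per_qt_qassoc"``.

    Rows with a missing/NA p-value are skipped; the skip count is logged.
    Duplicate (SNP, QT) keys raise :class:`ValidationError`.
    """
    if dialect == "long_tsv":
        path = Path(path)  # type: ignore[arg-type]
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        records, n_skipped = _parse_snp_rows(df[list(_LONG_COLUMNS)], None, str(path))
    elif dialect == "per_qt_qassoc":
        if isinstance(path, (str, Path)):
            p = Path(path)
            files = sorted(p.iterdir()) if p.is_dir() else [p]
        else:
            files = [Path(f) for f in path]
        records = []
        n_skipped = 0
        for f in files:
            df = pd.read_csv(f, sep=r"\s+", dtype=str)
            missing = [c for c in ("CHR", "SNP", "BP", "P") if c not in df.columns]
            if missing:
                raise ParseError(f"{f}: missing required columns {missing}")
            recs, skipped = _parse_snp_rows(df, f.stem, str(f))
            records.extend(recs)
            n_skipped += skipped
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if n_skipped:
        logger.warning("skipped %d SNP rows with missing p-values", n_skipped)
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.snp_id, rec.qt_id)
        if key in seen:
            raise ValidationError(f"duplicate (SNP, QT) record {key}")
        seen.add(key)
    return records


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneAnnotation]:
    """Read gene annotation from 4-column BED or 1-based TSV (GENE CHR START END).

    BED coordinates (0-based, half-open) are converted to the internal 1-based
    inclusive convention: ``start_internal = start_bed + 1``,
    ``end_internal = end_bed``, so interval lengths are preserved.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if format == "bed":
                if len(fields) < 4:
                    raise ParseError(f"{path}, line {lineno}: expected 4 BED columns")
                chrom, start_s, end_s, gene_id = fields[:4]
                try:
                    start, end = int(start_s) + 1, int(end_s)
                except ValueError as exc:
                    raise ParseError(f"{path}, line {lineno}: bad coordinates") from exc
            elif format == "tsv_1based":
                if fields[0].upper() == "GENE":  # optional header
                    continue
                if len(fields) < 4:
                    raise ParseError(f"{path}, line {lineno}: expected 4 TSV columns")
                gene_id, chrom, start_s, end_s = fields[:4]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ParseError(f"{path}, line {lineno}: bad coordinates") from exc
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            genes.append(GeneAnnotation(gene_id=gene_id, chrom=chrom, start=start, end=end))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValidationError(f"duplicate gene ids in annotation: {dupes[:5]}")
    return genes


def read_expression_matrix(
    path: str | Path, row_kind: str = "gene", col_kind: str = "roi"
) -> RawExpressionTable:
    """Read a labelled expression TSV (first column row ids, header column ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        # float() parsing is correctly rounded, so written values read back exactly
        numeric = raw.astype(float)
    except ValueError:
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & raw.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        ) from None
    if numeric.isna().to_numpy().any():
        raise ParseError(f"{path}: missing expression values are not supported")
    return RawExpressionTable(frame=numeric, row_kind=row_kind, col_kind=col_kind)


def write_expression_matrix(table, path: str | Path) -> None:
    """Write a labelled matrix as TSV with enough digits for lossless round trips.

    Accepts a :class:`RawExpressionTable`, a pandas DataFrame, or any object
    with ``gene_ids`` / ``roi_ids`` / ``values`` attributes.
    """
    if isinstance(table, RawExpressionTable):
        frame = table.frame
    elif isinstance(table, pd.DataFrame):
        frame = table
    else:
        frame = pd.DataFrame(table.values, index=table.gene_ids, columns=table.roi_ids)
    frame.to_csv(path, sep="\t", float_format="%.17g")


def iter_chrom_groups(snps: Iterable[SnpAssociation]):
    """Yield (normalized chromosome, records) groups, preserving input order."""
    groups: dict[str, list[SnpAssociation]] = {}
    for s in snps:
        groups.setdefault(normalize_chrom(s.chrom), []).append(s)
    yield from groups.items()
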
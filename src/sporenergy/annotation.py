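"""Reading and normalizing gene, abundance, and time-series inputs.

Implements the data-handling rules the cost ledgers depend on: identifier
token normalization, median imputation of missing lengths, mass-conserving
even splitting of multi-mapped abundances with a small ppm floor,
renormalization of ppm to absolute copies per cell, and conversion of
expression time series and cumulative revival scores into per-gene
probability weight vectors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import TOTAL_PROTEINS_PER_CELL

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "AbundanceRecord",
    "ExpressionWeights",
    "RevivalIntervalScores",
    "SPORULATION_HOURS",
    "REVIVAL_HOURS",
    "REVIVAL_EXCLUDED",
    "normalize_token",
    "load_gene_table",
    "write_gene_table",
    "impute_missing_lengths",
    "map_abundances",
    "ppm_to_copies",
    "parse_expression_heatmap",
    "parse_revival_scores",
]

#: Sporulation expression time bins (hours after initiation).
SPORULATION_HOURS: tuple[str, ...] = tuple(f"t{i}" for i in range(9))

#: Revival cumulative-score columns retained for costing (hours).
REVIVAL_HOURS: tuple[str, ...] = ("H0.25", "H0.5", "H1", "H1.5", "H2.5", "H3.5")

#: Revival column parsed but excluded from costing (overlaps vegetative growth).
REVIVAL_EXCLUDED = "H5.5"

_TOKEN_RE = re.compile(r"[^a-z0-9]+")
PPM_FLOOR = 0.1


def normalize_token(token) -> str:
    """Case-fold an identifier and strip characters outside [a-z0-9]."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return ""
    return _TOKEN_RE.sub("", str(token).strip().lower())


@dataclass
class GeneRecord:
    """One annotated gene: identifiers, lengths, trait tags, compartment."""

    locus_tag: str
    symbol: str = ""
    gene_length: float | None = None      # bp
    protein_length: float | None = None   # aa
    category_tags: frozenset[str] = field(default_factory=frozenset)
    compartment: str = "unassigned"       # mother | forespore | unassigned


@dataclass
class AbundanceRecord:
    """Protein abundance: relative (ppm) and absolute (copies per cell)."""

    locus_tag: str
    ppm: float
    copies: float = 0.0


@dataclass
class ExpressionWeights:
    """Per-gene temporal weight vector over ordered time bins.

    Weights are nonnegative and sum to 1; the first nonzero weight marks
    the interval where one-time transcript synthesis is charged.
    """

    locus_tag: str
    intervals: tuple[str, ...]
    weights: np.ndarray

    def first_nonzero(self) -> int:
        idx = np.flatnonzero(self.weights)
        if idx.size == 0:
            raise ValueError(f"{self.locus_tag}: all-zero weight vector")
        return int(idx[0])


@dataclass
class RevivalIntervalScores:
    """Interval weights derived from cumulative newly-synthesized scores."""

    locus_tag: str
    intervals: tuple[str, ...]
    weights: np.ndarray
    clamped: int = 0   # number of negative successive differences clamped to 0


def _detect_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [normalize_token(c) for c in df.columns]
    return df


def load_gene_table(
    path,
    dialect: str | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Read a delimited gene table into :class:`GeneRecord` objects.

    The delimiter is auto-detected (tab vs comma) unless ``dialect`` is
    ``"tsv"`` or ``"csv"``.  Identifier tokens are case-folded and
    stripped of non-alphanumerics.  Rows carrying only a symbol are mapped
    to locus tags through ``synonym_map`` (normalized token -> locus tag);
    rows with neither identifier are rejected with a logged count.
    Duplicate locus tags raise an error naming the duplicates.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str)
    df = _detect_columns(df)
    if "locustag" not in df.columns and "symbol" not in df.columns:
        raise ValueError(f"{path}: header must contain locus_tag or symbol")

    synonym_map = {normalize_token(k): v for k, v in (synonym_map or {}).items()}
    records: list[GeneRecord] = []
    rejected = 0
    for _, row in df.iterrows():
        locus = normalize_token(row.get("locustag"))
        symbol = normalize_token(row.get("symbol"))
        if not locus and symbol:
            locus = normalize_token(synonym_map.get(symbol, ""))
        if not locus:
            rejected += 1
            continue
        tags = frozenset(
            t for t in normalize_and_split(row.get("categorytags")) if t
        )
        records.append(GeneRecord(
            locus_tag=locus,
            symbol=symbol,
            gene_length=_to_float(row.get("genelength")),
            protein_length=_to_float(row.get("proteinlength")),
            category_tags=tags,
            compartment=(normalize_token(row.get("compartment")) or "unassigned"),
        ))
    if rejected:
        logger.info("rejected %d rows with no usable identifier", rejected)

    seen: dict[str, int] = {}
    dupes = []
    for rec in records:
        seen[rec.locus_tag] = seen.get(rec.locus_tag, 0) + 1
    dupes = sorted(tag for tag, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate locus tags: {dupes}")
    return records


def normalize_and_split(raw) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    return [normalize_token(part) for part in re.split(r"[;,|]", str(raw))]


def _to_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in {"na", "nan", ""}:
        return None
    return float(text)


def write_gene_table(records: Sequence[GeneRecord], path) -> None:
    """Write records as TSV with the normalized fixed column order."""
    df = pd.DataFrame({
        "locus_tag": [r.locus_tag for r in records],
        "symbol": [r.symbol for r in records],
        "gene_length": [r.gene_length for r in records],
        "protein_length": [r.protein_length for r in records],
        "category_tags": [";".join(sorted(r.category_tags)) for r in records],
        "compartment": [r.compartment for r in records],
    })
    df.to_csv(path, sep="\t", index=False)


def impute_missing_lengths(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Replace missing gene/protein lengths with the dataset median.

    Idempotent: a table without missing values is returned unchanged.
    Raises if a length field is missing everywhere (no median exists).
    """
    out = []
    for name in ("gene_length", "protein_length"):
        values = [getattr(r, name) for r in records if getattr(r, name) is not None]
        if not values:
            raise ValueError(f"all records missing {name}; cannot impute")
    gene_median = float(np.median([r.gene_length for r in records
                                   if r.gene_length is not None]))
    prot_median = float(np.median([r.protein_length for r in records
                                   if r.protein_length is not None]))
    imputed = 0
    for rec in records:
        gl, pl = rec.gene_length, rec.protein_length
        if gl is None or pl is None:
            imputed += 1
            rec = replace(rec,
                          gene_length=gl if gl is not None else gene_median,
                          protein_length=pl if pl is not None else prot_median)
        out.append(rec)
    if imputed:
        logger.info("imputed lengths for %d records (medians %.1f bp / %.1f aa)",
                    imputed, gene_median, prot_median)
    return out


def map_abundances(
    abundance_rows: Iterable[tuple],
    symbol_map: Mapping[str, Sequence[str] | str],
    proteome: Sequence[str] | None = None,
    *,
    floor: float = PPM_FLOOR,
) -> list[AbundanceRecord]:
    """Map raw (identifier, ppm) rows onto locus tags.

    A row whose token resolves to k locus tags contributes ppm/k to each
    (mass-conserving even split).  Proteome members (``proteome`` locus
    tags) with no matched row receive the small ppm floor *after*
    splitting, before any renormalization.  Total ppm is conserved across
    the split (asserted pre-floor).
    """
    norm_map: dict[str, list[str]] = {}
    for key, tags in symbol_map.items():
        if isinstance(tags, str):
            tags = [tags]
        norm_map[normalize_token(key)] = [normalize_token(t) for t in tags]
    proteome_set = {normalize_token(t) for t in (proteome or ())}

    ppm_by_tag: dict[str, float] = {}
    total_in = 0.0
    mapped_total = 0.0
    mapped_rows = 0
    for identifier, ppm in abundance_rows:
        ppm = float(ppm)
        if ppm < 0:
            raise ValueError(f"{identifier!r}: ppm must be >= 0, got {ppm!r}")
        token = normalize_token(identifier)
        # exact locus-tag matches take precedence over synonym-map hits
        tags = [token] if token in proteome_set else norm_map.get(token)
        total_in += ppm
        if not tags:
            continue
        mapped_rows += 1
        mapped_total += ppm
        share = ppm / len(tags)
        for tag in tags:
            ppm_by_tag[tag] = ppm_by_tag.get(tag, 0.0) + share
    if mapped_rows == 0:
        raise ValueError("no abundance rows could be mapped to locus tags")
    # even splitting is mass-conserving: assert before the floor is applied
    split_total = sum(ppm_by_tag.values())
    assert abs(split_total - mapped_total) <= 1e-9 * max(mapped_total, 1.0)

    floored = 0
    for tag in sorted(proteome_set):
        if tag not in ppm_by_tag:
            ppm_by_tag[tag] = floor
            floored += 1
    if floored:
        logger.info("applied %.2g ppm floor to %d unmatched proteome members",
                    floor, floored)
    return [AbundanceRecord(tag, ppm) for tag, ppm in sorted(ppm_by_tag.items())]


def ppm_to_copies(
    records: Sequence[AbundanceRecord],
    total_proteins: float = TOTAL_PROTEINS_PER_CELL,
) -> list[AbundanceRecord]:
    """Renormalize ppm to absolute copies per cell.

    ``copies_j = ppm_j / sum(ppm) * total_proteins``; the copies sum to
    ``total_proteins`` exactly (up to floating summation).
    """
    if total_proteins <= 0:
        raise ValueError(f"total_proteins must be > 0, got {total_proteins!r}")
    total_ppm = sum(r.ppm for r in records)
    if total_ppm <= 0:
        raise ValueError("sum of ppm must be > 0")
    return [replace(r, copies=r.ppm / total_ppm * total_proteins) for r in records]


def parse_expression_heatmap(
    rows: pd.DataFrame | Iterable[tuple],
    intervals: Sequence[str] = SPORULATION_HOURS,
    *,
    tol: float = 1e-9,
) -> list[ExpressionWeights]:
    """Convert long-format (locus_tag, time, expression) rows into weights.

    Per-gene weights are proportional to expression and normalized to 1;
    genes with all-zero expression are dropped with a log entry.  Negative
    expression is an input error.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows), columns=["locus_tag", "time", "expression"])
    df = rows.copy()
    df.columns = [normalize_token(c) for c in df.columns]
    df["locustag"] = df["locustag"].map(normalize_token)
    if (df["expression"].astype(float) < 0).any():
        bad = df.loc[df["expression"].astype(float) < 0, "locustag"].iloc[0]
        raise ValueError(f"negative expression for gene {bad!r}")
    wide = df.pivot_table(index="locustag", columns="time",
                          values="expression", aggfunc="sum", fill_value=0.0)
    wide = wide.reindex(columns=list(intervals), fill_value=0.0)

    out: list[ExpressionWeights] = []
    dropped = 0
    for locus, row in wide.iterrows():
        values = row.to_numpy(dtype=float)
        total = values.sum()
        if total <= 0:
            dropped += 1
            continue
        weights = values / total
        assert abs(weights.sum() - 1.0) <= tol
        out.append(ExpressionWeights(str(locus), tuple(intervals), weights))
    if dropped:
        logger.info("dropped %d genes with all-zero expression", dropped)
    return out


def parse_revival_scores(
    table: pd.DataFrame,
    *,
    intervals: Sequence[str] = REVIVAL_HOURS,
) -> list[RevivalIntervalScores]:
    """Convert cumulative newly-synthesized-protein scores to interval weights.

    Interval scores are successive differences of the cumulative columns
    (the first interval equals the first column).  The late column that
    overlaps resumed vegetative growth is parsed but excluded from
    costing.  Negative differences (measurement dips) are clamped to 0
    before normalization; clamp events are counted per gene and logged.
    """
    df = table.copy()
    rename = {c: normalize_token(c) for c in df.columns}
    df.columns = list(rename.values())
    wanted = [normalize_token(c) for c in intervals]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"revival table missing cumulative columns: {missing}")
    order = [df.columns.get_loc(c) for c in wanted]
    if order != sorted(order):
        raise ValueError("revival cumulative columns out of chronological order")
    excluded = normalize_token(REVIVAL_EXCLUDED)
    if excluded in df.columns:
        logger.info("column %s parsed but excluded from costing", REVIVAL_EXCLUDED)

    out: list[RevivalIntervalScores] = []
    total_clamped = 0
    for _, row in df.iterrows():
        locus = normalize_token(row.get("locustag"))
        cumulative = row[wanted].to_numpy(dtype=float)
        diffs = np.diff(cumulative, prepend=0.0)
        clamped = int((diffs < 0).sum())
        total_clamped += clamped
        diffs = np.clip(diffs, 0.0, None)
        total = diffs.sum()
        weights = diffs / total if total > 0 else diffs
        out.append(RevivalIntervalScores(locus, tuple(intervals), weights, clamped))
    if total_clamped:
        logger.info("clamped %d negative revival score differences", total_clamped)
    return out
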
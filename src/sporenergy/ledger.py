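"""Time-resolved ATP cost ledgers for sporulation and spore revival.

A :class:`TemporalLedger` books direct (PD) and opportunity (PO) costs
per (interval, category) cell, categories being genome replication,
one-time transcript synthesis, time-resolved transcription
polymerization, translation, septum, and (for revival) membrane
remodeling.  The module also provides compartment attribution,
per-generation head-to-head trait comparison against the cellular
budget, and the break-even time of the sporulation investment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    REVIVAL_HOURS,
    SPORULATION_HOURS,
    AbundanceRecord,
    ExpressionWeights,
    GeneRecord,
    RevivalIntervalScores,
)
from .constants import (
    GENOME_LENGTH_BP,
    PROTEINS_PER_MRNA,
    BudgetConstants,
    LipidCosts,
    MembraneGeometry,
    ReplicationConstants,
    RevivalMembraneParams,
    TranscriptionConstants,
    TranslationConstants,
)
from .costs import (
    CostPair,
    membrane_cost,
    protein_unit_costs,
    replication_cost,
    revival_membrane_cost,
    septum_cost,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "TemporalLedger",
    "TraitDefinition",
    "build_sporulation_ledger",
    "build_revival_ledger",
    "compartment_split",
    "head_to_head",
    "break_even",
    "cumulative_fraction",
]

CATEGORIES = (
    "replication",
    "transcription_synthesis",
    "transcription_polymerization",
    "translation",
    "membrane",
    "septum",
)

#: Revival interval boundaries in hours (germination 0–0.25, then outgrowth).
_REVIVAL_EDGES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.5, 3.5)


@dataclass
class TemporalLedger:
    """Per-interval, per-category PD/PO/PT cost table for one program.

    ``table`` has one row per (interval, category) with columns
    interval, interval_start_h, interval_end_h, category, direct,
    opportunity, total.  ``per_gene`` carries each costed gene's summed
    expression cost (transcription + translation) for compartment
    attribution; genome-level categories (replication, septum, membrane)
    are not gene-attributable.
    """

    table: pd.DataFrame
    program: str
    duration_h: float
    intervals: tuple[str, ...]
    per_gene: pd.DataFrame | None = None

    def grand_total(self) -> CostPair:
        return CostPair(float(self.table["direct"].sum()),
                        float(self.table["opportunity"].sum()))

    def category_totals(self) -> pd.DataFrame:
        out = (self.table.groupby("category")[["direct", "opportunity", "total"]]
               .sum().reindex([c for c in CATEGORIES
                               if c in set(self.table["category"])]))
        return out

    def interval_totals(self) -> pd.DataFrame:
        return (self.table.groupby("interval", sort=False)
                [["direct", "opportunity", "total"]]
                .sum().reindex(list(self.intervals), fill_value=0.0))

    def summary(self) -> dict:
        total = self.grand_total()
        cats = self.category_totals()
        return {
            "program": self.program,
            "duration_h": self.duration_h,
            "direct": total.direct,
            "opportunity": total.opportunity,
            "total": total.total,
            "category_percent": {
                cat: 100.0 * row["total"] / total.total if total.total else 0.0
                for cat, row in cats.iterrows()
            },
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class TraitDefinition:
    """A named trait or developmental program for head-to-head comparison."""

    name: str
    genes: frozenset[str]
    duration_h: float | None = None
    normalization: str = "per_generation_resynthesis"  # or per_program_duration

    def __post_init__(self) -> None:
        if self.normalization not in ("per_program_duration",
                                      "per_generation_resynthesis"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "per_program_duration" and not (
                self.duration_h and self.duration_h > 0):
            raise ValueError(f"trait {self.name!r}: duration_h must be > 0 "
                             "for per_program_duration normalization")


class _LedgerBuilder:
    """Accumulates (interval, category) cells and per-gene totals."""

    def __init__(self, intervals: Sequence[str], edges: Sequence[float]) -> None:
        self.intervals = tuple(intervals)
        self.edges = tuple(edges)
        self.direct = np.zeros((len(self.intervals), len(CATEGORIES)))
        self.opportunity = np.zeros_like(self.direct)
        self.gene_direct: dict[str, float] = {}
        self.gene_opportunity: dict[str, float] = {}

    def add(self, interval: int, category: str, direct: float, opportunity: float,
            gene: str | None = None) -> None:
        j = CATEGORIES.index(category)
        self.direct[interval, j] += direct
        self.opportunity[interval, j] += opportunity
        if gene is not None:
            self.gene_direct[gene] = self.gene_direct.get(gene, 0.0) + direct
            self.gene_opportunity[gene] = self.gene_opportunity.get(gene, 0.0) + opportunity

    def build(self, program: str, duration_h: float) -> TemporalLedger:
        rows = []
        for i, label in enumerate(self.intervals):
            for j, cat in enumerate(CATEGORIES):
                d, o = self.direct[i, j], self.opportunity[i, j]
                if d == 0.0 and o == 0.0:
                    continue
                rows.append({
                    "interval": label,
                    "interval_start_h": self.edges[i],
                    "interval_end_h": self.edges[i + 1],
                    "category": cat,
                    "direct": d,
                    "opportunity": o,
                    "total": d + o,
                })
        table = pd.DataFrame(rows, columns=[
            "interval", "interval_start_h", "interval_end_h", "category",
            "direct", "opportunity", "total"])
        genes = sorted(self.gene_direct)
        per_gene = pd.DataFrame({
            "locus_tag": genes,
            "direct": [self.gene_direct[g] for g in genes],
            "opportunity": [self.gene_opportunity[g] for g in genes],
        })
        per_gene["total"] = per_gene["direct"] + per_gene["opportunity"]
        return TemporalLedger(table=table, program=program, duration_h=duration_h,
                              intervals=self.intervals, per_gene=per_gene)


def _resolve_unit_costs(
    gene: GeneRecord,
    protein_costs: Mapping[str, tuple[float, float]] | None,
    translation: TranslationConstants,
) -> tuple[float, float]:
    if protein_costs is not None and gene.locus_tag in protein_costs:
        return protein_costs[gene.locus_tag]
    if gene.protein_length is None:
        raise ValueError(f"gene {gene.locus_tag}: no protein length or unit cost")
    return protein_unit_costs(None, length=gene.protein_length,
                              constants=translation)


def _expression_costs(
    builder: _LedgerBuilder,
    genes: Sequence[GeneRecord],
    abundances: Mapping[str, AbundanceRecord] | Sequence[AbundanceRecord],
    weight_vectors: Mapping[str, np.ndarray],
    transcription: TranscriptionConstants,
    translation: TranslationConstants,
    protein_costs: Mapping[str, tuple[float, float]] | None,
    yield_per_mrna: float,
    total_proteins: float,
) -> None:
    """Book per-gene transcription and translation costs into the builder."""
    if not isinstance(abundances, Mapping):
        abundances = {a.locus_tag: a for a in abundances}
    poly_rate = transcription.elongation + transcription.supercoil_overhead
    for gene in sorted(genes, key=lambda g: g.locus_tag):
        ab = abundances.get(gene.locus_tag)
        if ab is None or ab.copies <= 0:
            continue
        if gene.locus_tag not in weight_vectors:
            raise ValueError(f"no temporal weights for costed gene {gene.locus_tag!r}")
        weights = np.asarray(weight_vectors[gene.locus_tag], dtype=float)
        if gene.gene_length is None:
            raise ValueError(f"gene {gene.locus_tag}: missing gene length")
        length_nt = float(gene.gene_length)
        n_mrna = ab.copies / yield_per_mrna
        first = int(np.flatnonzero(weights)[0])

        # one-time nucleotide synthesis (direct) + precursor opportunity,
        # both charged at the first interval the gene is expressed
        nt = length_nt * n_mrna
        builder.add(first, "transcription_synthesis",
                    transcription.nt_synthesis_direct * nt,
                    transcription.nt_opportunity * nt, gene.locus_tag)
        # polymerization paid whenever transcripts are made
        unit_d, unit_o = _resolve_unit_costs(gene, protein_costs, translation)
        for i, w in enumerate(weights):
            if w == 0.0:
                continue
            builder.add(i, "transcription_polymerization",
                        poly_rate * nt * w, 0.0, gene.locus_tag)
            builder.add(i, "translation",
                        unit_d * ab.copies * w, unit_o * ab.copies * w,
                        gene.locus_tag)


def build_sporulation_ledger(
    genes: Sequence[GeneRecord],
    abundances: Sequence[AbundanceRecord] | Mapping[str, AbundanceRecord],
    weights: Sequence[ExpressionWeights],
    *,
    genome_length_bp: float = GENOME_LENGTH_BP,
    replication: ReplicationConstants = ReplicationConstants(),
    transcription: TranscriptionConstants = TranscriptionConstants(),
    translation: TranslationConstants = TranslationConstants(),
    septum_geometry: MembraneGeometry = MembraneGeometry(),
    lipid: LipidCosts = LipidCosts(),
    protein_costs: Mapping[str, tuple[float, float]] | None = None,
    yield_per_mrna: float = PROTEINS_PER_MRNA,
    total_proteins: float = 0.0,
    duration_h: float = 11.5,
) -> TemporalLedger:
    """Assemble the hour-resolved sporulation cost ledger.

    Full-genome replication is charged within the first hour bin (it is
    incurred early, before the ~2 h commitment point); the septum is
    charged in the second bin (septation follows initiation).  One-time
    transcript synthesis is booked at each gene's first nonzero expression
    hour; polymerization and translation are distributed across hours by
    the expression weights.
    """
    edges = tuple(float(i) for i in range(len(SPORULATION_HOURS) + 1))
    builder = _LedgerBuilder(SPORULATION_HOURS, edges)

    rep = replication_cost(genome_length_bp, replication)
    builder.add(0, "replication", rep.direct, rep.opportunity)
    _, sept = septum_cost(septum_geometry.diameter, septum_geometry.headgroup_area,
                          septum_geometry.protein_occupancy, lipid)
    builder.add(1, "septum", sept.direct, sept.opportunity)

    weight_vectors = {w.locus_tag: w.weights for w in weights}
    _expression_costs(builder, genes, abundances, weight_vectors,
                      transcription, translation, protein_costs,
                      yield_per_mrna, total_proteins)
    return builder.build("sporulation", duration_h)


def build_revival_ledger(
    genes: Sequence[GeneRecord],
    abundances: Sequence[AbundanceRecord] | Mapping[str, AbundanceRecord],
    revival_scores: Sequence[RevivalIntervalScores],
    *,
    transcription: TranscriptionConstants = TranscriptionConstants(),
    translation: TranslationConstants = TranslationConstants(),
    membrane_geometry: MembraneGeometry = MembraneGeometry(),
    lipid: LipidCosts = LipidCosts(),
    membrane_params: RevivalMembraneParams = RevivalMembraneParams(),
    protein_costs: Mapping[str, tuple[float, float]] | None = None,
    yield_per_mrna: float = PROTEINS_PER_MRNA,
    duration_h: float = 3.75,
) -> TemporalLedger:
    """Assemble the revival (germination + outgrowth) cost ledger.

    Transcription and translation are distributed over the six revival
    intervals by each protein's normalized interval scores.  Net membrane
    remodeling cost is spread uniformly over the outgrowth intervals
    (second interval onward); with ``fraction_new = 0`` the membrane
    category is absent.
    """
    builder = _LedgerBuilder(REVIVAL_HOURS, _REVIVAL_EDGES)

    mem = revival_membrane_cost(membrane_cost(membrane_geometry, lipid)[1],
                                membrane_params)
    if mem.total > 0:
        outgrowth = range(1, len(REVIVAL_HOURS))
        for i in outgrowth:
            builder.add(i, "membrane", mem.direct / len(outgrowth),
                        mem.opportunity / len(outgrowth))

    weight_vectors = {s.locus_tag: s.weights for s in revival_scores
                      if s.weights.sum() > 0}
    costed = [g for g in genes if g.locus_tag in weight_vectors]
    _expression_costs(builder, costed, abundances, weight_vectors,
                      transcription, translation, protein_costs,
                      yield_per_mrna, 0.0)
    return builder.build("revival", duration_h)


def compartment_split(
    ledger: TemporalLedger,
    compartments: Mapping[str, str],
    *,
    default: str = "mother",
) -> tuple[float, float]:
    """Mother-cell vs forespore share of a ledger's grand total.

    Gene-attributable expression costs follow each gene's compartment
    label; genes without a label default to the mother cell, which bears
    most of the biosynthetic burden.  Genome replication, septum, and
    membrane costs are attributed to the mother cell.  Shares sum to 1.
    """
    total = ledger.grand_total().total
    if total <= 0:
        return (1.0, 0.0)
    fore = 0.0
    if ledger.per_gene is not None:
        for _, row in ledger.per_gene.iterrows():
            label = compartments.get(row["locus_tag"], default)
            if label == "forespore":
                fore += row["total"]
    mother_share = (total - fore) / total
    return (mother_share, 1.0 - mother_share)


def head_to_head(
    traits: Sequence[TraitDefinition],
    genes: Sequence[GeneRecord],
    abundances: Sequence[AbundanceRecord] | Mapping[str, AbundanceRecord],
    *,
    budget: BudgetConstants = BudgetConstants(),
    transcription: TranscriptionConstants = TranscriptionConstants(),
    translation: TranslationConstants = TranslationConstants(),
    protein_costs: Mapping[str, tuple[float, float]] | None = None,
    yield_per_mrna: float = PROTEINS_PER_MRNA,
) -> pd.DataFrame:
    """Per-generation build costs of traits relative to the cellular budget.

    Build cost = transcription + translation of the trait's proteins at
    steady-state abundance.  Developmental programs are normalized by
    program duration expressed in generations; other traits are charged as
    full per-generation resynthesis.  The final column expresses each
    per-generation cost as a percentage of the total budget.
    """
    if not isinstance(abundances, Mapping):
        abundances = {a.locus_tag: a for a in abundances}
    gene_by_tag = {g.locus_tag: g for g in genes}
    poly_rate = transcription.elongation + transcription.supercoil_overhead
    rows = []
    for trait in traits:
        direct = opportunity = 0.0
        resolved = 0
        for tag in sorted(trait.genes):
            gene = gene_by_tag.get(tag)
            ab = abundances.get(tag)
            if gene is None or ab is None or ab.copies <= 0:
                continue
            resolved += 1
            nt = float(gene.gene_length) * ab.copies / yield_per_mrna
            direct += (transcription.nt_synthesis_direct + poly_rate) * nt
            opportunity += transcription.nt_opportunity * nt
            unit_d, unit_o = _resolve_unit_costs(gene, protein_costs, translation)
            direct += unit_d * ab.copies
            opportunity += unit_o * ab.copies
        if resolved == 0:
            logger.warning("trait %r resolved no costed genes", trait.name)
        build = direct + opportunity
        if trait.normalization == "per_program_duration":
            generations = trait.duration_h / budget.generation_time
            per_generation = build / generations
        else:
            per_generation = build
        rows.append({
            "trait": trait.name,
            "n_genes": resolved,
            "build_direct": direct,
            "build_opportunity": opportunity,
            "build_total": build,
            "per_generation": per_generation,
            "percent_of_budget": 100.0 * per_generation / budget.total_budget,
        })
    return pd.DataFrame(rows)


def break_even(cycle_cost: float, maintenance_rate: float) -> float:
    """Hours of vegetative maintenance equal to the one-time spore-cycle cost.

    ``t* = cycle_cost / maintenance_rate``: beyond this time, a cell that
    sporulated has spent less ATP than one idling at maintenance power.
    """
    if cycle_cost <= 0:
        raise ValueError(f"cycle_cost must be > 0, got {cycle_cost!r}")
    if maintenance_rate <= 0:
        raise ValueError(f"maintenance_rate must be > 0, got {maintenance_rate!r}")
    return cycle_cost / maintenance_rate


def cumulative_fraction(
    ledger: TemporalLedger,
    through: str,
    categories: Iterable[str] | None = None,
) -> float:
    """Fraction of a ledger's total cost incurred through a given interval.

    Optionally restricted to a subset of categories (e.g. transcription +
    translation); the fraction is relative to that subset's own total.
    An empty category restriction yields 0.
    """
    if through not in ledger.intervals:
        raise ValueError(f"unknown interval {through!r}; ledger has {ledger.intervals}")
    table = ledger.table
    if categories is not None:
        categories = list(categories)
        table = table[table["category"].isin(categories)]
        if table.empty:
            return 0.0
    cutoff = ledger.intervals.index(through)
    mask = table["interval"].map(lambda s: ledger.intervals.index(s)) <= cutoff
    denom = table["total"].sum()
    return float(table.loc[mask, "total"].sum() / denom) if denom else 0.0
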
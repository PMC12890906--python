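"""Closed-form ATP cost primitives for the central dogma and membranes.

Every operation returns a :class:`CostPair` partitioning the expenditure
into direct costs (PD: activation, charging, polymerization) and
opportunity costs (PO: precursor value diverted from growth), with
``total = direct + opportunity`` exactly as floating sums.  Counts are
continuous expected values throughout; nothing is rounded mid-pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    AA_OPPORTUNITY_PO,
    UM2_TO_NM2,
    LipidCosts,
    MembraneGeometry,
    ReplicationConstants,
    RevivalMembraneParams,
    TranscriptionConstants,
    TranslationConstants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CostPair",
    "replication_cost",
    "replication_cost_share",
    "transcript_demand",
    "transcription_cost",
    "protein_unit_costs",
    "translation_cost",
    "membrane_cost",
    "septum_cost",
    "revival_membrane_cost",
]


@dataclass(frozen=True)
class CostPair:
    """A (direct, opportunity) ATP expenditure; ``total`` is their sum."""

    direct: float
    opportunity: float

    def __post_init__(self) -> None:
        if self.direct < 0 or self.opportunity < 0:
            raise ValueError(
                f"cost components must be >= 0, got ({self.direct!r}, {self.opportunity!r})"
            )

    @property
    def total(self) -> float:
        return self.direct + self.opportunity

    def __add__(self, other: "CostPair") -> "CostPair":
        return CostPair(self.direct + other.direct, self.opportunity + other.opportunity)

    def scaled(self, factor: float) -> "CostPair":
        """Scale both components; costs are homogeneous degree 1 in counts."""
        if factor < 0:
            raise ValueError(f"scale factor must be >= 0, got {factor!r}")
        return CostPair(self.direct * factor, self.opportunity * factor)

    @classmethod
    def zero(cls) -> "CostPair":
        return cls(0.0, 0.0)


def replication_cost(
    genome_length_bp: float,
    constants: ReplicationConstants = ReplicationConstants(),
) -> CostPair:
    """ATP cost of duplicating ``genome_length_bp`` base pairs of DNA.

    Both daughter strands are newly synthesized (2 nucleotides per bp),
    paying synthesis + polymerization direct costs per nucleotide plus
    helicase unwinding and lagging-strand priming per bp; opportunity cost
    is the per-nucleotide precursor value on both strands.  Ligation and
    proofreading are below the accounting cutoff and omitted.
    """
    if genome_length_bp < 0:
        raise ValueError(f"genome_length_bp must be >= 0, got {genome_length_bp!r}")
    lg = float(genome_length_bp)
    direct = 2.0 * lg * (constants.nt_synthesis_direct + constants.polymerization) + lg * (
        constants.helicase + constants.primer
    )
    opportunity = 2.0 * lg * constants.nt_opportunity
    return CostPair(direct, opportunity)


def replication_cost_share(
    subset_bp: float,
    genome_length_bp: float,
    constants: ReplicationConstants = ReplicationConstants(),
) -> CostPair:
    """Replication cost attributable to a subset of the genome.

    Replication cost is linear in length, so the share is the full-genome
    cost scaled by ``subset_bp / genome_length_bp``.
    """
    if genome_length_bp <= 0:
        raise ValueError(f"genome_length_bp must be > 0, got {genome_length_bp!r}")
    if not 0 <= subset_bp <= genome_length_bp:
        raise ValueError(
            f"subset_bp must lie in [0, genome_length_bp], got {subset_bp!r} "
            f"with genome {genome_length_bp!r}"
        )
    return replication_cost(genome_length_bp, constants).scaled(subset_bp / genome_length_bp)


def transcript_demand(ppm: float, total_proteins: float, yield_per_mrna: float) -> float:
    """Expected transcript count needed to produce a protein's copy number.

    Copies = (ppm / 1e6) * total_proteins; each mRNA yields
    ``yield_per_mrna`` proteins over its lifetime.  Fractional counts are
    expected values and are kept continuous.
    """
    if ppm < 0:
        raise ValueError(f"ppm must be >= 0, got {ppm!r}")
    if yield_per_mrna <= 0:
        raise ValueError(f"yield_per_mrna must be > 0, got {yield_per_mrna!r}")
    return (ppm / 1.0e6) * total_proteins / yield_per_mrna


def transcription_cost(
    transcripts: Iterable[tuple],
    constants: TranscriptionConstants = TranscriptionConstants(),
    *,
    weight_tol: float = 1e-9,
) -> tuple[CostPair, np.ndarray]:
    """Total transcription cost and the per-interval polymerization series.

    Each record is ``(length_nt, count, weights)`` where ``weights`` is
    the temporal distribution of transcript production (sums to 1).
    Nucleotide synthesis is one-time (efficient recycling): charged once
    per transcript, booked at the record's first nonzero-weight interval
    by the ledger layer.  Polymerization (elongation + supercoil relief)
    is paid per transcript made and is distributed across intervals by the
    weights.  Returns the grand total and the per-interval *direct*
    polymerization cost series (whose sum equals the total polymerization
    direct cost).
    """
    records = list(transcripts)
    n_intervals = 0
    for idx, (length, count, weights) in enumerate(records):
        if length <= 0:
            raise ValueError(f"transcript record {idx}: length must be > 0, got {length!r}")
        if count < 0:
            raise ValueError(f"transcript record {idx}: count must be >= 0, got {count!r}")
        w = np.asarray(weights, dtype=float)
        if count > 0 and abs(w.sum() - 1.0) > weight_tol:
            raise ValueError(
                f"transcript record {idx}: weights sum to {w.sum()!r}, expected 1"
            )
        n_intervals = max(n_intervals, w.size)

    poly_series = np.zeros(n_intervals)
    synth_direct = 0.0
    opportunity = 0.0
    poly_rate = constants.elongation + constants.supercoil_overhead
    for length, count, weights in records:
        nt = float(length) * float(count)
        synth_direct += constants.nt_synthesis_direct * nt
        opportunity += constants.nt_opportunity * nt
        w = np.asarray(weights, dtype=float)
        poly_series[: w.size] += poly_rate * nt * w

    total = CostPair(synth_direct + float(poly_series.sum()), opportunity)
    return total, poly_series


def protein_unit_costs(
    sequence: str | None,
    aa_cost_table: Mapping[str, float] | None = None,
    constants: TranslationConstants = TranslationConstants(),
    *,
    length: float | None = None,
) -> tuple[float, float]:
    """Per-protein (direct, opportunity) unit costs.

    Direct cost is ``per_aa_direct * length + per_protein_direct`` (the
    flat term covers initiation/termination GTPs).  Opportunity cost sums
    per-residue values from the table; unknown residues and the
    no-sequence fallback use the bacterial mean.  Passing ``length``
    without a sequence selects the mean-based fallback; lengths stay
    continuous (imputed medians may be fractional).
    """
    if aa_cost_table is None:
        aa_cost_table = AA_OPPORTUNITY_PO
    if sequence is None:
        if length is None:
            raise ValueError("either sequence or length is required")
        n_aa = float(length)
        opportunity = constants.mean_aa_opportunity * n_aa
    else:
        seq = sequence.strip().upper()
        n_aa = len(seq)
        if n_aa == 0:
            logger.warning("zero-length protein sequence; charging per-protein cost only")
        unknown = sorted({aa for aa in seq if aa not in aa_cost_table})
        if unknown:
            logger.info(
                "nonstandard residues %s costed at the bacterial mean %.1f PO",
                "".join(unknown), constants.mean_aa_opportunity,
            )
        opportunity = sum(
            aa_cost_table.get(aa, constants.mean_aa_opportunity) for aa in seq
        )
    direct = constants.per_aa_direct * n_aa + constants.per_protein_direct
    return direct, opportunity


def translation_cost(proteins: Iterable[tuple]) -> CostPair:
    """Sum ``copies * unit cost`` over proteins.

    Records are ``(copies, unit_direct, unit_opportunity)``.  Degradation
    during the developmental window is slow relative to synthesis, so no
    turnover term appears.
    """
    direct = 0.0
    opportunity = 0.0
    for idx, (copies, unit_d, unit_o) in enumerate(proteins):
        if copies < 0:
            raise ValueError(f"protein record {idx}: copies must be >= 0, got {copies!r}")
        direct += copies * unit_d
        opportunity += copies * unit_o
    return CostPair(direct, opportunity)


def _lipid_bilayer_cost(area_um2: float, headgroup_area_nm2: float,
                        protein_occupancy: float, lipid: LipidCosts) -> tuple[float, CostPair]:
    n_lipid = area_um2 * UM2_TO_NM2 / headgroup_area_nm2 * (1.0 - protein_occupancy)
    return n_lipid, CostPair(
        lipid.per_lipid_direct * n_lipid, lipid.per_lipid_opportunity * n_lipid
    )


def membrane_cost(
    geometry: MembraneGeometry = MembraneGeometry(),
    lipid: LipidCosts = LipidCosts(),
) -> tuple[float, CostPair]:
    """Lipid count and ATP cost of the full vegetative membrane bilayer.

    The cell is a spherocylinder with semi-axes a = L/2, b = D/2; outer
    and inner leaflet areas are 4πab and 4π(a−h)(b−h), and the lipid count
    is the summed leaflet area over the headgroup area, discounted by the
    protein-occupied fraction.
    """
    a = geometry.length / 2.0
    b = geometry.diameter / 2.0
    h = geometry.bilayer_thickness
    if b <= h:
        raise ValueError(f"cell radius {b!r} µm must exceed bilayer thickness {h!r} µm")
    area = 4.0 * math.pi * a * b + 4.0 * math.pi * (a - h) * (b - h)
    return _lipid_bilayer_cost(area, geometry.headgroup_area,
                               geometry.protein_occupancy, lipid)


def septum_cost(
    diameter: float = 1.0,
    headgroup_area: float = 0.65,
    protein_occupancy: float = 0.5,
    lipid: LipidCosts = LipidCosts(),
) -> tuple[float, CostPair]:
    """Lipid count and ATP cost of the asymmetric sporulation septum.

    Modeled as a flat circular bilayer of radius b = diameter/2 with total
    bilayer area 2πb² (two leaflets; thickness effects negligible).
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter!r}")
    if not 0.0 <= protein_occupancy <= 1.0:
        raise ValueError("protein_occupancy must lie in [0, 1]")
    b = diameter / 2.0
    area = 2.0 * math.pi * b * b
    return _lipid_bilayer_cost(area, headgroup_area, protein_occupancy, lipid)


def revival_membrane_cost(
    full_membrane: CostPair,
    params: RevivalMembraneParams = RevivalMembraneParams(),
) -> CostPair:
    """Net membrane cost during outgrowth.

    Only ``fraction_new`` of the vegetative membrane is newly made and
    ``fraction_recycled`` of lipid cost is offset by reuse of spore
    membrane, so every component scales by
    ``fraction_new * (1 - fraction_recycled)`` (0.25 at defaults).
    """
    return full_membrane.scaled(params.fraction_new * (1.0 - params.fraction_recycled))
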
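"""Typed registries of bioenergetic unit costs and cell parameters.

All energetic quantities are expressed in ATP-equivalents ("P"): one
high-energy phosphate hydrolysis event, with GTP counted 1:1.  Direct
costs (PD) are hydrolysis events powering activation, charging and
polymerization; opportunity costs (PO) are the energetic value of
precursor molecules diverted away from growth.  Defaults are the 20 °C
values for *Bacillus subtilis*; every constant lives here so alternates
can be swapped in one place.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

__all__ = [
    "ReplicationConstants",
    "TranscriptionConstants",
    "TranslationConstants",
    "MembraneGeometry",
    "LipidCosts",
    "RevivalMembraneParams",
    "BudgetConstants",
    "AA_OPPORTUNITY_PO",
    "MEAN_AA_OPPORTUNITY_PO",
    "GENOME_LENGTH_BP",
    "TOTAL_PROTEINS_PER_CELL",
    "PROTEINS_PER_MRNA",
    "UM2_TO_NM2",
    "registry_to_json",
    "registry_from_json",
]

#: B. subtilis 168 reference genome length (bp, NC_000964.3).
GENOME_LENGTH_BP = 4_215_606

#: Total protein copies per vegetative cell used to convert ppm to copies.
TOTAL_PROTEINS_PER_CELL = 1_774_445.0

#: Representative protein yield per mRNA lifetime (proteins per transcript).
PROTEINS_PER_MRNA = 100.0

#: Unit conversion applied inside geometry operations, never by callers.
UM2_TO_NM2 = 1.0e6

#: Mean bacterial opportunity cost per amino acid (PO); the fallback when a
#: sequence or per-residue table is unavailable, and the value used for
#: nonstandard residues (X, B, Z, U, ...).
MEAN_AA_OPPORTUNITY_PO = 25.0

#: Per-residue biosynthetic opportunity costs (PO per amino acid) for a
#: heterotrophic bacterium growing on glucose, keyed by one-letter code.
AA_OPPORTUNITY_PO: dict[str, float] = {
    "A": 11.7, "R": 27.3, "N": 14.7, "D": 12.7, "C": 24.7,
    "E": 15.3, "Q": 16.3, "G": 11.7, "H": 38.3, "I": 32.3,
    "L": 27.3, "K": 30.3, "M": 34.3, "F": 52.0, "P": 20.3,
    "S": 11.7, "T": 18.7, "W": 74.3, "Y": 50.0, "V": 23.3,
}


def _require_nonnegative(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if value < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class ReplicationConstants:
    """Unit costs of duplicating the chromosome.

    ``nt_synthesis_direct`` and ``nt_opportunity`` are per DNA nucleotide
    (both strands are newly built, hence the factor two in the cost
    formula); helicase unwinding and lagging-strand priming are per bp of
    template.  Ligation and proofreading are below the accounting cutoff
    and carry no constant here.
    """

    nt_synthesis_direct: float = 11.0   # PD per nucleotide, synthesis w/o polymerization
    polymerization: float = 2.0         # PD per nucleotide
    helicase: float = 1.0               # PD per bp unwound
    primer: float = 0.32                # PD per bp, lagging-strand primers
    nt_opportunity: float = 34.0        # PO per nucleotide (precursors + conversion)

    def __post_init__(self) -> None:
        _require_nonnegative(self, *(f.name for f in fields(self)))


@dataclass(frozen=True)
class TranscriptionConstants:
    """Unit costs of making RNA.

    Nucleotide synthesis is charged once per transcript (efficient
    recycling); polymerization plus a small supercoil-relief overhead is
    paid every time a transcript is elongated.
    """

    nt_synthesis_direct: float = 10.0   # PD per RNA nucleotide, one-time
    nt_opportunity: float = 31.5        # PO per RNA nucleotide
    elongation: float = 2.0             # PD per nucleotide, RNA polymerase
    supercoil_overhead: float = 0.1     # PD per nucleotide, gyrase relief

    def __post_init__(self) -> None:
        _require_nonnegative(self, *(f.name for f in fields(self)))
        if not self.supercoil_overhead < self.elongation:
            raise ValueError(
                "supercoil_overhead must be a small fraction of elongation "
                f"({self.supercoil_overhead!r} >= {self.elongation!r})"
            )


@dataclass(frozen=True)
class TranslationConstants:
    """Unit costs of protein synthesis.

    4 PD per incorporated amino acid covers aminoacyl-tRNA charging and
    elongation; 2 PD per completed chain covers one GTP at initiation and
    one at termination/ribosome recycling.
    """

    per_aa_direct: float = 4.0
    per_protein_direct: float = 2.0
    mean_aa_opportunity: float = MEAN_AA_OPPORTUNITY_PO

    def __post_init__(self) -> None:
        _require_nonnegative(self, *(f.name for f in fields(self)))


@dataclass(frozen=True)
class MembraneGeometry:
    """Spherocylinder (cylinder + hemispherical caps) vegetative-cell envelope.

    Lengths in µm; headgroup area in nm² (the µm²→nm² conversion happens
    inside the cost operations).  ``protein_occupancy`` is the fraction of
    bilayer area occupied by protein rather than lipid.
    """

    length: float = 2.5            # µm, long axis L
    diameter: float = 1.0          # µm, D
    bilayer_thickness: float = 0.004   # µm (4 nm)
    headgroup_area: float = 0.65   # nm² per lipid
    protein_occupancy: float = 0.5

    def __post_init__(self) -> None:
        _require_nonnegative(self, *(f.name for f in fields(self)))
        if not 0.0 <= self.protein_occupancy <= 1.0:
            raise ValueError("protein_occupancy must lie in [0, 1]")
        if not self.length >= self.diameter:
            raise ValueError("spherocylinder requires length >= diameter")
        if not self.diameter > 2.0 * self.bilayer_thickness:
            raise ValueError("diameter must exceed twice the bilayer thickness")


@dataclass(frozen=True)
class LipidCosts:
    """ATP cost per membrane lipid molecule."""

    per_lipid_direct: float = 18.0
    per_lipid_opportunity: float = 212.0

    def __post_init__(self) -> None:
        _require_nonnegative(self, "per_lipid_direct", "per_lipid_opportunity")


@dataclass(frozen=True)
class RevivalMembraneParams:
    """Membrane remodeling during spore outgrowth.

    Only a fraction of the full vegetative membrane is newly synthesized,
    and a further fraction of the lipid cost is offset by recycling spore
    membrane; net scale factor is ``fraction_new * (1 - fraction_recycled)``
    (0.25 at defaults).
    """

    fraction_new: float = 0.30
    fraction_recycled: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("fraction_new", "fraction_recycled"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class BudgetConstants:
    """Per-generation cellular energy budget at 20 °C.

    ``total_budget`` = growth cost + generation_time * maintenance_rate;
    the constructor enforces this identity within ``rel_tol``.
    """

    growth_cost: float = 9.2608e10      # ATP per generation (CG)
    maintenance_rate: float = 1.2e9     # ATP per hour (CM)
    generation_time: float = 1.16       # h (tgen)
    total_budget: float = 9.4e10        # ATP per generation (Ctotal)
    rel_tol: float = 0.05

    def __post_init__(self) -> None:
        _require_nonnegative(self, "growth_cost", "maintenance_rate",
                             "generation_time", "total_budget")
        implied = self.growth_cost + self.generation_time * self.maintenance_rate
        if abs(implied - self.total_budget) > self.rel_tol * self.total_budget:
            raise ValueError(
                "total_budget inconsistent with growth_cost + tgen*maintenance_rate: "
                f"{self.total_budget!r} vs implied {implied!r}"
            )


_REGISTRY_TYPES = {
    "replication": ReplicationConstants,
    "transcription": TranscriptionConstants,
    "translation": TranslationConstants,
    "membrane_geometry": MembraneGeometry,
    "lipid": LipidCosts,
    "revival_membrane": RevivalMembraneParams,
    "budget": BudgetConstants,
}


def registry_to_json(path=None) -> str:
    """Serialize the default constants registry to JSON (all registries)."""
    payload = {key: asdict(cls()) for key, cls in _REGISTRY_TYPES.items()}
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def registry_from_json(source) -> dict:
    """Load a constants registry from a JSON string or file path.

    Missing sections or fields fall back to defaults; unknown sections
    raise ``ValueError``.
    """
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(text, encoding="utf-8") as fh:
                payload = json.load(fh)
    unknown = set(payload) - set(_REGISTRY_TYPES)
    if unknown:
        raise ValueError(f"unknown registry sections: {sorted(unknown)}")
    return {key: _REGISTRY_TYPES[key](**payload.get(key, {}))
            for key in _REGISTRY_TYPES}
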
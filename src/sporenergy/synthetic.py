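"""Seeded generators for every input shape the pipeline consumes.

These emulate the gross statistical structure of the real resources —
lognormal gene lengths and protein abundances, stage-peaked sporulation
expression waves, monotone cumulative revival scores (with optional
measurement dips to exercise clamping), a right-skewed deletion-size
spectrum, and a sporulation-efficiency compilation — so every stage of
the analysis runs and can be validated against constructed ground truth
without any download.  They are fixtures with controlled shape, not
biological claims.

Each generator draws from its own pseudo-random stream derived from the
master seed, so adding a generator never perturbs existing outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import REVIVAL_EXCLUDED, REVIVAL_HOURS, SPORULATION_HOURS
from .evolution import DeletionSizeDistribution

__all__ = ["SyntheticConfig", "make_annotation", "make_abundance",
           "make_expression_waves", "make_revival_scores",
           "make_efficiency_table", "make_deletion_sizes", "write_fasta"]

_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# fixed per-generator stream ids so streams are independent and stable
_STREAMS = {
    "annotation": 1, "abundance": 2, "expression": 3,
    "revival": 4, "efficiency": 5, "deletions": 6,
}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[generator]]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic-data generators (one master seed)."""

    seed: int = 42
    n_genes: int = 200
    length_log_mean: float = float(np.log(900.0))   # lognormal bp, median ~900
    length_log_sd: float = 0.55
    ppm_log_sd: float = 1.5
    n_stages: int = len(SPORULATION_HOURS)
    wave_sharpness: float = 1.5     # 1/width of the stage-peaked profiles
    force_stage: int | None = None  # pin every gene's expression to one stage
    revival_noise_sd: float = 0.05
    revival_dip_fraction: float = 0.0
    missing_length_fraction: float = 0.0
    symbol_only_fraction: float = 0.0
    multimapped_fraction: float = 0.0
    unmatched_fraction: float = 0.0
    mother_fraction: float = 0.75
    efficiency_median: float = 0.30
    efficiency_n: int = 200
    deletion_geom_p: float = 0.01
    deletion_spikes: tuple[int, ...] = (3, 9, 1000, 1200)
    deletion_spike_weight: float = 0.15

    def __post_init__(self) -> None:
        for name in ("revival_dip_fraction", "missing_length_fraction",
                     "symbol_only_fraction", "multimapped_fraction",
                     "unmatched_fraction", "mother_fraction",
                     "deletion_spike_weight"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if not 0.0 < self.efficiency_median < 1.0:
            raise ValueError("efficiency_median must lie in (0, 1)")


def _locus_tags(n: int) -> list[str]:
    return [f"syn{i:05d}" for i in range(1, n + 1)]


def make_annotation(config: SyntheticConfig = SyntheticConfig()) -> tuple[pd.DataFrame, dict[str, str]]:
    """Gene annotation table plus consistent protein sequences.

    Gene lengths are lognormal (median ~900 bp) rounded to codon
    multiples; protein length is gene_length/3 − 1 aa, and each protein
    gets a random sequence of exactly that length.  A configurable
    fraction of rows loses its lengths (to exercise median imputation) or
    its locus tag (symbol-only rows, resolvable through the synonym map).
    """
    rng = _rng(config.seed, "annotation")
    tags = _locus_tags(config.n_genes)
    lengths = rng.lognormal(config.length_log_mean, config.length_log_sd,
                            config.n_genes)
    gene_bp = (np.maximum(np.round(lengths / 3.0), 20) * 3).astype(int)
    protein_aa = gene_bp // 3 - 1

    symbols = [f"g{chr(97 + (i % 26))}{chr(97 + ((i // 26) % 26))}{i % 10}"
               for i in range(config.n_genes)]
    sequences = {
        tag: "".join(rng.choice(_AA_ALPHABET, size=aa))
        for tag, aa in zip(tags, protein_aa)
    }

    gene_col = np.array(gene_bp, dtype=object)
    prot_col = np.array(protein_aa, dtype=object)
    n_missing = int(round(config.missing_length_fraction * config.n_genes))
    if n_missing:
        idx = rng.choice(config.n_genes, size=n_missing, replace=False)
        gene_col[idx] = None
        prot_col[idx] = None

    locus_col = np.array(tags, dtype=object)
    n_symbol_only = int(round(config.symbol_only_fraction * config.n_genes))
    if n_symbol_only:
        idx = rng.choice(config.n_genes, size=n_symbol_only, replace=False)
        locus_col[idx] = None

    compartments = np.where(rng.random(config.n_genes) < config.mother_fraction,
                            "mother", "forespore")
    df = pd.DataFrame({
        "locus_tag": locus_col,
        "symbol": symbols,
        "gene_length": gene_col,
        "protein_length": prot_col,
        "category_tags": ["sporulation"] * config.n_genes,
        "compartment": compartments,
        # full tags kept alongside so callers can build the synonym map
        "_true_locus_tag": tags,
    })
    return df, sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write protein sequences keyed by locus tag to FASTA."""
    records = [SeqRecord(Seq(seq), id=tag, description="")
               for tag, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def make_abundance(
    config: SyntheticConfig,
    gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """Right-skewed ppm abundances summing to 1e6 before any masking.

    A configurable fraction of rows is relabeled with a shared synonym
    matching several locus tags (exercising the even-split rule) or with
    an unmappable identifier (exercising the ppm floor).
    """
    rng = _rng(config.seed, "abundance")
    tags = list(gene_table["_true_locus_tag"])
    raw = rng.lognormal(0.0, config.ppm_log_sd, len(tags))
    ppm = raw / raw.sum() * 1.0e6
    identifiers = list(tags)

    n_multi = int(round(config.multimapped_fraction * len(tags)))
    multi_groups = {}
    if n_multi >= 2:
        idx = rng.choice(len(tags), size=n_multi, replace=False)
        # pair off chosen rows under shared synthetic synonyms
        for k in range(0, n_multi - 1, 2):
            i, j = idx[k], idx[k + 1]
            synonym = f"multi{k // 2:03d}"
            identifiers[i] = identifiers[j] = synonym
            multi_groups[synonym] = [tags[i], tags[j]]

    n_unmatched = int(round(config.unmatched_fraction * len(tags)))
    if n_unmatched:
        idx = rng.choice(len(tags), size=n_unmatched, replace=False)
        for i in idx:
            if identifiers[i] == tags[i]:   # don't clobber multi-map rows
                identifiers[i] = f"orphan{i:04d}"

    df = pd.DataFrame({"identifier": identifiers, "ppm": ppm})
    df.attrs["synonym_map"] = multi_groups
    return df


def make_expression_waves(
    config: SyntheticConfig,
    gene_table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, int]]:
    """Stage-peaked sporulation expression in long format.

    Each gene is assigned a peak stage (cycling through the program, so
    early stages are as populated as late ones); its profile is a
    discretized Gaussian bump around the peak whose width is set by
    ``wave_sharpness``.  Returns the long-format frame, the gene →
    compartment labels, and the gene → peak-stage assignment (the ground
    truth that closed-form per-stage cost shares are computed from).
    """
    rng = _rng(config.seed, "expression")
    tags = list(gene_table["_true_locus_tag"])
    stages = np.arange(config.n_stages)
    if config.force_stage is None:
        peaks = {tag: int(i % config.n_stages) for i, tag in enumerate(tags)}
    else:
        peaks = {tag: int(config.force_stage) for tag in tags}

    rows = []
    for tag in tags:
        if config.force_stage is None:
            profile = np.exp(-config.wave_sharpness * (stages - peaks[tag]) ** 2)
            profile *= 1.0 + 0.1 * rng.random(config.n_stages)
        else:
            profile = np.where(stages == peaks[tag], 1.0, 0.0)
        for t, value in zip(SPORULATION_HOURS[: config.n_stages], profile):
            rows.append((tag, t, float(value)))
    long_df = pd.DataFrame(rows, columns=["locus_tag", "time", "expression"])
    compartments = dict(zip(tags, gene_table["compartment"]))
    return long_df, compartments, peaks


def make_revival_scores(
    config: SyntheticConfig,
    gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """Cumulative newly-synthesized-protein scores over revival time points.

    Curves are nondecreasing by construction; a configurable fraction of
    genes gets one artificial dip (a negative successive difference) to
    exercise the clamping rule.  The late column that the costing layer
    must exclude is always present.
    """
    rng = _rng(config.seed, "revival")
    tags = list(gene_table["_true_locus_tag"])
    n_cols = len(REVIVAL_HOURS) + 1   # + excluded late column
    increments = rng.gamma(2.0, 1.0, size=(len(tags), n_cols))
    increments += config.revival_noise_sd * rng.random((len(tags), n_cols))
    cumulative = np.cumsum(increments, axis=1)

    n_dips = int(round(config.revival_dip_fraction * len(tags)))
    if n_dips:
        idx = rng.choice(len(tags), size=n_dips, replace=False)
        for i in idx:
            j = int(rng.integers(1, len(REVIVAL_HOURS)))
            cumulative[i, j] = cumulative[i, j - 1] * 0.5   # forced dip

    columns = list(REVIVAL_HOURS) + [REVIVAL_EXCLUDED]
    df = pd.DataFrame(cumulative, columns=columns)
    df.insert(0, "locus_tag", tags)
    return df


def make_efficiency_table(config: SyntheticConfig = SyntheticConfig()) -> pd.DataFrame:
    """Sporulation-efficiency compilation with a configured median.

    Values in [0, 1] are drawn by mapping uniforms through a two-piece
    linear quantile function anchored at the configured median, emulating
    the broad 0–100% spread of literature-reported batch efficiencies.
    """
    rng = _rng(config.seed, "efficiency")
    u = rng.random(config.efficiency_n)
    m = config.efficiency_median
    eff = np.where(u < 0.5, m * 2.0 * u, m + (1.0 - m) * (2.0 * u - 1.0))
    return pd.DataFrame({
        "study": [f"study{i:03d}" for i in range(config.efficiency_n)],
        "efficiency": eff,
    })


def make_deletion_sizes(config: SyntheticConfig = SyntheticConfig(),
                        *, max_size: int = 5000) -> DeletionSizeDistribution:
    """Right-skewed deletion-size spectrum with sharp spikes.

    A geometric backbone (small deletions most frequent) mixed with point
    masses at a few characteristic sizes, mirroring the peaked empirical
    spectra of mutation-accumulation experiments.  The spectrum is a
    deterministic function of the mixture parameters.
    """
    sizes = np.arange(1, max_size + 1)
    geom = (1.0 - config.deletion_geom_p) ** (sizes - 1) * config.deletion_geom_p
    geom /= geom.sum()
    probs = (1.0 - config.deletion_spike_weight) * geom
    spikes = [s for s in config.deletion_spikes if s <= max_size]
    for s in spikes:
        probs[s - 1] += config.deletion_spike_weight / len(spikes)
    # keep the table compact: drop negligible tail mass and renormalize
    keep = probs > 1e-12
    probs = probs[keep] / probs[keep].sum()
    sizes = sizes[keep]
    return DeletionSizeDistribution(tuple(int(s) for s in sizes),
                                    tuple(float(p) for p in probs))
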
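"""Shared fixtures: a small synthetic study run end to end once per session."""

from __future__ import annotations

import pytest

from sporenergy.annotation import (
    GeneRecord,
    impute_missing_lengths,
    map_abundances,
    parse_expression_heatmap,
    parse_revival_scores,
    ppm_to_copies,
)
from sporenergy.synthetic import (
    SyntheticConfig,
    make_abundance,
    make_annotation,
    make_expression_waves,
    make_revival_scores,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=7,
        n_genes=60,
        missing_length_fraction=0.1,
        multimapped_fraction=0.1,
        unmatched_fraction=0.05,
        revival_dip_fraction=0.1,
    )


@pytest.fixture(scope="session")
def study(small_config):
    """Normalized records for a 60-gene synthetic study.

    Returns a dict with gene records (lengths imputed), abundance records
    (copies renormalized), sporulation expression weights, revival interval
    scores, compartment labels, and the stage assignments used to generate
    the expression waves.
    """
    genes_df, sequences = make_annotation(small_config)
    genes = [
        GeneRecord(
            locus_tag=tag,
            gene_length=None if gl is None else float(gl),
            protein_length=None if pl is None else float(pl),
            compartment=comp,
        )
        for tag, gl, pl, comp in zip(
            genes_df["_true_locus_tag"], genes_df["gene_length"],
            genes_df["protein_length"], genes_df["compartment"])
    ]
    genes = impute_missing_lengths(genes)

    ab_df = make_abundance(small_config, genes_df)
    abundances = ppm_to_copies(map_abundances(
        list(zip(ab_df["identifier"], ab_df["ppm"])),
        ab_df.attrs["synonym_map"],
        [g.locus_tag for g in genes],
    ))

    expression, compartments, peaks = make_expression_waves(small_config, genes_df)
    weights = parse_expression_heatmap(expression)
    scores = parse_revival_scores(make_revival_scores(small_config, genes_df))

    return {
        "config": small_config,
        "genes_df": genes_df,
        "sequences": sequences,
        "genes": genes,
        "abundances": abundances,
        "weights": weights,
        "scores": scores,
        "compartments": compartments,
        "peaks": peaks,
    }
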
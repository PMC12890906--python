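"""Temporal ledgers: conservation, oracle equivalence, attribution, comparisons."""

import numpy as np
import pandas as pd
import pytest

from sporenergy.annotation import (
    REVIVAL_HOURS,
    SPORULATION_HOURS,
    AbundanceRecord,
    ExpressionWeights,
    GeneRecord,
)
from sporenergy.constants import (
    PROTEINS_PER_MRNA,
    BudgetConstants,
    MembraneGeometry,
    RevivalMembraneParams,
    TranscriptionConstants,
    TranslationConstants,
)
from sporenergy.costs import membrane_cost, replication_cost, revival_membrane_cost, septum_cost
from sporenergy.ledger import (
    TemporalLedger,
    TraitDefinition,
    break_even,
    build_revival_ledger,
    build_sporulation_ledger,
    compartment_split,
    cumulative_fraction,
    head_to_head,
)


def naive_gene_loop_total(genes, abundances, weight_vectors,
                          yield_per_mrna=PROTEINS_PER_MRNA):
    """Independent per-gene oracle: scalar arithmetic, no ledger machinery."""
    tc, tl = TranscriptionConstants(), TranslationConstants()
    by_tag = {a.locus_tag: a for a in abundances}
    direct = opportunity = 0.0
    for gene in genes:
        ab = by_tag.get(gene.locus_tag)
        if ab is None or ab.copies <= 0 or gene.locus_tag not in weight_vectors:
            continue
        nt = gene.gene_length * ab.copies / yield_per_mrna
        direct += tc.nt_synthesis_direct * nt
        direct += (tc.elongation + tc.supercoil_overhead) * nt
        opportunity += tc.nt_opportunity * nt
        direct += (tl.per_aa_direct * gene.protein_length + tl.per_protein_direct) * ab.copies
        opportunity += tl.mean_aa_opportunity * gene.protein_length * ab.copies
    return direct, opportunity


class TestSporulationLedger:
    def test_grand_total_matches_naive_loop_oracle(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        weight_vectors = {w.locus_tag: w.weights for w in study["weights"]}
        d, o = naive_gene_loop_total(study["genes"], study["abundances"],
                                     weight_vectors)
        rep = replication_cost(4_215_606)
        _, sept = septum_cost(1.0)
        total = ledger.grand_total()
        assert total.direct == pytest.approx(d + rep.direct + sept.direct, rel=1e-6)
        assert total.opportunity == pytest.approx(o + rep.opportunity + sept.opportunity,
                                                  rel=1e-6)

    def test_row_additivity_and_conservation(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        table = ledger.table
        assert np.allclose(table["total"], table["direct"] + table["opportunity"])
        # PD and PO conserve independently between interval view and grand total
        by_interval = ledger.interval_totals()
        assert by_interval["direct"].sum() == pytest.approx(ledger.grand_total().direct)
        assert by_interval["opportunity"].sum() == pytest.approx(
            ledger.grand_total().opportunity)

    def test_permutation_invariance(self, study):
        ledger1 = build_sporulation_ledger(study["genes"], study["abundances"],
                                           study["weights"])
        rng = np.random.default_rng(5)
        genes = list(study["genes"])
        weights = list(study["weights"])
        rng.shuffle(genes)
        rng.shuffle(weights)
        ledger2 = build_sporulation_ledger(genes, study["abundances"][::-1], weights)
        pd.testing.assert_frame_equal(ledger1.table, ledger2.table)

    def test_replication_in_first_hour_septum_in_second(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        rep_rows = ledger.table[ledger.table["category"] == "replication"]
        assert set(rep_rows["interval"]) == {"t0"}
        sept_rows = ledger.table[ledger.table["category"] == "septum"]
        assert set(sept_rows["interval"]) == {"t1"}

    def test_expression_concentrated_at_t0(self, study):
        peak = np.zeros(len(SPORULATION_HOURS))
        peak[0] = 1.0
        weights = [ExpressionWeights(g.locus_tag, SPORULATION_HOURS, peak)
                   for g in study["genes"]]
        ledger = build_sporulation_ledger(study["genes"], study["abundances"], weights)
        expr = ledger.table[ledger.table["category"].isin(
            ["transcription_synthesis", "transcription_polymerization", "translation"])]
        assert set(expr["interval"]) == {"t0"}

    def test_zero_abundance_leaves_only_replication_and_septum(self, study):
        silent = [AbundanceRecord(a.locus_tag, a.ppm, 0.0) for a in study["abundances"]]
        ledger = build_sporulation_ledger(study["genes"], silent, study["weights"])
        assert set(ledger.table["category"]) == {"replication", "septum"}

    def test_missing_weights_error_names_gene(self, study):
        ledger_weights = [w for w in study["weights"]
                          if w.locus_tag != study["genes"][0].locus_tag]
        with pytest.raises(ValueError, match=study["genes"][0].locus_tag):
            build_sporulation_ledger(study["genes"], study["abundances"],
                                     ledger_weights)

    def test_decaying_expression_gives_nonincreasing_interval_costs(self, study):
        # exponentially decaying waves front-load cost; the per-interval PT
        # series of expression categories should be nonincreasing
        decay = np.exp(-1.0 * np.arange(len(SPORULATION_HOURS)))
        decay /= decay.sum()
        weights = [ExpressionWeights(g.locus_tag, SPORULATION_HOURS, decay)
                   for g in study["genes"]]
        ledger = build_sporulation_ledger(study["genes"], study["abundances"], weights)
        expr = ledger.table[ledger.table["category"].isin(
            ["transcription_polymerization", "translation"])]
        series = (expr.groupby("interval")["total"].sum()
                  .reindex(list(SPORULATION_HOURS), fill_value=0.0).to_numpy())
        assert (np.diff(series) <= 1e-9 * series[0]).all()


class TestRevivalLedger:
    def test_grand_total_matches_loop_oracle_plus_membrane(self, study):
        ledger = build_revival_ledger(study["genes"], study["abundances"],
                                      study["scores"])
        weight_vectors = {s.locus_tag: s.weights for s in study["scores"]
                          if s.weights.sum() > 0}
        d, o = naive_gene_loop_total(study["genes"], study["abundances"],
                                     weight_vectors)
        mem = revival_membrane_cost(membrane_cost()[1])
        total = ledger.grand_total()
        assert total.direct == pytest.approx(d + mem.direct, rel=1e-6)
        assert total.opportunity == pytest.approx(o + mem.opportunity, rel=1e-6)

    def test_no_new_membrane_drops_category(self, study):
        ledger = build_revival_ledger(
            study["genes"], study["abundances"], study["scores"],
            membrane_params=RevivalMembraneParams(fraction_new=0.0))
        assert "membrane" not in set(ledger.table["category"])

    def test_membrane_spread_over_outgrowth_only(self, study):
        ledger = build_revival_ledger(study["genes"], study["abundances"],
                                      study["scores"])
        mem_rows = ledger.table[ledger.table["category"] == "membrane"]
        assert set(mem_rows["interval"]) == set(REVIVAL_HOURS[1:])
        assert np.allclose(mem_rows["total"], mem_rows["total"].iloc[0])

    def test_single_protein_all_in_germination_window(self):
        gene = GeneRecord("g1", gene_length=900, protein_length=299)
        ab = AbundanceRecord("g1", 100.0, 1000.0)
        from sporenergy.annotation import RevivalIntervalScores
        w = np.zeros(len(REVIVAL_HOURS))
        w[0] = 1.0
        score = RevivalIntervalScores("g1", REVIVAL_HOURS, w)
        ledger = build_revival_ledger(
            [gene], [ab], [score],
            membrane_params=RevivalMembraneParams(fraction_new=0.0))
        assert set(ledger.table["interval"]) == {"H0.25"}


class TestCompartmentSplit:
    def test_all_mother_gives_unit_share(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        labels = {g.locus_tag: "mother" for g in study["genes"]}
        assert compartment_split(ledger, labels) == (1.0, 0.0)

    def test_constructed_three_to_one_split(self):
        # four identical genes, equal copies; 3 mother : 1 forespore; no
        # genome-level categories so the expression split is the whole story
        genes = [GeneRecord(f"g{i}", gene_length=900, protein_length=299)
                 for i in range(4)]
        abundances = [AbundanceRecord(g.locus_tag, 1.0, 500.0) for g in genes]
        w = np.zeros(len(SPORULATION_HOURS))
        w[0] = 1.0
        weights = [ExpressionWeights(g.locus_tag, SPORULATION_HOURS, w.copy())
                   for g in genes]
        ledger = build_sporulation_ledger(
            genes, abundances, weights, genome_length_bp=0.0,
            septum_geometry=MembraneGeometry(protein_occupancy=1.0))
        labels = {"g0": "mother", "g1": "mother", "g2": "mother", "g3": "forespore"}
        mother, fore = compartment_split(ledger, labels)
        assert mother == pytest.approx(0.75)
        assert fore == pytest.approx(0.25)

    def test_shares_sum_to_one_for_any_labeling(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        mother, fore = compartment_split(ledger, study["compartments"])
        assert mother + fore == pytest.approx(1.0)
        assert 0.0 <= fore <= mother <= 1.0

    def test_replication_and_septum_attributed_to_mother(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        labels = {g.locus_tag: "forespore" for g in study["genes"]}
        mother, _ = compartment_split(ledger, labels)
        rep = replication_cost(4_215_606).total
        sept = septum_cost(1.0)[1].total
        assert mother == pytest.approx((rep + sept) / ledger.grand_total().total)


class TestHeadToHead:
    def _trait_inputs(self):
        genes = [GeneRecord(f"g{i}", gene_length=900, protein_length=299)
                 for i in range(4)]
        abundances = [AbundanceRecord(g.locus_tag, 1.0, 1000.0) for g in genes]
        return genes, abundances

    def test_percent_of_budget_ratio_arithmetic(self):
        genes, abundances = self._trait_inputs()
        budget = BudgetConstants()
        trait = TraitDefinition("trait", frozenset(g.locus_tag for g in genes))
        [row] = head_to_head([trait], genes, abundances, budget=budget).to_dict("records")
        assert row["percent_of_budget"] == pytest.approx(
            100.0 * row["per_generation"] / 9.4e10)

    def test_program_duration_normalization(self):
        # an 11.6 h program is 10 vegetative generations at tgen = 1.16 h
        genes, abundances = self._trait_inputs()
        gene_set = frozenset(g.locus_tag for g in genes)
        per_gen = TraitDefinition("per-gen", gene_set)
        program = TraitDefinition("program", gene_set, duration_h=11.6,
                                  normalization="per_program_duration")
        table = head_to_head([per_gen, program], genes, abundances)
        full, scaled = table["per_generation"]
        assert scaled == pytest.approx(full / 10.0)

    def test_identical_traits_identical_rows(self):
        genes, abundances = self._trait_inputs()
        gene_set = frozenset(g.locus_tag for g in genes)
        t1 = TraitDefinition("a", gene_set)
        t2 = TraitDefinition("b", gene_set)
        table = head_to_head([t1, t2], genes, abundances)
        cols = ["build_total", "per_generation", "percent_of_budget"]
        assert table.loc[0, cols].tolist() == table.loc[1, cols].tolist()

    def test_empty_gene_set_yields_zero_row(self):
        genes, abundances = self._trait_inputs()
        trait = TraitDefinition("empty", frozenset(["missing"]))
        [row] = head_to_head([trait], genes, abundances).to_dict("records")
        assert row["build_total"] == 0.0
        assert row["n_genes"] == 0


class TestBreakEven:
    @pytest.mark.parametrize("maintenance, expected", [
        (1.2e9, 7.7), (1.2e8, 77.0), (1.2e7, 770.0),
    ])
    def test_break_even_across_maintenance_rates(self, maintenance, expected):
        assert break_even(9.2e9, maintenance) == pytest.approx(expected, rel=0.01)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            break_even(9.2e9, 0.0)
        with pytest.raises(ValueError):
            break_even(0.0, 1.2e9)


class TestCumulativeFraction:
    def test_reaches_one_at_final_interval(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        assert cumulative_fraction(ledger, SPORULATION_HOURS[-1]) == pytest.approx(1.0)

    def test_nondecreasing_in_interval_index(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        values = [cumulative_fraction(ledger, t) for t in SPORULATION_HOURS]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_front_loaded_prefix_sum_oracle(self, study):
        peak = np.zeros(len(SPORULATION_HOURS))
        peak[0], peak[1] = 0.8, 0.2
        weights = [ExpressionWeights(g.locus_tag, SPORULATION_HOURS, peak.copy())
                   for g in study["genes"]]
        ledger = build_sporulation_ledger(
            study["genes"], study["abundances"], weights, genome_length_bp=0.0,
            septum_geometry=MembraneGeometry(protein_occupancy=1.0))
        # hand prefix sum over polymerization+translation (synthesis all at t0)
        table = ledger.table
        t0 = table.loc[table["interval"] == "t0", "total"].sum()
        assert cumulative_fraction(ledger, "t0") == pytest.approx(
            t0 / table["total"].sum())

    def test_category_restriction(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        assert cumulative_fraction(ledger, "t0", categories=["replication"]) == 1.0
        assert cumulative_fraction(ledger, "t8", categories=[]) == 0.0

    def test_unknown_interval_rejected(self, study):
        ledger = build_sporulation_ledger(study["genes"], study["abundances"],
                                          study["weights"])
        with pytest.raises(ValueError, match="unknown interval"):
            cumulative_fraction(ledger, "t99")
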
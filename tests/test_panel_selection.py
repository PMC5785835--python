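import numpy as np
import pytest

from iisnp.ld_pruning import pairwise_r2
from iisnp.locus_stats import compute_locus_stats
from iisnp.panel_selection import PanelParams, select_panel, stage_table
from iisnp.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="module")
def planted_cohort():
    """Medium-size cohort with one planted violation of every kind."""
    # n = 2000 keeps the r-squared < 0.01 filter meaningful: for unlinked
    # loci n*r2 is ~ chi-square(1), so smaller cohorts trip it by chance
    cfg = SimulationConfig(
        n_samples=2000,
        n_loci=45,
        n_low_maf=4,
        n_multiallelic=3,
        n_hwe_violating=3,
        f_plant=0.4,
        n_ld_pairs=3,
        n_hla=2,
        n_low_callrate=2,
        missing_rate=0.01,
        rna_error_rate=0.02,
        seed=101,
    )
    return cfg, simulate_cohort(cfg)


class TestSelectPanel:
    def test_planted_violations_removed_at_their_stage(self, planted_cohort):
        cfg, (dna, rna, truth) = planted_cohort
        result = select_panel(dna, rna)
        by_name = {s.name: s for s in result.stages}
        # each stage's casualty count matches the planted design
        assert by_name["call_rate"].n_in - by_name["call_rate"].n_out == 2
        assert by_name["biallelic"].n_in - by_name["biallelic"].n_out == 3
        assert by_name["maf"].n_in - by_name["maf"].n_out == 4
        assert by_name["intersection"].n_in == by_name["intersection"].n_out
        assert by_name["hwe"].n_in - by_name["hwe"].n_out == 3
        assert by_name["hla"].n_in - by_name["hla"].n_out == 2
        assert by_name["ld"].n_in - by_name["ld"].n_out == 3

    def test_final_panel_matches_truth(self, planted_cohort):
        cfg, (dna, rna, truth) = planted_cohort
        result = select_panel(dna, rna)
        assert set(result.final_panel) == set(truth.expected_panel)

    def test_final_panel_invariants_by_recomputation(self, planted_cohort):
        cfg, (dna, rna, truth) = planted_cohort
        params = PanelParams()
        result = select_panel(dna, rna, params)
        panel = result.final_panel
        rna_stats = compute_locus_stats(rna, panel, with_hwe=False)
        dna_stats = compute_locus_stats(dna, panel, with_hwe=True)
        by_key = {loc.key: loc for loc in dna.loci}
        for k in panel:
            assert rna_stats[k].call_rate > params.call_rate
            assert rna_stats[k].n_alleles_observed <= 2
            assert rna_stats[k].maf > params.maf
            assert dna_stats[k].maf > params.maf
            assert not by_key[k].in_hla
        # HWE retention on the final set (q-values recomputed panel-wide are
        # at least as large as cascade-wide ones for the survivors)
        assert all(dna_stats[k].hwe_p > 1e-4 for k in panel)
        ld = pairwise_r2(dna, panel)
        finite = ld.r2[np.isfinite(ld.r2)]
        assert finite.max() < params.ld_r2

    def test_hwe_and_hla_stage_order_is_immaterial(self, planted_cohort):
        # both are independent predicates applied before LD: permuting them
        # cannot change the final set, so survivors never carry either flag
        cfg, (dna, rna, truth) = planted_cohort
        result = select_panel(dna, rna)
        labels = {truth.labels[k] for k in result.final_panel}
        assert "hwe" not in labels and "hla" not in labels

    def test_zero_violation_cohort_survives_everything(self):
        cfg = SimulationConfig(
            n_samples=2000, n_loci=25, missing_rate=0.0, rna_error_rate=0.0, seed=7
        )
        dna, rna, truth = simulate_cohort(cfg)
        result = select_panel(dna, rna)
        assert set(result.final_panel) == set(truth.clean_locus_keys)

    def test_all_low_maf_yields_empty_panel_not_error(self):
        cfg = SimulationConfig(
            n_samples=200, n_loci=10, n_low_maf=10, missing_rate=0.0, seed=8
        )
        dna, rna, _ = simulate_cohort(cfg)
        result = select_panel(dna, rna)
        assert result.final_panel == []
        by_name = {s.name: s for s in result.stages}
        assert by_name["maf"].n_out == 0

    def test_counts_non_increasing(self, planted_cohort):
        cfg, (dna, rna, _) = planted_cohort
        result = select_panel(dna, rna)
        for s in result.stages:
            assert s.n_out <= s.n_in
        assert result.final_panel == result.stages[-1].survivors

    def test_optional_cap_keeps_most_informative(self, planted_cohort):
        cfg, (dna, rna, _) = planted_cohort
        capped = select_panel(dna, rna, PanelParams(max_panel_size=5))
        full = select_panel(dna, rna)
        assert len(capped.final_panel) == 5
        assert set(capped.final_panel) <= set(full.final_panel)
        # capped loci are the lowest per-locus PI (highest heterozygosity)
        stats = compute_locus_stats(dna, full.final_panel, with_hwe=False)
        kept_maf = sorted(stats[k].maf for k in capped.final_panel)
        dropped_maf = sorted(
            stats[k].maf for k in full.final_panel if k not in set(capped.final_panel)
        )
        assert kept_maf[0] >= dropped_maf[-1] - 1e-9

    def test_empty_matrix_rejected(self, planted_cohort):
        cfg, (dna, rna, _) = planted_cohort
        with pytest.raises(ValueError):
            select_panel(dna.subset_loci([]), rna)


class TestStageTable:
    def test_table_lists_thresholds_and_counts(self, planted_cohort):
        cfg, (dna, rna, _) = planted_cohort
        result = select_panel(dna, rna)
        table = stage_table(result)
        assert "call_rate=0.9" in table and "ld_r2=0.01" in table
        rows = [l for l in table.splitlines() if l and not l.startswith("#")]
        assert len(rows) == len(result.stages) + 1  # + final_panel row
        assert rows[-1].endswith(str(len(result.final_panel)))

    def test_empty_panel_last_row_zero(self):
        cfg = SimulationConfig(n_samples=100, n_loci=6, n_low_maf=6, seed=9)
        dna, rna, _ = simulate_cohort(cfg)
        table = stage_table(select_panel(dna, rna))
        assert table.rstrip().splitlines()[-1].endswith("0")
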
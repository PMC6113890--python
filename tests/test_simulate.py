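"""Synthetic-data generator: determinism, placement rules, planted effects."""

import numpy as np
import pandas as pd
import pytest

from efcascade.peaks import call_binding, interval_gap
from efcascade.simulate import (
    ExperimentDesign,
    PlantedTruth,
    default_design,
    generate_expression,
    generate_gene_models,
    generate_peaks,
    generate_zonal_profiles,
    plant_truth,
    simulate_study,
)


class TestGeneModels:
    def test_minimal_instance(self):
        (g,) = generate_gene_models(1, n_chroms=1, seed=7)
        assert g.start < g.end and g.strand in "+-"

    def test_min_gap_respected_everywhere(self):
        genes = generate_gene_models(400, n_chroms=5, min_gap_bp=120_000, seed=1)
        assert len(genes) == 400
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: g.start)
            for a, b in zip(chrom_genes, chrom_genes[1:]):
                assert interval_gap(a.start, a.end, b.start, b.end) >= 120_000

    def test_deterministic_under_seed(self):
        assert generate_gene_models(50, seed=1) == generate_gene_models(50, seed=1)
        assert generate_gene_models(50, seed=1) != generate_gene_models(50, seed=2)

    def test_rejects_impossible_packing(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_gene_models(100, n_chroms=1, chrom_length_bp=1_000_000)
        with pytest.raises(ValueError, match="n_genes"):
            generate_gene_models(0)


def tiny_truth(binding_rows, labels=None):
    genes = sorted({g for _, g in binding_rows} | set(labels or {}))
    return PlantedTruth(
        cell_type={g: (labels or {}).get(g, "none") for g in genes},
        gradient={g: "none" for g in genes},
        regulation=pd.DataFrame(columns=["tf", "gene_id", "mode", "effect_log2fc"]),
        binding=pd.DataFrame(
            [{"tf": t, "gene_id": g, "bound": True} for t, g in binding_rows],
            columns=["tf", "gene_id", "bound"],
        ),
    )


class TestPeaks:
    def test_planted_only_no_decoys(self):
        genes = generate_gene_models(5, n_chroms=1, seed=3)
        truth = tiny_truth([("Tbr1", genes[0].gene_id)])
        peaks = generate_peaks(genes, truth.binding, decoy_per_tf=0, seed=3)
        assert len(peaks) == 1
        gap = interval_gap(peaks[0].start, peaks[0].end, genes[0].start, genes[0].end)
        assert gap <= 50_000

    def test_decoys_beyond_window_of_every_gene(self):
        genes = generate_gene_models(20, n_chroms=2, seed=4)
        truth = tiny_truth([("Tbr1", genes[0].gene_id)])
        peaks = generate_peaks(genes, truth.binding, decoy_per_tf=10, seed=4)
        decoys = [p for p in peaks if p.peak_id != peaks[0].peak_id]
        assert len(decoys) == 10
        for p in decoys:
            gaps = [
                interval_gap(p.start, p.end, g.start, g.end)
                for g in genes
                if g.chrom == p.chrom
            ]
            assert all(gap > 50_000 for gap in gaps)

    def test_binding_round_trip_reproduces_truth(self, small_study):
        calls = call_binding(small_study.peaks, small_study.gene_models)
        called = {(r.gene_id, r.tf) for r in calls.itertuples() if r.bound}
        truth = {
            (str(r.gene_id), str(r.tf))
            for r in small_study.truth.binding.itertuples()
            if r.bound
        }
        assert called == truth

    def test_unknown_gene_rejected(self):
        genes = generate_gene_models(3, n_chroms=1, seed=5)
        truth_binding = pd.DataFrame(
            [{"tf": "Tbr1", "gene_id": "ghost", "bound": True}]
        )
        with pytest.raises(ValueError, match="unknown gene"):
            generate_peaks(genes, truth_binding, seed=5)


class TestExpression:
    def test_zero_noise_effect_is_exact(self):
        truth = PlantedTruth(
            cell_type={"gA": "none", "gB": "none"},
            gradient={"gA": "none", "gB": "none"},
            regulation=pd.DataFrame(
                [{"tf": "Tbr2", "gene_id": "gA", "mode": "activates",
                  "effect_log2fc": 1.0}]
            ),
            binding=pd.DataFrame(
                [{"tf": "Tbr2", "gene_id": "gA", "bound": True}]
            ),
        )
        matrix, sheet, pmap = generate_expression(
            default_design(), truth, probes_per_gene=2, noise_sd=0.0, seed=1
        )
        mut = sheet[(sheet.genotype == "tbr2_cko") & (sheet.experiment == "MA2")].sample_id
        ctl = sheet[(sheet.genotype == "control") & (sheet.experiment == "MA2")].sample_id
        diff = matrix[list(mut)].mean(axis=1) - matrix[list(ctl)].mean(axis=1)
        for probe in ("gA_pr1", "gA_pr2"):
            assert diff[probe] == pytest.approx(-1.0)
        assert diff["gB_pr1"] == pytest.approx(0.0)

    def test_paper_replicate_counts_on_new_array(self):
        matrix, sheet, _ = generate_expression(
            default_design(), tiny_truth([("Tbr1", "g1")]), seed=1
        )
        ma2 = sheet[sheet.experiment == "MA2"]
        assert len(ma2) == 12  # 3 control + 4 Tbr1-KO + 2 Tbr2-cKO + 3 dKO
        counts = ma2.genotype.value_counts().to_dict()
        assert counts == {
            "control": 3, "tbr1_ko": 4, "tbr2_cko": 2, "tbr1_tbr2_dko": 3
        }

    def test_synergistic_gene_shifts_only_in_double_mutant(self):
        truth = PlantedTruth(
            cell_type={"gS": "none"},
            gradient={"gS": "none"},
            regulation=pd.DataFrame(
                [{"tf": "Tbr1+Tbr2", "gene_id": "gS",
                  "mode": "synergistic_activates", "effect_log2fc": 0.75}]
            ),
            binding=pd.DataFrame(
                [{"tf": "Tbr1", "gene_id": "gS", "bound": True},
                 {"tf": "Tbr2", "gene_id": "gS", "bound": True}]
            ),
        )
        matrix, sheet, _ = generate_expression(
            default_design(), truth, noise_sd=0.0, seed=1
        )
        ctl = matrix[list(sheet[sheet.genotype == "control"].sample_id)].mean(axis=1)
        for genotype, expected in [
            ("tbr1_ko", 0.0), ("tbr2_cko", 0.0), ("tbr1_tbr2_dko", -0.75)
        ]:
            grp = matrix[list(sheet[sheet.genotype == genotype].sample_id)].mean(axis=1)
            assert (grp - ctl)["gS_pr1"] == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        truth = tiny_truth([("Tbr1", "g1")])
        with pytest.raises(ValueError, match="noise_sd"):
            generate_expression(default_design(), truth, noise_sd=-0.1)
        with pytest.raises(ValueError, match="probes_per_gene"):
            generate_expression(default_design(), truth, probes_per_gene=0)
        bad = tiny_truth([("Tbr1", "g1")])
        bad.regulation = pd.DataFrame(
            [{"tf": "Sox2", "gene_id": "g1", "mode": "activates",
              "effect_log2fc": 1.0}]
        )
        with pytest.raises(ValueError, match="no mutant genotype"):
            generate_expression(default_design(), bad)


class TestZonalProfiles:
    def test_rgp_template_is_vz_only_at_zero_noise(self):
        prof = generate_zonal_profiles(
            tiny_truth([], labels={"g": "RGP"}), noise_sd=0.0
        ).set_index("gene_id")
        assert prof.loc["g", "VZ"] > 0
        assert (prof.loc["g", ["SVZ", "IZ", "CP"]] == 0).all()

    def test_bilaminar_template(self):
        prof = generate_zonal_profiles(
            tiny_truth([], labels={"g": "aIP+bIP"}), noise_sd=0.0, detect_floor=0.2
        ).set_index("gene_id")
        assert prof.loc["g", "VZ"] > 0.2 and prof.loc["g", "SVZ"] > 0.2
        assert (prof.loc["g", ["IZ", "CP"]] < 0.2).all()

    def test_unknown_label_rejected(self):
        truth = tiny_truth([], labels={"g": "none"})
        truth.cell_type["g"] = "astrocyte"
        with pytest.raises(ValueError, match="unknown cell-type label"):
            generate_zonal_profiles(truth)


class TestDesignAndTruth:
    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError, match=">= 2 replicates"):
            ExperimentDesign(
                replicates={"MA1": {"control": 1}}, lineage_replicates={"GFP_pos": 2}
            )

    def test_truth_consistency_enforced(self):
        with pytest.raises(ValueError, match="must be bound"):
            PlantedTruth(
                cell_type={"g": "none"},
                gradient={"g": "none"},
                regulation=pd.DataFrame(
                    [{"tf": "Tbr1", "gene_id": "g", "mode": "activates",
                      "effect_log2fc": 1.0}]
                ),
                binding=pd.DataFrame(columns=["tf", "gene_id", "bound"]),
            )

    def test_synergy_truth_requires_double_binding(self):
        truth = plant_truth([f"g{i}" for i in range(60)], seed=1, n_single_edges=6,
                            n_synergy=2, n_bound_only_per_tf=1)
        bound = {
            (str(r.tf), str(r.gene_id))
            for r in truth.binding.itertuples()
            if r.bound
        }
        for r in truth.regulation.itertuples():
            if r.mode.startswith("synergistic"):
                assert ("Tbr1", r.gene_id) in bound and ("Tbr2", r.gene_id) in bound


class TestStudyDeterminism:
    def test_identical_seeds_give_byte_identical_files(self, tmp_path):
        a = simulate_study(n_genes=40, seed=9, n_single_edges=3, n_synergy=1,
                           n_bound_only_per_tf=1)
        b = simulate_study(n_genes=40, seed=9, n_single_edges=3, n_synergy=1,
                           n_bound_only_per_tf=1)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        a.write(dir_a)
        b.write(dir_b)
        files_a = sorted(p.name for p in dir_a.iterdir())
        assert files_a == sorted(p.name for p in dir_b.iterdir())
        for name in files_a:
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()

    def test_different_seed_changes_outputs(self):
        a = simulate_study(n_genes=40, seed=9, n_single_edges=3, n_synergy=1,
                           n_bound_only_per_tf=1)
        b = simulate_study(n_genes=40, seed=10, n_single_edges=3, n_synergy=1,
                           n_bound_only_per_tf=1)
        assert not np.allclose(a.matrix.to_numpy(), b.matrix.to_numpy())
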
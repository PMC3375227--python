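"""Generators: planted-signal MSAs and ground-truth activity landscapes."""

import numpy as np
import pytest

from promiscreen import (
    MsaSpec,
    PlantedColumn,
    SignatureCriterion,
    generate_activity_table,
    generate_msa,
    paper_scale_scenario,
    sca_statistical_energy,
    write_fasta,
)
from promiscreen.alignment import AA_INDEX, positional_frequencies
from promiscreen.genotypes import design_matrix
from promiscreen.synthetic import LandscapeSpec, random_landscape_spec, true_landscape


class TestMsaGenerator:
    def test_zero_shift_leaves_planted_column_undetectable(self):
        """Without a shift the designated column carries no signature signal:
        among ten statistically identical zero-shift columns it attains the
        top energy rank no more often than chance allows.  (Conservation
        itself inflates the energy's sampling variance, so the comparison
        must be against equally conserved columns, not uniform ones.)"""
        zero_cols = [
            PlantedColumn(pos, "A", "S", 0.0)
            for pos in (5, 8, 10, 13, 16, 20, 24, 28, 31, 37)
        ]
        top = 0
        for seed in range(20):
            spec = MsaSpec(n_seq=300, length=40, planted=zero_cols, seed=seed)
            res = sca_statistical_energy(
                generate_msa(spec), SignatureCriterion(34, {"H"}, {"P"})
            )
            energies = {c.position: res.energy_at(c.position) for c in zero_cols}
            top += max(energies, key=energies.get) == 10
        # expected 2/20 under exchangeability; 7+ would be p < 0.002
        assert top <= 6

    def test_full_shift_ranks_planted_columns_top(self):
        spec = MsaSpec(
            n_seq=400,
            length=50,
            planted=[
                PlantedColumn(10, "A", "S", 1.0),
                PlantedColumn(20, "L", "F", 1.0),
            ],
            seed=2,
        )
        res = sca_statistical_energy(
            generate_msa(spec), SignatureCriterion(34, {"H"}, {"P"})
        )
        assert set(map(int, res.ranked_positions()[:2])) == {10, 20}

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        spec = MsaSpec(n_seq=50, length=20, signature_position=5, seed=3)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(generate_msa(spec), p1)
        write_fasta(generate_msa(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empirical_frequencies_converge_to_spec(self):
        """Background columns approach the uniform target at large n."""
        spec = MsaSpec(n_seq=10_000, length=10, signature_position=5, seed=4)
        aln = generate_msa(spec)
        ft = positional_frequencies(aln, pseudocount=0.0)
        # any non-signature column
        row = ft.row(2)
        np.testing.assert_allclose(row, 0.05, atol=0.02)

    def test_planted_sub_column_distribution_matches_design(self):
        spec = MsaSpec(
            n_seq=10_000,
            length=10,
            signature_position=5,
            planted=[PlantedColumn(2, "A", "S", 0.6)],
            seed=7,
        )
        aln = generate_msa(spec)
        from promiscreen import select_subalignment

        sub, comp = select_subalignment(aln, SignatureCriterion(5, {"H"}, {"P"}))
        f_sub = positional_frequencies(sub, 0.0).row(2)
        f_comp = positional_frequencies(comp, 0.0).row(2)
        conserved = 0.9 + 0.1 * 0.05  # baseline mass incl. background
        assert f_comp[AA_INDEX["A"]] == pytest.approx(conserved, abs=0.03)
        assert f_sub[AA_INDEX["S"]] == pytest.approx(
            0.6 * conserved + 0.1 * 0.05, abs=0.03
        )

    def test_signature_position_cannot_be_planted(self):
        with pytest.raises(ValueError):
            MsaSpec(planted=[PlantedColumn(34, "A", "S", 0.5)])

    def test_shift_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PlantedColumn(3, "A", "S", 1.2)


class TestActivityGenerator:
    def _spec(self):
        return random_landscape_spec(m=4, n_couplings=2, noise_sd=0.0, seed=8)

    def test_background_genotype_returns_background_activity(self):
        spec = self._spec()
        table, _ = generate_activity_table(spec, genotypes=[(0, 0, 0, 0)])
        np.testing.assert_allclose(table.values()[0], spec.background_activity)

    def test_single_mutant_adds_main_effect(self):
        spec = self._spec()
        table, _ = generate_activity_table(spec, genotypes=[(0, 1, 0, 0)])
        want = spec.background_activity + spec.main_effects[1]
        np.testing.assert_allclose(table.values()[0], want)

    def test_double_mutant_adds_coupling(self):
        spec = self._spec()
        table, _ = generate_activity_table(spec, genotypes=[(1, 1, 0, 0)])
        # pair (0,1) is the first column of the lexicographic pair block
        want = (
            spec.background_activity
            + spec.main_effects[0]
            + spec.main_effects[1]
            + spec.couplings[0]
        )
        np.testing.assert_allclose(table.values()[0], want)

    def test_landscape_matches_brute_force_model_evaluation(self):
        """Ground truth is recoverable by direct evaluation of the coupling
        model on every genotype."""
        spec = self._spec()
        land = true_landscape(spec)
        from promiscreen import enumerate_library

        X = design_matrix(enumerate_library(4), include_pairs=True)
        brute = spec.background_activity + X @ spec.coefficient_matrix()
        np.testing.assert_allclose(land.activities, brute, atol=1e-12)

    def test_noise_is_seed_reproducible(self):
        spec = random_landscape_spec(m=4, noise_sd=0.3, seed=9)
        t1, _ = generate_activity_table(spec, n_random=8, seed=10)
        t2, _ = generate_activity_table(spec, n_random=8, seed=10)
        np.testing.assert_array_equal(t1.values(), t2.values())
        assert t1.genotypes == t2.genotypes

    def test_mismatched_coupling_shape_rejected(self):
        with pytest.raises(ValueError):
            LandscapeSpec(m=4, couplings=np.zeros((5, 2)))


class TestTableIO:
    def test_activity_table_tsv_round_trip(self, tmp_path):
        spec = random_landscape_spec(m=5, noise_sd=0.2, seed=12)
        table, _ = generate_activity_table(spec, n_random=10, seed=13)
        path = tmp_path / "screen.tsv"
        table.write_tsv(path)
        from promiscreen import ActivityTable

        loaded = ActivityTable.read_tsv(path)
        assert loaded.genotypes == table.genotypes
        assert loaded.objectives == table.objectives
        np.testing.assert_allclose(loaded.values(), table.values(), atol=1e-9)

    def test_generated_fasta_reads_back(self, tmp_path):
        from promiscreen import read_alignment

        spec = MsaSpec(n_seq=30, length=20, signature_position=7, seed=14)
        aln = generate_msa(spec)
        path = tmp_path / "msa.fasta"
        write_fasta(aln, path)
        loaded = read_alignment(path, reference_id="ref")
        assert loaded.sequences == aln.sequences
        assert loaded.column_map == aln.column_map


class TestScenario:
    def test_canonical_geometry(self):
        bundle = paper_scale_scenario(seed=0)
        assert len(bundle.table) == 29
        assert len(bundle.table.objectives) == 2
        assert bundle.table.values().size == 58
        assert bundle.landscape.activities.shape == (1024, 2)
        assert bundle.n_bootstrap == 20

    def test_fixed_seed_identical_bundle(self):
        a = paper_scale_scenario(seed=5)
        b = paper_scale_scenario(seed=5)
        assert a.table.genotypes == b.table.genotypes
        np.testing.assert_array_equal(a.table.values(), b.table.values())
        np.testing.assert_array_equal(
            a.landscape.activities, b.landscape.activities
        )
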
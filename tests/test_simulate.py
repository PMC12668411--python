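"""Synthetic-data generator: determinism, ground-truth geometry, noise
injection rates, and the homology-table construction."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from spatime import (
    SimConfig,
    generate_bead_array,
    generate_expression,
    generate_ortholog_table,
    generate_spatial_reads,
    generate_truth,
)
from spatime.simulate import BC1_LEN, BC2_LEN, bump_mean, write_whitelist


class TestBeadArray:
    def test_barcodes_unique_and_bead_oligo_length(self):
        cfg = SimConfig(n_beads=100, seed=1)
        wl = generate_bead_array(cfg)
        assert len(wl) == 100
        assert wl["barcode"].is_unique
        assert (wl["barcode"].str.len() == BC1_LEN + BC2_LEN).all()
        assert set("".join(wl["barcode"])) <= set("ACGT")

    def test_coordinates_inside_disc(self):
        cfg = SimConfig(n_beads=500, array_radius=123.0, seed=2)
        wl = generate_bead_array(cfg)
        assert (np.hypot(wl.x, wl.y) <= 123.0).all()

    def test_seeded_determinism_byte_identical_csv(self):
        cfg = SimConfig(n_beads=200, seed=3)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_whitelist(generate_bead_array(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_barcode_space_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="barcode space"):
            SimConfig(n_beads=300, bead_barcode_len=4)


class TestTruth:
    def test_pseudotime_is_one_minus_radius_ratio(self):
        cfg = SimConfig(n_cells=200, array_radius=500.0, seed=4)
        truth = generate_truth(cfg)
        for sp in (truth.species_a, truth.species_b):
            r = np.hypot(sp.positions[:, 0], sp.positions[:, 1])
            np.testing.assert_allclose(sp.pseudotime, 1 - r / 500.0, atol=1e-12)

    def test_doublet_fraction_matches_rate(self):
        cfg = SimConfig(n_cells=400, doublet_rate=0.1, seed=4)
        truth = generate_truth(cfg)
        frac = truth.species_a.doublet_labels.mean()
        assert abs(frac - 0.1 / 1.1) < 0.01  # doublets appended on top of cells

    def test_shared_responsive_pair_count(self):
        cfg = SimConfig(
            n_cells=50, n_genes=200, responsive_frac=0.5,
            shared_ortholog_frac=0.3, seed=6,
        )
        truth = generate_truth(cfg)
        assert len(truth.shared_responsive_pairs) == 30  # 0.3 * 100
        for sp in (truth.species_a, truth.species_b):
            assert sp.genes["responsive"].sum() == 100

    def test_shared_pairs_conserve_response_parameters(self):
        cfg = SimConfig(n_cells=50, n_genes=100, responsive_frac=0.4,
                        shared_ortholog_frac=1.0, seed=7)
        truth = generate_truth(cfg)
        ga = truth.species_a.genes.set_index("gene")
        gb = truth.species_b.genes.set_index("gene")
        for ma, hb in truth.shared_responsive_pairs:
            for col in ("center", "width", "amplitude", "baseline"):
                assert ga.at[ma, col] == gb.at[hb, col]

    def test_requires_a_responsive_gene_when_sharing(self):
        cfg = SimConfig(n_genes=50, responsive_frac=0.0, shared_ortholog_frac=0.5)
        with pytest.raises(ValueError, match="responsive"):
            generate_truth(cfg)


class TestExpression:
    def test_matrix_dimensions_include_doublets(self):
        cfg = SimConfig(n_cells=100, n_genes=60, doublet_rate=0.05, seed=8)
        truth = generate_truth(cfg)
        a, b = generate_expression(cfg, truth)
        assert a.shape == (105, 60)
        assert b.shape == (105, 60)
        assert a.var["mt"].sum() == round(0.05 * 60)

    def test_null_config_plants_no_responsive_genes(self):
        cfg = SimConfig(n_cells=50, n_genes=40, responsive_frac=0.0,
                        shared_ortholog_frac=0.0, seed=9)
        truth = generate_truth(cfg)
        a, _ = generate_expression(cfg, truth)
        assert not a.var["true_responsive"].any()
        assert truth.species_a.genes["center"].isna().all()

    def test_responsive_gene_tracks_its_bump_regressor(self):
        """A planted responsive gene correlates with its own bump regressor
        more strongly than 95% of flat genes do (rank-correlation oracle on
        the simulated matrix)."""
        cfg = SimConfig(
            n_cells=2000, n_genes=100, responsive_frac=0.01,
            shared_ortholog_frac=0.0, doublet_rate=0.0, seed=10,
        )
        truth = generate_truth(cfg)
        a, _ = generate_expression(cfg, truth)
        sp = truth.species_a
        resp_idx = sp.genes.index[sp.genes["responsive"]]
        assert len(resp_idx) == 1
        g = sp.genes.loc[resp_idx[0]]
        regressor = bump_mean(sp.pseudotime, g["center"], g["width"], 2.0)
        X = np.asarray(a.X)
        corrs = np.array(
            [abs(pearsonr(X[:, j], regressor).statistic) for j in range(a.n_vars)]
        )
        flat = np.delete(corrs, resp_idx[0])
        assert corrs[resp_idx[0]] > np.percentile(flat, 95)

    def test_expression_deterministic(self):
        cfg = SimConfig(n_cells=30, n_genes=20, seed=11)
        truth = generate_truth(cfg)
        a1, _ = generate_expression(cfg, truth)
        a2, _ = generate_expression(cfg, truth)
        np.testing.assert_array_equal(np.asarray(a1.X), np.asarray(a2.X))


class TestSpatialReads:
    def test_error_rates_injected_at_configured_frequencies(self):
        """Each corruption appears at its configured per-read rate within
        3 binomial standard deviations (>= 10,000 reads)."""
        cfg = SimConfig(
            n_beads=2000, n_cells=200, reads_per_cell_mean=60.0, seed=12,
        )
        truth = generate_truth(cfg)
        wl = generate_bead_array(cfg)
        reads = generate_spatial_reads(cfg, truth, wl)
        log = reads.log
        n = len(log)
        assert n >= 10_000
        er = cfg.read_error_rates
        for col, rate in [
            ("umi_has_N", er.p_umi_N),
            ("up_del", er.p_up_deletion),
            ("chimera", er.p_chimera),
        ]:
            obs = log[col].astype(bool).mean()
            sd = np.sqrt(rate * (1 - rate) / n)
            assert abs(obs - rate) <= 3 * sd, (col, obs, rate)
        obs = (log["up_subs"] > 0).mean()
        sd = np.sqrt(er.p_up_mismatch * (1 - er.p_up_mismatch) / n)
        assert abs(obs - er.p_up_mismatch) <= 3 * sd
        obs = (log["bc_subs"] > 0).mean()
        sd = np.sqrt(er.p_bc_mismatch * (1 - er.p_bc_mismatch) / n)
        assert abs(obs - er.p_bc_mismatch) <= 3 * sd

    def test_read_layout(self, small_sim):
        _, _, _, reads = small_sim
        assert all(len(s) == 16 + 12 for _, s in reads.r1)
        assert all(len(s) == 8 + 18 + 7 + 9 for _, s in reads.r2)

    def test_rejects_out_of_bounds_whitelist(self):
        cfg = SimConfig(n_beads=10, array_radius=10.0, n_cells=5, seed=13)
        truth = generate_truth(cfg)
        wl = generate_bead_array(cfg)
        wl.loc[0, "x"] = 50.0
        with pytest.raises(ValueError, match="outside array_radius"):
            generate_spatial_reads(cfg, truth, wl)

    def test_fastq_roundtrip(self, small_sim, tmp_path):
        _, _, _, reads = small_sim
        reads.write(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        lines = (tmp_path / "r1.fastq").read_text().splitlines()
        assert len(lines) == 4 * len(reads.r1)
        assert lines[0].startswith("@") and lines[2] == "+"


class TestReadSurvival:
    """Injected errors and the read filters they exercise, checked against
    the per-read truth log."""

    def _simulate(self, **rates):
        from spatime.config import ReadErrorRates

        cfg = SimConfig(
            n_beads=1500, n_cells=150, reads_per_cell_mean=50.0, seed=15,
            read_error_rates=ReadErrorRates(**rates),
        )
        truth = generate_truth(cfg)
        wl = generate_bead_array(cfg)
        return cfg, truth, wl

    def test_error_free_reads_all_survive(self):
        from spatime import parse_spatial_reads

        cfg, truth, wl = self._simulate(
            p_umi_N=0, p_up_mismatch=0, p_up_deletion=0, p_bc_mismatch=0, p_chimera=0
        )
        reads = generate_spatial_reads(cfg, truth, wl)
        m = parse_spatial_reads(reads.r1, reads.r2, wl, truth.species_a.barcodes)
        assert m.provenance["pass"] == m.provenance["total"]

    def test_certain_umi_corruption_kills_every_read(self):
        from spatime import parse_spatial_reads

        cfg, truth, wl = self._simulate(
            p_umi_N=1, p_up_mismatch=0, p_up_deletion=0, p_bc_mismatch=0, p_chimera=0
        )
        reads = generate_spatial_reads(cfg, truth, wl)
        m = parse_spatial_reads(reads.r1, reads.r2, wl, truth.species_a.barcodes)
        assert m.provenance["pass"] == 0
        assert m.provenance["umi_N"] == m.provenance["total"]

    def test_survival_equals_product_of_per_filter_pass_rates(self):
        """With per-read-independent corruptions (no chimeras, no
        duplicate reads) the joint survival fraction factorizes into the
        per-filter pass rates, counted independently on the read log."""
        from spatime import parse_spatial_reads

        cfg, truth, wl = self._simulate(p_chimera=0)
        reads = generate_spatial_reads(cfg, truth, wl, dup_mean=0.0)
        m = parse_spatial_reads(reads.r1, reads.r2, wl, truth.species_a.barcodes)
        log = reads.log
        n = len(log)
        f1 = (~log.umi_has_N).mean()
        f2 = (
            ((log.up_del == 0) & (log.up_subs <= 2))
            | ((log.up_del == 1) & (log.up_subs == 0))
        ).mean()
        f3 = (log.bc_subs <= 1).mean()
        observed = m.provenance["pass"] / n
        predicted = f1 * f2 * f3
        assert abs(observed - predicted) <= 3 * np.sqrt(predicted * (1 - predicted) / n)


class TestOrthologTable:
    def test_strict_and_violating_classes(self):
        cfg = SimConfig(n_cells=20, n_genes=80, seed=14)
        truth = generate_truth(cfg)
        table = generate_ortholog_table(cfg, truth, n_one_to_many=10, n_many_to_one=7)
        counts = table.groupby("DB Class Key").size()
        assert (counts == 2).sum() == len(truth.ortholog_pairs)
        assert (counts == 3).sum() == 17
        assert set(table["Common Organism Name"]) == {"mouse, laboratory", "human"}
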
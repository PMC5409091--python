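"""Generators: annotation flattening, genotypes, expression, GWAS, junctions."""

import numpy as np
import pandas as pd
import pytest

from cceqtl import ExpressionMatrix, GeneModel, SimulationConfig, eqtl_map, simgen


def gm(gene_id, transcripts, chrom="chr1", strand="+"):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     transcripts=transcripts)


class TestFlattenAnnotation:
    def test_disjoint_exons_pass_through(self):
        metas = simgen.flatten_annotation(
            [gm("g", [("t1", [(100, 200), (300, 400)])])]
        )
        assert [m.interval for m in metas] == [(100, 200), (300, 400)]
        assert all(m.member_transcripts == ["t1"] for m in metas)
        assert [m.index for m in metas] == [1, 2]

    def test_breakpoint_splitting_with_membership(self):
        # overlapping exons [100,200] and [150,250] cut at every boundary
        metas = simgen.flatten_annotation(
            [gm("g", [("t1", [(100, 200)]), ("t2", [(150, 250)])])]
        )
        assert [m.interval for m in metas] == [(100, 149), (150, 200), (201, 250)]
        assert [m.member_transcripts for m in metas] == [
            ["t1"], ["t1", "t2"], ["t2"]
        ]

    def test_union_mode_merges_overlap(self):
        metas = simgen.flatten_annotation(
            [gm("g", [("t1", [(100, 200)]), ("t2", [(150, 250)])])],
            split_at_breakpoints=False,
        )
        assert [m.interval for m in metas] == [(100, 250)]

    def test_transcript_unique_unit_exists_iff_unique_bp(self):
        # t1 covers bp no other transcript covers -> a t1-only unit exists
        metas = simgen.flatten_annotation(
            [gm("g", [("t1", [(100, 300)]), ("t2", [(100, 200)])])]
        )
        only_t1 = [m for m in metas if m.member_transcripts == ["t1"]]
        assert only_t1 and only_t1[0].interval == (201, 300)
        # identical transcripts -> no unique unit
        metas2 = simgen.flatten_annotation(
            [gm("g", [("t1", [(100, 200)]), ("t2", [(100, 200)])])]
        )
        assert not any(len(m.member_transcripts) == 1 for m in metas2)

    def test_total_bp_equals_union_bp(self, rng):
        # random transcript structures conserve exonic base pairs exactly
        for _ in range(20):
            txs = []
            for t in range(rng.integers(1, 4)):
                starts = np.sort(rng.choice(np.arange(100, 2000, 10), size=3,
                                            replace=False))
                exons = [(int(s), int(s + rng.integers(5, 120))) for s in starts]
                merged = []
                for s, e in sorted(exons):
                    if merged and s <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                    else:
                        merged.append((s, e))
                txs.append((f"t{t}", merged))
            gene = gm("g", txs)
            metas = simgen.flatten_annotation([gene])
            covered = set()
            for _, exons in txs:
                for s, e in exons:
                    covered.update(range(s, e + 1))
            assert sum(len(m) for m in metas) == len(covered)
            # meta-exons are pairwise disjoint
            seen = set()
            for m in metas:
                unit = set(range(m.interval[0], m.interval[1] + 1))
                assert not unit & seen
                seen |= unit

    def test_empty_transcripts_raise(self):
        with pytest.raises(ValueError, match="gX"):
            simgen.flatten_annotation(
                [GeneModel("gX", "chr1", "+", transcripts=[])]
            )


class TestGeneFromExons:
    def _exon_matrix(self, values, gene_ids):
        feats = pd.DataFrame(
            {"gene_id": gene_ids, "chrom": "chr1",
             "start": range(1, len(gene_ids) + 1), "end": range(2, len(gene_ids) + 2)},
            index=pd.Index([f"e{i}" for i in range(len(gene_ids))], name="feature_id"),
        )
        vals = pd.DataFrame(values, columns=feats.index, index=["s1"])
        return ExpressionMatrix(values=vals, features=feats)

    def test_sum_identity_and_permutation(self):
        em = self._exon_matrix([[3.0, 5.0, 2.0]], ["g1", "g1", "g1"])
        out = simgen.gene_from_exons(em)
        assert out.values.loc["s1", "g1"] == 10.0
        perm = ExpressionMatrix(
            values=em.values[["e2", "e0", "e1"]],
            features=em.features.loc[["e2", "e0", "e1"]],
        )
        assert simgen.gene_from_exons(perm).values.loc["s1", "g1"] == 10.0

    def test_single_exon_gene_is_identity(self):
        em = self._exon_matrix([[4.5]], ["g1"])
        assert simgen.gene_from_exons(em).values.loc["s1", "g1"] == 4.5

    def test_missing_gene_id_errors(self):
        em = self._exon_matrix([[1.0]], [None])
        with pytest.raises(ValueError, match="gene_id"):
            simgen.gene_from_exons(em)


class TestSimulateGenotypes:
    def test_determinism(self):
        cfg = SimulationConfig(seed=5, n_individuals=100, n_snps=20)
        a = simgen.simulate_genotypes(cfg)
        b = simgen.simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert [s.id for s in a.snps] == [s.id for s in b.snps]

    def test_ld_zero_gives_uncorrelated_neighbours(self):
        cfg = SimulationConfig(seed=6, n_individuals=500, n_snps=501,
                               ld_decay=0.0)
        panel = simgen.simulate_genotypes(cfg)
        D = panel.dosages
        rs = [np.corrcoef(D[:, j], D[:, j + 1])[0, 1] for j in range(500)]
        assert abs(np.mean(rs)) < 3 / np.sqrt(500 * cfg.n_individuals) * 10
        assert np.mean(np.abs(rs)) < 3 / np.sqrt(cfg.n_individuals)

    def test_ld_target_hit_at_09(self):
        cfg = SimulationConfig(seed=7, n_individuals=2000, n_snps=120,
                               ld_decay=0.9, maf_range=(0.2, 0.5))
        panel = simgen.simulate_genotypes(cfg)
        D = panel.dosages
        rs = [np.corrcoef(D[:, j], D[:, j + 1])[0, 1] for j in range(119)]
        assert abs(np.mean(rs) - 0.9) < 0.05

    def test_dosage_mean_matches_allele_frequency(self):
        cfg = SimulationConfig(seed=8, n_individuals=1000, n_snps=50)
        panel = simgen.simulate_genotypes(cfg)
        for j, rec in enumerate(panel.snps):
            p_emp = panel.dosages[:, j].mean() / 2
            p_target = rec.maf if p_emp <= 0.5 else 1 - rec.maf
            se = np.sqrt(p_target * (1 - p_target) / (2 * cfg.n_individuals))
            assert abs(p_emp - p_target) < 3 * se + 1e-9

    def test_too_few_snps_errors(self):
        with pytest.raises(ValueError):
            simgen.simulate_genotypes(SimulationConfig(seed=1, n_snps=1))


class TestSimulateExpression:
    def test_null_type_one_error_calibrated(self):
        cfg = SimulationConfig(seed=9, n_individuals=300, n_snps=10,
                               effect_size_r2=0.0, n_genes=1, exons_per_gene=1)
        panel = simgen.simulate_genotypes(cfg)
        g = panel.dosage(panel.snp_ids[5])
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(300, 1000))
        res = eqtl_map.bulk_associate(g, Y)
        frac = float((res["p"][0] < 0.05).mean())
        ci = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < ci

    def test_exon_specific_layout_hits_only_target(self):
        # Bonferroni over 5 exons; null exons each clear it w.p. 0.99, so the
        # per-replicate success probability is ~0.96 by construction
        wins = 0
        reps = 50
        for rep in range(reps):
            cfg = SimulationConfig(seed=100 + rep, n_individuals=800,
                                   n_snps=20, effect_size_r2=0.1,
                                   n_genes=1, exons_per_gene=5)
            panel = simgen.simulate_genotypes(cfg)
            genes = simgen.make_gene_models(cfg)
            snp = panel.snp_ids[10]
            expr, truth = simgen.simulate_expression(
                panel, genes, cfg, causal={"G1": snp},
                layout="exon_specific", target_exons=[3],
            )
            assert set(truth["feature_id"]) == {"G1:me3"}
            res = eqtl_map.bulk_associate(
                panel.dosage(snp), expr.values.to_numpy()
            )
            p = res["p"][0]
            hit = {f: p[j] < 0.05 / len(p)
                   for j, f in enumerate(expr.feature_ids)}
            wins += hit["G1:me3"] and not any(
                v for f, v in hit.items() if f != "G1:me3"
            )
        assert wins >= 0.9 * reps

    def test_whole_gene_layout_shifts_gene_sum(self):
        cfg = SimulationConfig(seed=11, n_individuals=800, n_snps=20,
                               effect_size_r2=0.1, n_genes=1, exons_per_gene=4)
        panel = simgen.simulate_genotypes(cfg)
        genes = simgen.make_gene_models(cfg)
        snp = panel.snp_ids[10]
        expr, _ = simgen.simulate_expression(
            panel, genes, cfg, causal={"G1": snp}, layout="whole_gene"
        )
        gene = simgen.gene_from_exons(expr)
        res_e = eqtl_map.bulk_associate(panel.dosage(snp), expr.values.to_numpy())
        res_g = eqtl_map.bulk_associate(panel.dosage(snp), gene.values.to_numpy())
        if (res_e["p"][0] < 0.05).all():
            assert res_g["p"][0, 0] < 0.05

    def test_invalid_r2_errors(self):
        cfg = SimulationConfig(seed=1, n_individuals=50, n_snps=5)
        panel = simgen.simulate_genotypes(cfg)
        cfg.effect_size_r2 = 1.0  # bypass construction-time validation
        with pytest.raises(ValueError):
            simgen.simulate_expression(panel, simgen.make_gene_models(cfg), cfg)

    def test_truth_table_recovery(self):
        """Best cis-eQTL recovers the causal SNP (or a tight proxy) in >=90%
        of replicates at n=800, r2=0.1."""
        wins = 0
        reps = 200
        for rep in range(reps):
            cfg = SimulationConfig(seed=300 + rep, n_individuals=800,
                                   n_snps=100, effect_size_r2=0.1,
                                   n_genes=1, exons_per_gene=1)
            panel = simgen.simulate_genotypes(cfg)
            causal = panel.snp_ids[50]
            g = panel.dosage(causal)
            y = np.sqrt(0.1 / 0.9) / g.std() * g + \
                np.random.default_rng(rep).normal(size=800)
            res = eqtl_map.bulk_associate(panel.dosages, y)
            best = int(np.argmin(res["p"][:, 0]))
            r2 = np.corrcoef(g, panel.dosages[:, best])[0, 1] ** 2
            wins += (panel.snp_ids[best] == causal) or (r2 > 0.8)
        assert wins >= 0.9 * reps


class TestSimulateGwas:
    def test_determinism_and_p_consistency(self, small_panel):
        a = simgen.simulate_gwas(small_panel, None, 0.0, 1000,
                                 rng=np.random.default_rng(3))
        b = simgen.simulate_gwas(small_panel, None, 0.0, 1000,
                                 rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a.stats, b.stats)
        from scipy import stats as st
        z = a.stats.beta / a.stats.se
        p_expected = 2 * st.norm.sf(np.abs(z))
        assert np.allclose(a.stats.p, p_expected, rtol=1e-6)

    def test_null_max_z_rate(self):
        cfg = SimulationConfig(seed=12, n_individuals=400, n_snps=100,
                               ld_decay=0.0)
        panel = simgen.simulate_genotypes(cfg)
        rng = np.random.default_rng(13)
        hits = 0
        reps = 500
        for _ in range(reps):
            gw = simgen.simulate_gwas(panel, None, 0.0, 5000, rng=rng)
            hits += (gw.stats.beta / gw.stats.se).abs().max() > 3.29
        # nominal 1-(1-0.001)^100 = 0.095; empirical panel LD trims the
        # effective number of tests slightly
        assert 0.05 < hits / reps < 0.14

    def test_strong_signal_localizes_to_causal(self):
        hits = 0
        reps = 60
        rng = np.random.default_rng(14)
        for rep in range(reps):
            cfg = SimulationConfig(seed=400 + rep, n_individuals=500,
                                   n_snps=60, ld_decay=0.8)
            panel = simgen.simulate_genotypes(cfg)
            causal = panel.snp_ids[30]
            lam = 12.0 / np.sqrt(5000)  # z_causal ~ 12
            gw = simgen.simulate_gwas(panel, causal, lam, 5000, rng=rng)
            z = (gw.stats.beta / gw.stats.se).abs()
            top = z.idxmax()
            r2 = np.corrcoef(panel.dosage(causal), panel.dosage(top))[0, 1] ** 2
            hits += (top == causal) or (r2 > 0.8)
        assert hits >= 0.95 * reps


class TestSimulateJunctions:
    def _gene(self, cfg):
        return simgen.make_gene_models(cfg)[0]

    def test_counts_conserve_multinomial_total(self):
        cfg = SimulationConfig(seed=15, n_individuals=100, n_snps=5)
        panel = simgen.simulate_genotypes(cfg)
        fwd, rev, _ = simgen.simulate_junctions(
            panel, self._gene(cfg), panel.snp_ids[2], 0.4, 30,
            rng=np.random.default_rng(16),
        )
        for tab in (fwd, rev):
            totals = tab.counts.sum(axis=1)
            assert (tab.counts >= 0).all().all()
            assert (totals == tab.counts.iloc[:, 0] + tab.counts.iloc[:, 1]).all()

    def test_usage_shift_monotone_across_dosage_groups(self):
        cfg = SimulationConfig(seed=17, n_individuals=900, n_snps=5,
                               maf_range=(0.35, 0.45))
        panel = simgen.simulate_genotypes(cfg)
        snp = panel.snp_ids[2]
        fwd, _, _ = simgen.simulate_junctions(
            panel, self._gene(cfg), snp, 0.8, 50,
            rng=np.random.default_rng(18),
        )
        frac = fwd.counts.iloc[:, 0] / fwd.counts.sum(axis=1)
        d = panel.dosage(snp)
        means = [frac[d == k].mean() for k in (0, 1, 2)]
        assert means[0] < means[1] < means[2]

    def test_null_shift_calibrated(self):
        cfg = SimulationConfig(seed=19, n_individuals=200, n_snps=5)
        panel = simgen.simulate_genotypes(cfg)
        snp = panel.snp_ids[2]
        g = panel.dosage(snp)
        rng = np.random.default_rng(20)
        hits = 0
        reps = 500
        for _ in range(reps):
            fwd, _, _ = simgen.simulate_junctions(
                panel, self._gene(cfg), None, 0.0, 30, rng=rng
            )
            tot = fwd.counts.sum(axis=1)
            frac = (fwd.counts.iloc[:, 0] / tot.where(tot > 0)).to_numpy()
            res = eqtl_map.bulk_associate(g, frac[:, None])
            hits += res["p"][0, 0] < 0.05
        ci = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < ci + 0.01

    def test_single_transcript_gene_errors(self):
        cfg = SimulationConfig(seed=21, n_individuals=50, n_snps=5)
        panel = simgen.simulate_genotypes(cfg)
        gene = GeneModel("g", "chr1", "+", [("t1", [(100, 200), (300, 400)])])
        with pytest.raises(ValueError):
            simgen.simulate_junctions(panel, gene, None, 0.0, 30)


class TestAddTagSnp:
    def test_tag_is_tight_proxy(self, small_panel):
        target = small_panel.snp_ids[25]
        panel = simgen.add_tag_snp(small_panel, target, flip_prob=0.02,
                                   rng=np.random.default_rng(2))
        r = np.corrcoef(panel.dosage(target), panel.dosage("rs_tag"))[0, 1]
        assert r**2 > 0.85
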
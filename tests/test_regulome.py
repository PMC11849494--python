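import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from integrinscore.config import RunConfig
from integrinscore.regulome import (
    _in_promoter,
    build_regulatory_network,
    cnv_expression_association,
    filter_mirna_cascade,
    map_probes_to_promoters,
    methylation_screen,
    passes_correlation_filter,
    spearman,
    tf_screen,
)

from _oracles import spearman_oracle


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=30)
        rho, p, n = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_exact_negative(self):
        x = np.arange(10.0)
        rho, _, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_tie_heavy_matches_rank_formula_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 3.0, 9.0, 5.0, np.nan])
        _, _, n = spearman(x, y)
        assert n == 3

    def test_constant_after_filtering_errors(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_permutation_p_close_to_t_p(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        _, pt, _ = spearman(x, y)
        _, pp, _ = spearman(x, y, p_method="permutation", n_perm=2000, seed=0)
        assert pp == pytest.approx(pt, abs=0.05)

    @given(st.integers(0, 1000))
    def test_monotone_invariance_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, _, _ = spearman(x, y)
        r2, _, _ = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_null_calibration_of_t_approximation(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            _, p, _ = spearman(rng.normal(size=50), rng.normal(size=50))
            hits += p < 0.05
        assert 0.025 <= hits / reps <= 0.075


class TestFilterPredicate:
    @pytest.mark.parametrize(
        "rho,p,rho_min,p_max,expected",
        [
            (0.149, 0.01, 0.15, 0.05, False),  # below inclusive magnitude cut
            (0.15, 0.01, 0.15, 0.05, True),  # exactly at cut: kept (>=)
            (-0.15, 0.01, 0.15, 0.05, True),  # magnitude rule is two-sided
            (0.2, 0.009, 0.2, 0.01, True),  # rho boundary inclusive for TF rule
            (0.5, 0.05, 0.15, 0.05, False),  # p boundary strict
        ],
    )
    def test_inclusive_rho_strict_p(self, rho, p, rho_min, p_max, expected):
        assert passes_correlation_filter(rho, p, rho_min, p_max) is expected


class TestPromoterMapping:
    def test_window_membership_plus_strand(self):
        assert _in_promoter(4200, 5000, "+")  # 800 bp upstream
        assert not _in_promoter(5300, 5000, "+")  # 300 bp downstream: outside
        assert _in_promoter(4000, 5000, "+")  # exactly 1000 upstream: inside
        assert not _in_promoter(5200, 5000, "+")  # exactly 200 downstream: outside

    def test_window_strand_antisymmetric(self, rng):
        for _ in range(50):
            tss = int(rng.integers(10_000, 50_000))
            pos = int(tss + rng.integers(-2000, 2000))
            mirrored = 2 * tss - pos
            assert _in_promoter(pos, tss, "+") == _in_promoter(mirrored, tss, "-")

    def test_highest_mean_beta_probe_selected(self):
        tss = pd.DataFrame(
            [{"gene": "G1", "chrom": "chr1", "tss": 5000, "strand": "+"}]
        )
        probes = pd.DataFrame(
            [
                {"probe": "pA", "chrom": "chr1", "pos": 4500},
                {"probe": "pB", "chrom": "chr1", "pos": 4600},
                {"probe": "pC", "chrom": "chr1", "pos": 9000},  # outside window
            ]
        )
        beta = pd.DataFrame(
            {"S1": {"pA": 0.3, "pB": 0.7, "pC": 0.9}, "S2": {"pA": 0.3, "pB": 0.7, "pC": 0.9}}
        )
        pmap = map_probes_to_promoters(probes, tss, beta)
        assert pmap.probe_for("G1") == "pB"
        assert pmap.table["n_candidates"].iloc[0] == 2

    def test_tie_resolves_to_smaller_coordinate(self):
        tss = pd.DataFrame([{"gene": "G1", "chrom": "chr1", "tss": 5000, "strand": "+"}])
        probes = pd.DataFrame(
            [
                {"probe": "far", "chrom": "chr1", "pos": 4900},
                {"probe": "near", "chrom": "chr1", "pos": 4400},
            ]
        )
        beta = pd.DataFrame({"S1": {"far": 0.5, "near": 0.5}, "S2": {"far": 0.5, "near": 0.5}})
        pmap = map_probes_to_promoters(probes, tss, beta)
        assert pmap.probe_for("G1") == "near"

    def test_unknown_chromosome_warns_empty_errors(self):
        tss = pd.DataFrame([{"gene": "G1", "chrom": "chr1", "tss": 5000, "strand": "+"}])
        probes = pd.DataFrame([{"probe": "p", "chrom": "chrUn", "pos": 4500}])
        beta = pd.DataFrame({"S1": {"p": 0.5}, "S2": {"p": 0.5}})
        with pytest.warns(UserWarning, match="chrUn"):
            with pytest.raises(ValueError, match="no gene"):
                map_probes_to_promoters(probes, tss, beta)


def _planted_pair_matrices(rng, n_cancers=7, n=60, rho_strong=True):
    """miRNA/gene matrices where miR-i tracks gene Gi strongly in every cancer."""
    genes = ["G0", "G1", "G2"]
    mirnas = ["miR-0", "miR-1", "miR-2", "miR-weak"]
    cols, labels = [], {}
    gene_cols, mirna_cols = [], []
    for c in range(n_cancers):
        cancer = f"C{c}"
        base = rng.normal(size=(3, n))
        g = np.exp(base + 2)
        m = np.vstack([np.exp(-base + 1), np.exp(rng.normal(size=(1, n)))])
        names = [f"{cancer}-S{i}" for i in range(n)]
        cols += names
        labels.update({s: cancer for s in names})
        gene_cols.append(pd.DataFrame(g, index=genes, columns=names))
        mirna_cols.append(pd.DataFrame(m, index=mirnas, columns=names))
    return (
        pd.concat(mirna_cols, axis=1),
        pd.concat(gene_cols, axis=1),
        pd.Series(labels),
    )


class TestMirnaCascade:
    def test_constructed_fixture_returns_exactly_validated_pairs(self, rng):
        mirna, gene, labels = _planted_pair_matrices(rng)
        validated = pd.DataFrame(
            {"feature": ["miR-0", "miR-2"], "gene": ["G0", "G2"]}
        )
        cfg = RunConfig(mirna_min_samples=200, mirna_min_cancers=5)
        rec, final = filter_mirna_cascade(mirna, gene, labels, validated, cfg)
        # 3 planted strong pairs survive stage 2; only the 2 validated survive stage 3
        assert set(map(tuple, final.values)) == {("miR-0", "G0"), ("miR-2", "G2")}
        passed = rec[rec["stage3_validated"]]
        assert passed["stage2_multicancer"].all()
        assert passed["stage1_expressed"].all()

    def test_expression_count_boundary_strictly_more_than(self, rng):
        # miRNA above threshold in exactly N samples is dropped; N+1 is kept
        n = 600
        cols = [f"S{i}" for i in range(n)]
        labels = pd.Series("C0", index=cols)
        gene = pd.DataFrame(
            np.exp(rng.normal(size=(1, n))), index=["G0"], columns=cols
        )
        base = np.full(n, 0.5)
        exactly = base.copy()
        exactly[:500] = 2.0
        above = base.copy()
        above[:501] = 2.0
        mirna = pd.DataFrame([exactly, above], index=["miR-eq", "miR-gt"], columns=cols)
        cfg = RunConfig(mirna_min_cancers=0)
        rec, _ = filter_mirna_cascade(mirna, gene, labels, None, cfg)
        assert "miR-eq" not in set(rec["feature"])
        assert "miR-gt" in set(rec["feature"])

    def test_cancer_count_boundary_strictly_more_than(self, rng):
        # pair significant in exactly 5 of 7 cancers fails; 6 passes
        mirna, gene, labels = _planted_pair_matrices(rng)
        cancers = sorted(labels.unique())
        # destroy the miR-1 ~ G1 link in 2 cancers -> significant in only 5
        for cancer in cancers[:2]:
            cols = labels.index[labels == cancer]
            mirna.loc["miR-1", cols] = np.exp(rng.normal(size=len(cols)))
        cfg = RunConfig(mirna_min_samples=200, mirna_min_cancers=5)
        rec, final = filter_mirna_cascade(mirna, gene, labels, None, cfg)
        pairs = set(map(tuple, final.values))
        assert ("miR-1", "G1") not in pairs  # exactly 5 cancers: dropped
        assert ("miR-0", "G0") in pairs  # 7 cancers: kept
        counts = rec.groupby(["feature", "gene"])["significant"].sum()
        assert counts[("miR-1", "G1")] == 5

    def test_empty_validated_table_warns_and_skips_stage3(self, rng):
        mirna, gene, labels = _planted_pair_matrices(rng)
        cfg = RunConfig(mirna_min_samples=200, mirna_min_cancers=5)
        with pytest.warns(UserWarning, match="SKIPPED"):
            _, final = filter_mirna_cascade(mirna, gene, labels, None, cfg)
        assert len(final) == 3  # stage-2 survivors pass through unvalidated


class TestMethylationScreen:
    def test_planted_negative_pair_flagged(self, rng):
        n = 300
        cols = [f"S{i}" for i in range(n)]
        labels = pd.Series("C0", index=cols)
        g = rng.normal(size=n)
        expr = pd.DataFrame([np.exp(g + 2)], index=["G0"], columns=cols)
        beta = pd.DataFrame([1 / (1 + np.exp(g))], index=["p0"], columns=cols)
        tssdf = pd.DataFrame([{"gene": "G0", "chrom": "chr1", "tss": 5000, "strand": "+"}])
        probes = pd.DataFrame([{"probe": "p0", "chrom": "chr1", "pos": 4500}])
        pmap = map_probes_to_promoters(probes, tssdf, beta)
        rec = methylation_screen(pmap, beta, expr, labels)
        assert rec["significant"].iloc[0]
        assert rec["rho"].iloc[0] < -0.5

    def test_null_pairs_rarely_flagged(self, rng):
        n = 200
        cols = [f"S{i}" for i in range(n)]
        labels = pd.Series("C0", index=cols)
        k = 10  # independent gene-probe pairs per seed
        genes = [f"G{i}" for i in range(k)]
        tssdf = pd.DataFrame(
            [{"gene": g, "chrom": "chr1", "tss": 5000 + 50_000 * i, "strand": "+"}
             for i, g in enumerate(genes)]
        )
        probes = pd.DataFrame(
            [{"probe": f"p{i}", "chrom": "chr1", "pos": 4500 + 50_000 * i}
             for i in range(k)]
        )
        flagged = total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            expr = pd.DataFrame(np.exp(r.normal(size=(k, n))), index=genes, columns=cols)
            beta = pd.DataFrame(
                1 / (1 + np.exp(r.normal(size=(k, n)))),
                index=[f"p{i}" for i in range(k)],
                columns=cols,
            )
            pmap = map_probes_to_promoters(probes, tssdf, beta)
            rec = methylation_screen(pmap, beta, expr, labels)
            flagged += int(rec["significant"].sum())
            total += len(rec)
        assert flagged / total <= 0.08


class TestTfScreen:
    def test_planted_positive_pair_and_top_ranking(self, rng):
        n = 120
        cols = [f"S{i}" for i in range(n)]
        labels = pd.Series("C0", index=cols)
        base = rng.normal(size=n)
        expr = pd.DataFrame(
            {
                "TFbig": np.exp(base + 2),
                "G0": np.exp(0.7 * base + rng.normal(size=n) * 0.7),
                "G1": np.exp(rng.normal(size=n)),
                "TFsmall": np.exp(rng.normal(size=n)),
            }
        ).T
        expr.columns = cols
        pairs = pd.DataFrame(
            {
                "tf": ["TFbig"] * 6 + ["TFsmall"] * 2,
                "target": ["G0", "G1", "SIGa", "SIGb", "SIGc", "SIGd", "G1", "SIGa"],
            }
        )
        signature = ["G0", "G1", "SIGa", "SIGb", "SIGc", "SIGd"]
        rec, top = tf_screen(pairs, expr, labels, signature)
        hit = rec[(rec["feature"] == "TFbig") & (rec["gene"] == "G0")]
        assert hit["significant"].iloc[0] and hit["rho"].iloc[0] > 0
        assert top["tf"].iloc[0] == "TFbig"  # 6 signature targets vs 2
        assert top["n_signature_targets"].iloc[0] == 6

    def test_absent_tf_skipped_with_warning(self, rng):
        n = 50
        cols = [f"S{i}" for i in range(n)]
        expr = pd.DataFrame([np.exp(rng.normal(size=n))], index=["G0"], columns=cols)
        pairs = pd.DataFrame({"tf": ["GHOST"], "target": ["G0"]})
        with pytest.warns(UserWarning, match="GHOST"):
            rec, _ = tf_screen(pairs, expr, pd.Series("C0", index=cols), ["G0"])
        assert rec.empty


class TestCnvAssociation:
    def test_all_diploid_skipped_with_warning(self, rng):
        cols = [f"S{i}" for i in range(30)]
        states = pd.DataFrame([["diploid"] * 30], index=["G0"], columns=cols)
        expr = pd.DataFrame([np.exp(rng.normal(size=30))], index=["G0"], columns=cols)
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = cnv_expression_association(states, expr)
        assert out.empty

    def test_planted_shift_detected(self, rng):
        n = 500
        cols = [f"S{i}" for i in range(n)]
        states = np.array(["amplification"] * 100 + ["diploid"] * 300 + ["deletion"] * 100)
        shift = np.where(states == "amplification", 1.0, np.where(states == "deletion", -1.0, 0))
        expr = pd.DataFrame([np.exp(rng.normal(size=n) + shift)], index=["G0"], columns=cols)
        out = cnv_expression_association(
            pd.DataFrame([states], index=["G0"], columns=cols), expr
        )
        assert out["kruskal_p"].iloc[0] < 0.01
        assert out["median_amplification"].iloc[0] > out["median_diploid"].iloc[0]
        assert out["median_diploid"].iloc[0] > out["median_deletion"].iloc[0]


class TestNetwork:
    def test_assembly_and_dedup(self):
        mirna = pd.DataFrame(
            {"feature": ["m1", "m2", "m1"], "gene": ["G1", "G2", "G1"], "rho": [-0.5, -0.4, -0.5]}
        )
        tf = pd.DataFrame({"feature": ["T1"], "gene": ["G1"], "rho": [0.6]})
        links = pd.DataFrame({"mirna": ["m1"], "tf": ["T1"]})
        net = build_regulatory_network(mirna, tf, links)
        assert len(net) == 4  # duplicate m1-G1 collapsed
        assert set(net["source_type"]) == {"miRNA", "TF"}

    def test_empty_inputs_give_empty_network(self):
        net = build_regulatory_network(pd.DataFrame(), pd.DataFrame(), None)
        assert net.empty
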
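"""Single-variant association, screens, the scan, clumping, annotation, Q-Q."""

import numpy as np
import pandas as pd
import pytest

from hostmicrobe import (
    AbundanceTable,
    AssociationRecord,
    GeneInterval,
    GenomeWideScan,
    TargetedScreen,
    VariantRecord,
    annotate_genes,
    bonferroni_threshold,
    clump_associations,
    encode_genotype,
    linear_assoc,
    qq_points,
    targeted_screen,
)
from hostmicrobe.variant_assoc import build_covariates


def _record(pos, p, feature="sp", chrom="chrS"):
    return AssociationRecord(
        VariantRecord(chrom, pos, f"v{pos}"), feature, "stool",
        beta=0.1, t_stat=1.0, p=p, n=100, df=98,
    )


class TestEncodeGenotype:
    @pytest.mark.parametrize(
        "dosage,model,expected",
        [
            (2.0, "recessive_alt", 1.0),
            (1.0, "recessive_alt", 0.0),
            (0.0, "recessive_alt", 0.0),
            (1.0, "additive", 1.0),
            (2.0, "additive", 2.0),
        ],
    )
    def test_encodings(self, dosage, model, expected):
        assert encode_genotype(dosage, model) == expected

    def test_missing_propagates(self):
        assert np.isnan(encode_genotype(float("nan"), "recessive_alt"))

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            encode_genotype(3.0, "additive")

    def test_vectorized_recessive(self):
        g = np.array([0.0, 1.0, 2.0, np.nan])
        out = encode_genotype(g, "recessive_alt")
        np.testing.assert_array_equal(out[:3], [0.0, 0.0, 1.0])
        assert np.isnan(out[3])


class TestLinearAssoc:
    def test_matches_statsmodels_full_design_ols(self):
        """Residual-correlation t-test equals the OLS coefficient test on g in
        the full model, to <= 1e-10 relative error."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for rep in range(5):
            n = 150
            C = np.column_stack([
                rng.integers(0, 2, n).astype(float),
                rng.normal(size=n),
                rng.normal(size=n),
            ])
            g = rng.binomial(2, 0.4, n).astype(float)
            y = 0.3 * g + C @ [0.5, -1.0, 0.2] + rng.normal(size=n)
            rec = linear_assoc(y, g, C)
            X = sm.add_constant(np.column_stack([C, g]))
            fit = sm.OLS(y, X).fit()
            assert rec.beta == pytest.approx(fit.params[-1], rel=1e-10)
            assert rec.t_stat == pytest.approx(fit.tvalues[-1], rel=1e-10)
            assert rec.p == pytest.approx(fit.pvalues[-1], rel=1e-8)
            assert rec.df == int(fit.df_resid)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        n = 100
        ps = []
        for _ in range(500):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = rng.normal(size=n)
            ps.append(linear_assoc(y, g, None).p)
        ps = np.asarray(ps)
        assert abs((ps < 0.05).mean() - 0.05) < 0.03
        assert abs(ps.mean() - 0.5) < 0.04

    def test_beta_recovery(self):
        rng = np.random.default_rng(2)
        n = 200
        g = rng.binomial(2, 0.5, n).astype(float)
        y = 0.5 * g + rng.normal(scale=0.1, size=n)
        rec = linear_assoc(y, g, None)
        assert rec.beta == pytest.approx(0.5, abs=0.05)

    def test_covariate_equal_to_genotype_rejected(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, 50).astype(float)
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            linear_assoc(y, g, g.copy())

    def test_rank_deficient_covariates_name_columns(self):
        rng = np.random.default_rng(4)
        n = 60
        c0 = rng.normal(size=n)
        C = np.column_stack([c0, 2 * c0])
        with pytest.raises(ValueError, match="columns \\[1\\]"):
            linear_assoc(rng.normal(size=n), rng.binomial(2, 0.5, n).astype(float), C)

    def test_constant_genotype_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="constant"):
            linear_assoc(rng.normal(size=30), np.ones(30), None)

    def test_complete_case_deletion(self):
        rng = np.random.default_rng(6)
        n = 80
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.4 * g + rng.normal(size=n)
        y_nan = y.copy()
        y_nan[:10] = np.nan
        rec_full = linear_assoc(y[10:], g[10:], None)
        rec_nan = linear_assoc(y_nan, g, None)
        assert rec_nan.n == n - 10
        assert rec_nan.t_stat == pytest.approx(rec_full.t_stat, rel=1e-12)


def _screen_table(Y, donors):
    frame = pd.DataFrame(
        Y, index=donors, columns=[f"sp{j}" for j in range(Y.shape[1])]
    )
    return AbundanceTable(frame, {d: d for d in donors}, "stool",
                         kind="species", transformed=True)


class TestTargetedScreen:
    def test_identical_group_means_give_p_one(self):
        donors = [f"d{i}" for i in range(8)]
        y = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        g = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        t = _screen_table(y[:, None], donors)
        out = targeted_screen(t, g, donors, test="t_test")
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_small_group_skipped_with_warning(self):
        donors = [f"d{i}" for i in range(6)]
        g = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
        t = _screen_table(np.random.default_rng(7).normal(size=(6, 1)), donors)
        with pytest.warns(UserWarning, match="skipped"):
            out = targeted_screen(t, g, donors, test="t_test")
        assert len(out) == 0

    def test_null_min_p_order_statistic_behaviour(self):
        """118 null features: median minimum p across repeats near 1/119."""
        rng = np.random.default_rng(8)
        n, m = 60, 118
        donors = [f"d{i}" for i in range(n)]
        min_ps = []
        for _ in range(40):
            g = rng.binomial(2, 0.4, n).astype(float)
            Y = rng.normal(size=(n, m))
            out = targeted_screen(_screen_table(Y, donors), g, donors,
                                  test="regression")
            min_ps.append(out["p"].min())
        # min of m uniforms ~ Beta(1, m); its median is 1 - 0.5**(1/m) ~ ln2/m.
        # With 40 repeats the sample median is noisy; require the right order
        # of magnitude rather than a tight match.
        expected = 1 - 0.5 ** (1 / m)
        assert expected / 4 < np.median(min_ps) < expected * 4

    def test_planted_effect_attains_minimal_q(self):
        """A planted additive effect is the screen's top hit in >= 90% of
        seeded cohorts."""
        from hostmicrobe import SimulationConfig, simulate_cohort
        from hostmicrobe.abundance import prepare_features

        hits = 0
        for rep in range(10):
            cfg = SimulationConfig(
                n_donors=150, n_variants=200, n_populations=1, fst=0.1,
                population_weights=(1.0,), related_pairs=(),
                n_species=30, n_pathways=5, zero_inflation=0.0,
                planted_variant_effects=((5, 0, "additive", 1.5),),
                seed=3000 + rep,
            )
            cohort = simulate_cohort(cfg)
            prepared = prepare_features(cohort.species_table)
            screen = TargetedScreen(prepared, cohort.genotypes, "var5",
                                    metadata=cohort.metadata)
            res = screen.fit(test="regression")
            if res.frame.loc[res.frame["q"].idxmin(), "feature"] == "species_0":
                hits += 1
        assert hits >= 9


@pytest.fixture(scope="module")
def null_cohort():
    from hostmicrobe import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_donors=100, n_variants=120, n_populations=1, fst=0.1,
        population_weights=(1.0,), related_pairs=(), n_species=25,
        n_pathways=5, zero_inflation=0.0, seed=77,
    )
    return simulate_cohort(cfg)


class TestGenomeWideScan:
    def test_record_count_conserved(self, null_cohort):
        from hostmicrobe.abundance import prepare_features

        prepared = prepare_features(null_cohort.species_table)
        res = GenomeWideScan(null_cohort.genotypes, prepared,
                             metadata=null_cohort.metadata, maf_min=0.1).fit()
        n_kept = res.frame["id"].nunique()
        assert len(res.frame) == n_kept * len(prepared.features)
        assert res.n_tests == len(res.frame)

    def test_null_scan_calibrated(self, null_cohort):
        from hostmicrobe.abundance import prepare_features

        prepared = prepare_features(null_cohort.species_table)
        res = GenomeWideScan(null_cohort.genotypes, prepared,
                             metadata=null_cohort.metadata, maf_min=0.1).fit()
        frac = float((res.frame["p"] < 0.01).mean())
        assert frac == pytest.approx(0.01, abs=0.005)
        _, _, slope = res.qq()
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_variant_subset_restricts_exactly(self, null_cohort):
        from hostmicrobe.abundance import prepare_features

        prepared = prepare_features(null_cohort.species_table)
        subset = ["var3", "var10", "var50"]
        res = GenomeWideScan(null_cohort.genotypes, prepared,
                             metadata=null_cohort.metadata, maf_min=0.0,
                             variant_subset=subset).fit()
        assert set(res.frame["id"]) <= set(subset)

    def test_donor_mismatch_detected(self, null_cohort):
        from hostmicrobe.abundance import prepare_features

        prepared = prepare_features(null_cohort.species_table)
        values = prepared.values.rename(index={prepared.samples[0]: "ghost"})
        donor_of = {s: s for s in values.index}
        bad = AbundanceTable(values, donor_of, "stool", kind="species",
                             transformed=True)
        with pytest.raises(ValueError, match="ghost"):
            GenomeWideScan(null_cohort.genotypes, bad).fit()


class TestBonferroni:
    def test_simple_division(self):
        assert bonferroni_threshold(10, 0.05) == pytest.approx(0.005)

    def test_single_test_keeps_alpha(self):
        assert bonferroni_threshold(1, 0.05) == 0.05

    def test_genome_scale_magnitude(self):
        # ~1.66e10 tests at alpha 0.05 -> threshold ~3e-12
        thr = bonferroni_threshold(int(1.66e10), 0.05)
        assert thr == pytest.approx(3e-12, rel=0.01)


class TestClumping:
    def test_gap_joins_and_splits(self):
        records = [_record(100, 0.01), _record(5000, 0.001), _record(20_000, 0.02)]
        clumps = clump_associations(records, max_gap=10_000)
        assert len(clumps) == 2
        assert clumps[0].representative.variant.pos == 5000
        assert clumps[1].representative.variant.pos == 20_000
        assert clumps[0].span == (100, 5000)

    def test_single_record_is_own_representative(self):
        (c,) = clump_associations([_record(42, 0.5)])
        assert c.representative.variant.pos == 42
        assert c.span == (42, 42)

    def test_boundary_gap_of_exactly_max_stays_joined(self):
        clumps = clump_associations([_record(0 + 1, 0.1), _record(10_001, 0.2)],
                                    max_gap=10_000)
        assert len(clumps) == 1

    def test_partition_matches_exhaustive_check(self):
        """Greedy grouping partitions the records; representatives are group
        minima (exhaustive verification on 20 records)."""
        rng = np.random.default_rng(9)
        positions = np.sort(rng.integers(1, 200_000, 20))
        records = [_record(int(p), float(rng.uniform(1e-6, 1))) for p in positions]
        clumps = clump_associations(records, max_gap=10_000)
        flattened = [m for c in clumps for m in c.members]
        assert flattened == records  # every record exactly once, in order
        for c in clumps:
            assert c.representative.p == min(m.p for m in c.members)
            gaps = np.diff([m.variant.pos for m in c.members])
            assert np.all(gaps <= 10_000)
        for a, b in zip(clumps, clumps[1:]):
            assert b.members[0].variant.pos - a.members[-1].variant.pos > 10_000

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            clump_associations([_record(500, 0.1), _record(100, 0.2)])

    def test_mixed_features_rejected(self):
        with pytest.raises(ValueError, match="one feature"):
            clump_associations([_record(1, 0.1, "a"), _record(2, 0.1, "b")])


class TestAnnotateGenes:
    GENES = [GeneInterval("GENE1", "chrS", 100_000, 120_000)]

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (60_000, ["GENE1"]),   # 40 kb upstream of the interval
            (110_000, ["GENE1"]),  # inside: distance 0
            (170_000, ["GENE1"]),  # exactly 50 kb downstream
            (170_001, []),         # one bp beyond the window
            (49_999, []),
        ],
    )
    def test_window_arithmetic(self, pos, expected):
        v = VariantRecord("chrS", pos, "v")
        assert annotate_genes(v, self.GENES, window=50_000) == expected

    def test_other_contig_ignored(self):
        v = VariantRecord("chr2", 110_000, "v")
        assert annotate_genes(v, self.GENES, window=50_000) == []


class TestQQPoints:
    def test_uniform_null_slope_near_one(self):
        rng = np.random.default_rng(10)
        _, _, slope = qq_points(rng.uniform(size=5000))
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_singleton_plotting_position(self):
        expected, observed, _ = qq_points(np.array([0.5]))
        assert expected[0] == pytest.approx(-np.log10(0.5))
        assert observed[0] == pytest.approx(-np.log10(0.5))

    def test_constant_small_p(self):
        _, observed, _ = qq_points(np.full(10, 1e-6))
        np.testing.assert_allclose(observed, 6.0)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            _, observed, _ = qq_points(np.array([0.0, 0.5]))
        assert np.isfinite(observed).all()


def test_build_covariates_one_hot_reference():
    meta = pd.DataFrame(
        {
            "sex": ["female", "male", "male"],
            "ethnicity": ["pop0", "pop1", "pop2"],
            "collection_site": ["siteA", "siteA", "siteB"],
        },
        index=["d0", "d1", "d2"],
    )
    C = build_covariates(meta, ["d0", "d1", "d2"])
    # drop-first: 1 (sex) + 2 (ethnicity) + 1 (site) columns
    assert C.shape == (3, 4)
    assert set(np.unique(C)) <= {0.0, 1.0}
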
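"""Frequency screen, two-proportion Z, BH, zygosity and contingency tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neanderscore import (
    GenotypeMatrix,
    SimConfig,
    annotation_filter,
    bh_adjust,
    carrier_contingency,
    enrichment_screen,
    frequency_screen,
    simulate_cohort,
    synthetic_catalog,
    two_proportion_z,
    zygosity_enrichment,
)
from neanderscore.enrichment import EnrichmentError

from naive_oracles import naive_bh, naive_two_proportion_z


def matrix_from(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    cat = synthetic_catalog(dosage.shape[1], np.random.default_rng(0))
    return GenotypeMatrix([f"s{i}" for i in range(dosage.shape[0])], cat, dosage)


class TestTwoProportionZ:
    def test_equal_proportions_zero(self):
        z, p, deg = two_proportion_z(10, 100, 20, 200)
        assert z == 0.0 and p == 1.0 and not deg

    def test_hand_computed_value(self):
        z, p, _ = two_proportion_z(30, 100, 10, 100)
        assert z == pytest.approx(3.5355, abs=1e-4)
        assert p == pytest.approx(4.07e-4, rel=0.01)

    def test_antisymmetry(self):
        z1, p1, _ = two_proportion_z(30, 100, 10, 100)
        z2, p2, _ = two_proportion_z(10, 100, 30, 100)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z(0, 50, 0, 70) == (0.0, 1.0, True)
        assert two_proportion_z(50, 50, 70, 70) == (0.0, 1.0, True)

    def test_z_squared_equals_uncorrected_chi_square(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(10, 200, 2)
            x1 = rng.integers(1, n1)
            x2 = rng.integers(1, n2)
            z, _, deg = two_proportion_z(int(x1), int(n1), int(x2), int(n2))
            if deg:
                continue
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            chi2 = stats.chi2_contingency(table, correction=False)[0]
            assert z**2 == pytest.approx(chi2, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(EnrichmentError):
            two_proportion_z(5, 3, 1, 10)
        with pytest.raises(EnrichmentError):
            two_proportion_z(1, 0, 1, 10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_naive_step_up_and_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, naive_bh(pvals), atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            bh_adjust([0.5, 1.2])


class TestFrequencyScreen:
    def test_inclusive_cutoff_boundary(self):
        case = matrix_from(np.full((10, 1), 1))    # case freq 0.5
        ctrl_dosage = np.zeros((10, 1)); ctrl_dosage[:9, 0] = 1
        control = GenotypeMatrix([f"c{i}" for i in range(10)], case.snps,
                                 ctrl_dosage.astype(np.int8))  # freq 0.45
        t = frequency_screen(case, control, "WNH", cutoff=0.05)
        assert t.loc[0, "freq_diff"] == pytest.approx(0.05)
        assert bool(t.loc[0, "passed_cutoff"])

    def test_depletion_never_passes(self):
        case = matrix_from(np.zeros((10, 1)))
        control = GenotypeMatrix(
            [f"c{i}" for i in range(10)], case.snps, np.full((10, 1), 1, dtype=np.int8)
        )
        t = frequency_screen(case, control, "WNH", cutoff=0.05)
        assert not t["passed_cutoff"].any()

    def test_zero_differences_empty(self):
        d = np.tile([1, 0], (6, 2))[:, :2]
        case = matrix_from(d)
        control = GenotypeMatrix([f"c{i}" for i in range(6)], case.snps,
                                 d.astype(np.int8))
        t = frequency_screen(case, control, "WNH", cutoff=0.05)
        assert not t["passed_cutoff"].any()

    def test_mismatched_snp_sets_rejected(self):
        a = matrix_from(np.zeros((3, 4)))
        b = matrix_from(np.zeros((3, 3)))
        with pytest.raises(EnrichmentError):
            frequency_screen(a, b, "WNH", 0.05)


class TestAnnotationFilter:
    def frame(self, rsids, passed_bh):
        return pd.DataFrame({"rsid": rsids, "passed_bh": passed_bh})

    def test_retains_brain_qtls_only(self):
        results = self.frame(["r1", "r2", "r3", "r4"], [True] * 4)
        ann = pd.DataFrame({"rsid": ["r1", "r2", "r3", "r4"],
                            "brain_qtl": [True, False, True, False]})
        out = annotation_filter(results, ann)
        assert list(out["rsid"]) == ["r1", "r3"]

    def test_unannotated_candidates_dropped_conservatively(self):
        results = self.frame(["r1", "r2"], [True, True])
        ann = pd.DataFrame({"rsid": ["r1"], "brain_qtl": [True]})
        assert list(annotation_filter(results, ann)["rsid"]) == ["r1"]

    def test_empty_annotation_empty_result(self):
        results = self.frame(["r1"], [True])
        ann = pd.DataFrame({"rsid": [], "brain_qtl": []})
        assert annotation_filter(results, ann).empty

    def test_stratum_totals_match_fixture_truth(self):
        """Screen three strata built so 6 + 18 + 1 candidates survive."""
        rng = np.random.default_rng(77)
        frames = []
        for stratum, n_final in (("BNH", 6), ("WHS", 18), ("WNH", 1)):
            cfg = SimConfig(n_cases=150, n_controls=150, n_snps=60,
                            freqs=np.full(60, 0.2),
                            enriched_snp_fraction=n_final / 60,
                            effect_delta=0.35, stratum=stratum,
                            seed=int(rng.integers(2**31)))
            matrix, meta, truth = simulate_cohort(cfg)
            ann = pd.DataFrame({
                "rsid": matrix.snps.rsids,
                "brain_qtl": np.isin(matrix.snps.rsids, truth.enriched_rsids),
            })
            table = enrichment_screen(matrix, meta, stratum, cutoff=0.10,
                                      annotation=ann)
            survivors = table.loc[table["passed_annotation"] == True]  # noqa: E712
            assert len(survivors) == n_final
            frames.append(survivors)
        assert sum(map(len, frames)) == 25


class TestZygosityEnrichment:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        m = matrix_from(np.vstack([d, d]))
        a = m.sample_ids[:40]
        b = m.sample_ids[40:]
        res = zygosity_enrichment(m, m.snps.rsids, a, b)
        assert res.het.p_value > 0.9 and res.hom.p_value > 0.9

    def test_shifted_group_detected(self):
        cfg = SimConfig(n_cases=200, n_controls=200, n_snps=20,
                        freqs=np.full(20, 0.2), enriched_snp_fraction=1.0,
                        effect_delta=0.2, seed=3)
        m, meta, _ = simulate_cohort(cfg)
        cases = meta.loc[meta["group"] == "case", "sample_id"].tolist()
        ctrls = meta.loc[meta["group"] == "control", "sample_id"].tolist()
        res = zygosity_enrichment(m, m.snps.rsids, cases, ctrls)
        assert res.het.p_value < 0.01 and res.hom.p_value < 0.01

    def test_all_zero_dosages_not_computable(self):
        m = matrix_from(np.zeros((20, 5)))
        res = zygosity_enrichment(m, m.snps.rsids, m.sample_ids[:10],
                                  m.sample_ids[10:])
        assert not res.het.computable and not res.hom.computable
        assert math.isnan(res.het.p_value)

    def test_empty_inputs_rejected(self):
        m = matrix_from(np.zeros((4, 2)))
        with pytest.raises(EnrichmentError):
            zygosity_enrichment(m, [], m.sample_ids[:2], m.sample_ids[2:])
        with pytest.raises(EnrichmentError):
            zygosity_enrichment(m, m.snps.rsids, [], m.sample_ids[2:])


class TestCarrierContingency:
    def test_no_association(self):
        g = [1] * 10 + [0] * 90 + [1] * 10 + [0] * 90
        y = [1] * 100 + [0] * 100
        res = carrier_contingency(g, y)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi_square == pytest.approx(0.0)

    def test_odds_ratio_arithmetic(self):
        # carriers: 20 labeled, 30 unlabeled; non-carriers: 5 / 45
        g = [1] * 50 + [0] * 50
        y = [1] * 20 + [0] * 30 + [1] * 5 + [0] * 45
        res = carrier_contingency(g, y)
        assert res.odds_ratio == pytest.approx(6.0)
        se = math.sqrt(1 / 20 + 1 / 30 + 1 / 5 + 1 / 45)
        assert res.ci_low == pytest.approx(math.exp(math.log(6) - 1.96 * se))
        assert res.ci_high == pytest.approx(math.exp(math.log(6) + 1.96 * se))
        assert res.ci_low > 1.0  # CI excludes the null

    def test_zero_cell_haldane_corrected(self):
        g = [1] * 10 + [0] * 10
        y = [1] * 10 + [0] * 10
        res = carrier_contingency(g, y)
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)

    def test_hom_carrier_definition(self):
        g = [2] * 5 + [1] * 5 + [0] * 10
        y = [1] * 5 + [0] * 15
        res = carrier_contingency(g, y, carrier="hom")
        assert res.table[0].tolist() == [5, 0]
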
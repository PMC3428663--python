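import numpy as np
import pytest

from doee import (
    DegenerateScanError,
    DomainError,
    PixelGeometry,
    detection_error,
    ji_from_si,
    kappa_on_frame,
    outline_error,
    scan_agreement,
    score_pair,
    si_estimate,
    si_from_ji,
)
from doee.doee_metrics import agreements_to_table

from conftest import make_pair, random_pair, region


class TestWorkedExample:
    """Slice with eight lesion pairs: six matched (nested outlines), two
    drawn by one rater only."""

    def test_detection_error(self, worked_example_regions):
        assert detection_error(worked_example_regions) == pytest.approx(39.5, abs=1e-9)

    def test_outline_error(self, worked_example_regions):
        assert outline_error(worked_example_regions) == pytest.approx(141.1, abs=1e-9)

    def test_outline_error_rate(self, worked_example_regions):
        agg = scan_agreement(worked_example_regions)
        assert agg.mta == pytest.approx(997.4)
        assert agg.oer == pytest.approx(0.142, abs=1e-3)


class TestErrors:
    def test_detection_error_sums_single_rater_regions(self):
        regions = [region("CR1", a, 0, 0) for a in (1.0, 2.0, 3.0)]
        assert detection_error(regions) == 6.0
        assert detection_error([]) == 0.0

    def test_outline_error_zero_for_identical(self):
        regions = [region("CR12", a, a, a) for a in (3.0, 7.0)]
        assert outline_error(regions) == 0.0

    def test_outline_error_union_minus_intersection(self):
        assert outline_error([region("CR12", 6, 5, 2)]) == 7.0

    def test_de_plus_oe_is_union_minus_intersection(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pair = random_pair(rng)
            agg = score_pair(pair)
            union = (pair.rater1 | pair.rater2).sum()
            inter = (pair.rater1 & pair.rater2).sum()
            assert agg.de + agg.oe == pytest.approx(union - inter)


class TestScanAgreement:
    def test_identical_masks(self):
        m = np.zeros((1, 8, 8), bool)
        m[0, 2:5, 2:5] = True
        agg = score_pair(make_pair(m, m.copy()))
        assert agg.si == 1.0 and agg.de == 0.0 and agg.oe == 0.0 and agg.ji == 1.0

    def test_disjoint_masks(self):
        r1 = np.zeros((1, 8, 8), bool)
        r2 = np.zeros((1, 8, 8), bool)
        r1[0, 1:3, 1:3] = True
        r2[0, 5:7, 5:7] = True
        agg = score_pair(make_pair(r1, r2))
        assert agg.si == 0.0 and agg.mta == 4.0 and agg.de == 8.0 and agg.oe == 0.0

    def test_both_empty_is_degenerate(self):
        z = np.zeros((1, 4, 4), bool)
        with pytest.raises(DegenerateScanError):
            score_pair(make_pair(z, z.copy()))

    def test_totals_cross_check(self, worked_example_regions):
        agg = scan_agreement(worked_example_regions, totals=(946.6, 1048.2))
        assert agg.mta == pytest.approx(997.4)

    def test_si_forms_agree_and_ji_relation(self):
        """Intersection/MTA and DE/OE decomposition forms of SI agree to
        1e-12, and SI = 2 JI/(1+JI), on random mask pairs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            agg = score_pair(random_pair(rng))
            si_decomp = 1 - 0.5 * agg.oer - 0.5 * agg.de / agg.mta
            assert agg.si == pytest.approx(si_decomp, rel=1e-12, abs=1e-12)
            assert agg.si == pytest.approx(si_from_ji(agg.ji), rel=1e-12, abs=1e-12)

    def test_indices_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng)
        a = score_pair(pair)
        b = score_pair(make_pair(pair.rater1, pair.rater2, PixelGeometry(2, 2)))
        assert b.si == pytest.approx(a.si) and b.ji == pytest.approx(a.ji)
        assert b.oer == pytest.approx(a.oer)
        for x, y in ((b.de, a.de), (b.oe, a.oe), (b.mta, a.mta)):
            assert x == pytest.approx(4 * y)


class TestSiEstimate:
    def test_high_burden_limit(self):
        # as MTA -> inf the detection term vanishes: SI -> 1 - meanOER/2
        assert si_estimate(746.8, 0.4077, 1e12) == pytest.approx(0.79615, abs=1e-6)

    def test_study_mean_burden(self):
        assert si_estimate(746.8, 0.4077, 5028) == pytest.approx(0.7219, abs=1e-4)

    def test_perfect_raters(self):
        for mta in (1.0, 100.0, 1e6):
            assert si_estimate(0.0, 0.0, mta) == 1.0

    def test_negative_at_tiny_burden_not_clamped(self):
        assert si_estimate(746.8, 0.4077, 100.0) < 0

    def test_domain_error(self):
        with pytest.raises(DomainError):
            si_estimate(746.8, 0.4077, 0.0)


class TestSiJi:
    @pytest.mark.parametrize("ji,si", [(0.0, 0.0), (1.0, 1.0), (1 / 3, 0.5)])
    def test_known_values(self, ji, si):
        assert si_from_ji(ji) == pytest.approx(si)
        assert ji_from_si(si) == pytest.approx(ji)

    def test_bijection_on_unit_interval(self):
        for v in np.linspace(0, 1, 21):
            assert ji_from_si(si_from_ji(v)) == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("fn", [si_from_ji, ji_from_si])
    def test_out_of_range(self, fn):
        with pytest.raises(DomainError):
            fn(1.5)


class TestKappa:
    def test_identical_masks_give_one(self):
        m = np.zeros((1, 6, 6), bool)
        m[0, 1:4, 1:4] = True
        assert kappa_on_frame(make_pair(m, m.copy()), 1000) == pytest.approx(1.0)

    def test_matches_closed_form_2x2_table(self):
        rng = np.random.default_rng(1)
        pair = random_pair(rng)
        n11 = int((pair.rater1 & pair.rater2).sum())
        n10 = int((pair.rater1 & ~pair.rater2).sum())
        n01 = int((~pair.rater1 & pair.rater2).sum())
        n00 = 5000
        # independent oracle: sklearn on the flattened label vectors
        from sklearn.metrics import cohen_kappa_score

        y1 = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
        y2 = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
        assert kappa_on_frame(pair, n00) == pytest.approx(cohen_kappa_score(y1, y2), abs=1e-12)

    def test_monotone_convergence_to_si(self):
        rng = np.random.default_rng(2)
        pair = random_pair(rng)
        agg = score_pair(pair)
        union = int((pair.rater1 | pair.rater2).sum())
        kappas = [kappa_on_frame(pair, n) for n in (union, 10 * union, 100 * union, 1000 * union)]
        assert all(a < b for a, b in zip(kappas, kappas[1:]))
        assert abs(kappas[-1] - agg.si) < 1e-3

    def test_disjoint_masks_approach_zero_from_below(self):
        r1 = np.zeros((1, 8, 8), bool)
        r2 = np.zeros((1, 8, 8), bool)
        r1[0, 1:3, 1:3] = True
        r2[0, 5:7, 5:7] = True
        pair = make_pair(r1, r2)
        k = kappa_on_frame(pair, 100000)
        assert -0.01 < k < 0.0

    def test_frame_smaller_than_union_rejected(self):
        m = np.ones((1, 4, 4), bool)
        with pytest.raises(DomainError):
            kappa_on_frame(make_pair(m, m.copy()), 3)


def test_table_rounding(tmp_path):
    rng = np.random.default_rng(8)
    aggs = [score_pair(random_pair(rng, scan_id=f"s{i}")) for i in range(3)]
    path = tmp_path / "per_scan.tsv"
    df = agreements_to_table(aggs, path)
    assert len(df) == 3 and df["SI"].between(0, 1).all()
    header = path.read_text().splitlines()[0].split("\t")
    assert header[:5] == ["scan_id", "MTA", "DE", "OE", "OER"]
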
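"""Patterson's D computation and block-jackknife uncertainty."""

import math

import numpy as np
import pytest

from introscan.dstat import (
    DResult,
    PanelConfig,
    SiteWeights,
    block_jackknife,
    compute_d,
    per_specimen_scan,
    site_pattern_weights,
)
from introscan.genotype_io import MISSING, GenotypeMatrix

from _oracles import scalar_d
from conftest import make_random_matrix


def matrix_from_dosages(dosages, sample_ids):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    return GenotypeMatrix(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64) * 10,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        dosages=dosages,
        sample_ids=tuple(sample_ids),
    )


class TestSitePatternWeights:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0, 1, 1, 0), (1.0, 0.0)),  # pure ABBA
            ((1, 0, 1, 0), (0.0, 1.0)),  # pure BABA
            ((1, 1, 0, 0), (0.0, 0.0)),  # BBAA species-tree pattern
            ((0.5, 0.5, 0.5, 0), (0.125, 0.125)),
        ],
    )
    def test_examples(self, freqs, expected):
        assert site_pattern_weights(*freqs) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [(-0.1, 0, 0, 0), (0, 1.2, 0, 0)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            site_pattern_weights(*bad)


class TestComputeD:
    def test_all_abba_gives_d_one(self):
        # dosage columns: p1, p2, p3 with the ABBA pattern at every site
        gm = matrix_from_dosages([[0, 2, 2]] * 4, ["p1", "p2", "p3"])
        r = compute_d(gm, PanelConfig(("p1",), ("p2",), ("p3",)))
        assert r.d == pytest.approx(1.0)
        assert (r.sum_abba, r.sum_baba) == (4.0, 0.0)

    def test_equal_abba_baba_gives_zero(self):
        gm = matrix_from_dosages([[0, 2, 2], [2, 0, 2]] * 3, ["p1", "p2", "p3"])
        r = compute_d(gm, PanelConfig(("p1",), ("p2",), ("p3",)))
        assert r.d == pytest.approx(0.0)

    def test_no_informative_sites_flagged_not_raised(self):
        gm = matrix_from_dosages([[0, 0, 0], [2, 2, 0]], ["p1", "p2", "p3"])
        r = compute_d(gm, PanelConfig(("p1",), ("p2",), ("p3",)))
        assert math.isnan(r.d)
        assert r.status == "no_informative_sites"

    def test_matches_scalar_oracle_small(self, rng):
        gm = make_random_matrix(rng, 6, 5, missing_rate=0.2)
        ids = gm.sample_ids
        panels = PanelConfig((ids[0], ids[1]), (ids[2],), (ids[3], ids[4]))
        r = compute_d(gm, panels)
        d, sa, sb, n = scalar_d(gm, panels.p1_samples, panels.p2_samples, panels.p3_samples)
        if math.isnan(d):
            assert math.isnan(r.d)
        else:
            assert r.d == pytest.approx(d, abs=1e-12)
        assert r.sum_abba == pytest.approx(sa, abs=1e-12)
        assert r.sum_baba == pytest.approx(sb, abs=1e-12)
        assert r.n_sites_used == n

    def test_antisymmetry_under_p1_p2_swap(self, rng):
        for _ in range(10):
            gm = make_random_matrix(rng, 80, 6, missing_rate=0.1)
            ids = gm.sample_ids
            a = compute_d(gm, PanelConfig((ids[0], ids[1]), (ids[2],), (ids[3],)))
            b = compute_d(gm, PanelConfig((ids[2],), (ids[0], ids[1]), (ids[3],)))
            if math.isnan(a.d):
                assert math.isnan(b.d)
            else:
                assert a.d == pytest.approx(-b.d, abs=1e-12)
                assert abs(a.d) <= 1.0

    def test_identical_p1_p2_gives_zero(self, rng):
        """abba = baba whenever p1 = p2 at every site, so D = 0."""
        gm = make_random_matrix(rng, 100, 3, missing_rate=0.0)
        dup = np.column_stack([gm.dosages[:, 0], gm.dosages[:, 0], gm.dosages[:, 1]])
        gm2 = matrix_from_dosages(dup, ["p1", "p2", "p3"])
        r = compute_d(gm2, PanelConfig(("p1",), ("p2",), ("p3",)))
        if not math.isnan(r.d):
            assert r.d == pytest.approx(0.0, abs=1e-12)

    def test_outgroup_sample_mode_gates_derived_outgroup(self):
        """p4 = 1 zeroes both weights; the fixed site with p4 = 0 dominates."""
        gm = matrix_from_dosages(
            [[0, 2, 2, 2], [0, 2, 2, 0], [2, 0, 2, 2]], ["p1", "p2", "p3", "out"]
        )
        panels = PanelConfig(("p1",), ("p2",), ("p3",),
                             outgroup_mode="sample_ids", outgroup_samples=("out",))
        r = compute_d(gm, panels)
        assert (r.sum_abba, r.sum_baba) == (1.0, 0.0)

    def test_unknown_sample_raises(self, rng):
        gm = make_random_matrix(rng, 10, 3)
        with pytest.raises(LookupError):
            compute_d(gm, PanelConfig(("nope",), (gm.sample_ids[0],), (gm.sample_ids[1],)))


class TestPanelConfig:
    def test_overlapping_panels_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            PanelConfig(("a",), ("a",), ("b",))

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            PanelConfig((), ("a",), ("b",))


class TestBlockJackknife:
    def test_identical_blocks_zero_se(self):
        w = SiteWeights(site_index=np.arange(8), abba=np.tile([1.0, 0.5], 4),
                        baba=np.tile([0.2, 0.1], 4))
        se, z, g = block_jackknife(w, block_size=2)
        assert g == 4
        assert se == pytest.approx(0.0, abs=1e-14)

    def test_two_block_hand_calculation(self):
        # sites: abba = [1,1,0,0], baba = [0,0,1,0], blocks of 2
        # A=2, B=1, D=1/3; delete-block D values: -1 and 1; equal blocks
        # reduce the weighted jackknife to ((g-1)/g) * sum (theta_j - mean)^2 = 1
        w = SiteWeights(site_index=np.arange(4), abba=np.array([1.0, 1, 0, 0]),
                        baba=np.array([0.0, 0, 1, 0]))
        se, z, g = block_jackknife(w, block_size=2)
        assert g == 2
        assert se == pytest.approx(1.0, abs=1e-12)
        assert z == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_single_block_na(self):
        w = SiteWeights(site_index=np.arange(3), abba=np.ones(3), baba=np.zeros(3))
        se, z, g = block_jackknife(w, block_size=10)
        assert g == 1 and math.isnan(se) and math.isnan(z)


class TestPerSpecimenScan:
    def test_empty_focal_list(self, rng):
        gm = make_random_matrix(rng, 10, 4)
        from introscan.genotype_io import SampleRecord, SampleSet

        ss = SampleSet(records=tuple(SampleRecord(s, "focal") for s in gm.sample_ids))
        assert per_specimen_scan(gm, ss, gm.sample_ids[0], gm.sample_ids[1], []) == []

    def test_failed_specimen_reported_not_fatal(self, rng):
        gm = make_random_matrix(rng, 20, 4, missing_rate=0.0)
        from introscan.genotype_io import SampleRecord, SampleSet

        ss = SampleSet(records=tuple(SampleRecord(s, "focal") for s in gm.sample_ids))
        res = per_specimen_scan(gm, ss, gm.sample_ids[0], gm.sample_ids[1],
                                [gm.sample_ids[2], "ghost", gm.sample_ids[3]])
        assert [r.focal_id for r in res] == [gm.sample_ids[2], "ghost", gm.sample_ids[3]]
        assert res[0].status == "ok"
        assert res[1].status.startswith("error")
        assert math.isnan(res[1].d)
        assert res[2].status == "ok"

    def test_bound_on_random_matrices(self, rng):
        for _ in range(20):
            gm = make_random_matrix(rng, 50, 5, missing_rate=0.3)
            r = compute_d(gm, PanelConfig((gm.sample_ids[0],), (gm.sample_ids[1],),
                                          (gm.sample_ids[2],)))
            if not math.isnan(r.d):
                assert -1.0 <= r.d <= 1.0
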
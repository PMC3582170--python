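"""Area/volume estimators and the systematic-sampling coefficient of error."""

import math

import numpy as np
import pytest

from cordstereo.estimators import (
    area_mean,
    ce_systematic,
    volume_cavalieri,
    wm_consistency,
)
from cordstereo.pointcount import count_hits, count_triplicate, make_grid
from cordstereo.sampling import SamplingDesign, plan_slabs, section_positions


def ce_bruteforce(counts, shape=6.0):
    """Independent loop-based evaluation of the same CE formula."""
    n = len(counts)
    total = sum(counts)
    A = sum(c * c for c in counts)
    B = sum(counts[i] * counts[i + 1] for i in range(n - 1))
    C = sum(counts[i] * counts[i + 2] for i in range(n - 2))
    noise = 0.0724 * shape * math.sqrt(n * total)
    var = max((3 * (A - noise) - 4 * B + C) / 240.0, 0.0)
    return math.sqrt(noise + var) / total


class TestFormulas:
    def test_area_mean_direct(self):
        est = area_mean([20.0, 22.0, 18.0], a_per_p=6.0)
        assert est.a_mean == pytest.approx(60 * 6 / 3)
        assert est.per_section == pytest.approx((120.0, 132.0, 108.0))

    def test_single_section(self):
        assert area_mean([17.0], a_per_p=6.0).a_mean == pytest.approx(102.0)

    def test_volume_direct(self):
        v = volume_cavalieri([20.0, 22.0, 18.0], a_per_p=6.0, t=3.4)
        assert v.v_est == pytest.approx(60 * 6 * 3.4)

    def test_volume_equals_area_times_sn_t(self):
        """V_est = A_mean x Sn x t is an algebraic identity."""
        sig = [11.0, 13.5, 9.0, 12.0]
        a = area_mean(sig, a_per_p=0.6)
        v = volume_cavalieri(sig, a_per_p=0.6, t=6.8)
        assert v.v_est == pytest.approx(a.a_mean * a.sn * 6.8, rel=1e-12)

    def test_fractional_sigma_p_allowed(self):
        v = volume_cavalieri([10.333333], a_per_p=6.0, t=3.4)
        assert v.v_est == pytest.approx(10.333333 * 6 * 3.4)

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            area_mean([], a_per_p=6.0)

    def test_nonuniform_spacing_raises(self):
        with pytest.raises(ValueError, match="spacing"):
            volume_cavalieri(
                [10, 11, 12], a_per_p=6.0, t=3.4, positions=[0.0, 3.4, 7.5]
            )


class TestCE:
    def test_matches_bruteforce_oracle(self):
        for counts in ([10, 12, 14, 12, 10], [5, 5, 6, 8, 13, 21], [3, 9, 4]):
            assert ce_systematic(counts) == pytest.approx(ce_bruteforce(counts))

    def test_constant_series_smoothness_term(self):
        """With zero nugget noise a constant series leaves only the residual
        end-effect 2*P^2/240 of the second-difference sum."""
        counts = [10.0] * 4
        expected = math.sqrt(2 * 100.0 / 240.0) / 40.0
        assert ce_systematic(counts, shape_coefficient=0.0) == pytest.approx(expected)

    def test_requires_three_sections(self):
        with pytest.raises(ValueError):
            ce_systematic([10, 12])

    def test_ce_decreases_with_more_sections(self, tapered_phantom, rng):
        """More sections through the same object predict a smaller CE."""
        ces = []
        for n_sections in (4, 8, 16):
            zs = np.linspace(1.0, 37.0, n_sections)
            counts = []
            for z in zs:
                sec = tapered_phantom.section_at(float(z), pixel_size=0.05)
                counts.append(count_hits(sec, make_grid(6.0, sec.bbox(), rng), "GS"))
            ces.append(ce_systematic(counts))
        assert ces[2] < ces[0]

    def test_paper_scale_ce_magnitude(self, tapered_phantom, rng):
        """At 8-13 sections and the coarse GS grid, CE lands in the
        few-percent range."""
        sec_zs = np.linspace(0.5, 37.5, 10)
        counts = [
            count_hits(
                tapered_phantom.section_at(float(z), 0.05),
                make_grid(6.0, tapered_phantom.section_at(float(z), 0.05).bbox(), rng),
                "GS",
            )
            for z in sec_zs
        ]
        ce = ce_systematic(counts)
        assert 0.005 < ce < 0.10


class TestCavalieriOnPhantom:
    def test_exhaustive_sections_recover_cylinder_volume(self, cylinder_phantom, rng):
        ph = cylinder_phantom
        t = 1.0
        zs = np.arange(0.5, 20.0, t)
        recs = [
            count_triplicate(ph.section_at(float(z), 0.05), 0.6, "GS", rng)
            for z in zs
        ]
        v = volume_cavalieri(recs, 0.6, t, positions=list(zs))
        assert v.v_est == pytest.approx(ph.truth.volume("GS", "S1"), rel=0.02)

    def test_unbiased_over_random_designs(self, cylinder_phantom, rng):
        """Mean Cavalieri estimate over many random systematic designs is
        within 1% of pi*a*b*L (sections of an untapered cord are identical,
        so one render serves every position)."""
        ph = cylinder_phantom
        sec = ph.section_at(10.0, pixel_size=0.02)
        design = SamplingDesign()
        est = []
        for _ in range(500):
            plan = plan_slabs(20.0, design, rng)
            zs = section_positions(plan, rng)
            counts = [
                count_hits(sec, make_grid(6.0, sec.bbox(), rng), "GS") for _ in zs
            ]
            est.append(sum(counts) * 6.0 * design.slab_thickness)
        assert np.mean(est) == pytest.approx(ph.truth.volume("GS", "S1"), rel=0.01)


def test_wm_consistency_subtraction_identity():
    gs = area_mean([100.0], a_per_p=1.0)
    gm = area_mean([15.0], a_per_p=1.0)
    wm = area_mean([84.9], a_per_p=1.0)
    rep = wm_consistency(gs, gm, 0.1, wm)
    assert rep.wm_subtracted == pytest.approx(84.9)
    assert rep.gap == pytest.approx(0.0, abs=1e-9)
    rep2 = wm_consistency(gs, gm, 0.1, area_mean([80.0], a_per_p=1.0))
    assert rep2.relative_gap == pytest.approx(4.9 / 84.9)


def test_wm_consistency_table_scale():
    """At the published C1 scale: GS 132, GM 16.5 give WM ~ 115.5, within
    rounding of the tabulated 115."""
    gs = area_mean([132.0], a_per_p=1.0)
    gm = area_mean([16.5], a_per_p=1.0)
    wm = area_mean([115.0], a_per_p=1.0)
    rep = wm_consistency(gs, gm, 0.0, wm)
    assert abs(rep.gap) <= 0.5


def test_wm_consistency_zero_gm():
    gs = area_mean([50.0], a_per_p=1.0)
    zero = area_mean([0.0], a_per_p=1.0)
    rep = wm_consistency(gs, zero, 0.0, gs)
    assert rep.gap == 0.0
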
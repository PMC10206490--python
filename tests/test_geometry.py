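"""Reconstruction, flow extensions, analysis regions, and gridding."""

import numpy as np
import pandas as pd
import pytest

from atheroflow.geometry import (
    add_flow_extensions,
    analysis_regions,
    build_grid,
    reconstruct_profile,
)
from atheroflow.synthetic import SyntheticSpec, make_vessel_profile
from atheroflow.types import VesselProfile


class TestReconstructProfile:
    def test_constant_area_gives_equivalent_circle_radius(self):
        area = 0.2
        slices = [{"area": area}] * 5
        prof = reconstruct_profile(slices, 0.5)
        assert np.allclose(prof.r, np.sqrt(area / np.pi))

    def test_feret_convention_takes_priority(self):
        slices = [{"feret_min": 0.4, "feret_max": 0.6}] * 4
        prof = reconstruct_profile(slices, 0.5)
        assert np.allclose(prof.r, 0.25)  # half the mean Feret diameter

    def test_generator_roundtrip_within_half_percent(self):
        spec = SyntheticSpec()
        truth = make_vessel_profile(spec)
        slices = [{"area": np.pi * r**2} for r in truth.r]
        prof = reconstruct_profile(slices, spec.slice_thickness)
        assert np.allclose(prof.r, truth.r, rtol=0.005)
        assert np.allclose(prof.z, truth.z)

    def test_slice_stack_length(self):
        prof = reconstruct_profile([{"area": 0.2}] * 14, 0.5)
        assert prof.z[-1] - prof.z[0] == pytest.approx(6.5)

    def test_rejects_mixed_conventions_and_bad_values(self):
        with pytest.raises(ValueError):
            reconstruct_profile([{"area": 0.2}, {"feret_min": 0.4, "feret_max": 0.5},
                                 {"area": 0.2}], 0.5)
        with pytest.raises(ValueError):
            reconstruct_profile([{"area": -1.0}] * 3, 0.5)

    def test_accepts_dataframe(self):
        frame = pd.DataFrame({"area": [0.2, 0.2, 0.2]})
        prof = reconstruct_profile(frame, 0.5)
        assert len(prof.z) == 3


class TestFlowExtensions:
    def test_extension_lengths_scale_with_diameters(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=np.full(14, 0.25))
        ext = add_flow_extensions(prof)
        assert ext.extensions[0] == pytest.approx(1.5 * 0.5)
        assert ext.extensions[1] == pytest.approx(7 * 0.5)
        assert ext.core_interval == (pytest.approx(0.0), pytest.approx(6.5))

    def test_tapered_outlet_uses_local_diameter(self):
        r = np.linspace(0.25, 0.2, 14)
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=r)
        ext = add_flow_extensions(prof)
        assert ext.extensions[1] == pytest.approx(7 * 0.4)
        assert np.allclose(ext.r[ext.z > 6.5], 0.2)

    def test_double_extension_is_rejected(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=np.full(14, 0.25))
        with pytest.raises(ValueError, match="already"):
            add_flow_extensions(add_flow_extensions(prof))


class TestAnalysisRegions:
    def test_cuffed_regions_flank_the_cuff(self):
        prof = VesselProfile(z=np.linspace(0, 7, 15), r=np.full(15, 0.25),
                             cuff_interval=(3.0, 4.0))
        reg = analysis_regions(prof)
        assert reg.upstream == (pytest.approx(1.0), pytest.approx(3.0))
        assert reg.downstream == (pytest.approx(4.0), pytest.approx(6.0))
        assert not reg.upstream_clipped and not reg.downstream_clipped

    def test_no_cuff_regions_abut_midpoint(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=np.full(14, 0.25))
        reg = analysis_regions(prof)
        assert reg.upstream == (pytest.approx(1.25), pytest.approx(3.25))
        assert reg.downstream == (pytest.approx(3.25), pytest.approx(5.25))

    def test_short_vessel_clips_and_flags(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=np.full(14, 0.25),
                             cuff_interval=(1.0, 2.0))
        with pytest.warns(UserWarning, match="clipped"):
            reg = analysis_regions(prof)
        assert reg.upstream == (pytest.approx(0.0), pytest.approx(1.0))
        assert reg.upstream_clipped and not reg.downstream_clipped

    def test_extensions_do_not_shift_regions(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=np.full(14, 0.25),
                             cuff_interval=(2.25, 3.75))
        before = analysis_regions(prof)
        after = analysis_regions(add_flow_extensions(prof))
        assert before == after


class TestBuildGrid:
    def test_uniform_tube_is_coarse_with_bounded_spacing(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14), r=np.full(14, 0.25))
        grid = build_grid(prof)
        assert set(grid.zones) == {"coarse"}
        assert np.diff(grid.z).max() <= 0.05 + 1e-12

    def test_zones_and_spacings_around_cuff(self):
        # extensions reach >3 mm from the cuff, so all three zones appear
        prof = add_flow_extensions(make_vessel_profile(SyntheticSpec()))
        grid = build_grid(prof)
        dz = np.diff(grid.z)
        for zone, limit in (("fine", 0.013), ("medium", 0.025), ("coarse", 0.05)):
            sel = grid.zones[:-1] == zone
            assert sel.any()
            assert dz[sel].max() <= limit + 1e-12

    def test_halving_spacings_roughly_quadruples_nodes(self):
        prof = make_vessel_profile(SyntheticSpec())
        n1 = np.prod(build_grid(prof, 0.026, 0.05, 0.1).shape)
        n2 = np.prod(build_grid(prof, 0.013, 0.025, 0.05).shape)
        # 2x axial times 2x radial, up to interval rounding at zone breaks
        assert 3.5 * n1 <= n2 <= 4.5 * n1

    def test_throat_radial_resolution(self):
        # 14% area stenosis: throat radius ~0.0935 mm needs >= 7 fine intervals
        prof = make_vessel_profile(SyntheticSpec())
        grid = build_grid(prof)
        n_intervals = len(grid.eta) - 1
        assert n_intervals >= int(np.ceil(grid.R.min() / 0.013))
        # wall nodes sit exactly on r(z)
        assert np.allclose(grid.r_nodes[:, -1], grid.R)
        assert np.allclose(grid.r_nodes[:, 0], 0.0)

    def test_unresolvable_stenosis_fails(self):
        prof = VesselProfile(z=np.linspace(0, 6.5, 14),
                             r=np.full(14, 0.02))  # below 2 x fine spacing
        with pytest.raises(ValueError, match="unresolvable"):
            build_grid(prof)
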
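import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hspfit import (
    BinaryMixtureSpec,
    HansenSphere,
    HspTriple,
    default_grid,
    lookup,
    min_red_closed_form,
    mix_hsp,
    mix_hsp_volume,
    predict_synergy,
    red,
    red_profile,
)
from hspfit.mixtures import MixtureError
from hspfit.solvents import SolventRecord

centers = st.builds(
    HspTriple,
    st.floats(min_value=10, max_value=25),
    st.floats(min_value=0, max_value=25),
    st.floats(min_value=0, max_value=25),
)
solvent_triples = st.builds(
    HspTriple,
    st.floats(min_value=12, max_value=20),
    st.floats(min_value=0, max_value=20),
    st.floats(min_value=0, max_value=25),
)
spheres = st.builds(HansenSphere, centers, st.floats(min_value=2, max_value=12))


def _spec(s1, s2, grid=None):
    return BinaryMixtureSpec(
        SolventRecord("s1", s1), SolventRecord("s2", s2), grid or default_grid()
    )


def test_mix_endpoints_return_the_pure_solvents():
    s1, s2 = HspTriple(15.1, 12.3, 22.3), HspTriple(16.0, 9.0, 5.1)
    assert mix_hsp(s1, s2, 1.0).as_tuple() == pytest.approx(s1.as_tuple())
    assert mix_hsp(s1, s2, 0.0).as_tuple() == pytest.approx(s2.as_tuple())


def test_mix_midpoint_is_the_arithmetic_mean():
    s1, s2 = HspTriple(15.1, 12.3, 22.3), HspTriple(16.0, 9.0, 5.1)
    assert mix_hsp(s1, s2, 0.5).as_tuple() == pytest.approx((15.55, 10.65, 13.70))


def test_mix_rejects_fractions_outside_unit_interval():
    s = HspTriple(15, 10, 10)
    with pytest.raises(MixtureError):
        mix_hsp(s, s, -0.1)
    with pytest.raises(MixtureError):
        mix_hsp(s, s, 1.1)


def test_volume_fraction_blend_weights_by_molar_volume():
    s1, s2 = HspTriple(10.0, 10.0, 10.0), HspTriple(20.0, 20.0, 20.0)
    # equal moles but solvent 2 twice the molar volume -> phi2 = 2/3
    blended = mix_hsp_volume(s1, s2, 0.5, molar_volume1=50.0, molar_volume2=100.0)
    assert blended.as_tuple() == pytest.approx((50 / 3, 50 / 3, 50 / 3))
    with pytest.raises(MixtureError):
        mix_hsp_volume(s1, s2, 0.5, molar_volume1=-1.0, molar_volume2=100.0)


def test_grid_validation():
    s = SolventRecord("s", HspTriple(15, 10, 10))
    with pytest.raises(MixtureError):
        BinaryMixtureSpec(s, s, (0.0, 0.5, 0.5, 1.0))
    with pytest.raises(MixtureError):
        BinaryMixtureSpec(s, s, (0.0, 1.2))
    with pytest.raises(MixtureError):
        BinaryMixtureSpec(s, s, ())


@pytest.mark.parametrize(
    "sphere_name, solvent1, solvent2, expected_x",
    [
        ("resveratrol", "methanol", "methyl ethyl ketone", 0.5),
        ("resveratrol", "methanol", "methyl isobutyl ketone", 0.5),
        ("hesperetin", "methanol", "methyl isobutyl ketone", 0.5),
        ("hesperetin", "ethanol", "methyl isobutyl ketone", 0.4),
    ],
)
def test_minimum_red_compositions_for_the_study_systems(
    study_library, resveratrol_sphere, hesperetin_sphere, sphere_name, solvent1, solvent2, expected_x
):
    sphere = resveratrol_sphere if sphere_name == "resveratrol" else hesperetin_sphere
    spec = BinaryMixtureSpec(
        lookup(study_library, solvent1), lookup(study_library, solvent2)
    )
    profile = red_profile(sphere, spec)
    assert profile.x_min_grid == pytest.approx(expected_x)
    assert profile.shape == "interior_minimum"


def test_alcohol_alcohol_blend_shows_no_interior_minimum(
    study_library, resveratrol_sphere, hesperetin_sphere
):
    spec = BinaryMixtureSpec(
        lookup(study_library, "methanol"), lookup(study_library, "ethanol")
    )
    for sphere in (resveratrol_sphere, hesperetin_sphere):
        profile = red_profile(sphere, spec)
        assert profile.shape == "monotonic"
        assert predict_synergy(sphere, spec)["synergy"] is False


def test_profile_endpoints_equal_pure_solvent_reds(study_library, resveratrol_sphere):
    spec = BinaryMixtureSpec(
        lookup(study_library, "methanol"), lookup(study_library, "methyl ethyl ketone")
    )
    profile = red_profile(resveratrol_sphere, spec)
    assert profile.points[0].red == pytest.approx(
        red(resveratrol_sphere, spec.solvent1.hsp)
    )
    assert profile.points[-1].red == pytest.approx(
        red(resveratrol_sphere, spec.solvent2.hsp)
    )


def test_identical_solvents_give_a_constant_profile():
    s = SolventRecord("s", HspTriple(15.0, 10.0, 10.0))
    sphere = HansenSphere(HspTriple(12.0, 9.0, 12.0), 8.0)
    spec = BinaryMixtureSpec(s, s)
    profile = red_profile(sphere, spec)
    reds = [p.red for p in profile.points]
    assert max(reds) == pytest.approx(min(reds))
    assert profile.shape == "monotonic"
    x_star, red_min = min_red_closed_form(sphere, s.hsp, s.hsp)
    assert x_star == 0.0
    assert red_min == pytest.approx(reds[0])


def test_center_on_the_mixing_segment_reaches_red_zero():
    s1, s2 = HspTriple(14.0, 6.0, 8.0), HspTriple(16.0, 12.0, 18.0)
    center = mix_hsp(s1, s2, 0.7)  # 0.3 mole fraction of solvent 2
    sphere = HansenSphere(center, 5.0)
    x_star, red_min = min_red_closed_form(sphere, s1, s2)
    assert x_star == pytest.approx(0.3, abs=1e-9)
    assert red_min == pytest.approx(0.0, abs=1e-6)  # sqrt amplifies rounding


def test_sphere_centered_on_solvent_one_predicts_no_synergy():
    s1 = SolventRecord("s1", HspTriple(15.0, 10.0, 10.0))
    s2 = SolventRecord("s2", HspTriple(17.0, 5.0, 4.0))
    sphere = HansenSphere(s1.hsp, 6.0)
    report = predict_synergy(sphere, BinaryMixtureSpec(s1, s2))
    assert report["synergy"] is False
    assert report["x_at_min"] == 0.0


def test_profile_csv_export(tmp_path, study_library, resveratrol_sphere):
    spec = BinaryMixtureSpec(
        lookup(study_library, "methanol"), lookup(study_library, "methyl ethyl ketone")
    )
    profile = red_profile(resveratrol_sphere, spec)
    out = tmp_path / "profile.csv"
    profile.write_csv(out)
    header = out.read_text().splitlines()[0]
    assert header == "x2,delta_d,delta_p,delta_h,ra,red"
    assert len(out.read_text().splitlines()) == len(default_grid()) + 1


@settings(derandomize=True, max_examples=200)
@given(sphere=spheres, s1=solvent_triples, s2=solvent_triples)
def test_squared_distance_is_a_convex_quadratic_with_one_minimum(sphere, s1, s2):
    xs = np.linspace(0, 1, 201)
    ra2 = np.array(
        [
            (4 * (sphere.center.delta_d - m.delta_d) ** 2
             + (sphere.center.delta_p - m.delta_p) ** 2
             + (sphere.center.delta_h - m.delta_h) ** 2)
            for m in (mix_hsp(s1, s2, 1 - x) for x in xs)
        ]
    )
    second_diff = np.diff(ra2, 2)
    assert np.all(second_diff >= -1e-8)  # convex
    reds = np.sqrt(ra2) / sphere.radius_r0
    interior_minima = np.sum((reds[1:-1] < reds[:-2] - 1e-12) & (reds[1:-1] < reds[2:] - 1e-12))
    assert interior_minima <= 1


@settings(derandomize=True, max_examples=200)
@given(sphere=spheres, s1=solvent_triples, s2=solvent_triples)
def test_grid_minimum_sits_next_to_the_closed_form_minimum(sphere, s1, s2):
    spec = _spec(s1, s2)
    profile = red_profile(sphere, spec)
    x_star = profile.x_min_closed_form
    grid = np.array(spec.grid)
    dist = np.abs(grid - x_star)
    nearest = grid[dist <= dist.min() + 1e-12]
    # ties resolve to the smaller composition
    assert profile.x_min_grid == pytest.approx(nearest.min(), abs=0.1 + 1e-9)


@settings(derandomize=True, max_examples=200)
@given(sphere=spheres, s1=solvent_triples, s2=solvent_triples)
def test_swapping_solvents_reflects_the_minimum_composition(sphere, s1, s2):
    x_fwd, red_fwd = min_red_closed_form(sphere, s1, s2)
    x_rev, red_rev = min_red_closed_form(sphere, s2, s1)
    if 1e-9 < x_fwd < 1 - 1e-9:  # interior: reflection is exact
        assert x_rev == pytest.approx(1.0 - x_fwd, abs=1e-9)
    assert red_rev == pytest.approx(red_fwd, abs=1e-9)
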
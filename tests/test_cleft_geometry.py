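"""Shrake–Rupley SASA, loop–cysteine distance and open/closed states."""

import numpy as np
import pytest

from e2dyn.cleft_geometry import (
    VDW_RADII,
    StateThresholds,
    fibonacci_sphere,
    atom_radii,
    shrake_rupley,
    relative_sidechain_sasa,
    loop_cys_distance,
    classify_state,
    cleft_profile,
)
from e2dyn.structio import ConformerSet
from e2dyn.synthetic import (
    preset_spec,
    preset_region,
    generate_ensemble,
    build_scaffold,
)

from conftest import make_conformers


def dense_integration_sasa(center, radius, others, other_radii, probe, n_theta=400):
    """Independent oracle: latitude-longitude quadrature of the exposed
    fraction of one expanded sphere."""
    R = radius + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    area = 0.0
    for t in theta:
        n_phi = max(8, int(round(2 * n_theta * np.sin(t))))
        phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
        pts = center + R * np.column_stack(
            [np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.full(n_phi, np.cos(t))]
        )
        exposed = np.ones(n_phi, dtype=bool)
        for c, r in zip(others, other_radii):
            exposed &= np.sum((pts - c) ** 2, axis=1) >= (r + probe) ** 2
        # each point represents a patch of area R² sinθ dθ dφ
        area += exposed.sum() * R**2 * np.sin(t) * (np.pi / n_theta) * (2 * np.pi / n_phi)
    return area


class TestShrakeRupley:
    def test_isolated_atom_full_sphere_exact(self):
        r, w = 1.7, 1.4
        sasa = shrake_rupley(np.zeros((1, 3)), np.array([r]), probe=w, n_points=200)
        assert sasa[0] == pytest.approx(4 * np.pi * (r + w) ** 2, rel=1e-12)

    def test_distant_atoms_keep_full_spheres(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        radii = np.array([1.7, 1.8])
        sasa = shrake_rupley(coords, radii, probe=1.4, n_points=500)
        for i in range(2):
            assert sasa[i] == pytest.approx(4 * np.pi * (radii[i] + 1.4) ** 2, rel=1e-12)

    def test_engulfed_atom_has_zero_area(self):
        coords = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        radii = np.array([3.5, 1.0])  # small sphere strictly inside the big one
        sasa = shrake_rupley(coords, radii, probe=1.0, n_points=500)
        assert sasa[1] == 0.0

    @pytest.mark.parametrize("separation", [3.0, 4.5, 5.5])
    def test_partial_overlap_matches_dense_integration(self, separation):
        coords = np.array([[0.0, 0, 0], [separation, 0, 0]])
        radii = np.array([1.7, 1.8])
        probe = 1.4
        sasa = shrake_rupley(coords, radii, probe=probe, n_points=960)
        oracle = dense_integration_sasa(
            coords[0], radii[0], coords[1:], radii[1:], probe
        )
        assert sasa[0] == pytest.approx(oracle, rel=0.02)

    def test_point_count_convergence_below_1_percent(self):
        spec = preset_spec("cdc34_like", seed=0)
        spec.n_frames, spec.equil_frames = 1, 0
        cs = generate_ensemble(spec)
        coords, radii = cs.frames[0], atom_radii(cs)
        a = shrake_rupley(coords, radii, n_points=960)
        b = shrake_rupley(coords, radii, n_points=1920)
        # convergence quoted as exposed-fraction change (per cent of each
        # atom's full expanded sphere), the scale on which relative
        # accessibility is reported
        full = 4 * np.pi * (radii + 1.4) ** 2
        assert np.max(np.abs(a - b) / full) < 0.01

    def test_area_invariant_under_rigid_motion(self, rng):
        coords = rng.normal(size=(15, 3)) * 3
        radii = np.full(15, 1.6)
        Rz = np.array([[0.0, -1.0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        moved = coords @ Rz.T + np.array([5.0, -3.0, 2.0])
        a = shrake_rupley(coords, radii)
        # same point lattice rotated with the frame: exact equivariance
        b = shrake_rupley(
            moved, radii, sphere_points=fibonacci_sphere(960) @ Rz.T
        )
        assert np.allclose(a, b, rtol=1e-6, atol=1e-9)
        # with the fixed lattice, totals still agree to quadrature accuracy
        c = shrake_rupley(moved, radii)
        assert a.sum() == pytest.approx(c.sum(), rel=0.01)

    def test_agrees_with_independent_biotite_implementation(self, rng):
        import biotite.structure as struc

        coords = rng.normal(size=(20, 3)) * 3
        radii = np.full(20, 1.7)
        ours = shrake_rupley(coords, radii, probe=1.4, n_points=2000)
        arr = struc.AtomArray(20)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 21)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=2000)
        assert np.all(np.abs(ours - theirs) < np.maximum(0.02 * theirs, 0.5))

    def test_parameter_contracts(self):
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((1, 3)), np.array([0.0]))
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((1, 3)), np.array([1.0]), n_points=8)

    def test_sphere_points_are_unit_and_well_spread(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-2


class TestRelativeSasa:
    def test_isolated_sidechain_is_100_percent(self):
        cs = make_conformers(
            np.zeros((1, 1, 3)), residue_numbers=[95], atom_names=["SG"], elements=["S"]
        )
        series = relative_sidechain_sasa(cs, 95)
        assert series.values[0] == pytest.approx(100.0)

    def test_fully_caged_sidechain_is_0_percent(self):
        cage = 3.2 * fibonacci_sphere(80)
        coords = np.vstack([[0.0, 0, 0], cage])[None]
        cs = make_conformers(
            coords,
            residue_numbers=[95] + [1] * 80,
            atom_names=["SG"] + ["CA"] * 80,
            elements=["S"] + ["C"] * 80,
        )
        series = relative_sidechain_sasa(cs, 95)
        assert series.values[0] == 0.0

    def test_stable_under_point_count(self, rng):
        spec = preset_spec("cdc34_like", seed=1)
        spec.n_frames, spec.equil_frames = 3, 0
        cs = generate_ensemble(spec)
        a = relative_sidechain_sasa(cs, 95, n_points=960).values
        b = relative_sidechain_sasa(cs, 95, n_points=1920).values
        assert np.allclose(a, b, atol=1.0)  # percentage points

    def test_residue_without_sidechain_rejected(self, rng):
        cs = make_conformers(rng.normal(size=(1, 3, 3)))
        with pytest.raises(ValueError, match="side-chain"):
            relative_sidechain_sasa(cs, 1)


def basin_frames():
    """Noise-free frames with the loop placed at each preset basin."""
    spec = preset_spec("cdc34_like")
    atoms, scaffold = build_scaffold(spec)
    resnum = atoms["residue_number"].to_numpy()
    loop = np.flatnonzero((resnum >= 103) & (resnum <= 114))
    frames = []
    for b in spec.basins:
        fr = scaffold.copy()
        fr[loop] += b.loop_offset
        frames.append(fr)
    return ConformerSet(atoms=atoms, frames=np.array(frames)), spec


class TestLoopDistanceAndStates:
    def test_constructed_offset_gives_exact_distance(self):
        coords = np.zeros((1, 4, 3))
        coords[0, 2:] = [[10.0, 0, 0], [10.0, 0, 0]]
        cs = make_conformers(
            coords,
            residue_numbers=[95, 95, 103, 104],
            atom_names=["CA", "SG", "CA", "CA"],
            elements=["C", "S", "C", "C"],
        )
        region = preset_region("cdc34_like")
        d = loop_cys_distance(cs, type(region)(acidic_loop=(103, 104)))
        assert d.values[0] == pytest.approx(10.0)
        assert d.values[0] / 10.0 == pytest.approx(1.0)  # nm

    def test_delta12_ensemble_reports_not_applicable(self):
        spec = preset_spec("delta12_like")
        spec.n_frames, spec.equil_frames = 3, 0
        cs = generate_ensemble(spec)
        with pytest.raises(ValueError, match="not applicable|no acidic loop"):
            loop_cys_distance(cs, preset_region("delta12_like"))

    def test_preset_basin_distances_match_design(self):
        cs, spec = basin_frames()
        d = loop_cys_distance(cs, preset_region("cdc34_like"))
        assert np.allclose(d.values, [5.0, 9.01, 11.88, 15.30, 17.76], atol=0.02)
        assert np.all(np.diff(d.values) > 0)

    def test_occlusion_monotone_in_loop_distance(self):
        cs, _ = basin_frames()
        sas = relative_sidechain_sasa(cs, 95).values
        assert np.all(np.diff(sas) >= 0)  # closer loop never more exposed
        assert sas[0] < sas[-1]

    def test_boundary_conventions(self):
        th = StateThresholds(d_closed=8.0, d_open=12.0)
        assert classify_state(8.0, thresholds=th)[0] == "closed"
        assert classify_state(10.0, thresholds=th)[0] == "intermediate"
        assert classify_state(12.0, thresholds=th)[0] == "open"

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            StateThresholds(d_closed=12.0, d_open=8.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_phospho_more_open_than_wild_type(self, seed):
        fractions = {}
        for name in ("cdc34_like", "phospho_like"):
            spec = preset_spec(name, seed=seed)
            cs = generate_ensemble(spec)
            cs = cs.subset_frames(slice(spec.equil_frames, None))
            d = loop_cys_distance(cs, preset_region(name))
            states = classify_state(d.values)
            fractions[name] = np.mean(states == "open")
        assert fractions["phospho_like"] > fractions["cdc34_like"]


class TestCleftProfile:
    def test_single_frame_summary_equals_frame_values(self):
        cs, _ = basin_frames()
        one = cs.subset_frames([0])
        prof = cleft_profile(one, preset_region("cdc34_like"))
        assert prof.avsas == pytest.approx(prof.table["sas_pct"].iloc[0])
        assert prof.state_fractions["closed"] == 1.0
        assert prof.pearson_r is None and "undefined" in prof.pearson_note

    def test_accessibility_increases_with_distance(self):
        spec = preset_spec("cdc34_like", seed=5)
        spec.n_frames, spec.equil_frames = 400, 40
        cs = generate_ensemble(spec).subset_frames(slice(40, None, 4))
        prof = cleft_profile(cs, preset_region("cdc34_like"))
        assert prof.pearson_r is not None and prof.pearson_r > 0

    def test_zero_variance_distance_reports_undefined_correlation(self):
        cs, _ = basin_frames()
        two = cs.subset_frames([1, 1])
        prof = cleft_profile(two, preset_region("cdc34_like"))
        assert prof.pearson_r is None

    def test_radii_table_defaults(self):
        cs, _ = basin_frames()
        radii = atom_radii(cs)
        assert set(np.round(np.unique(radii), 2)) == {VDW_RADII["C"], VDW_RADII["S"]}
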
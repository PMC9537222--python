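"""Monodomain tissue model: geometry, assembly, assignment, propagation."""

import dataclasses

import numpy as np
import pytest

import atriavar as av
from atriavar.crn import REST_STATE
from atriavar.crn import _step as cell_step  # same kernel the solver uses
from atriavar.cv import measure_cv
from atriavar.tissue import (DiffusionOperator, MaterialRegion, Stimulus,
                             assemble_system, conductivity_tensor,
                             node_parameter_arrays, run_monodomain)


def test_default_slab_dimensions(materials):
    grid = av.build_slab(1.8, 1.8, 18.0, 300.0, materials["RA"])
    assert (grid.nx, grid.ny, grid.nz) == (6, 6, 60)
    assert grid.n_elements == 2160
    assert grid.n_nodes == 2989
    assert grid.h == pytest.approx(0.3)


def test_non_multiple_dimension_rejected(materials):
    with pytest.raises(ValueError):
        av.build_slab(1.7, 1.8, 18.0, 300.0, materials["RA"])


def test_material_table(materials):
    assert set(materials) >= {"RA", "CT", "PV", "BB/PM", "ISTMO", "SAN",
                              "FO", "CS", "LA", "FO_RING"}
    ra = materials["RA"]
    assert ra.conductive and not ra.isotropic
    assert ra.sigma_L >= ra.sigma_T > 0
    assert sum(ra.mixture.values()) == pytest.approx(1.0)
    fo = materials["FO"]
    assert not fo.conductive
    assert materials["ISTMO"].isotropic


def test_material_validation():
    with pytest.raises(ValueError):
        MaterialRegion("X", {"RA": 0.4}, 1.0, 0.5, True)   # mixture != 1
    with pytest.raises(ValueError):
        MaterialRegion("X", {"RA": 1.0}, 0.5, 1.0, True)   # sigma_T > sigma_L


def test_conductivity_tensor_axes(materials):
    ra = materials["RA"]
    D = conductivity_tensor(ra, np.array([0.0, 0.0, 1.0]))
    d_l = ra.sigma_L / (1400.0 * 1.0) * 100.0
    assert D[2, 2] == pytest.approx(d_l)
    assert D[0, 0] == pytest.approx(d_l * ra.r)
    assert D[0, 0] == D[1, 1] < D[2, 2]
    iso = conductivity_tensor(materials["ISTMO"], np.array([0.0, 0.0, 1.0]))
    assert iso[0, 0] == pytest.approx(iso[2, 2])
    assert not np.any(conductivity_tensor(materials["FO"],
                                          np.array([0, 0, 1.0])))


def test_stiffness_nullspace_and_symmetry(materials):
    grid = av.build_slab(0.9, 0.9, 1.8, 300.0, materials["RA"])
    K, m = assemble_system(grid)
    assert np.allclose((K - K.T).data, 0.0)
    # constant field is in the nullspace (no-flux natural BCs)
    assert np.allclose(K @ np.ones(grid.n_nodes), 0.0, atol=1e-12)
    assert m.sum() == pytest.approx(grid.n_elements * grid.h ** 3)


def test_diffusion_conserves_and_smooths(materials):
    grid = av.build_slab(0.9, 0.9, 1.8, 300.0, materials["RA"])
    op = DiffusionOperator(grid, dt=0.02)
    rng = np.random.default_rng(0)
    v = rng.normal(-80.0, 5.0, grid.n_nodes)
    total0, var0 = op.total(v), v.var()
    for _ in range(200):
        v = op.step(v)
    assert op.total(v) == pytest.approx(total0, rel=1e-10)
    assert v.var() < var0  # diffusion can only smooth


def test_assignment_modes(small_pop, small_pops, materials):
    grid = av.build_slab(0.9, 0.9, 3.0, 300.0, materials["RA"])
    het = av.assign_ap_models(grid, small_pops, small_pop,
                              "heterogeneous", seed=3)
    het2 = av.assign_ap_models(grid, small_pops, small_pop,
                               "heterogeneous", seed=3)
    np.testing.assert_array_equal(het.node_model, het2.node_model)
    hom = av.assign_ap_models(grid, small_pops, small_pop,
                              "homogeneous", seed=3)
    # homogeneous: every node of a region uses the regional mean model
    for region, rpop in small_pops.items():
        sel = hom.node_region == region
        if sel.any():
            assert set(hom.node_model[sel]) == {rpop.mean_model_id}
    assert set(het.node_model) <= set(small_pop.stable["model_id"])
    with pytest.raises(ValueError):
        av.assign_ap_models(grid, small_pops, small_pop, "banana", 0)


def test_mixture_shares(small_pop, small_pops, materials):
    """Node-level region shares follow the material mixture fractions."""
    grid = av.build_slab(1.8, 1.8, 18.0, 300.0, materials["RA"])
    grid = av.assign_ap_models(grid, small_pops, small_pop,
                               "heterogeneous", seed=0)
    regions, counts = np.unique(grid.node_region, return_counts=True)
    shares = dict(zip(regions, counts / grid.n_nodes))
    mix = materials["RA"].mixture  # RA 80.0%, AVR 7.9%, RAA 12.1%
    populated = {r: f for r, f in mix.items()
                 if small_pops[r] is not None and small_pops[r].n > 0}
    norm = sum(populated.values())
    for r, f in populated.items():
        assert shares.get(r, 0.0) == pytest.approx(f / norm, abs=0.03)


def test_decoupled_limit_matches_single_cell(small_pop, small_pops,
                                             materials):
    """With sigma = 0 every tissue node integrates exactly like one cell."""
    mat = dataclasses.replace(materials["RA"], sigma_L=0.0, sigma_T=0.0)
    grid = av.build_slab(0.3, 0.3, 0.9, 300.0, mat)
    nn = grid.n_nodes
    states = np.tile(REST_STATE, (nn, 1))
    stim = Stimulus(nodes=np.arange(nn), amplitude=-45.0, duration=1.0)
    sol = run_monodomain(grid, states, [stim], duration=40.0, dt=0.02,
                         frame_dt=1.0)

    y = REST_STATE.copy()
    dy = np.empty(21)
    gi = np.empty(15)
    gt = np.empty(15)
    single = []
    for k in range(int(round(40.0 / 0.02)) + 1):
        t = k * 0.02
        if abs(t - round(t)) < 1e-9 and round(t) <= 40:
            single.append(y[0])
        if k == int(round(40.0 / 0.02)):
            break
        cell_step(y, np.ones(9), -45.0 if t < 1.0 else 0.0, 0.02, dy, gi, gt)
    single = np.array(single)
    np.testing.assert_allclose(sol.frames[:, 0], single, atol=1e-4)
    # all nodes identical
    assert np.ptp(sol.frames[-1, :]) < 1e-9


def test_rest_persistence(materials):
    grid = av.build_slab(0.3, 0.3, 0.9, 300.0, materials["RA"])
    states = np.tile(REST_STATE, (grid.n_nodes, 1))
    sol = run_monodomain(grid, states, [], duration=20.0, dt=0.02)
    assert np.abs(sol.frames - REST_STATE[0]).max() < 0.05
    assert np.all(np.isnan(sol.crossing))


def test_activation_symmetry(materials):
    """Mid-plane stimulus gives an activation map symmetric in z."""
    grid = av.build_slab(0.9, 0.9, 6.0, 300.0, materials["RA"])
    states = np.tile(REST_STATE, (grid.n_nodes, 1))
    coords = grid.node_coords()
    iz = np.round(coords[:, 2] / grid.h).astype(int)
    mid = grid.nz // 2
    stim = Stimulus(nodes=np.flatnonzero(iz == mid), amplitude=-80.0,
                    duration=2.0)
    sol = run_monodomain(grid, states, [stim], duration=60.0, dt=0.02,
                         frame_dt=None, stop_after_crossing_margin=0.5)
    for k in range(mid + 1):
        a = sol.crossing[iz == mid - k]
        b = sol.crossing[iz == mid + k]
        np.testing.assert_allclose(np.sort(a), np.sort(b), atol=0.05)


def test_cv_increases_with_sigma(small_pop, small_pops, materials):
    cvs = []
    # sigma range chosen in the well-resolved CV regime: at sigma ~ 1 the
    # 300 um mesh depresses CV and steepens the apparent exponent
    for sig in (2.0, 4.0, 8.0):
        mat = dataclasses.replace(materials["ISTMO"], sigma_L=sig,
                                  sigma_T=sig)
        grid = av.build_slab(0.9, 0.9, 9.0, 300.0, mat)
        grid = av.assign_ap_models(grid, small_pops, small_pop,
                                   "homogeneous", seed=0)
        mults, states = node_parameter_arrays(grid, small_pop)
        z = grid.node_coords()[:, 2]
        stim = Stimulus(nodes=np.flatnonzero(z < grid.h + 1e-9))
        sol = run_monodomain(grid, states, [stim], duration=120.0, dt=0.02,
                             mults=mults, frame_dt=None,
                             stop_after_crossing_margin=0.5)
        cvs.append(measure_cv(sol, grid))
    assert cvs[0] < cvs[1] < cvs[2]
    # cable scaling: CV ~ sqrt(sigma) -> log-log slope near 0.5
    slope = np.log(cvs[2] / cvs[0]) / np.log(4.0)
    assert 0.4 < slope < 0.6


def test_two_region_slab_and_prepace(materials):
    grid = av.build_two_region_slab(0.9, 0.9, 3.0, 300.0, materials["RA"],
                                    materials["CT"])
    ez = grid.elem_lattice_index()[:, 2]
    assert np.all(grid.elem_material[ez < grid.nz // 2] == 0)
    assert np.all(grid.elem_material[ez >= grid.nz // 2] == 1)
    states = np.tile(REST_STATE, (grid.n_nodes, 1))
    out = av.pre_pace_tissue(grid, states, np.array([0]), n_beats=0)
    np.testing.assert_array_equal(out, states)


def test_bad_initial_shape_rejected(materials):
    grid = av.build_slab(0.3, 0.3, 0.9, 300.0, materials["RA"])
    with pytest.raises(ValueError):
        run_monodomain(grid, np.zeros((3, 21)), [], duration=1.0)
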
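"""Coupling analysis: boundary exclusion oracle, node biomarkers and the
directional electrotonic-smoothing findings on a heterogeneous slab."""

import numpy as np
import pandas as pd
import pytest

import atriavar as av
from atriavar.coupling import (coupling_effect, exclude_boundary_layers,
                               group_nodes, node_biomarkers,
                               triangulation_comparison)
from atriavar.tissue import MonodomainSolution, Stimulus, node_parameter_arrays


# ---------------------------------------------------------------------------
# boundary-layer exclusion vs an independent brute-force implementation
# ---------------------------------------------------------------------------

def _brute_force_keep(grid, n_layers, stim_nodes=None):
    """Reference implementation: explicit Manhattan distance from sources."""
    nn = grid.n_nodes
    keep = np.ones(nn, dtype=bool)
    if n_layers == 0:
        return keep
    lat = grid.elem_lattice_index()
    mat = grid.elem_material
    conn = grid.element_nodes()
    idx = {tuple(p): e for e, p in enumerate(lat)}

    sources = set()
    for e, (ex, ey, ez) in enumerate(lat):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                  (0, 0, 1), (0, 0, -1)):
            nb = idx.get((ex + d[0], ey + d[1], ez + d[2]))
            if nb is None:
                continue  # outer surface never triggers
            if mat[nb] != mat[e]:
                sources.add(e)
            if not grid.materials[mat[nb]].conductive:
                sources.add(e)
        if not grid.materials[mat[e]].conductive:
            sources.add(e)
    if stim_nodes is not None:
        sn = set(np.asarray(stim_nodes).tolist())
        for e in range(grid.n_elements):
            if sn & set(conn[e].tolist()):
                sources.add(e)

    flagged = set()
    src = np.array(sorted(sources))
    if src.size:
        for e, p in enumerate(lat):
            d = np.abs(lat[src] - p).sum(axis=1)
            if d.min() <= n_layers - 1:
                flagged.add(e)
    for e in flagged:
        keep[conn[e]] = False
    return keep


@pytest.mark.parametrize("n_layers", [0, 1, 3])
def test_exclusion_matches_brute_force_two_region(materials, n_layers):
    grid = av.build_two_region_slab(0.9, 0.9, 6.0, 300.0, materials["RA"],
                                    materials["CT"])
    got = exclude_boundary_layers(grid, n_layers=n_layers)
    want = _brute_force_keep(grid, n_layers)
    np.testing.assert_array_equal(got, want)


def test_exclusion_with_stimulus_and_nonconductive(materials):
    grid = av.build_two_region_slab(0.9, 0.9, 6.0, 300.0, materials["RA"],
                                    materials["FO"])
    stim = grid.boundary_layer_nodes(axis=2, side=0)
    got = exclude_boundary_layers(grid, n_layers=2, stim_nodes=stim)
    want = _brute_force_keep(grid, 2, stim_nodes=stim)
    np.testing.assert_array_equal(got, want)
    # the whole non-conductive half is excluded
    z = grid.node_coords()[:, 2]
    assert not got[z > 3.0 + 1e-9].any()


def test_outer_surface_never_triggers(materials):
    grid = av.build_slab(0.9, 0.9, 3.0, 300.0, materials["RA"])
    assert exclude_boundary_layers(grid, n_layers=3).all()


def test_default_three_layers_on_standard_slab(materials):
    grid = av.build_two_region_slab(1.8, 1.8, 18.0, 300.0, materials["RA"],
                                    materials["CT"])
    keep = exclude_boundary_layers(grid, n_layers=3)
    iz = np.round(grid.node_coords()[:, 2] / grid.h).astype(int)
    # interface elements 29|30 plus two dilation layers -> nodes iz 27..33
    assert not keep[(iz >= 27) & (iz <= 33)].any()
    assert keep[(iz < 27) | (iz > 33)].all()


# ---------------------------------------------------------------------------
# node biomarkers on a synthetic analytic solution
# ---------------------------------------------------------------------------

def _analytic_solution(materials):
    grid = av.build_slab(0.3, 0.3, 0.3, 300.0, materials["RA"])
    nn = grid.n_nodes
    t = np.arange(0.0, 131.0, 1.0)
    v = np.full((t.size, nn), -80.0, dtype=np.float32)
    for i in range(nn):
        dec = (t >= 10.0) & (t <= 110.0)
        v[dec, i] = 20.0 - (t[dec] - 10.0)
    act = np.full(nn, 10.0)
    return MonodomainSolution(grid=grid, frame_times=t, frames=v,
                              activation=act, crossing=act.copy(),
                              end_states=np.zeros((nn, 21)), dt=0.02)


def test_node_biomarkers_analytic(materials):
    sol = _analytic_solution(materials)
    bm = node_biomarkers(sol)
    assert np.allclose(bm["RMP"], -80.0)
    assert np.allclose(bm["APA"], 100.0)
    assert np.allclose(bm["APD20"], 20.0)
    assert np.allclose(bm["APD50"], 50.0)
    assert np.allclose(bm["APD90"], 90.0)
    assert np.allclose(bm["TRI"], bm["APD90"] - bm["APD50"])
    assert bm.attrs["APA_low_confidence"] is True


def test_node_biomarkers_keep_mask_and_nan(materials):
    sol = _analytic_solution(materials)
    sol.activation[0] = np.nan          # node 0 never activated
    keep = np.ones(sol.grid.n_nodes, dtype=bool)
    keep[1] = False
    bm = node_biomarkers(sol, keep=keep)
    assert 1 not in bm["node"].values
    assert np.isnan(bm.loc[bm["node"] == 0, "APD90"]).all()


# ---------------------------------------------------------------------------
# coupling effect: identity at zero coupling, smoothing on a real slab
# ---------------------------------------------------------------------------

def test_coupling_effect_identity(small_pop, small_pops):
    """A 'tissue' whose node table is exactly the source population gives
    zero percent change for every biomarker (decoupled limit)."""
    rpop = small_pops["RA"]
    members = small_pop.df[small_pop.df["model_id"].isin(rpop.model_ids)]
    table = members[["RMP", "APA", "APD20", "APD50", "APD90", "TRI"]].copy()
    table["node"] = np.arange(len(table))
    table["region"] = "RA"
    table["model_id"] = members["model_id"].to_numpy()
    table["material"] = "RA"
    groups = group_nodes(table)
    rep = coupling_effect(groups, small_pops)
    assert len(rep.table) == 4
    assert np.allclose(rep.table["pct_change_mean"], 0.0, atol=1e-9)
    assert np.allclose(rep.table["pct_change_sd"], 0.0, atol=1e-9)


@pytest.fixture(scope="module")
def het_slab_run(small_pop, small_pops, materials):
    grid = av.build_slab(0.9, 0.9, 3.0, 300.0, materials["RA"])
    grid = av.assign_ap_models(grid, small_pops, small_pop,
                               "heterogeneous", seed=3)
    mults, states = node_parameter_arrays(grid, small_pop)
    stim = Stimulus(nodes=grid.boundary_layer_nodes(axis=2, side=0),
                    amplitude=-80.0, duration=2.0)
    sol = av.run_monodomain(grid, states, [stim], duration=450.0, dt=0.02,
                            mults=mults, frame_dt=1.0)
    keep = exclude_boundary_layers(grid, n_layers=1, stim_nodes=stim.nodes)
    return grid, sol, keep, stim


@pytest.fixture(scope="module")
def hom_slab_run(small_pop, small_pops, materials):
    grid = av.build_slab(0.9, 0.9, 3.0, 300.0, materials["RA"])
    grid = av.assign_ap_models(grid, small_pops, small_pop,
                               "homogeneous", seed=3)
    mults, states = node_parameter_arrays(grid, small_pop)
    stim = Stimulus(nodes=grid.boundary_layer_nodes(axis=2, side=0),
                    amplitude=-80.0, duration=2.0)
    sol = av.run_monodomain(grid, states, [stim], duration=450.0, dt=0.02,
                            mults=mults, frame_dt=1.0)
    keep = exclude_boundary_layers(grid, n_layers=1, stim_nodes=stim.nodes)
    return grid, sol, keep, stim


def test_electrotonic_smoothing_directional(het_slab_run, small_pop):
    """Tissue coupling reduces APD90 variability below the single-cell SD
    of the very models assigned to the kept nodes."""
    grid, sol, keep, _ = het_slab_run
    bm = node_biomarkers(sol, keep=keep)
    tissue_sd = bm["APD90"].std(ddof=1)
    cell_apd90 = small_pop.df.set_index("model_id").loc[
        bm["model_id"], "APD90"].to_numpy()
    cell_sd = cell_apd90.std(ddof=1)
    assert tissue_sd < cell_sd
    # early repolarisation lengthens under coupling
    cell_apd50 = small_pop.df.set_index("model_id").loc[
        bm["model_id"], "APD50"].to_numpy()
    assert bm["APD50"].mean() > cell_apd50.mean()
    # triangulation is reduced
    cell_tri = small_pop.df.set_index("model_id").loc[
        bm["model_id"], "TRI"].to_numpy()
    assert bm["TRI"].mean() < cell_tri.mean()


def test_coupling_report_shape_and_signs(het_slab_run, small_pops):
    grid, sol, keep, _ = het_slab_run
    groups = group_nodes(node_biomarkers(sol, keep=keep))
    rep = coupling_effect(groups, small_pops)
    assert {"material", "region", "biomarker", "pct_change_mean",
            "pct_change_sd"} <= set(rep.table.columns)
    apd90 = rep.table[rep.table["biomarker"] == "APD90"]
    n_weighted = (apd90["pct_change_sd"] * apd90["n_nodes"]).sum() / \
        apd90["n_nodes"].sum()
    assert n_weighted < 0.0  # variability shrinks overall


def test_triangulation_comparison(het_slab_run, hom_slab_run, small_pops):
    _, het_sol, het_keep, _ = het_slab_run
    _, hom_sol, hom_keep, _ = hom_slab_run
    het_bm = node_biomarkers(het_sol, keep=het_keep)
    hom_bm = node_biomarkers(hom_sol, keep=hom_keep)
    table = triangulation_comparison(hom_bm, het_bm, small_pops)
    assert {"region", "TRI_hom", "TRI_het",
            "pct_change_mean_vs_pop"} <= set(table.columns)
    assert len(table) >= 1
    assert np.isfinite(table["TRI_het"]).all()
    # coupling lowers TRI relative to the single-cell population in the
    # dominant (largest) region; tiny regions are too noisy at this n
    counts = het_bm.groupby("region").size()
    dominant = counts.idxmax()
    row = table[table["region"] == dominant].iloc[0]
    assert row["pct_change_mean_vs_pop"] < 0


def test_report_serialisation(het_slab_run, small_pops, tmp_path):
    _, sol, keep, _ = het_slab_run
    rep = coupling_effect(group_nodes(node_biomarkers(sol, keep=keep)),
                          small_pops)
    rep.to_csv(tmp_path / "rep.csv")
    rep.to_json(tmp_path / "rep.json")
    back = pd.read_csv(tmp_path / "rep.csv")
    assert len(back) == len(rep.table)
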
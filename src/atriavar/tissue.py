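"""Monodomain reaction–diffusion solver on structured hexahedral slabs.

The tissue model is the monodomain equation with a transversely isotropic
conductivity tensor ``D = sigma_L [ (1-r) n_f n_f^T + r I ]`` where
``r = sigma_T / sigma_L`` and ``n_f`` is the fibre direction, with
zero-flux (no-current) boundary conditions on the outer surface.  It is
discretised with trilinear hexahedral finite elements on a regular lattice
(default spacing 300 um) and solved by first-order operator splitting at a
constant time step (default 0.02 ms): a Crank–Nicolson diffusion substep on
the assembled stiffness / lumped-mass system, then the ionic substep of the
per-node CRN models.

Conductivities are expressed in mS/cm and converted to an effective
diffusivity via a fixed surface-to-volume ratio (1400 /cm) and specific
membrane capacitance (1 uF/cm^2); since conductivities are calibrated to
conduction-velocity targets these constants only set the scale of the
reported sigma values.

Per-node ionic models come from the regional populations: each anatomical
material hosts a stated mixture of regional AP models.  ``heterogeneous``
assignment draws the source region by mixture fraction and then a member
uniformly within that regional population; ``homogeneous`` assignment uses
the same source-region draw but that region's mean AP model at every node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit, prange
from scipy.sparse.linalg import splu

from .crn import N_STATES, REST_STATE, _step

__all__ = ["MaterialRegion", "TissueGrid", "Stimulus", "MonodomainSolution",
           "load_materials", "build_slab", "build_two_region_slab",
           "assign_ap_models", "node_parameter_arrays", "run_monodomain",
           "pre_pace_tissue"]

#: Surface-to-volume ratio (1/cm) and specific capacitance (uF/cm^2) used to
#: convert conductivity (mS/cm) into monodomain diffusivity.
CHI = 1400.0
CM_SPECIFIC = 1.0


@dataclass
class MaterialRegion:
    """Anatomical tissue material: conductivities, fibre ratio and AP mixture.

    ``mixture`` maps electrophysiological source regions to fractions
    summing to 1 for conductive materials.  ``sigma_L``/``sigma_T`` are in
    mS/cm and are usually set by conduction-velocity calibration.
    """

    name: str
    mixture: dict
    sigma_L: float = 1.0
    sigma_T: float = 0.4
    conductive: bool = True
    isotropic: bool = False

    def __post_init__(self) -> None:
        if self.conductive:
            s = sum(self.mixture.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"mixture fractions of {self.name} sum to {s}")
        if self.sigma_L < self.sigma_T:
            raise ValueError("sigma_L must be >= sigma_T")

    @property
    def r(self) -> float:
        return self.sigma_T / self.sigma_L if self.sigma_L > 0 else 0.0


def load_materials(path=None) -> dict:
    """Load the packaged material table; mixtures are renormalised to 1.

    (Two printed mixtures sum to 100.1% at one-decimal precision.)
    """
    if path is None:
        path = resources.files("atriavar.data") / "materials.csv"
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        conductive = bool(row["conductive"])
        mix = {}
        if conductive and isinstance(row["mixture"], str):
            parts = [p for p in row["mixture"].split(";") if p]
            raw = {p.split(":")[0]: float(p.split(":")[1]) for p in parts}
            tot = sum(raw.values())
            mix = {k: v / tot for k, v in raw.items()}
        iso = float(row["cv_long"]) == float(row["cv_trans"])
        out[row["material"]] = MaterialRegion(
            name=row["material"], mixture=mix, conductive=conductive,
            isotropic=iso, sigma_L=1.0 if conductive else 0.0,
            sigma_T=(1.0 if iso else 0.4) if conductive else 0.0)
    return out


@dataclass
class TissueGrid:
    """Regular hexahedral lattice; node index = ix + (nx+1)(iy + (ny+1) iz)."""

    nx: int
    ny: int
    nz: int
    h: float                       # node spacing, mm
    materials: list                # list[MaterialRegion]
    elem_material: np.ndarray      # (ne,) index into materials
    node_material: np.ndarray      # (nn,) index into materials
    fibres: np.ndarray             # (n_materials, 3) unit vectors
    node_model: np.ndarray | None = None    # (nn,) model_id or -1
    node_region: np.ndarray | None = None   # (nn,) source-region label
    assignment_meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1) * (self.nz + 1)

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny * self.nz

    def node_coords(self) -> np.ndarray:
        ii = np.arange(self.n_nodes)
        ix = ii % (self.nx + 1)
        iy = (ii // (self.nx + 1)) % (self.ny + 1)
        iz = ii // ((self.nx + 1) * (self.ny + 1))
        return np.column_stack([ix, iy, iz]) * self.h

    def element_nodes(self) -> np.ndarray:
        """(ne, 8) connectivity of each trilinear hexahedron."""
        e = np.arange(self.n_elements)
        ez = e // (self.nx * self.ny)
        ey = (e // self.nx) % self.ny
        ex = e % self.nx

        def nid(ix, iy, iz):
            return ix + (self.nx + 1) * (iy + (self.ny + 1) * iz)

        return np.column_stack([
            nid(ex, ey, ez), nid(ex + 1, ey, ez),
            nid(ex + 1, ey + 1, ez), nid(ex, ey + 1, ez),
            nid(ex, ey, ez + 1), nid(ex + 1, ey, ez + 1),
            nid(ex + 1, ey + 1, ez + 1), nid(ex, ey + 1, ez + 1)])

    def elem_lattice_index(self) -> np.ndarray:
        """(ne, 3) integer (ex, ey, ez) per element, matching element order."""
        e = np.arange(self.n_elements)
        ez = e // (self.nx * self.ny)
        ey = (e // self.nx) % self.ny
        ex = e % self.nx
        return np.column_stack([ex, ey, ez])

    def boundary_layer_nodes(self, axis: int = 2, side: int = 0) -> np.ndarray:
        """Node ids of one outer face layer (e.g. the stimulus plane)."""
        coords = self.node_coords()
        n_ax = (self.nx, self.ny, self.nz)[axis]
        target = 0.0 if side == 0 else n_ax * self.h
        return np.flatnonzero(np.abs(coords[:, axis] - target) < 1e-9)


def _check_multiple(value_mm: float, h_mm: float, name: str) -> int:
    n = value_mm / h_mm
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{name}={value_mm} mm is not a multiple of "
                         f"h={h_mm} mm")
    return int(round(n))


def build_slab(length: float, width: float, height: float, h: float,
               material: MaterialRegion,
               fibre_axis: Sequence[float] = (0.0, 0.0, 1.0)) -> TissueGrid:
    """Single-material slab; dimensions in mm, spacing ``h`` in um.

    The default experiment geometry is 1.8 x 1.8 x 18 mm at 300 um, i.e.
    6 x 6 x 60 elements and 2,989 nodes, with the long axis along z.
    """
    h_mm = h / 1000.0
    nx = _check_multiple(length, h_mm, "length")
    ny = _check_multiple(width, h_mm, "width")
    nz = _check_multiple(height, h_mm, "height")
    ne = nx * ny * nz
    nn = (nx + 1) * (ny + 1) * (nz + 1)
    fib = np.asarray(fibre_axis, dtype=float)
    fib = fib / np.linalg.norm(fib)
    return TissueGrid(nx=nx, ny=ny, nz=nz, h=h_mm,
                      materials=[material],
                      elem_material=np.zeros(ne, dtype=int),
                      node_material=np.zeros(nn, dtype=int),
                      fibres=fib[None, :])


def build_two_region_slab(length: float, width: float, height: float, h: float,
                          material_a: MaterialRegion,
                          material_b: MaterialRegion,
                          fibre_axis: Sequence[float] = (0.0, 0.0, 1.0),
                          ) -> TissueGrid:
    """Butt-joined two-material slab split at the mid-plane along z.

    Surrogate for inter-regional boundaries of the organ-scale model; used
    to study how a neighbouring region distorts biomarkers near boundaries.
    Interface nodes take material A's index for grouping purposes.
    """
    grid = build_slab(length, width, height, h, material_a, fibre_axis)
    if grid.nz % 2:
        raise ValueError("height must give an even element count for a "
                         "mid-plane split")
    grid.materials = [material_a, material_b]
    grid.fibres = np.vstack([grid.fibres, grid.fibres])
    ez = grid.elem_lattice_index()[:, 2]
    grid.elem_material = np.where(ez < grid.nz // 2, 0, 1)
    iz = grid.node_coords()[:, 2] / grid.h
    grid.node_material = np.where(iz <= grid.nz // 2, 0, 1)
    return grid


def assign_ap_models(grid: TissueGrid, populations: dict, pop,
                     mode: str, seed: int) -> TissueGrid:
    """Assign a regional AP model to every node (deterministic given seed).

    Each node's source region is drawn from its material's mixture
    fractions; ``heterogeneous`` then draws a member uniformly from that
    regional population while ``homogeneous`` uses the region's mean model.
    Mixture regions whose clustered population is empty are dropped and the
    remaining fractions renormalised.  Non-conductive materials receive the
    baseline model id -1.
    """
    if mode not in ("homogeneous", "heterogeneous"):
        raise ValueError("mode must be 'homogeneous' or 'heterogeneous'")
    rng = np.random.default_rng(seed)
    nn = grid.n_nodes
    node_model = np.full(nn, -1, dtype=int)
    node_region = np.full(nn, "", dtype=object)

    for mi, mat in enumerate(grid.materials):
        nodes = np.flatnonzero(grid.node_material == mi)
        if nodes.size == 0:
            continue
        if not mat.conductive or not mat.mixture:
            continue
        regions = [r for r in mat.mixture
                   if populations.get(r) is not None
                   and populations[r].n > 0]
        if not regions:
            raise ValueError(f"no populated source region for material "
                             f"{mat.name}")
        w = np.array([mat.mixture[r] for r in regions])
        w = w / w.sum()
        draw = rng.choice(len(regions), size=nodes.size, p=w)
        for k, r in enumerate(regions):
            sel = nodes[draw == k]
            node_region[sel] = r
            rpop = populations[r]
            if mode == "heterogeneous":
                node_model[sel] = rng.choice(rpop.model_ids, size=sel.size)
            else:
                node_model[sel] = rpop.mean_model_id
    grid = replace(grid, node_model=node_model, node_region=node_region,
                   assignment_meta={"mode": mode, "seed": seed})
    return grid


def node_parameter_arrays(grid: TissueGrid, pop):
    """Per-node conductance multipliers and checkpoint initial states."""
    if grid.node_model is None:
        raise ValueError("grid has no AP-model assignment")
    nn = grid.n_nodes
    mults = np.ones((nn, 9))
    states = np.tile(REST_STATE, (nn, 1))
    df = pop.df.set_index("model_id")
    scal_cols = ["s_gNa", "s_gTo", "s_gKur", "s_gKr", "s_gKs",
                 "s_gK1", "s_gCaL", "s_gNaK", "s_gNaCa"]
    ids = np.unique(grid.node_model)
    for mid in ids:
        if mid < 0:
            continue
        sel = grid.node_model == mid
        mults[sel] = df.loc[mid, scal_cols].to_numpy(float)
        states[sel] = pop.checkpoints[pop.df.index[
            pop.df["model_id"] == mid][0]]
    return mults, states


# ---------------------------------------------------------------------------
# FEM assembly
# ---------------------------------------------------------------------------

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_CORNERS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                    dtype=float)


def _element_stiffness(h: float, D: np.ndarray) -> np.ndarray:
    """8x8 stiffness of a cube element of edge h (mm) for tensor D (mm^2/ms)."""
    ke = np.zeros((8, 8))
    jac = h / 2.0
    detj = jac ** 3
    for gx in _GP:
        for gy in _GP:
            for gz in _GP:
                xi = np.array([gx, gy, gz])
                # dN/dxi for trilinear shape functions
                dn = np.empty((3, 8))
                for a in range(8):
                    c = _CORNERS[a]
                    dn[0, a] = c[0] * (1 + c[1] * xi[1]) * (1 + c[2] * xi[2]) / 8
                    dn[1, a] = c[1] * (1 + c[0] * xi[0]) * (1 + c[2] * xi[2]) / 8
                    dn[2, a] = c[2] * (1 + c[0] * xi[0]) * (1 + c[1] * xi[1]) / 8
                b = dn / jac
                ke += detj * b.T @ D @ b
    return ke


def conductivity_tensor(mat: MaterialRegion, fibre: np.ndarray) -> np.ndarray:
    """Monodomain diffusivity tensor in mm^2/ms from sigma in mS/cm."""
    if not mat.conductive or mat.sigma_L <= 0:
        return np.zeros((3, 3))
    d_l = mat.sigma_L / (CHI * CM_SPECIFIC) * 100.0  # mm^2/ms
    r = mat.r
    nf = np.asarray(fibre, dtype=float)
    return d_l * ((1.0 - r) * np.outer(nf, nf) + r * np.eye(3))


def assemble_system(grid: TissueGrid):
    """Assemble stiffness K (with -div(D grad) sign) and lumped mass M."""
    conn = grid.element_nodes()
    nn = grid.n_nodes
    h = grid.h
    kes = {}
    for mi, mat in enumerate(grid.materials):
        kes[mi] = _element_stiffness(h, conductivity_tensor(
            mat, grid.fibres[mi]))
    rows, cols, vals = [], [], []
    for mi in kes:
        elems = np.flatnonzero(grid.elem_material == mi)
        if elems.size == 0 or not np.any(kes[mi]):
            continue
        c = conn[elems]                      # (ne_m, 8)
        ke = kes[mi]
        rows.append(np.repeat(c, 8, axis=1).ravel())
        cols.append(np.tile(c, (1, 8)).ravel())
        vals.append(np.tile(ke.ravel(), c.shape[0]))
    if rows:
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(nn, nn)).tocsr()
    else:
        K = sp.csr_matrix((nn, nn))
    m = np.zeros(nn)
    np.add.at(m, conn.ravel(), h ** 3 / 8.0)
    return K, m


class DiffusionOperator:
    """Crank–Nicolson step for M dV/dt = -K V with prefactorised system."""

    def __init__(self, grid: TissueGrid, dt: float):
        self.K, self.m = assemble_system(grid)
        self.dt = dt
        M = sp.diags(self.m / dt)
        self._A = splu((M + 0.5 * self.K).tocsc())
        self._B = (M - 0.5 * self.K).tocsr()

    def step(self, v: np.ndarray) -> np.ndarray:
        return self._A.solve(self._B @ v)

    def total(self, v: np.ndarray) -> float:
        """Mass-weighted integral of V (conserved by pure diffusion)."""
        return float(self.m @ v)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stimulus:
    """Transmembrane current injection on a node set.

    ``amplitude`` in pA/pF (depolarising negative), ``onset``/``duration``
    in ms; ``period``/``n_pulses`` describe a pacing train.
    """

    nodes: np.ndarray
    amplitude: float = -80.0
    duration: float = 2.0
    onset: float = 0.0
    period: float = np.inf
    n_pulses: int = 1

    def active(self, t: float) -> bool:
        if t < self.onset:
            return False
        k = 0 if not np.isfinite(self.period) else int(
            (t - self.onset) // self.period)
        if k >= self.n_pulses:
            return False
        rel = t - self.onset - (k * self.period if np.isfinite(self.period)
                                else 0.0)
        return 0.0 <= rel < self.duration


@njit(parallel=True, cache=True)
def _ionic_all(states, mults, istim, dt, dy, gi, gt):
    for i in prange(states.shape[0]):
        _step(states[i], mults[i], istim[i], dt, dy[i], gi[i], gt[i])


@dataclass
class MonodomainSolution:
    """Voltage frames plus per-node activation data and end-state checkpoint.

    ``activation`` is the time of the maximum temporal voltage step from
    the fine solver trace (NaN where no upstroke was seen);
    ``crossing`` is the first upward crossing of -10 mV, used for
    conduction-velocity measurement and early stopping.
    """

    grid: TissueGrid
    frame_times: np.ndarray
    frames: np.ndarray             # (nt, nn) float32
    activation: np.ndarray
    crossing: np.ndarray
    end_states: np.ndarray
    dt: float
    stimuli: list = field(default_factory=list)

    def apd90_map(self) -> np.ndarray:
        from .coupling import node_biomarkers
        bm = node_biomarkers(self)
        return bm["APD90"].to_numpy(float)

    def repolarisation_map(self) -> np.ndarray:
        return self.activation + self.apd90_map()


def run_monodomain(grid: TissueGrid,
                   initial: np.ndarray,
                   stimuli: Sequence[Stimulus],
                   duration: float,
                   dt: float = 0.02,
                   mults: np.ndarray | None = None,
                   frame_dt: float | None = 1.0,
                   crossing_level: float = -10.0,
                   stop_after_crossing_margin: float | None = None,
                   ) -> MonodomainSolution:
    """Operator-split monodomain integration.

    ``initial`` is an (n_nodes, 21) state array (single-cell checkpoints or
    a tissue checkpoint); ``mults`` the per-node conductance multipliers
    (baseline when omitted).  Voltage frames are stored every ``frame_dt``
    ms (None disables storage).  When ``stop_after_crossing_margin`` is
    set, integration stops that many ms after every conductive node has
    crossed ``crossing_level`` upward — enough for activation mapping.
    Non-finite voltages abort with the offending frame index.
    """
    nn = grid.n_nodes
    states = np.array(initial, dtype=float)
    if states.shape != (nn, N_STATES):
        raise ValueError("initial states must be (n_nodes, 21)")
    if mults is None:
        mults = np.ones((nn, 9))
    mults = np.asarray(mults, dtype=float)

    diff = DiffusionOperator(grid, dt)
    dy = np.empty((nn, N_STATES))
    gi = np.empty((nn, 15))
    gt = np.empty((nn, 15))
    istim = np.zeros(nn)

    conductive = np.array([grid.materials[m].conductive
                           for m in grid.node_material])
    n_steps = int(round(duration / dt))
    act = np.full(nn, np.nan)
    best_dv = np.zeros(nn)
    cross = np.full(nn, np.nan)

    frames = []
    frame_times = []
    next_frame = 0.0
    stop_at = np.inf

    v_prev = states[:, 0].copy()
    for step_i in range(n_steps + 1):
        t = step_i * dt
        if frame_dt is not None and t >= next_frame - 1e-9:
            frames.append(states[:, 0].astype(np.float32).copy())
            frame_times.append(t)
            next_frame += frame_dt
        if step_i == n_steps or t >= stop_at:
            break

        istim[:] = 0.0
        for s in stimuli:
            if s.active(t):
                istim[s.nodes] = s.amplitude

        # ionic substep then diffusion substep (Godunov splitting)
        _ionic_all(states, mults, istim, dt, dy, gi, gt)
        states[:, 0] = diff.step(states[:, 0])

        v = states[:, 0]
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite voltage at step {step_i} (t={t:.2f} ms)")
        dv = v - v_prev
        upd = dv > best_dv
        best_dv[upd] = dv[upd]
        act[upd] = t + dt
        newly = (v >= crossing_level) & (v_prev < crossing_level) & np.isnan(cross)
        cross[newly] = t + dt
        v_prev[:] = v

        if (stop_after_crossing_margin is not None and not np.isfinite(stop_at)
                and not np.any(np.isnan(cross[conductive]))):
            stop_at = t + stop_after_crossing_margin

    act[np.isnan(cross)] = np.nan  # no upstroke -> no activation
    return MonodomainSolution(
        grid=grid,
        frame_times=np.asarray(frame_times),
        frames=(np.asarray(frames) if frames
                else np.empty((0, nn), dtype=np.float32)),
        activation=act, crossing=cross, end_states=states, dt=dt,
        stimuli=list(stimuli))


def pre_pace_tissue(grid: TissueGrid,
                    initial: np.ndarray,
                    stim_nodes: np.ndarray,
                    n_beats: int,
                    bcl: float = 800.0,
                    amplitude: float = -80.0,
                    duration: float = 2.0,
                    dt: float = 0.02,
                    mults: np.ndarray | None = None) -> np.ndarray:
    """Stabilise the coupled tissue with a pacing train; returns checkpoint.

    ``n_beats=0`` returns the single-cell-derived initial states unchanged.
    """
    if n_beats == 0:
        return np.array(initial, dtype=float)
    train = Stimulus(nodes=np.asarray(stim_nodes), amplitude=amplitude,
                     duration=duration, onset=0.0, period=bcl,
                     n_pulses=n_beats)
    sol = run_monodomain(grid, initial, [train], duration=n_beats * bcl,
                         dt=dt, mults=mults, frame_dt=None)
    return sol.end_states
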
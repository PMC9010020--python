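"""Synthetic tracked mosaic epithelium with known ground truth.

The generator emulates the statistical structure of tissue-scale neural
plate tracking data: a sheet of polygonal cells (jittered-lattice Voronoi
tessellation with shared vertices) evolving by per-cell area targeting, with

* region-specific area regimes — gradual constriction in anterior-like
  sheets; a late-onset/rapid constriction mixed with drift/dilation in
  posterior-like sheets;
* fluorescence channels coupled to the realized standardized apical area
  with configurable target correlation plus AR(1) noise;
* a bimodal membrane-BFP tracer split by genotype in a half-plane mosaic;
* scripted T1 neighbor exchanges executed by edge collapse/re-expansion.

Everything stochastic flows from one seed; identical config + seed gives
byte-identical tables.  The ground truth (genotypes, regimes, realized
trajectories, scripted events, painted intensity means) is retained for
recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from apicaltrack.image_measure import LabelFrame
from apicaltrack.tables_io import (
    CELL_COLUMNS,
    CONTROL,
    CRISPANT,
    JUNCTION_COLUMNS,
    Dataset,
    EmbryoConfig,
    encode_vertices,
)
from apicaltrack.genotype import AdjacencyFrame, classify_junction

__all__ = ["SyntheticConfig", "SyntheticGroundTruth", "Simulation",
           "build_mesh", "simulate", "render_frames"]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate an anterior-like control sheet
    with a 30% crispant half-plane mosaic.

    Area trajectories are parametrized as fractional area change: a cell's
    target area is its initial area times a regime-dependent ramp.
    ``couplings`` maps (regime, genotype) to per-channel target Pearson
    correlations between the standardized area and the channel intensity.
    """

    n_cells: int = 150
    n_frames: int = 60
    seed: int = 0
    region: str = "anterior"          # anterior-like | posterior-like regime
    crispant_fraction: float = 0.3

    # anterior-like: gradual constriction across the movie (controls);
    # crispants dilation-biased
    anterior_constriction: float = 0.5       # fractional area loss, controls
    anterior_crispant_dilation: float = 0.35  # fractional area gain
    anterior_crispant_dilating_fraction: float = 0.7

    # posterior-like: mixture of late/rapid constrictors and drift/dilators
    posterior_onset_frac: float = 0.75       # constriction onset, fraction of movie
    posterior_constriction: float = 0.5
    posterior_dilation: float = 0.15
    posterior_constricting_fraction: float = 0.6

    # intensity model: target correlation with standardized area per
    # (regime, genotype); channels absent from a map default to 0
    couplings: dict = field(default_factory=lambda: {
        ("anterior", CONTROL): {
            "medial_actin": -0.7, "junctional_actin": -0.5,
            "medial_Ncadherin": -0.6, "junctional_Ncadherin": -0.4,
        },
        ("anterior", CRISPANT): {
            "medial_actin": -0.15, "junctional_actin": -0.1,
            "medial_Ncadherin": 0.1, "junctional_Ncadherin": 0.05,
        },
        ("posterior", CONTROL): {
            "medial_actin": -0.3, "junctional_actin": -0.3,
            "medial_Ncadherin": 0.0, "junctional_Ncadherin": 0.0,
        },
        ("posterior", CRISPANT): {
            "medial_actin": -0.2, "junctional_actin": -0.2,
            "medial_Ncadherin": 0.0, "junctional_Ncadherin": 0.0,
        },
    })
    # junction-channel target correlation with standardized junction length
    junction_couplings: dict = field(default_factory=lambda: {
        "actin": -0.5, "Ncadherin": -0.3,
    })
    intensity_baseline: float = 100.0
    noise_sd: float = 1.0
    noise_rho: float = 0.8
    # smoothing window the downstream analysis will apply; the generator
    # compensates for the attenuation of its own AR(1) noise under this
    # window so configured couplings are realized on the smoothed series
    analysis_window: int = 7

    bfp_control_mean: float = 100.0
    bfp_crispant_mean: float = 1000.0
    bfp_sd: float = 50.0

    scripted_t1_frames: list = field(default_factory=list)

    microns_per_pixel: float = 0.5
    z_amplitude_micron: float = 2.0
    cell_diameter_px: float = 24.0
    movie: str = "synthetic"

    def __post_init__(self):
        if not 0.0 <= self.crispant_fraction <= 1.0:
            raise ValueError("crispant_fraction must lie in [0, 1]")
        for m in self.couplings.values():
            for ch, r in m.items():
                if abs(r) >= 1:
                    raise ValueError(f"|coupling| must be < 1 ({ch}={r})")
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")

    def embryo_config(self) -> EmbryoConfig:
        return EmbryoConfig(
            movie=self.movie,
            region=self.region,
            microns_per_pixel=self.microns_per_pixel,
            ap_axis_angle_deg=90.0,
        )


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows, retained for recovery tests."""

    genotype: dict
    regime: dict
    area_trajectories: np.ndarray          # (n_cells, n_frames) realized px²
    couplings: dict
    events: list                           # scripted T1 events (dicts)
    painted_means: dict = field(default_factory=dict)  # (frame, cell) -> domain means


class Mesh:
    """Shared-vertex polygonal tessellation with adjacency.

    ``verts`` is (V, 2); ``loops[c]`` is cell c's ordered (CCW) vertex index
    list.  Adjacency = pairs of cells sharing an edge (two vertices).
    """

    def __init__(self, verts: np.ndarray, loops: list[list[int]]):
        self.verts = verts
        self.loops = loops
        self._rebuild()

    def _rebuild(self):
        self.edges = {}  # frozenset(v1, v2) -> set of cells
        for c, loop in enumerate(self.loops):
            for i in range(len(loop)):
                e = frozenset((loop[i], loop[(i + 1) % len(loop)]))
                self.edges.setdefault(e, set()).add(c)
        self.adjacency = set()
        self.shared_edge = {}
        for e, cells in self.edges.items():
            if len(cells) == 2:
                pair = frozenset(cells)
                self.adjacency.add(pair)
                self.shared_edge[pair] = tuple(sorted(e))
        # flat arrays for vectorized relaxation
        cell_idx, v_idx, prev_v, next_v = [], [], [], []
        for c, loop in enumerate(self.loops):
            n = len(loop)
            for i in range(n):
                cell_idx.append(c)
                v_idx.append(loop[i])
                prev_v.append(loop[i - 1])
                next_v.append(loop[(i + 1) % n])
        self._ci = np.array(cell_idx)
        self._vi = np.array(v_idx)
        self._pv = np.array(prev_v)
        self._nv = np.array(next_v)
        self.n_cells = len(self.loops)

    def areas(self) -> np.ndarray:
        x, y = self.verts[:, 0], self.verts[:, 1]
        cross = x[self._vi] * y[self._nv] - x[self._nv] * y[self._vi]
        a = np.zeros(self.n_cells)
        np.add.at(a, self._ci, 0.5 * cross)
        return a

    def centroids(self) -> np.ndarray:
        x, y = self.verts[:, 0], self.verts[:, 1]
        cross = x[self._vi] * y[self._nv] - x[self._nv] * y[self._vi]
        cx = (x[self._vi] + x[self._nv]) * cross
        cy = (y[self._vi] + y[self._nv]) * cross
        a = self.areas()
        sx = np.zeros(self.n_cells)
        sy = np.zeros(self.n_cells)
        np.add.at(sx, self._ci, cx)
        np.add.at(sy, self._ci, cy)
        return np.column_stack([sx, sy]) / (6.0 * a)[:, None]

    def relax(self, targets: np.ndarray, rest_edge_scale: np.ndarray,
              rest_lengths: dict, n_iter: int = 15,
              k_area: float = 0.25, k_edge: float = 0.12):
        """Move vertices so cell areas approach ``targets``.

        Gradient steps on the area residual plus an edge-length spring toward
        ``rest_lengths[edge] * rest_edge_scale``-derived targets; keeps the
        tracked geometry kinematically consistent without full mechanics.
        """
        edge_list = [tuple(sorted(e)) for e in self.edges]
        e1 = np.array([e[0] for e in edge_list])
        e2 = np.array([e[1] for e in edge_list])
        # target edge length: rest length scaled by sqrt of the mean target
        # area ratio of incident cells
        scale = np.array([
            np.sqrt(np.mean([rest_edge_scale[c] for c in self.edges[frozenset(e)]]))
            for e in edge_list
        ])
        l_t = np.array([rest_lengths[frozenset(e)] for e in edge_list]) * scale
        a0 = np.abs(targets)
        for _ in range(n_iter):
            x, y = self.verts[:, 0], self.verts[:, 1]
            a = self.areas()
            resid = (targets - a) / a0
            gx = 0.5 * (y[self._nv] - y[self._pv])
            gy = 0.5 * (x[self._pv] - x[self._nv])
            f = np.zeros_like(self.verts)
            w = resid[self._ci]
            np.add.at(f[:, 0], self._vi, k_area * w * gx)
            np.add.at(f[:, 1], self._vi, k_area * w * gy)
            d = self.verts[e2] - self.verts[e1]
            ln = np.hypot(d[:, 0], d[:, 1])
            ln = np.maximum(ln, 1e-9)
            pull = k_edge * (l_t - ln) / ln
            np.add.at(f, e2, pull[:, None] * d * 0.5)
            np.add.at(f, e1, -pull[:, None] * d * 0.5)
            self.verts = self.verts + f

    def t1_candidates(self, excluded_cells: set) -> list:
        """Interior edges suitable for a scripted T1."""
        out = []
        for pair in sorted(self.adjacency, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            if a in excluded_cells or b in excluded_cells:
                continue
            v1, v2 = self.shared_edge[pair]
            c1 = [c for c in range(self.n_cells)
                  if c not in (a, b) and v1 in self.loops[c]]
            c2 = [c for c in range(self.n_cells)
                  if c not in (a, b) and v2 in self.loops[c]]
            if len(c1) == 1 and len(c2) == 1 and c1[0] != c2[0]:
                c, d = c1[0], c2[0]
                if c in excluded_cells or d in excluded_cells:
                    continue
                if frozenset((c, d)) in self.adjacency:
                    continue
                out.append((a, b, c, d, v1, v2))
        return out

    def apply_t1(self, a: int, b: int, c: int, d: int, v1: int, v2: int,
                 new_length: float):
        """Collapse edge (v1, v2) between a and b; open an edge between c, d.

        v1 (incident a, b, c) becomes the new vertex on c's side; v2
        (incident a, b, d) the one on d's side.  a keeps v1, b keeps v2,
        c gains v2, d gains v1.
        """
        m = (self.verts[v1] + self.verts[v2]) / 2.0
        old = self.verts[v2] - self.verts[v1]
        u = np.array([-old[1], old[0]])
        u = u / max(np.hypot(*u), 1e-9)
        cen_c = self.verts[self.loops[c]].mean(axis=0)
        if np.dot(u, cen_c - m) < 0:
            u = -u
        self.verts[v1] = m + u * new_length / 2.0
        self.verts[v2] = m - u * new_length / 2.0
        self.loops[b] = [v for v in self.loops[b] if v != v1]
        self.loops[a] = [v for v in self.loops[a] if v != v2]
        for cell, gain, anchor in ((c, v2, v1), (d, v1, v2)):
            loop = self.loops[cell]
            i = loop.index(anchor)
            best = None
            for pos in (i, i + 1):
                trial = loop[:pos] + [gain] + loop[pos:]
                ar = _signed_area(self.verts, trial)
                if ar > 0 and (best is None or ar > best[1]):
                    best = (trial, ar)
            self.loops[cell] = best[0] if best else loop[:i + 1] + [gain] + loop[i + 1:]
        self._rebuild()


def _signed_area(verts, loop):
    v = verts[loop]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def build_mesh(config: SyntheticConfig) -> Mesh:
    """Jittered-lattice Voronoi tessellation with ``n_cells`` interior cells.

    Deterministic for a seed; every interior edge is shared by exactly two
    cells, vertices are shared between neighboring loops.
    """
    if config.n_cells < 4:
        raise ValueError("n_cells must be >= 4")
    rng = np.random.default_rng(config.seed)
    nx = int(np.ceil(np.sqrt(config.n_cells)))
    ny = int(np.ceil(config.n_cells / nx))
    guard = 2
    gx, gy = nx + 2 * guard, ny + 2 * guard
    xs, ys = np.meshgrid(np.arange(gx, dtype=float), np.arange(gy, dtype=float))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    # offset rows for a roughly hexagonal packing, then jitter
    pts[:, 0] += (pts[:, 1] % 2) * 0.5
    pts += rng.uniform(-0.22, 0.22, size=pts.shape)
    vor = Voronoi(pts)
    keep = []
    for j in range(guard, gy - guard):
        for i in range(guard, gx - guard):
            keep.append(j * gx + i)
            if len(keep) == config.n_cells:
                break
        if len(keep) == config.n_cells:
            break
    used: dict[int, int] = {}
    verts_list: list = []
    loops = []
    for gen in keep:
        region = vor.regions[vor.point_region[gen]]
        if -1 in region:
            raise RuntimeError("interior Voronoi region unexpectedly open")
        center = pts[gen]
        ordered = sorted(
            region,
            key=lambda vi: np.arctan2(vor.vertices[vi][1] - center[1],
                                      vor.vertices[vi][0] - center[0]),
        )
        loop = []
        for vi in ordered:
            if vi not in used:
                used[vi] = len(verts_list)
                verts_list.append(vor.vertices[vi])
            loop.append(used[vi])
        if _signed_area(np.array(verts_list), loop) < 0:
            loop = loop[::-1]
        loops.append(loop)
    verts = np.array(verts_list) * config.cell_diameter_px
    return Mesh(verts, loops)


def _ar1(rng, shape, sd, rho):
    """Stationary AR(1) noise, sd ``sd``, lag-1 autocorrelation ``rho``."""
    n_series, n_t = shape
    out = np.empty(shape)
    out[:, 0] = rng.normal(0.0, sd, n_series)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_t):
        out[:, t] = rho * out[:, t - 1] + rng.normal(0.0, innov_sd, n_series)
    return out


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    m = a.mean(axis=1, keepdims=True)
    s = a.std(axis=1, ddof=1, keepdims=True)
    s = np.where(s == 0, 1.0, s)
    return (a - m) / s


def _smoothing_attenuation(window: int, rho: float) -> float:
    """Variance retention of stationary AR(1) noise under a centered
    ``window``-frame moving average: Var(mean)/Var = (w + 2Σ(w−k)ρᵏ)/w²."""
    w = max(int(window), 1)
    k = np.arange(1, w)
    return float((w + 2.0 * np.sum((w - k) * rho**k)) / w**2)


def _coupling_coeff(r: float, sd: float, window: int = 1, rho: float = 0.0) -> float:
    """Coefficient c realizing corr(z, c·(−z) + noise) = r on smoothed series.

    z is the slow standardized area signal (essentially unattenuated by the
    window); the AR(1) noise keeps only ``_smoothing_attenuation`` of its
    variance, so c is calibrated against the smoothed noise s.d.
    """
    if r == 0:
        return 0.0
    sd_eff = sd * np.sqrt(_smoothing_attenuation(window, rho))
    return -r * sd_eff / np.sqrt(1.0 - r * r)


@dataclass
class Simulation:
    """Output of :func:`simulate`: raw tables + adjacency + geometry states."""

    config: SyntheticConfig
    dataset: Dataset
    adjacency: list[AdjacencyFrame]
    frames: list          # per frame: (verts copy, loops copy)
    ground_truth: SyntheticGroundTruth


def simulate(config: SyntheticConfig) -> Simulation:
    """Run the generator: geometry, intensities, genotypes, scripted T1s.

    Returns raw (unsmoothed, unstandardized) cell and junction tables in the
    tracked-table schema, per-frame adjacency, per-frame mesh geometry for
    rendering, and the ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mesh = build_mesh(cfg)
    n, T = cfg.n_cells, cfg.n_frames

    # --- genotype: half-plane mosaic by initial centroid x
    cen0 = mesh.centroids()
    if cfg.crispant_fraction <= 0:
        genotype = {c: CONTROL for c in range(n)}
    else:
        cut = np.quantile(cen0[:, 0], 1.0 - cfg.crispant_fraction)
        genotype = {c: (CRISPANT if cen0[c, 0] > cut else CONTROL)
                    for c in range(n)}

    # --- regimes and target area ramps
    t = np.arange(T) / max(T - 1, 1)
    ramps = np.empty((n, T))
    regime = {}
    if cfg.region == "anterior":
        dilating = rng.random(n) < cfg.anterior_crispant_dilating_fraction
        for c in range(n):
            if genotype[c] == CONTROL:
                regime[c] = "anterior-gradual"
                ramps[c] = 1.0 - cfg.anterior_constriction * t
            elif dilating[c]:
                regime[c] = "anterior-crispant-dilating"
                ramps[c] = 1.0 + cfg.anterior_crispant_dilation * t
            else:
                regime[c] = "anterior-crispant-weak"
                ramps[c] = 1.0 - 0.3 * cfg.anterior_constriction * t
    else:
        constricting = rng.random(n) < cfg.posterior_constricting_fraction
        onset = cfg.posterior_onset_frac
        late = np.clip((t - onset) / max(1.0 - onset, 1e-9), 0.0, 1.0)
        for c in range(n):
            amp = cfg.posterior_constriction * (
                1.0 if genotype[c] == CONTROL else 0.8)
            if constricting[c]:
                regime[c] = "posterior-late-rapid"
                ramps[c] = 1.0 - amp * late
            else:
                regime[c] = "posterior-drift"
                ramps[c] = 1.0 + cfg.posterior_dilation * t
    if np.any(ramps <= 0):
        raise ValueError("infeasible (non-positive) target areas")

    # --- geometry evolution with scripted T1 surgery
    a0 = mesh.areas()
    rest_lengths = {
        e: float(np.hypot(*(mesh.verts[tuple(e)[0]] - mesh.verts[tuple(e)[1]])))
        for e in mesh.edges
    }
    event_frames = sorted(int(f) for f in cfg.scripted_t1_frames)
    events = []
    involved: set = set()
    frames_geom = []
    adjacency = []
    mean_edge = float(np.mean(list(rest_lengths.values())))
    for ti in range(T):
        for ef in [f for f in event_frames if f == ti]:
            cands = mesh.t1_candidates(involved)
            if not cands:
                raise ValueError(f"no suitable edge for scripted T1 at frame {ef}")
            # deterministic choice: most central candidate edge
            cen = mesh.centroids().mean(axis=0)
            def _dist(cand):
                v1, v2 = cand[4], cand[5]
                mid = (mesh.verts[v1] + mesh.verts[v2]) / 2.0
                return float(np.hypot(*(mid - cen)))
            a, b, c, d, v1, v2 = min(cands, key=_dist)
            mesh.apply_t1(a, b, c, d, v1, v2, new_length=0.35 * mean_edge)
            rest_lengths = {
                e: rest_lengths.get(
                    e,
                    float(np.hypot(*(mesh.verts[tuple(e)[0]]
                                     - mesh.verts[tuple(e)[1]]))))
                for e in mesh.edges
            }
            involved.update((a, b, c, d))
            events.append({"frame": ti + 1, "losing_pair": (a, b),
                           "gaining_pair": (c, d)})
        mesh.relax(a0 * ramps[:, ti], ramps[:, ti], rest_lengths,
                   n_iter=25 if ti == 0 else 12)
        frames_geom.append((mesh.verts.copy(), [list(l) for l in mesh.loops]))
        adjacency.append(AdjacencyFrame(
            minute=ti + 1, pairs=frozenset(mesh.adjacency)))

    # --- realized areas and standardized series
    areas = np.empty((n, T))
    for ti, (verts, loops) in enumerate(frames_geom):
        areas[:, ti] = [abs(_signed_area(verts, loop)) for loop in loops]
    z_area = _zscore_rows(areas)

    # --- intensities coupled to (negated) standardized area
    channels = ["medial_actin", "junctional_actin",
                "medial_Ncadherin", "junctional_Ncadherin"]
    intens = {}
    for ch in channels:
        noise = _ar1(rng, (n, T), cfg.noise_sd, cfg.noise_rho)
        base = cfg.intensity_baseline + rng.normal(0.0, 5.0, n)[:, None]
        coeff = np.array([
            _coupling_coeff(
                cfg.couplings.get((cfg.region, genotype[c]), {}).get(ch, 0.0),
                cfg.noise_sd, cfg.analysis_window, cfg.noise_rho)
            for c in range(n)
        ])[:, None]
        intens[ch] = base + coeff * (-z_area) + noise

    # --- membrane-BFP: bimodal by genotype, constant per lineage
    bfp_cell = np.where(
        np.array([genotype[c] == CRISPANT for c in range(n)]),
        rng.normal(cfg.bfp_crispant_mean, cfg.bfp_sd, n),
        rng.normal(cfg.bfp_control_mean, cfg.bfp_sd, n),
    )
    bfp_cell = np.maximum(bfp_cell, 1.0)
    intens["medial_memBFP"] = bfp_cell[:, None] + _ar1(rng, (n, T), 2.0, 0.5)
    intens["junctional_memBFP"] = bfp_cell[:, None] + _ar1(rng, (n, T), 2.0, 0.5)

    # --- neighbor genotype counts per frame
    ctrl_nb = np.zeros((n, T), dtype=int)
    crisp_nb = np.zeros((n, T), dtype=int)
    for ti, fr in enumerate(adjacency):
        for pair in fr.pairs:
            a, b = tuple(pair)
            for me, other in ((a, b), (b, a)):
                if genotype[other] == CRISPANT:
                    crisp_nb[me, ti] += 1
                else:
                    ctrl_nb[me, ti] += 1

    # --- z-displacement field for junction Δz
    extent = mesh.verts.max(axis=0) - mesh.verts.min(axis=0)
    origin = mesh.verts.min(axis=0)

    def zfield(p):
        q = (p - origin) / np.maximum(extent, 1e-9)
        return cfg.z_amplitude_micron * np.sin(2 * np.pi * q[0]) * np.cos(2 * np.pi * q[1])

    # --- assemble cell table
    cell_rows = {c: [] for c in CELL_COLUMNS}
    for ti, (verts, loops) in enumerate(frames_geom):
        m = Mesh(verts, loops)  # centroids need flat arrays
        cen = m.centroids()
        for c in range(n):
            cell_rows["region"].append(cfg.region)
            cell_rows["movie"].append(cfg.movie)
            cell_rows["track_id_cells"].append(c)
            cell_rows["minute"].append(ti + 1)
            cell_rows["center_x_cells"].append(cen[c, 0])
            cell_rows["center_y_cells"].append(cen[c, 1])
            cell_rows["vx_coords_cells"].append(encode_vertices(verts[loops[c]]))
            cell_rows["CRISPR"].append(genotype[c])
            cell_rows["control_neighbors"].append(ctrl_nb[c, ti])
            cell_rows["crispant_neighbors"].append(crisp_nb[c, ti])
            cell_rows["apical_area_pixels"].append(areas[c, ti])
            for ch in channels + ["medial_memBFP", "junctional_memBFP"]:
                cell_rows[ch].append(intens[ch][c, ti])
    for col in CELL_COLUMNS:
        if not cell_rows[col]:
            cell_rows[col] = [np.nan] * (n * T)
    cells = pd.DataFrame(cell_rows)[CELL_COLUMNS]

    # --- junction tracks: one track per contiguous run of adjacency per pair
    jx_records = []
    run_of: dict = {}
    run_count: dict = {}
    for ti, fr in enumerate(adjacency):
        verts, loops = frames_geom[ti]
        m = Mesh(verts, loops)
        for pair in sorted(fr.pairs, key=lambda p: tuple(sorted(p))):
            if pair not in m.shared_edge:
                continue
            v1, v2 = m.shared_edge[pair]
            if pair not in run_of or run_of[pair][1] != ti - 1:
                a, b = sorted(pair)
                k = run_count.get(pair, 0)
                rid = f"j{a}-{b}" if k == 0 else f"j{a}-{b}-r{k}"
                run_count[pair] = k + 1
                run_of[pair] = (rid, ti)
            run_of[pair] = (run_of[pair][0], ti)
            rid = run_of[pair][0]
            p1, p2 = verts[v1], verts[v2]
            dz = abs(zfield(p1) - zfield(p2))
            jx_records.append((rid, pair, ti, p1[0], p1[1], p2[0], p2[1],
                               float(np.hypot(*(p2 - p1))), float(dz)))

    jdf = pd.DataFrame(jx_records, columns=[
        "track_id_junctions", "pair", "ti", "vx_1_x", "vx_1_y",
        "vx_2_x", "vx_2_y", "length_px", "delta_z_micron"])
    # per-run standardized length for intensity coupling
    jdf["z_len"] = jdf.groupby("track_id_junctions")["length_px"].transform(
        lambda s: (s - s.mean()) / (s.std(ddof=1) or 1.0)
        if len(s) > 1 else 0.0)
    jn = len(jdf)
    runs = jdf["track_id_junctions"].unique()
    run_index = {r: i for i, r in enumerate(runs)}
    jx_rows = {c: [np.nan] * jn for c in JUNCTION_COLUMNS}
    noise = {ch: _ar1(rng, (len(runs), T), cfg.noise_sd, cfg.noise_rho)
             for ch in ("actin", "Ncadherin")}
    base = {ch: cfg.intensity_baseline + rng.normal(0.0, 5.0, len(runs))
            for ch in ("actin", "Ncadherin")}
    for i, rec in enumerate(jdf.itertuples()):
        a, b = sorted(rec.pair)
        jx_rows["region"][i] = cfg.region
        jx_rows["movie"][i] = cfg.movie
        jx_rows["track_id_junctions"][i] = rec.track_id_junctions
        jx_rows["CRISPR"][i] = classify_junction(genotype[a], genotype[b])
        jx_rows["minute"][i] = rec.ti + 1
        jx_rows["vx_1_x"][i] = rec.vx_1_x
        jx_rows["vx_1_y"][i] = rec.vx_1_y
        jx_rows["vx_2_x"][i] = rec.vx_2_x
        jx_rows["vx_2_y"][i] = rec.vx_2_y
        jx_rows["length_px"][i] = rec.length_px
        jx_rows["delta_z_micron"][i] = rec.delta_z_micron
        ri = run_index[rec.track_id_junctions]
        for ch in ("actin", "Ncadherin"):
            c_coeff = _coupling_coeff(cfg.junction_couplings.get(ch, 0.0),
                                      cfg.noise_sd, cfg.analysis_window,
                                      cfg.noise_rho)
            jx_rows[ch][i] = (base[ch][ri] + c_coeff * (-rec.z_len)
                              + noise[ch][ri, rec.ti])
    junctions = pd.DataFrame(jx_rows)[JUNCTION_COLUMNS]

    truth = SyntheticGroundTruth(
        genotype=genotype,
        regime=regime,
        area_trajectories=areas,
        couplings=cfg.couplings,
        events=events,
    )
    return Simulation(
        config=cfg,
        dataset=Dataset(cells=cells, junctions=junctions),
        adjacency=adjacency,
        frames=frames_geom,
        ground_truth=truth,
    )


def render_frames(sim: Simulation, frame_indices=None, pad: int = 4):
    """Rasterize simulation frames into label masks plus painted channels.

    Polygons are filled with their cell label; pixels 4-adjacent to a
    different cell become the 0-valued boundary skeleton, so no two labels
    touch.  Channels are painted with the tabulated per-domain means: the
    cell interior takes the medial value, each skeleton pixel the mean of
    its adjacent cells' junctional values.  Realized per-domain painted
    means (by direct pixel enumeration) are recorded in the ground truth.
    Returns ``{frame_index: LabelFrame}``.
    """
    from skimage.draw import polygon as draw_polygon

    cfg = sim.config
    if frame_indices is None:
        frame_indices = [0]
    channels = ["medial_actin", "junctional_actin",
                "medial_Ncadherin", "junctional_Ncadherin",
                "medial_memBFP", "junctional_memBFP"]
    cells_df = sim.dataset.cells
    out = {}
    for ti in frame_indices:
        verts, loops = sim.frames[ti]
        origin = verts.min(axis=0) - pad
        size = verts.max(axis=0) - origin + pad
        h, w = int(np.ceil(size[1])), int(np.ceil(size[0]))
        if h * w > 4096 * 4096:
            raise ValueError("raster too large; reduce cell count or diameter")
        labels = np.zeros((h, w), dtype=np.int32)
        for c, loop in enumerate(loops):
            poly = verts[loop] - origin
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=labels.shape)
            labels[rr, cc] = c + 1
        # carve the 1-px boundary skeleton: any pixel 4-adjacent to a
        # different nonzero label goes to 0
        diff = np.zeros_like(labels, dtype=bool)
        for sy, sx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            shifted = np.roll(labels, (sy, sx), axis=(0, 1))
            diff |= (labels != 0) & (shifted != 0) & (labels != shifted)
        labels[diff] = 0

        frame_rows = cells_df[cells_df["minute"] == ti + 1].set_index("track_id_cells")
        chan = {ch: np.zeros((h, w)) for ch in channels}
        # medial paint: uniform over each cell region
        for c in range(len(loops)):
            reg = labels == c + 1
            for ch in channels:
                if ch.startswith("medial"):
                    chan[ch][reg] = frame_rows.loc[c, ch]
        # junctional paint: skeleton pixel = mean of adjacent cells' values
        from scipy import ndimage as ndi
        skel = labels == 0
        for ch in channels:
            if not ch.startswith("junctional"):
                continue
            total = np.zeros((h, w))
            count = np.zeros((h, w))
            near = {}
            for c in range(len(loops)):
                nb = ndi.binary_dilation(labels == c + 1, np.ones((3, 3), bool))
                near[c] = nb & skel
                total[near[c]] += frame_rows.loc[c, ch]
                count[near[c]] += 1
            sel = skel & (count > 0)
            chan[ch][sel] = total[sel] / count[sel]
            # record realized junctional means by direct enumeration
            for c in range(len(loops)):
                pix = near[c]
                key = (ti, c)
                rec = sim.ground_truth.painted_means.setdefault(key, {})
                rec[ch] = float(chan[ch][pix].mean()) if pix.any() else np.nan
        for c in range(len(loops)):
            key = (ti, c)
            rec = sim.ground_truth.painted_means.setdefault(key, {})
            for ch in channels:
                if ch.startswith("medial"):
                    rec[ch] = float(frame_rows.loc[c, ch])
        out[ti] = LabelFrame(labels=labels, channels=chan)
    return out
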
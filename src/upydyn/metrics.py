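"""Structural observables for stacked UPy dimers.

The central primitive is the rational switching function used to count
dimerization hydrogen bonds as a continuous coordination number:

    s(r) = 1                                for r <= D0
    s(r) = (1 - x^n) / (1 - x^m),  x = (r - D0)/R0,   otherwise

with defaults R0 = 0.12 nm, D0 = 0.27 nm, n = 6, m = 12 (the removable
singularity at x = 1 evaluates to n/m).  N_HB-dim of a dimer is the sum of
s over its four donor-acceptor pairs, and N_HB-dim0 is the same sum always
evaluated against the t=0 partner, which is what makes it a rupture
detector for the *original* dimers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import StackTopology, TipSpec, Trajectory, label_tips, minimum_image

log = logging.getLogger("upydyn")


# ---------------------------------------------------------------------------
# Switching function / H-bond coordination
# ---------------------------------------------------------------------------

@dataclass
class SwitchingParams:
    r0: float = 0.12    # nm
    d0: float = 0.27    # nm
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (self.m_exp > self.n_exp > 0):
            raise ValueError("need m_exp > n_exp > 0")


def switching_value(r, params: SwitchingParams = SwitchingParams()):
    """Rational coordination switching function, vectorized over ``r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    x = np.maximum(r - params.d0, 0.0) / params.r0
    n, m = params.n_exp, params.m_exp
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(np.abs(x - 1.0) < 1e-10,
                     n / m,
                     (1.0 - x ** n) / (1.0 - x ** m))
    s = np.where(x <= 0, 1.0, s)
    return s if s.ndim else float(s)


def count_hb_dim(frame: np.ndarray, hb_pairs: list[list[tuple[int, int]]],
                 box: np.ndarray | None = None,
                 params: SwitchingParams = SwitchingParams()) -> np.ndarray:
    """Continuous H-bond count per dimer: sum of s over its 4 atom pairs."""
    counts = np.empty(len(hb_pairs))
    n_atoms = frame.shape[0]
    for d, pairs in enumerate(hb_pairs):
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        if ia.max() >= n_atoms or ib.max() >= n_atoms:
            raise ValueError(f"dimer {d}: hb pairing references atoms absent from frame")
        d_ab = np.linalg.norm(minimum_image(frame[ia] - frame[ib], box), axis=1)
        counts[d] = switching_value(d_ab, params).sum()
    return counts


@dataclass
class HBSeries:
    """Per-dimer N_HB-dim(0) time series, values in [0, 4]."""

    times: np.ndarray
    values: np.ndarray          # (n_frames, n_dimers)
    dimer_monomers: list[tuple[int, int]]

    def per_monomer_mean(self) -> dict[int, float]:
        """Time-averaged N_HB-dim0 attributed to each monomer of the pair."""
        means = self.values.mean(axis=0)
        out: dict[int, float] = {}
        for d, (a, b) in enumerate(self.dimer_monomers):
            out[a] = float(means[d])
            out[b] = float(means[d])
        return out


def hb_dim0_series(traj: Trajectory, topology: StackTopology,
                   params: SwitchingParams = SwitchingParams()) -> HBSeries:
    """N_HB-dim0(t): coordination against the t=0 partner at every frame."""
    hb_pairs = [topology.hb_pairs_of_dimer(d) for d in range(len(topology.dimers0))]
    vals = np.empty((traj.n_frames, len(hb_pairs)))
    for f in range(traj.n_frames):
        vals[f] = count_hb_dim(traj.coordinates[f], hb_pairs,
                               traj.effective_box(f), params)
    return HBSeries(times=traj.times.copy(), values=vals,
                    dimer_monomers=list(topology.dimers0))


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def core_centers(traj: Trajectory, topology: StackTopology) -> np.ndarray:
    """Geometric centers of each monomer's core, (n_frames, M, 3).

    A monomer's explicit ``center`` atom is used when the topology names
    one; otherwise the centroid of its core subset.
    """
    mids = sorted(m.id for m in topology.monomers)
    out = np.empty((traj.n_frames, len(mids), 3))
    for i, mid in enumerate(mids):
        m = topology.monomer(mid)
        if m.center is not None:
            out[:, i] = traj.coordinates[:, m.center]
        else:
            out[:, i] = traj.coordinates[:, m.core].mean(axis=1)
    return out


def rdf_per_monomer(centers: np.ndarray, box: np.ndarray | None,
                    r_max: float, bin_width: float,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-monomer RDF of center-center distances.

    The histogram of all minimum-image pair distances, averaged over frames,
    is divided by the shell volume 4 pi r^2 dr and by the number of monomers
    -- deliberately *not* by a bulk density, so peak heights grow with the
    number of neighbors at a given separation (longer stacks give higher
    stacking peaks).

    Returns (bin_centers, g).
    """
    if bin_width <= 0 or r_max <= bin_width:
        raise ValueError("need 0 < bin_width < r_max")
    centers = np.asarray(centers, float)
    if centers.ndim == 2:
        centers = centers[None]
    n_frames, n, _ = centers.shape
    if n < 2:
        raise ValueError("need at least 2 centers")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    iu = np.triu_indices(n, k=1)
    for f in range(n_frames):
        d = minimum_image(centers[f][iu[0]] - centers[f][iu[1]],
                          box if box is None or np.ndim(box) == 1 else box[f])
        r = np.linalg.norm(d, axis=1)
        hist += np.histogram(r, bins=edges)[0]
    hist /= n_frames
    mids = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * mids ** 2 * bin_width
    g = hist / shell / n
    return mids, g


def rdf_peaks(r: np.ndarray, g: np.ndarray, min_height: float = 0.0,
              k: int = 2, min_r: float = 0.0) -> np.ndarray:
    """Positions of the first ``k`` local maxima of g(r) above ``min_height``.

    ``min_r`` excludes the small-r region where isolated close passes are
    blown up by the 1/r^2 shell correction (the centers carry no excluded
    volume).
    """
    peaks = []
    for i in range(len(g)):
        if r[i] < min_r:
            continue
        left = g[i - 1] if i > 0 else -np.inf
        right = g[i + 1] if i < len(g) - 1 else -np.inf
        if g[i] > min_height and g[i] >= left and g[i] >= right:
            peaks.append(r[i])
        if len(peaks) == k:
            break
    return np.array(peaks)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

@dataclass
class SasaParams:
    probe: float = 0.14            # nm, water-sized probe
    n_points: int = 960            # sphere points per atom
    default_radius: float = 0.15   # nm, applied when no per-atom radii given

    def __post_init__(self):
        if self.n_points < 32:
            raise ValueError("n_points < 32 is below the accuracy floor")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere points."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_atoms(coords: np.ndarray, radii: np.ndarray | float | None = None,
               params: SasaParams = SasaParams()) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom, nm^2."""
    coords = np.asarray(coords, float)
    n = len(coords)
    if radii is None:
        radii = params.default_radius
    radii = np.broadcast_to(np.asarray(radii, float), (n,)).copy()
    ext = radii + params.probe
    pts = _sphere_points(params.n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    rmax = ext.max()
    for i in range(n):
        surf = coords[i] + ext[i] * pts
        nbr = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax) if j != i]
        if nbr:
            d2 = ((surf[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas


def sasa_per_monomer(frame: np.ndarray, topology: StackTopology,
                     radii: np.ndarray | float | None = None,
                     params: SasaParams = SasaParams()) -> dict[int, float]:
    """Per-monomer SASA: each atom's exposed area in the full-solute context."""
    areas = sasa_atoms(frame, radii, params)
    return {m.id: float(areas[m.atoms].sum()) for m in topology.monomers}


def sasa_series(traj: Trajectory, topology: StackTopology,
                radii: np.ndarray | float | None = None,
                params: SasaParams = SasaParams(), stride: int = 1,
                ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """SASA per monomer over (possibly strided) frames.

    Returns (times, values (n_used, M), monomer_ids).
    """
    mids = sorted(m.id for m in topology.monomers)
    frames = range(0, traj.n_frames, stride)
    vals = np.empty((len(frames), len(mids)))
    for row, f in enumerate(frames):
        per = sasa_per_monomer(traj.coordinates[f], topology, radii, params)
        vals[row] = [per[m] for m in mids]
    return traj.times[::stride].copy(), vals, mids


def aggregation_propensity(frame: np.ndarray, topology: StackTopology,
                           radii: np.ndarray | float | None = None,
                           params: SasaParams = SasaParams()) -> float:
    """AP = sum of isolated-stack SASAs / SASA of the assembled bundle.

    Each stack is evaluated alone in its current internal conformation; the
    ratio is 1 for non-interacting stacks and grows as surface is buried by
    inter-stack contacts.
    """
    sids = topology.stack_ids()
    if len(sids) < 2:
        raise ValueError("aggregation propensity needs at least 2 stacks")
    radii_arr = None
    if radii is not None:
        radii_arr = np.broadcast_to(np.asarray(radii, float), (len(frame),))
    total = sum(sasa_atoms(frame, radii, params))
    isolated = 0.0
    for sid in sids:
        idx = np.concatenate([topology.monomer(m).atoms
                              for m in topology.monomers_of_stack(sid)])
        sub_r = radii_arr[idx] if radii_arr is not None else None
        isolated += sasa_atoms(frame[idx], sub_r, params).sum()
    return float(isolated / total)


# ---------------------------------------------------------------------------
# Inter-stack contacts
# ---------------------------------------------------------------------------

def inter_stack_contacts(traj: Trajectory, topology: StackTopology,
                         cutoff: float = 0.5, atom_scope: str = "all-solute",
                         tip_spec: TipSpec = TipSpec(2),
                         ) -> dict:
    """Count inter-stack atom-pair contacts (< cutoff) per monomer per frame.

    ``atom_scope`` is "all-solute" or "core-only".  Returns per-monomer nc
    arrays plus tip/backbone frame averages (tip depth defaults to 2:
    end dimers and their first neighbors).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if atom_scope not in ("all-solute", "core-only"):
        raise ValueError(f"unknown atom_scope {atom_scope!r}")
    mids = sorted(m.id for m in topology.monomers)
    midx = {m: i for i, m in enumerate(mids)}
    atom_mono = {}
    atom_stack = {}
    scoped = []
    for m in topology.monomers:
        idx = m.core if atom_scope == "core-only" else m.atoms
        for a in idx:
            atom_mono[a] = m.id
            atom_stack[a] = topology.stacks[m.id]
            scoped.append(a)
    scoped = np.array(sorted(scoped))
    stack_of = np.array([atom_stack[a] for a in scoped])
    mono_of = np.array([midx[atom_mono[a]] for a in scoped])

    nc = np.zeros((traj.n_frames, len(mids)))
    for f in range(traj.n_frames):
        box = traj.effective_box(f)
        pos = traj.coordinates[f][scoped]
        if box is not None and np.all(np.isfinite(box)):
            tree = cKDTree(np.mod(pos, box), boxsize=box)
        else:
            tree = cKDTree(pos)
        for i, j in tree.query_pairs(cutoff):
            if stack_of[i] != stack_of[j]:
                nc[f, mono_of[i]] += 1
                nc[f, mono_of[j]] += 1
    tips = label_tips(topology, tip_spec)
    tip_cols = [midx[m] for m in mids if tips[m] == "tip"]
    back_cols = [midx[m] for m in mids if tips[m] == "backbone"]
    return {
        "monomer_ids": mids,
        "nc": nc,
        "tip_mean": nc[:, tip_cols].mean(axis=1) if tip_cols else np.zeros(traj.n_frames),
        "backbone_mean": nc[:, back_cols].mean(axis=1) if back_cols else np.zeros(traj.n_frames),
        "cutoff": cutoff,
        "atom_scope": atom_scope,
    }


# ---------------------------------------------------------------------------
# Dimer planarity
# ---------------------------------------------------------------------------

def _plane_normal(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[-2] < 1e-10:
        raise ValueError("collinear core atoms: plane undefined")
    return vt[-1]


def dimer_planarity(traj: Trajectory, topology: StackTopology,
                    planar_threshold_deg: float = 20.0) -> dict:
    """Angle between the two monomers' best-fit core planes, per dimer.

    The angle is folded to [0, 90] degrees; the planar fraction is the
    fraction of (dimer, frame) samples below ``planar_threshold_deg``.
    """
    n_d = len(topology.dimers0)
    angles = np.empty((traj.n_frames, n_d))
    for f in range(traj.n_frames):
        for d, (a, b) in enumerate(topology.dimers0):
            na = _plane_normal(traj.coordinates[f][topology.monomer(a).core])
            nb = _plane_normal(traj.coordinates[f][topology.monomer(b).core])
            cosang = np.clip(abs(np.dot(na, nb)), 0.0, 1.0)
            angles[f, d] = np.degrees(np.arccos(cosang))
    return {
        "angles_deg": angles,
        "planar_fraction": float((angles < planar_threshold_deg).mean()),
        "threshold_deg": planar_threshold_deg,
    }


# ---------------------------------------------------------------------------
# Per-monomer summary table
# ---------------------------------------------------------------------------

@dataclass
class MonomerMetrics:
    """Time-averaged per-monomer observables used in correlation analyses."""

    monomer_ids: list[int]
    hb_dim0_mean: np.ndarray
    sasa_mean: np.ndarray
    tip: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def monomer_metrics(traj: Trajectory, topology: StackTopology,
                    switching: SwitchingParams = SwitchingParams(),
                    sasa_params: SasaParams = SasaParams(),
                    sasa_stride: int = 10,
                    tip_spec: TipSpec = TipSpec(1)) -> MonomerMetrics:
    hb = hb_dim0_series(traj, topology, switching).per_monomer_mean()
    _, sas, mids = sasa_series(traj, topology, None, sasa_params, sasa_stride)
    tips = label_tips(topology, tip_spec)
    return MonomerMetrics(
        monomer_ids=mids,
        hb_dim0_mean=np.array([hb[m] for m in mids]),
        sasa_mean=sas.mean(axis=0),
        tip=np.array([tips[m] == "tip" for m in mids]),
    )
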
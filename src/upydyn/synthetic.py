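"""Synthetic stack trajectories with planted exchange dynamics.

Monomers are rigid 5-point motifs (4 H-bond atoms in a planar DDAA row plus
one core center); dimers face each other across a 0.6 nm core–core gap and
stack every 0.37 nm along z.  Exchange dynamics (dimer rupture, sliding of
unbound monomers along the stack axis, rebinding) is generated by a direct
Gillespie kinetic-Monte-Carlo walk with per-class rupture rates, so every
downstream estimator can be checked against exact planted ground truth.

No physical realism is attempted beyond the geometry the estimators see: no
solvent, no forces, no stacking energetics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import (BiasTrace, Monomer, StackTopology, TipSpec, Trajectory,
                    beta_from_temperature, label_tips)

log = logging.getLogger("upydyn")

def _rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix for an axis-angle vector."""
    theta = float(np.linalg.norm(rotvec))
    if theta < 1e-12:
        return np.eye(3)
    k = rotvec / theta
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


# internal geometry constants of the 5-point motif (nm)
HB_GAP = 0.2          # H-bond donor-acceptor pair distance in an intact dimer
HB_SPACING = 0.15     # spacing of the 4 hb atoms along the DDAA row
RUPTURE_SHIFT = 0.25  # outward displacement of each stacked-unbound monomer
SLIDE_RADIUS = 1.2    # radial detachment of travelling monomers (> SOAP r_cut)
GOLDEN_ANGLE = 2.399963229728653  # per-monomer azimuth spread of slide lanes


@dataclass
class SyntheticParams:
    """Knobs of the synthetic stack generator.

    Rates are per ps; distances in nm.  ``k_tip >= k_back`` mirrors the
    tip/backbone asymmetry of dimer rupture.
    """

    n_dimers: int = 20
    d_dimer: float = 0.6        # core-core distance within a dimer
    d_stack: float = 0.37       # stacking spacing along the axis
    k_tip: float = 0.0          # rupture rate of tip dimers (1/ps)
    k_back: float = 0.0         # rupture rate of backbone dimers (1/ps)
    k_slide: float = 0.0        # hop rate of unbound monomers (1/ps)
    k_rebind: float = 0.0       # rebinding rate of facing unbound monomers
    noise_sigma: float = 0.01   # rigid-body thermal jitter per monomer (nm)
    rot_sigma: float = 0.12     # rigid-body orientational jitter (rad)
    wobble_unbound: float = 8.0 # jitter multiplier for stacked-unbound monomers
    dt_frame: float = 50.0      # ps
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_dimers < 1:
            raise ValueError("n_dimers must be >= 1")
        for name in ("k_tip", "k_back", "k_slide", "k_rebind", "noise_sigma",
                     "rot_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_tip < self.k_back:
            raise ValueError("k_tip must be >= k_back")
        if not (self.d_dimer > self.d_stack > 0):
            raise ValueError("need d_dimer > d_stack > 0")


@dataclass
class Event:
    time: float
    monomers: tuple[int, ...]
    type: str                   # rupture | rebind | slide-step
    site: int


@dataclass
class GroundTruth:
    """Planted per-frame state labels and the full event list."""

    labels: np.ndarray          # (n_frames, n_monomers) of {bound, stacked-unbound, travelling}
    events: list[Event]
    rates: dict[str, float]     # planted per-class rupture rates
    tip_monomers: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "events": [asdict(e) for e in self.events],
            "rates": self.rates,
            "tip_monomers": self.tip_monomers,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(labels=np.array(d["labels"]),
                   events=[Event(**e) for e in d["events"]],
                   rates=d["rates"], tip_monomers=d["tip_monomers"])


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _monomer_atoms(col: int, site_z: float, lateral_y: float, su_shift: float,
                   d_dimer: float, center_xy: np.ndarray) -> np.ndarray:
    """5-point motif for one monomer.

    ``col`` is 0 (left of the dimer gap, facing +x) or 1 (right, facing -x);
    ``su_shift`` pushes the monomer outward along x when stacked-unbound.
    """
    sgn = -1.0 if col == 0 else 1.0
    x_core = center_xy[0] + sgn * (d_dimer / 2.0 + su_shift)
    x_hb = center_xy[0] + sgn * (HB_GAP / 2.0 + su_shift)
    y0 = center_xy[1] + lateral_y
    ys = np.array([-1.5, -0.5, 0.5, 1.5]) * HB_SPACING
    pts = np.empty((5, 3))
    pts[0] = (x_core, y0, site_z)                      # core center
    pts[1:, 0] = x_hb
    pts[1:, 1] = y0 + ys
    pts[1:, 2] = site_z
    return pts


def build_stack(params: SyntheticParams, center_xy: np.ndarray | None = None,
                stack_id: int = 0, id_offset: int = 0, atom_offset: int = 0,
                box: np.ndarray | None = None) -> tuple[StackTopology, np.ndarray]:
    """Build a pre-stacked topology of ``n_dimers`` dimers and its frame-0."""
    D = params.n_dimers
    if box is None:
        box = np.array([6.0, 6.0, max(6.0, D * params.d_stack + 4.0)])
    if center_xy is None:
        center_xy = box[:2] / 2.0
    z0 = (box[2] - (D - 1) * params.d_stack) / 2.0
    monomers, coords = [], []
    dimers0, stacks = [], {}
    for k in range(D):
        for col in (0, 1):
            mid = id_offset + 2 * k + col
            a0 = atom_offset + 5 * (2 * k + col)
            atoms = np.arange(a0, a0 + 5)
            monomers.append(Monomer(id=mid, atoms=atoms, core=atoms,
                                    side=np.array([], int), hb=atoms[1:],
                                    center=int(atoms[0])))
            coords.append(_monomer_atoms(col, z0 + k * params.d_stack, 0.0, 0.0,
                                         params.d_dimer, center_xy))
            stacks[mid] = stack_id
        dimers0.append((id_offset + 2 * k, id_offset + 2 * k + 1))
    topo = StackTopology(monomers=monomers, dimers0=dimers0, stacks=stacks,
                         axis_order={stack_id: list(range(len(dimers0)))})
    return topo, np.concatenate(coords, axis=0)


def make_bundle(n_stacks: int, params: SyntheticParams, spacing: float,
                ) -> tuple[StackTopology, np.ndarray]:
    """Parallel stacks at lateral (y) spacing, distinct stack ids."""
    if n_stacks < 2:
        raise ValueError("need n_stacks >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    D = params.n_dimers
    box = np.array([6.0, (n_stacks + 1) * max(spacing, 2.0) + 4.0,
                    max(6.0, D * params.d_stack + 4.0)])
    monomers, coords, dimers0, stacks, axis_order = [], [], [], {}, {}
    y0 = (box[1] - (n_stacks - 1) * spacing) / 2.0
    for s in range(n_stacks):
        topo_s, xyz = build_stack(
            params, center_xy=np.array([box[0] / 2.0, y0 + s * spacing]),
            stack_id=s, id_offset=2 * D * s, atom_offset=10 * D * s, box=box)
        monomers += topo_s.monomers
        coords.append(xyz)
        d0 = len(dimers0)
        dimers0 += topo_s.dimers0
        stacks.update(topo_s.stacks)
        axis_order[s] = [d0 + i for i in topo_s.axis_order[s]]
    topo = StackTopology(monomers=monomers, dimers0=dimers0, stacks=stacks,
                         axis_order=axis_order)
    return topo, np.concatenate(coords, axis=0)


def default_box(params: SyntheticParams) -> np.ndarray:
    return np.array([6.0, 6.0, max(6.0, params.n_dimers * params.d_stack + 4.0)])


# ---------------------------------------------------------------------------
# Kinetic Monte Carlo
# ---------------------------------------------------------------------------

class _State:
    """Mutable per-monomer KMC state."""

    __slots__ = ("site", "col", "status", "partner", "lateral")

    def __init__(self, site, col):
        self.site = site          # lattice site (int)
        self.col = col            # 0/1 dimer column
        self.status = "B"         # B | SU | TR
        self.partner = None
        self.lateral = 0.0


def simulate_exchange(topology: StackTopology, frame0: np.ndarray,
                      params: SyntheticParams,
                      box: np.ndarray | None = None,
                      ) -> tuple[Trajectory, GroundTruth]:
    """Gillespie KMC over rupture / slide / rebind events, sampled on frames.

    Rupture propensity is per intact dimer, ``k_tip`` for dimers at the
    frame-0 stack ends (depth 1) and ``k_back`` otherwise.  Unbound monomers
    hop +-1 lattice site at ``k_slide`` (becoming "travelling"); two unbound
    monomers of complementary columns at the same site rebind at
    ``k_rebind``.  Identical seed implies bit-identical output; the thermal
    jitter stream is separate from the KMC stream, so ground truth is
    invariant to ``noise_sigma``.
    """
    D = params.n_dimers
    if box is None:
        box = default_box(params)
    rng = np.random.default_rng(params.seed)
    kmc_rng, noise_rng = rng.spawn(2)

    tip_labels = label_tips(topology, TipSpec(1))
    mids = sorted(m.id for m in topology.monomers)
    midx = {m: i for i, m in enumerate(mids)}
    state = {}
    for d, (a, b) in enumerate(topology.dimers0):
        for col, m in enumerate((a, b)):
            st = _State(site=d, col=col)
            st.partner = b if m == a else a
            state[m] = st
    dimer_rate = {d: (params.k_tip if tip_labels[a] == "tip" else params.k_back)
                  for d, (a, b) in enumerate(topology.dimers0)}

    z0 = None
    # recover the lattice origin from frame-0 core centers
    core0 = frame0[topology.monomer(mids[0]).atoms[0]]
    z0 = core0[2]
    center_xy = np.array([
        0.5 * (frame0[topology.monomer(topology.dimers0[0][0]).atoms[0], 0]
               + frame0[topology.monomer(topology.dimers0[0][1]).atoms[0], 0]),
        core0[1],
    ])

    events: list[Event] = []
    n_frames = params.n_frames
    times = np.arange(n_frames) * params.dt_frame
    labels = np.empty((n_frames, len(mids)), dtype=object)
    coords = np.empty((n_frames, frame0.shape[0], 3))
    status_name = {"B": "bound", "SU": "stacked-unbound", "TR": "travelling"}

    def snapshot(fi):
        for m in mids:
            st = state[m]
            labels[fi, midx[m]] = status_name[st.status]
            su = RUPTURE_SHIFT if st.status == "SU" else 0.0
            pts = _monomer_atoms(st.col, z0 + st.site * params.d_stack, 0.0, su,
                                 params.d_dimer, center_xy)
            if st.status == "TR":
                # travelling monomers detach radially, each on its own
                # azimuthal lane so detached centers stay isolated
                ang = GOLDEN_ANGLE * m
                target = center_xy + SLIDE_RADIUS * np.array(
                    [np.cos(ang), np.sin(ang)])
                pts[:, :2] += target - pts[0, :2]
            # orientational jitter about the hb-quadruple center: tilts the
            # motif plane without moving the descriptor center
            rotvec = params.rot_sigma * noise_rng.standard_normal(3)
            hb_com = pts[1:].mean(axis=0)
            pts = (pts - hb_com) @ _rotation_matrix(rotvec).T + hb_com
            amp = params.noise_sigma * (params.wobble_unbound
                                        if st.status in ("SU", "TR") else 1.0)
            disp = amp * noise_rng.standard_normal(3)
            coords[fi, topology.monomer(m).atoms] = pts + disp

    def propensities():
        chans = []
        for d, (a, b) in enumerate(topology.dimers0):
            if state[a].status == "B" and state[a].partner == b and dimer_rate[d] > 0:
                chans.append((dimer_rate[d], ("rupture", d)))
        if params.k_slide > 0:
            for m in mids:
                if state[m].status in ("SU", "TR"):
                    chans.append((params.k_slide, ("slide", m)))
        if params.k_rebind > 0:
            unbound = [m for m in mids if state[m].status in ("SU", "TR")]
            seen = set()
            for m in unbound:
                for m2 in unbound:
                    if m2 <= m or (m, m2) in seen:
                        continue
                    s1, s2 = state[m], state[m2]
                    # at least one partner must be stacked-unbound (waiting in
                    # the stack frame); two travelling monomers in the
                    # detached lanes cannot re-form a dimer mid-stack
                    if (s1.site == s2.site and s1.col != s2.col
                            and "SU" in (s1.status, s2.status)
                            and topology.stacks[m] == topology.stacks[m2]):
                        chans.append((params.k_rebind, ("rebind", (m, m2))))
                        seen.add((m, m2))
        return chans

    t = 0.0
    fi = 0
    chans = propensities()
    total = sum(r for r, _ in chans)
    if total == 0 and n_frames > 0 and (params.k_tip or params.k_back or params.k_slide):
        pass  # static below threshold; handled by the generic loop
    if total == 0:
        log.warning("zero total KMC rate: trajectory is static apart from jitter")
    t_end = (n_frames - 1) * params.dt_frame if n_frames else 0.0
    while True:
        if total > 0:
            dt = kmc_rng.exponential(1.0 / total)
        else:
            dt = math.inf
        t_next = t + dt
        while fi < n_frames and times[fi] <= t_next:
            snapshot(fi)
            fi += 1
        if fi >= n_frames or t_next > t_end:
            break
        # pick channel
        u = kmc_rng.uniform(0.0, total)
        acc = 0.0
        for r, ch in chans:
            acc += r
            if u < acc:
                break
        kind, arg = ch
        t = t_next
        if kind == "rupture":
            a, b = topology.dimers0[arg]
            for m in (a, b):
                state[m].status = "SU"
                state[m].partner = None
            events.append(Event(time=t, monomers=(a, b), type="rupture", site=arg))
        elif kind == "slide":
            m = arg
            st = state[m]
            step = 1 if kmc_rng.uniform() < 0.5 else -1
            new = st.site + step
            if new < 0 or new > D - 1:
                new = st.site - step          # reflect at the ends
            st.site = new
            st.status = "TR"
            events.append(Event(time=t, monomers=(m,), type="slide-step", site=new))
        else:  # rebind
            m, m2 = arg
            for mm in (m, m2):
                state[mm].status = "B"
            state[m].partner = m2
            state[m2].partner = m
            events.append(Event(time=t, monomers=(m, m2), type="rebind",
                                site=state[m].site))
        chans = propensities()
        total = sum(r for r, _ in chans)

    traj = Trajectory(coordinates=coords, times=times,
                      box=np.tile(box, (n_frames, 1)))
    gt = GroundTruth(labels=labels, events=events,
                     rates={"tip": params.k_tip, "backbone": params.k_back,
                            "slide": params.k_slide, "rebind": params.k_rebind},
                     tip_monomers=[m for m, l in tip_labels.items() if l == "tip"])
    return traj, gt


# ---------------------------------------------------------------------------
# Synthetic infrequent-metadynamics bias traces
# ---------------------------------------------------------------------------

@dataclass
class BiasedRun:
    """One synthetic biased run: the trace, its biased stopping time, and the
    planted unbiased transition time it encodes."""

    trace: BiasTrace
    t_transition: float          # biased (simulation-clock) transition time, ps
    unbiased_time: float         # planted draw from Exp(true_tau), ps


def sample_biased_transitions(true_tau: float, bias_rate: float, pace: float,
                              n_runs: int, seed: int = 0,
                              temperature: float = 298.0,
                              bias_factor: float = 10.0) -> list[BiasedRun]:
    """Draw unbiased transition times from Exp(true_tau) and wrap each in a
    well-tempered-style bias staircase.

    The bias grows by ``h_k = bias_rate * exp(-V_k / ((gamma - 1) k_B T))``
    every ``pace`` ps.  The biased stopping time t_b is constructed so that
    the running acceleration integral sum_i dt_i exp(beta V_i) equals the
    planted draw, i.e. the standard time-rescaling reconstruction recovers
    the draw exactly.
    """
    if true_tau <= 0:
        raise ValueError("true_tau must be positive")
    rng = np.random.default_rng(seed)
    beta = beta_from_temperature(temperature)
    kT = 1.0 / beta
    runs = []
    for _ in range(n_runs):
        t_unb = rng.exponential(true_tau)
        # staircase: V constant on [k*pace, (k+1)*pace)
        v_list = [0.0]
        acc = 0.0           # accelerated (unbiased) time consumed so far
        t_b = None
        k = 0
        while True:
            v = v_list[k]
            seg = pace * math.exp(beta * v)
            if acc + seg >= t_unb:
                t_b = k * pace + (t_unb - acc) / math.exp(beta * v)
                break
            acc += seg
            if bias_rate > 0 and bias_factor > 1:
                v_next = v + bias_rate * math.exp(-v / ((bias_factor - 1.0) * kT))
            else:
                v_next = v + bias_rate
            v_list.append(v_next)
            k += 1
        times = np.arange(len(v_list)) * pace
        v_arr = np.array(v_list)
        cv = np.where(times < t_b, 4.0, 0.0)   # HB-count-like CV: intact, then broken
        trace = BiasTrace(times=times, cv_values=cv[:, None], v_bias=v_arr,
                          temperature=temperature, cv_names=("n_hb",))
        runs.append(BiasedRun(trace=trace, t_transition=t_b, unbiased_time=t_unb))
    return runs


def write_dataset(outdir: str | Path, topology: StackTopology, traj: Trajectory,
                  gt: GroundTruth | None, params: SyntheticParams,
                  manifest_extra: dict | None = None) -> None:
    """Write topology/trajectory/ground-truth plus a parameter manifest."""
    from .model import write_xyz
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    topology.save(out / "topology.json")
    write_xyz(traj, out / "trajectory.xyz")
    if gt is not None:
        gt.save(out / "ground_truth.json")
    manifest = {"params": asdict(params), "n_frames": traj.n_frames,
                "n_atoms": traj.n_atoms}
    manifest.update(manifest_extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
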
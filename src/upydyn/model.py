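"""Data model and I/O for UPy stack analyses.

Unit conventions used throughout the package: coordinates in nm, times in
ps, energies in kJ/mol.  ``KB`` is Boltzmann's constant in kJ/(mol K), the
GROMACS convention.  All pair distances respect the minimum-image
convention for periodic dimensions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger("upydyn")

KB = 0.0083144621  # kJ/(mol K)


def beta_from_temperature(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)


def minimum_image(dx: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    dx : (..., 3) displacement vectors in nm.
    box : (3,) orthorhombic box lengths in nm, or None for no periodicity.
    """
    if box is None:
        return dx
    box = np.asarray(box, dtype=float)
    return dx - box * np.round(dx / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image distances between paired points ``a[i]``–``b[i]``."""
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), box)
    return np.linalg.norm(d, axis=-1)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class Monomer:
    """One monomer: atom indices plus the 4-atom H-bond donor/acceptor array.

    ``center`` optionally names the atom whose position is the geometric
    center of the core (used for center-center distances); when absent the
    centroid of the core subset is used.
    """

    id: int
    atoms: np.ndarray           # all atom indices of this monomer
    core: np.ndarray            # core-atom subset (used for centers/planarity)
    side: np.ndarray            # side-chain subset (may be empty)
    hb: np.ndarray              # exactly 4 atom indices (DDAA array)
    center: int | None = None

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=int)
        self.core = np.asarray(self.core, dtype=int)
        self.side = np.asarray(self.side, dtype=int)
        self.hb = np.asarray(self.hb, dtype=int)
        if self.hb.shape != (4,) or len(set(self.hb.tolist())) != 4:
            raise ValueError(
                f"monomer {self.id}: hb quadruple must be 4 distinct atom "
                f"indices, got {self.hb.tolist()}"
            )


@dataclass
class StackTopology:
    """Stack topology: monomers, initial dimer pairing, stack membership.

    ``axis_order[stack_id]`` lists dimer indices (into ``dimers0``) in order
    along the stacking axis.
    """

    monomers: list[Monomer]
    dimers0: list[tuple[int, int]]
    stacks: dict[int, int]                  # monomer id -> stack id
    axis_order: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.monomers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate monomer ids")
        known = set(ids)
        for a, b in self.dimers0:
            if a not in known or b not in known:
                raise ValueError(f"dimers0 pair ({a},{b}) references unknown monomer")
            if self.stacks.get(a) != self.stacks.get(b):
                raise ValueError(f"dimers0 pair ({a},{b}) spans two stacks")
        missing = known - set(self.stacks)
        if missing:
            raise ValueError(f"monomers without stack membership: {sorted(missing)}")
        for sid, order in self.axis_order.items():
            sdimers = [i for i, (a, b) in enumerate(self.dimers0)
                       if self.stacks[a] == sid]
            if sorted(order) != sorted(sdimers):
                raise ValueError(
                    f"axis_order for stack {sid} is not a permutation of its dimers"
                )

    # -- convenience --------------------------------------------------------
    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    @property
    def n_atoms(self) -> int:
        return int(max(m.atoms.max() for m in self.monomers)) + 1

    def monomer(self, mid: int) -> Monomer:
        for m in self.monomers:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def stack_ids(self) -> list[int]:
        return sorted(set(self.stacks.values()))

    def monomers_of_stack(self, sid: int) -> list[int]:
        return [m.id for m in self.monomers if self.stacks[m.id] == sid]

    def hb_pairs_of_dimer(self, d: int) -> list[tuple[int, int]]:
        """The 4 donor–acceptor atom pairs of dimer ``d`` (index into dimers0)."""
        a, b = self.dimers0[d]
        ha, hb_ = self.monomer(a).hb, self.monomer(b).hb
        return list(zip(ha.tolist(), hb_.tolist()))

    def compute_axis_order(self, frame0: np.ndarray) -> None:
        """Order each stack's dimers by projection on its principal axis.

        Used when the annotation does not state the ordering; deterministic
        given frame-0 coordinates.
        """
        for sid in self.stack_ids():
            dimer_idx = [i for i, (a, b) in enumerate(self.dimers0)
                         if self.stacks[a] == sid]
            centers = []
            for i in dimer_idx:
                a, b = self.dimers0[i]
                idx = np.concatenate([self.monomer(a).core, self.monomer(b).core])
                centers.append(frame0[idx].mean(axis=0))
            centers = np.array(centers)
            c = centers - centers.mean(axis=0)
            if len(dimer_idx) == 1:
                self.axis_order[sid] = dimer_idx
                continue
            _, _, vt = np.linalg.svd(c, full_matrices=False)
            proj = c @ vt[0]
            # deterministic sign: point the axis from first to last dimer
            if proj[-1] < proj[0]:
                proj = -proj
            self.axis_order[sid] = [dimer_idx[k] for k in np.argsort(proj, kind="stable")]

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "monomers": [
                {"id": m.id, "atoms": m.atoms.tolist(), "core": m.core.tolist(),
                 "side": m.side.tolist(), "hb": m.hb.tolist(),
                 "center": m.center}
                for m in self.monomers
            ],
            "dimers0": [list(p) for p in self.dimers0],
            "stacks": {str(k): v for k, v in self.stacks.items()},
            "axis_order": {str(k): list(v) for k, v in self.axis_order.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackTopology":
        monomers = []
        for mrec in d["monomers"]:
            if "hb" not in mrec or mrec["hb"] is None:
                raise ValueError(
                    f"monomer {mrec.get('id')}: missing hb quadruple annotation"
                )
            atoms = np.asarray(mrec["atoms"], dtype=int)
            core = np.asarray(mrec.get("core", mrec["atoms"]), dtype=int)
            side = mrec.get("side")
            if side is None:
                # unannotated atoms fall into the side-chain subset
                side = sorted(set(atoms.tolist()) - set(core.tolist()))
            center = mrec.get("center")
            monomers.append(Monomer(id=int(mrec["id"]), atoms=atoms, core=core,
                                    side=np.asarray(side, dtype=int),
                                    hb=np.asarray(mrec["hb"], dtype=int),
                                    center=None if center is None else int(center)))
        return cls(
            monomers=monomers,
            dimers0=[tuple(int(x) for x in p) for p in d["dimers0"]],
            stacks={int(k): int(v) for k, v in d["stacks"].items()},
            axis_order={int(k): [int(x) for x in v]
                        for k, v in d.get("axis_order", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def load_topology(topology_file: str | Path, annotation: dict | str | Path | None = None,
                  ) -> StackTopology:
    """Load a stack topology from file.

    ``topology_file`` may be the internal JSON topology (self-contained) or a
    PDB/GRO structure, in which case ``annotation`` must map each monomer's
    H-bond quadruple (by atom name or index), the initial pairing, and stack
    membership.
    """
    p = Path(topology_file)
    if p.suffix == ".json":
        topo = StackTopology.from_dict(json.loads(p.read_text()))
        return topo
    if annotation is None:
        raise ValueError("PDB/GRO topologies require an annotation")
    if isinstance(annotation, (str, Path)):
        annotation = json.loads(Path(annotation).read_text())
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(p))
    names = [a.name for a in u.atoms]
    monomers = []
    for mrec in annotation["monomers"]:
        atoms = np.asarray(mrec["atoms"], dtype=int)
        hb_spec = mrec.get("hb")
        if hb_spec is None:
            raise ValueError(f"monomer {mrec.get('id')}: missing hb quadruple annotation")
        hb = []
        for h in hb_spec:
            if isinstance(h, str):
                cand = [i for i in atoms if names[i] == h]
                if len(cand) != 1:
                    raise ValueError(
                        f"monomer {mrec['id']}: hb atom name {h!r} matches "
                        f"{len(cand)} atoms, need exactly 1"
                    )
                hb.append(cand[0])
            else:
                hb.append(int(h))
        core = np.asarray(mrec.get("core", hb), dtype=int)
        side = sorted(set(atoms.tolist()) - set(core.tolist()))
        monomers.append(Monomer(id=int(mrec["id"]), atoms=atoms, core=core,
                                side=np.asarray(side, int), hb=np.asarray(hb, int)))
    topo = StackTopology(
        monomers=monomers,
        dimers0=[tuple(int(x) for x in pr) for pr in annotation["dimers0"]],
        stacks={int(k): int(v) for k, v in annotation["stacks"].items()},
        axis_order={int(k): [int(x) for x in v]
                    for k, v in annotation.get("axis_order", {}).items()},
    )
    if not topo.axis_order:
        topo.compute_axis_order(u.atoms.positions / 10.0)  # A -> nm
    return topo


# ---------------------------------------------------------------------------
# Tip labelling
# ---------------------------------------------------------------------------

@dataclass
class TipSpec:
    """How many terminal dimers per stack end count as "tip".

    depth=1 marks the end dimers; depth=2 additionally their first neighbors.
    """

    depth: int = 1


def label_tips(topology: StackTopology, spec: TipSpec | int = TipSpec(1)) -> dict[int, str]:
    """Label each monomer 'tip' or 'backbone' from the stack axis order."""
    depth = spec.depth if isinstance(spec, TipSpec) else int(spec)
    labels: dict[int, str] = {}
    for sid in topology.stack_ids():
        order = topology.axis_order.get(sid)
        if order is None:
            raise ValueError(f"stack {sid}: axis_order not populated")
        n = len(order)
        if n:
            if depth < 1 or depth > max(1, n // 2):
                if not (depth == 1 and n == 1):
                    raise ValueError(
                        f"tip depth {depth} out of bounds for a {n}-dimer stack"
                    )
            tip_dimers = set(order[:depth]) | set(order[-depth:])
            for i, (a, b) in enumerate(topology.dimers0):
                if topology.stacks[a] != sid:
                    continue
                lab = "tip" if i in tip_dimers else "backbone"
                labels[a] = lab
                labels[b] = lab
        # monomers outside any dimer (detached) count as tips
        for m in topology.monomers_of_stack(sid):
            labels.setdefault(m, "tip")
    return labels


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered coordinate frames with a periodic box.

    coordinates: (n_frames, n_atoms, 3) nm; times: (n_frames,) ps;
    box: (n_frames, 3) nm; periodic: (3,) bool flags.
    """

    coordinates: np.ndarray
    times: np.ndarray
    box: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.array([True] * 3))

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        self.times = np.asarray(self.times, float)
        self.box = np.asarray(self.box, float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (len(self.times), 1))
        if self.coordinates.ndim != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise ValueError("times/coordinates length mismatch")
        dt = np.diff(self.times)
        if len(dt) and np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"times not strictly increasing at frame {bad}")
        if len(dt) > 1:
            tol = 1e-6 * max(1.0, abs(dt[0]))
            off = np.abs(dt - dt[0]) > tol
            if np.any(off):
                bad = int(np.argmax(off)) + 1
                raise ValueError(f"non-uniform frame interval at frame {bad}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def dt_frame(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def effective_box(self, frame: int) -> np.ndarray | None:
        """Box for minimum imaging at a frame; None if fully aperiodic."""
        if not self.periodic.any():
            return None
        b = self.box[frame].copy()
        b[~self.periodic] = np.inf
        return b


def write_xyz(traj: Trajectory, path: str | Path, precision: int = 6) -> None:
    """Write the internal plain-text XYZ trajectory (nm; box/time in comment)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            bx = " ".join(f"{v:.{precision}f}" for v in traj.box[f])
            fh.write(f"t= {traj.times[f]:.{precision}f} box= {bx}\n")
            for x, y, z in traj.coordinates[f]:
                fh.write(f"X {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")


def read_trajectory(path: str | Path, selection: np.ndarray | None = None,
                    stride: int = 1) -> Trajectory:
    """Read a trajectory.

    The internal ``.xyz`` text format is parsed directly; standard binary
    formats (XTC/DCD, with a PDB/GRO topology passed as a tuple) go through
    MDAnalysis and are converted from A to nm.
    """
    p = Path(path)
    if isinstance(path, (tuple, list)):
        return _read_mdanalysis(path, selection, stride)
    if p.suffix != ".xyz":
        raise ValueError(f"unsupported trajectory format {p.suffix!r}; "
                         "pass (topology, trajectory) for XTC/DCD")
    frames, times, boxes = [], [], []
    with open(p) as fh:
        lines = fh.read().split("\n")
    i = 0
    nl = len(lines)
    while i < nl and lines[i].strip():
        try:
            nat = int(lines[i].strip())
        except ValueError as e:
            raise ValueError(f"bad atom-count line {i + 1}") from e
        if i + 2 + nat > nl or any(not lines[i + 2 + k].strip() for k in range(nat)):
            raise ValueError(f"truncated frame starting at line {i + 1}")
        comment = lines[i + 1].split()
        t = float(comment[comment.index("t=") + 1])
        bi = comment.index("box=")
        box = [float(v) for v in comment[bi + 1:bi + 4]]
        coords = np.array(
            [[float(v) for v in lines[i + 2 + k].split()[1:4]] for k in range(nat)]
        )
        frames.append(coords)
        times.append(t)
        boxes.append(box)
        i += 2 + nat
    if not frames:
        raise ValueError(f"no frames in {p}")
    coords = np.array(frames)[::stride]
    times = np.array(times)[::stride]
    boxes = np.array(boxes)[::stride]
    if selection is not None:
        coords = coords[:, np.asarray(selection, int), :]
    return Trajectory(coordinates=coords, times=times, box=boxes)


def _read_mdanalysis(paths, selection, stride):
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(*[str(p) for p in paths])
    coords, times, boxes = [], [], []
    for ts in u.trajectory[::stride]:
        coords.append(u.atoms.positions / 10.0)
        times.append(ts.time)
        boxes.append(ts.dimensions[:3] / 10.0 if ts.dimensions is not None
                     else [np.inf] * 3)
    coords = np.array(coords)
    if selection is not None:
        coords = coords[:, np.asarray(selection, int), :]
    return Trajectory(coordinates=coords, times=np.array(times), box=np.array(boxes))


# ---------------------------------------------------------------------------
# Bias traces
# ---------------------------------------------------------------------------

@dataclass
class BiasTrace:
    """A COLVAR-style record: times, CV values, and the metadynamics bias."""

    times: np.ndarray               # ps, strictly increasing
    cv_values: np.ndarray           # (n, n_cv)
    v_bias: np.ndarray              # kJ/mol
    temperature: float              # K
    c_t: np.ndarray | None = None   # kJ/mol, optional reweighting offset
    cv_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.cv_values = np.atleast_2d(np.asarray(self.cv_values, float).T).T \
            if np.asarray(self.cv_values).ndim == 1 else np.asarray(self.cv_values, float)
        self.v_bias = np.asarray(self.v_bias, float)
        if not np.all(np.isfinite(self.v_bias)):
            raise ValueError("non-finite bias values")
        order = np.argsort(self.times, kind="stable")
        if np.any(np.diff(self.times) <= 0):
            if len(np.unique(self.times)) != len(self.times):
                raise ValueError("duplicate times in bias trace")
            log.warning("bias trace times unsorted; sorting")
            self.times = self.times[order]
            self.cv_values = self.cv_values[order]
            self.v_bias = self.v_bias[order]
            if self.c_t is not None:
                self.c_t = np.asarray(self.c_t, float)[order]

    @property
    def beta(self) -> float:
        return beta_from_temperature(self.temperature)


def read_bias_trace(path: str | Path, temperature: float,
                    column_map: dict | None = None) -> BiasTrace:
    """Read a whitespace-delimited COLVAR-style table.

    The header may be a PLUMED ``#! FIELDS ...`` line or a plain ``#``-prefixed
    (or bare) list of column names.  ``column_map`` maps roles to column names:
    ``{"time": ..., "bias": ..., "cv": [...], "c_t": ...}``; defaults are
    inferred (time, *.bias/bias columns, remaining numeric columns as CVs).
    """
    p = Path(path)
    header = None
    rows = []
    with open(p) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                toks = s.split()
                if len(toks) > 1 and toks[1] == "FIELDS":
                    header = toks[2:]
                continue
            if s.startswith("#"):
                if header is None:
                    header = s.lstrip("#").split()
                continue
            toks = s.split()
            if header is None:
                if any(not _is_number(t) for t in toks):
                    header = toks
                    continue
                raise ValueError(f"{p}: no header naming columns")
            try:
                rows.append([float(t) for t in toks])
            except ValueError:
                raise ValueError(f"{p}: non-numeric row at line {ln}")
    if header is None or not rows:
        raise ValueError(f"{p}: empty bias table")
    data = np.array(rows)
    cmap = dict(column_map or {})
    cols = {name: i for i, name in enumerate(header)}

    def col(name):
        if name not in cols:
            raise ValueError(f"{p}: missing column {name!r} (have {header})")
        return data[:, cols[name]]

    tname = cmap.get("time", "time")
    bname = cmap.get("bias")
    if bname is None:
        cand = [h for h in header if h == "bias" or h.endswith(".bias")]
        if not cand:
            raise ValueError(f"{p}: missing bias column (have {header})")
        bname = cand[0]
    ctname = cmap.get("c_t")
    if ctname is None:
        cand = [h for h in header if h in ("c_t", "ct") or h.endswith(".c_t")]
        ctname = cand[0] if cand else None
    cvnames = cmap.get("cv")
    if cvnames is None:
        cvnames = [h for h in header if h not in (tname, bname, ctname)]
    return BiasTrace(
        times=col(tname),
        cv_values=np.column_stack([col(c) for c in cvnames]) if cvnames
        else np.zeros((len(data), 0)),
        v_bias=col(bname),
        temperature=temperature,
        c_t=col(ctname) if ctname else None,
        cv_names=tuple(cvnames),
    )


def write_bias_trace(trace: BiasTrace, path: str | Path) -> None:
    names = list(trace.cv_names) or [f"cv{i}" for i in range(trace.cv_values.shape[1])]
    cols = ["time"] + names + ["metad.bias"] + (["metad.c_t"] if trace.c_t is not None else [])
    arrs = [trace.times] + [trace.cv_values[:, i] for i in range(trace.cv_values.shape[1])] \
        + [trace.v_bias] + ([trace.c_t] if trace.c_t is not None else [])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for row in zip(*arrs):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
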
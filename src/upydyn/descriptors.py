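"""Dynamic-environment descriptors: SOAP, tauSOAP, and LENS.

SOAP (smooth overlap of atomic positions) represents each center's
neighborhood as a Gaussian-smeared density expanded in an orthonormal
radial basis times spherical harmonics; the rotationally invariant power
spectrum p_{n n' l} = sum_m c_{nlm} c*_{n'lm} is the fingerprint.  Centers
here are the centers of mass of each monomer's 4-atom H-bond quadruple (the
interacting groups of the dimer), treated as a single species.

tauSOAP_i(t) is the Euclidean distance between the L2-normalized SOAP
vectors of center i at consecutive frames, min-max normalized over the
whole dataset to [0, 1]: static neighborhoods score 0, fully reshuffling
ones 1.  LENS is the purely set-based analogue: the fraction of the
neighbor-id list replaced between consecutive frames.

The radial expansion uses the closed-form spherical-harmonic expansion of a
displaced Gaussian (scaled modified spherical Bessel functions) with
Gauss-Legendre radial quadrature; tests check it against a direct 3-D
quadrature of the density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import sqrtm
from scipy.spatial import cKDTree
from scipy.special import ive, sph_harm_y

from .model import StackTopology, Trajectory, minimum_image

log = logging.getLogger("upydyn")


@dataclass(frozen=True)
class SOAPSpec:
    r_cut: float = 0.6       # nm
    n_max: int = 8           # radial basis functions
    l_max: int = 6           # angular band limit
    sigma_atom: float = 0.05 # nm, Gaussian smearing width
    n_radial_quad: int = 96  # Gauss-Legendre radial nodes

    def __post_init__(self):
        if self.r_cut <= 0 or self.n_max < 1 or self.l_max < 1:
            raise ValueError("invalid SOAP basis parameters")


@lru_cache(maxsize=8)
def _radial_basis(spec: SOAPSpec):
    """Orthonormal polynomial radial basis g_n(r) on [0, r_cut].

    Built from phi_n(r) = (r_cut - r)^(n+2) with the closed-form overlap
    S_nm = 2 rc^(n+m+7) / ((n+m+5)(n+m+6)(n+m+7)) and Loewdin S^(-1/2)
    orthonormalization; evaluated at Gauss-Legendre nodes.
    """
    rc, n_max = spec.r_cut, spec.n_max
    x, w = np.polynomial.legendre.leggauss(spec.n_radial_quad)
    r = 0.5 * rc * (x + 1.0)
    wr = 0.5 * rc * w
    n = np.arange(n_max)
    S = np.empty((n_max, n_max))
    for i in n:
        for j in n:
            p = i + j + 4
            S[i, j] = 2.0 * rc ** (p + 3) / ((p + 1) * (p + 2) * (p + 3))
    S_inv_half = np.real(np.linalg.inv(sqrtm(S)))
    phi = np.array([(rc - r) ** (k + 2) for k in n])      # (n_max, nr)
    G = S_inv_half @ phi
    return r, wr, G


def _sph_harm_table(l_max: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Y[l, m+l, k] complex spherical harmonics for all neighbors k."""
    k = len(theta)
    Y = np.zeros((l_max + 1, 2 * l_max + 1, k), dtype=complex)
    for l in range(l_max + 1):
        m = np.arange(-l, l + 1)
        # sph_harm_y broadcasts over (m, points)
        Y[l, :2 * l + 1] = sph_harm_y(l, m[:, None], theta[None, :], phi[None, :])
    return Y


def soap_vector(rel_positions: np.ndarray, spec: SOAPSpec = SOAPSpec()) -> np.ndarray:
    """L2-normalized SOAP power-spectrum vector of one neighborhood.

    ``rel_positions``: (k, 3) neighbor displacement vectors from the center,
    already filtered to |R| <= r_cut.  An empty neighborhood returns the
    isolated-center reference vector (all-zero spectrum with a unit padding
    component), so consecutive empty frames have zero distance.
    """
    n_pairs = spec.n_max * (spec.n_max + 1) // 2
    dim = n_pairs * (spec.l_max + 1) + 1
    R = np.atleast_2d(np.asarray(rel_positions, float))
    if R.size == 0:
        v = np.zeros(dim)
        v[-1] = 1.0
        return v
    r_nodes, w_nodes, G = _radial_basis(spec)
    sig2 = spec.sigma_atom ** 2
    Rn = np.linalg.norm(R, axis=1)
    k = len(Rn)
    ls = np.arange(spec.l_max + 1)
    # radial part: exp(-(r-R)^2/(2 sig^2)) * i_l(r R / sig^2) * e^{-rR/sig^2}
    x = r_nodes[None, None, :] * Rn[:, None, None] / sig2            # (k, 1, nr)
    gauss = np.exp(-(r_nodes[None, :] - Rn[:, None]) ** 2 / (2 * sig2))  # (k, nr)
    with np.errstate(invalid="ignore"):
        il = np.sqrt(np.pi / (2.0 * x)) * ive(ls[None, :, None] + 0.5, x)
    il = np.where(x > 0, il, np.where(ls[None, :, None] == 0, 1.0, 0.0))
    A = gauss[:, None, :] * il                                        # (k, l, nr)
    # radial integrals: I[k, n, l] = sum_r w r^2 G[n, r] A[k, l, r]
    I = np.einsum("r,nr,klr->knl", w_nodes * r_nodes ** 2, G, A)
    theta = np.arccos(np.clip(R[:, 2] / Rn, -1.0, 1.0))
    phi = np.arctan2(R[:, 1], R[:, 0])
    Y = _sph_harm_table(spec.l_max, theta, phi)                       # (l, 2l+1, k)
    # c[n, l, m] = 4 pi sum_k I[k, n, l] conj(Y[l, m, k])
    c = 4.0 * np.pi * np.einsum("knl,lmk->nlm", I, np.conj(Y))
    # power spectrum over unique (n <= n') pairs
    p = np.empty(dim)
    iu = np.triu_indices(spec.n_max)
    offdiag = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    for l in ls:
        pref = np.pi * np.sqrt(8.0 / (2 * l + 1))
        cl = c[:, l, :2 * l + 1]                                      # (n, m)
        M = np.real(cl @ np.conj(cl.T))                               # (n, n')
        p[l * n_pairs:(l + 1) * n_pairs] = M[iu] * offdiag * pref
    p[-1] = 0.0
    norm = np.linalg.norm(p)
    return p / norm if norm > 0 else p


def hb_centers(traj: Trajectory, topology: StackTopology) -> np.ndarray:
    """Per-monomer centers of mass of the H-bond quadruple, (n_frames, M, 3)."""
    mids = sorted(m.id for m in topology.monomers)
    out = np.empty((traj.n_frames, len(mids), 3))
    for i, mid in enumerate(mids):
        out[:, i] = traj.coordinates[:, topology.monomer(mid).hb].mean(axis=1)
    return out


def soap_frame(centers: np.ndarray, box: np.ndarray | None,
               spec: SOAPSpec = SOAPSpec()) -> tuple[np.ndarray, np.ndarray]:
    """SOAP vectors for all centers of one frame.

    Returns (vectors (M, dim), empty_mask (M,)).
    """
    M = len(centers)
    if box is not None and np.all(np.isfinite(box)):
        tree = cKDTree(np.mod(centers, box), boxsize=box)
        query = np.mod(centers, box)
    else:
        tree = cKDTree(centers)
        query = centers
        box = None
    nbrs = tree.query_ball_point(query, spec.r_cut)
    vecs = []
    empty = np.zeros(M, dtype=bool)
    for i in range(M):
        js = [j for j in nbrs[i] if j != i]
        rel = minimum_image(centers[js] - centers[i], box) if js else np.empty((0, 3))
        empty[i] = len(js) == 0
        vecs.append(soap_vector(rel, spec))
    return np.array(vecs), empty


@dataclass
class TauSOAPSeries:
    """Per-center tauSOAP series on frames 1..n-1, values in [0, 1]."""

    values: np.ndarray          # (n_frames - 1, M) normalized
    raw: np.ndarray             # same shape, pre-normalization distances
    times: np.ndarray           # frame times for rows (frames 1..)
    dt: float
    monomer_ids: list[int]
    empty_mask: np.ndarray      # (n_frames, M) empty-neighborhood flags

    def pooled(self) -> np.ndarray:
        return self.values.ravel()


def tau_soap_series(traj: Trajectory, topology: StackTopology,
                    spec: SOAPSpec = SOAPSpec(), stride: int = 1,
                    normalization: str = "dataset") -> TauSOAPSeries:
    """tauSOAP: consecutive-frame SOAP distances, min-max normalized.

    ``normalization``: "dataset" (default; one min/max over all centers and
    frames) or "per-center".  A degenerate (zero) range yields all-zero
    normalized values.
    """
    if traj.n_frames < 2:
        raise ValueError("tauSOAP needs at least 2 frames")
    centers = hb_centers(traj, topology)[::stride]
    mids = sorted(m.id for m in topology.monomers)
    n_f = len(centers)
    vecs = np.empty((n_f, len(mids), spec.n_max * (spec.n_max + 1) // 2
                     * (spec.l_max + 1) + 1))
    empty = np.zeros((n_f, len(mids)), dtype=bool)
    for f in range(n_f):
        vecs[f], empty[f] = soap_frame(centers[f],
                                       traj.effective_box(min(f * stride,
                                                              traj.n_frames - 1)),
                                       spec)
    raw = np.linalg.norm(np.diff(vecs, axis=0), axis=2)
    lo, hi = raw.min(), raw.max()
    if normalization == "per-center":
        lo = raw.min(axis=0, keepdims=True)
        hi = raw.max(axis=0, keepdims=True)
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(rng > 0, (raw - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return TauSOAPSeries(values=vals, raw=raw,
                         times=traj.times[::stride][1:].copy(),
                         dt=float(traj.dt_frame * stride),
                         monomer_ids=mids, empty_mask=empty)


def lens_series(traj: Trajectory, topology: StackTopology,
                cutoff: float = 0.6) -> np.ndarray:
    """LENS_i(t) = |symmetric difference| / (|N_t| + |N_{t-1}|) of neighbor-id
    sets within ``cutoff``; 0 when both sets are empty.  Shape (n_frames-1, M).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames < 2:
        raise ValueError("LENS needs at least 2 frames")
    centers = hb_centers(traj, topology)
    M = centers.shape[1]
    sets: list[list[set]] = []
    for f in range(traj.n_frames):
        box = traj.effective_box(f)
        if box is not None and np.all(np.isfinite(box)):
            tree = cKDTree(np.mod(centers[f], box), boxsize=box)
            q = np.mod(centers[f], box)
        else:
            tree = cKDTree(centers[f])
            q = centers[f]
        nbrs = tree.query_ball_point(q, cutoff)
        sets.append([set(js) - {i} for i, js in enumerate(nbrs)])
    out = np.zeros((traj.n_frames - 1, M))
    for f in range(1, traj.n_frames):
        for i in range(M):
            a, b = sets[f - 1][i], sets[f][i]
            tot = len(a) + len(b)
            out[f - 1, i] = len(a ^ b) / tot if tot else 0.0
    return out
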
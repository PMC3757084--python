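"""Elastic network models: springs, Hessian, covariance, predicted MSRF.

A protein is coarse-grained to one bead per residue at the Cα position,
with Hookean springs between spatial neighbours and the input structure as
the global energy minimum,

    V = Σ_(i<j) ½ k_ij (d_ij − d⁰_ij)²,

where d_ij and d⁰_ij are the instantaneous and equilibrium inter-bead
distances.  Classic variants choose k as a function of distance only,

    k(d) = γ (d / 1 Å)^(−p) Θ(r_c − d),

with cutoff r_c and decay exponent p; table-driven variants look k up in a
derived table of amino-acid-pair- and distance-specific spring constants.
Covalently bonded (consecutive) residues always get a stiffer spring:
``bonded_factor`` (default 10) times the mean non-bonded spring constant at
a separation of 3.5 Å, averaged over amino-acid types.

The linearised equilibrium statistics come from the 3N × 3N Hessian H of V:
the Moore–Penrose pseudo-inverse over the non-rigid-body modes, scaled by
kBT, is the coordinate covariance matrix C.  MSRF_i = trace of the 3 × 3
diagonal block C_ii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .ensemble_io import Structure

__all__ = [
    "SpringModel",
    "PRESETS",
    "preset",
    "ElasticNetwork",
    "spring_constant",
    "build_network",
    "assemble_hessian",
    "compute_covariance",
    "covariance_block",
    "msrf_from_covariance",
    "fit_temperature_scale",
    "msrf_to_bfactor",
]


class NetworkError(ValueError):
    """Raised for disconnected or degenerate elastic networks."""


@dataclass(frozen=True)
class SpringModel:
    """Rule assigning a spring constant to a residue pair.

    ``kind`` is "classic" (distance power law with cutoff, amino-acid
    agnostic) or "table" (lookup in a derived :class:`~stiffnet.derivation.
    SpringTable`).  ``gamma`` carries units kBT/Å² (the power law uses a
    1 Å reference distance); its absolute value is immaterial downstream
    because the temperature factor is fitted per protein.
    """

    kind: str = "classic"
    cutoff: float = math.inf
    exponent: float = 0.0
    gamma: float = 1.0
    bonded_factor: float = 10.0
    table: object | None = None

    def __post_init__(self):
        if self.kind not in ("classic", "table"):
            raise ValueError(f"unknown spring model kind {self.kind!r}")
        if self.kind == "table" and self.table is None:
            raise ValueError("table model requires a spring table")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive (or infinite)")
        if self.exponent < 0:
            raise ValueError("decay exponent must be >= 0")
        if not self.bonded_factor > 0:
            raise ValueError("bonded_factor must be positive")

    @property
    def max_range(self) -> float:
        """Largest distance at which a non-bonded spring can be nonzero."""
        if self.kind == "classic":
            return self.cutoff
        return self.table.max_range


#: Classic variants: homogeneous cutoff networks at 10 and 13 Å, the
#: parameter-free ENM (k ∝ d⁻²; no cutoff), and a Hinsen-style d⁻⁶ decay.
PRESETS: dict[str, SpringModel] = {
    "enm10": SpringModel(kind="classic", cutoff=10.0, exponent=0.0),
    "enm13": SpringModel(kind="classic", cutoff=13.0, exponent=0.0),
    "pfenm": SpringModel(kind="classic", cutoff=math.inf, exponent=2.0),
    "pow6": SpringModel(kind="classic", cutoff=math.inf, exponent=6.0),
}


def preset(name: str, **overrides) -> SpringModel:
    """Return a named preset, optionally with fields overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    model = PRESETS[name]
    return replace(model, **overrides) if overrides else model


def spring_constant(model: SpringModel, aa_i: str, aa_j: str, d: float,
                    bonded: bool = False) -> float:
    """Spring constant (kBT/Å²) for a residue pair at distance ``d`` Å."""
    if not d > 0:
        raise ValueError("distance must be positive")
    if bonded:
        return model.bonded_factor * _mean_nonbonded_k(model, 3.5)
    if model.kind == "classic":
        if d >= model.cutoff:
            return 0.0
        return model.gamma * d ** (-model.exponent)
    return model.table.lookup(aa_i, aa_j, d)


def _mean_nonbonded_k(model: SpringModel, d: float) -> float:
    if model.kind == "classic":
        # amino-acid independent: the mean over types is the value itself
        return model.gamma * d ** (-model.exponent)
    return model.table.mean_k_near(d)


@dataclass
class ElasticNetwork:
    """Equilibrium geometry plus the spring list of an elastic network."""

    coords: np.ndarray          # (N, 3) Å
    pairs: np.ndarray           # (M, 2) int, i < j
    k: np.ndarray               # (M,) kBT/Å²
    d0: np.ndarray              # (M,) Å, equilibrium distances
    bonded: np.ndarray          # (M,) bool, exactly |i - j| == 1
    kBT: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.k = np.asarray(self.k, dtype=float)
        self.d0 = np.asarray(self.d0, dtype=float)
        self.bonded = np.asarray(self.bonded, dtype=bool)
        m = len(self.pairs)
        if not (len(self.k) == len(self.d0) == len(self.bonded) == m):
            raise ValueError("pair annotation arrays must share one length")
        if np.any(self.k < 0):
            raise ValueError("spring constants must be >= 0")
        if m and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must be i < j")
        seps = np.abs(self.pairs[:, 1] - self.pairs[:, 0]) if m else np.array([])
        if m and np.any(self.bonded != (seps == 1)):
            raise ValueError("bonded flag must mark exactly |i - j| == 1 pairs")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def scaled(self, factor: float) -> "ElasticNetwork":
        """Network with all spring constants multiplied by ``factor``."""
        return ElasticNetwork(self.coords.copy(), self.pairs.copy(),
                              self.k * factor, self.d0.copy(),
                              self.bonded.copy(), self.kBT)


def build_network(rep: Structure, model: SpringModel,
                  max_pair_distance: float | None = None,
                  kBT: float = 1.0,
                  lookup_distances: np.ndarray | None = None) -> ElasticNetwork:
    """Enumerate springs for a representative structure under a spring model.

    All pairs i < j with nonzero spring constant within
    ``max_pair_distance`` (default: the model's own range) are included;
    consecutive residues are always included as bonded springs regardless of
    distance.  A disconnected network (a bead without a path to the rest)
    raises, since it would carry more than six rigid-body modes.

    ``lookup_distances`` (N × N, Å) optionally overrides the distances used
    to *assign* spring constants (and the range filter) while the stored
    equilibrium distances stay those of ``rep``.  The derivation loop uses
    this to assign springs by the ensemble-mean equilibrium distance — the
    same quantity that bins the stiffness profiles — instead of the noisier
    single-model distance.
    """
    coords = rep.coords
    n = coords.shape[0]
    seq = rep.sequence
    if max_pair_distance is None:
        max_pair_distance = model.max_range
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    ldist = dist if lookup_distances is None else \
        np.asarray(lookup_distances, dtype=float)
    if ldist.shape != (n, n):
        raise ValueError("lookup_distances must be an N x N matrix")
    pairs, ks, d0s, bonded = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = ldist[i, j]
            is_bonded = j == i + 1
            if not is_bonded and d > max_pair_distance:
                continue
            kij = spring_constant(model, seq[i], seq[j], d, bonded=is_bonded)
            if kij <= 0.0 and not is_bonded:
                continue
            pairs.append((i, j))
            ks.append(kij)
            d0s.append(dist[i, j])
            bonded.append(is_bonded)
    net = ElasticNetwork(coords.copy(), np.array(pairs, dtype=int),
                         np.array(ks), np.array(d0s),
                         np.array(bonded, dtype=bool), kBT=kBT)
    _check_connected(net)
    return net


def _check_connected(net: ElasticNetwork) -> None:
    n = net.n_beads
    active = net.k > 0
    rows = net.pairs[active, 0]
    cols = net.pairs[active, 1]
    adj = scipy.sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                                  shape=(n, n))
    n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp != 1:
        raise NetworkError(f"network has {n_comp} connected components; "
                           "an ENM must be a single component")


def assemble_hessian(net: ElasticNetwork) -> np.ndarray:
    """3N × 3N Hessian of the network potential at equilibrium (kBT/Å²).

    Each spring contributes −k u uᵀ to the off-diagonal block of its pair
    (u the unit bond vector); diagonal blocks are minus the sum of the
    row's off-diagonal blocks, so rigid translations are exact zero modes.
    """
    n = net.n_beads
    h = np.zeros((3 * n, 3 * n))
    rij = net.coords[net.pairs[:, 0]] - net.coords[net.pairs[:, 1]]
    d = np.linalg.norm(rij, axis=1)
    if np.any(d <= 0):
        raise NetworkError("coincident beads in network")
    u = rij / d[:, None]
    blocks = -net.k[:, None, None] * u[:, :, None] * u[:, None, :]
    for (i, j), blk in zip(net.pairs, blocks):
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] += blk
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] += blk
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= blk
    return h


def _n_rigid_body_modes(coords: np.ndarray | None) -> int:
    """6 in general; 5 when all beads are collinear (no axial rotation)."""
    if coords is None:
        return 6
    centered = coords - coords.mean(axis=0)
    return 5 if np.linalg.matrix_rank(centered, tol=1e-8) < 2 else 6


def compute_covariance(h: np.ndarray, kBT: float = 1.0,
                       coords: np.ndarray | None = None,
                       zero_tol: float = 1e-8) -> np.ndarray:
    """Coordinate covariance C = kBT Σ_m λ_m⁻¹ v_m v_mᵀ over nonzero modes.

    Eigenvalues below ``zero_tol`` times the largest count as rigid-body
    modes.  If more near-zero modes are present than rigid-body motion can
    account for (6, or 5 for collinear geometries passed via ``coords``),
    the network is disconnected or degenerate and an error is raised.
    """
    h = np.asarray(h, dtype=float)
    if not np.allclose(h, h.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = scipy.linalg.eigh(h)
    lam_max = evals[-1]
    if lam_max <= 0:
        raise NetworkError("Hessian has no positive eigenvalues")
    zero = evals < zero_tol * lam_max
    n_zero = int(zero.sum())
    if n_zero > _n_rigid_body_modes(coords):
        raise NetworkError(
            f"{n_zero} near-zero modes: disconnected or degenerate network")
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, evals))
    c = (evecs * inv) @ evecs.T * kBT
    return 0.5 * (c + c.T)


def covariance_block(c: np.ndarray, i: int, j: int) -> np.ndarray:
    """3 × 3 submatrix C_ij of a 3N × 3N covariance matrix."""
    return c[3 * i:3 * i + 3, 3 * j:3 * j + 3]


def msrf_from_covariance(c: np.ndarray) -> np.ndarray:
    """Predicted MSRF per residue: trace of the diagonal block C_ii (Å²)."""
    n = c.shape[0] // 3
    c4 = c.reshape(n, 3, n, 3)
    return np.einsum("iaia->i", c4)


def fit_temperature_scale(pred_msrf, exp_msrf) -> float:
    """Global factor matching predicted to experimental MSRF sums.

    The ENM spring constants are defined up to a multiplicative factor (the
    temperature); the factor is fitted for each protein independently as
    s = Σ MSRF_exp / Σ MSRF_pred, so s·pred and exp have equal sums.
    """
    pred = np.asarray(pred_msrf, dtype=float)
    exp = np.asarray(exp_msrf, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("predicted and experimental MSRF lengths differ")
    total = pred.sum()
    if not total > 0:
        raise ValueError("predicted MSRF sum must be positive")
    return float(exp.sum() / total)


def msrf_to_bfactor(msrf) -> np.ndarray:
    """Isotropic crystallographic B-factor, B = (8π²/3) · MSRF (Å²)."""
    msrf = np.asarray(msrf, dtype=float)
    if np.any(msrf < 0):
        raise ValueError("MSRF must be non-negative")
    return (8.0 * math.pi ** 2 / 3.0) * msrf
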
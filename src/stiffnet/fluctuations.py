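"""Inter-residue distance fluctuations and apparent-stiffness profiles.

The apparent stiffness of a residue pair,

    k_app = kBT / σ²(d_ij),

converts the variance of the inter-residue distance over an equilibrium
ensemble into an effective pair rigidity that includes all indirect network
effects.  Its uncorrelated counterpart k_unc uses the variance recomputed
after zeroing every cross-covariance between the two residues' motions, and
so isolates the contribution of their individual fluctuations.

Pooling pairs of one amino-acid type and one (discretised) equilibrium
distance over many proteins yields the stiffness of a *mean protein
environment* — pair-type statistics freed from any single fold's
architecture.  Each pair's variance is weighted by its protein's model
count n_p, and sparse pair types are blended toward the type-agnostic
profile with a pseudo-count N₀.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble_io import ConformerEnsemble
from . import enm

__all__ = [
    "ALL_TYPES",
    "aa_pair_key",
    "DistanceBinning",
    "PairStatistics",
    "StiffnessProfile",
    "experimental_distance_variance",
    "ensemble_coordinate_covariance",
    "distance_jacobian",
    "propagated_distance_variance",
    "propagated_distance_variances",
    "decorrelate",
    "apparent_stiffness",
    "compute_pair_statistics",
    "aggregate_stiffness",
    "sparse_corrected_stiffness",
    "write_profile",
]

#: Key of the type-agnostic ("all amino-acid pairs") profile row.
ALL_TYPES = "XX"


def aa_pair_key(aa_i: str, aa_j: str) -> str:
    """Canonical unordered amino-acid pair key, e.g. ('L','A') -> 'AL'."""
    return aa_i + aa_j if aa_i <= aa_j else aa_j + aa_i


@dataclass(frozen=True)
class DistanceBinning:
    """Half-open distance bins [edge, edge + width) on a fixed grid.

    Edges sit at multiples of ``width`` (0.5 Å by default, fine enough to
    resolve the 5–5.5 Å hydrogen-bonding feature of regular secondary
    structure).  Distances outside [d_min, d_max) have no bin.
    """

    width: float = 0.5
    d_min: float = 3.0
    d_max: float = 25.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("bin width must be positive")
        if not self.d_max > self.d_min >= 0:
            raise ValueError("need d_max > d_min >= 0")
        for edge in (self.d_min, self.d_max):
            if abs(round(edge / self.width) * self.width - edge) > 1e-9:
                raise ValueError("range edges must sit on multiples of width")

    @property
    def edges(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.width))
        return self.d_min + self.width * np.arange(n)

    def left_edge(self, d: float) -> float | None:
        """Left edge of the bin containing ``d``, or None if out of range."""
        if not (self.d_min <= d < self.d_max):
            return None
        idx = int(math.floor((d - self.d_min) / self.width + 1e-9))
        idx = min(idx, int(round((self.d_max - self.d_min) / self.width)) - 1)
        return round(self.d_min + idx * self.width, 6)

    def contains(self, d: float) -> bool:
        return self.d_min <= d < self.d_max


@dataclass
class PairStatistics:
    """Distance-fluctuation statistics of one residue pair in one protein."""

    protein_id: str
    i: int
    j: int
    aa_pair: str                     # canonical unordered key
    d0: float                        # equilibrium distance (Å)
    var_exp: float                   # experimental σ² (Å²)
    var_pred: float = math.nan       # model-predicted σ² (Å²)
    var_unc: float = math.nan        # decorrelated σ² (Å²)
    bonded: bool = False
    n_models: int = 1                # protein's model count n_p (weight)

    def variance(self, source: str) -> float:
        return {"exp": self.var_exp, "pred": self.var_pred,
                "unc": self.var_unc}[source]


# ---------------------------------------------------------------------------
# Per-pair variances
# ---------------------------------------------------------------------------

def experimental_distance_variance(ens: ConformerEnsemble, i: int,
                                   j: int) -> float:
    """Population variance of d_ij over the ensemble's models (Å²)."""
    d = np.linalg.norm(ens.coords[:, i] - ens.coords[:, j], axis=1)
    return float(np.mean((d - d.mean()) ** 2))


def ensemble_coordinate_covariance(ens: ConformerEnsemble) -> np.ndarray:
    """3N × 3N covariance of residue displacements about the ensemble mean.

    Population normalisation (1/n_models).  Requires a superposed ensemble:
    otherwise rigid-body motion would contaminate the covariance.
    """
    if not ens.superposed:
        raise ValueError("ensemble must be superposed before extracting "
                         "the coordinate covariance")
    if ens.n_models < 2:
        raise ValueError("need at least 2 models for a covariance")
    disp = (ens.coords - ens.mean_coords()).reshape(ens.n_models, -1)
    return disp.T @ disp / ens.n_models


def distance_jacobian(coords_i, coords_j) -> np.ndarray:
    """Jacobian of d_ij w.r.t. the six coordinates of residues i and j.

    Returns (u, −u) with u the unit vector from j to i, i.e. the first
    triple is ∂d/∂r_i = (r_i − r_j)/d.
    """
    ri = np.asarray(coords_i, dtype=float)
    rj = np.asarray(coords_j, dtype=float)
    diff = ri - rj
    d = np.linalg.norm(diff)
    if d <= 0:
        raise ValueError("coincident points: distance Jacobian undefined")
    u = diff / d
    return np.concatenate([u, -u])


def propagated_distance_variance(c: np.ndarray, coords: np.ndarray,
                                 i: int, j: int) -> float:
    """First-order propagated variance of d_ij: σ² = J C_pair Jᵀ (Å²).

    Accounts for the individual anisotropic fluctuations of both residues
    and the correlation between their motions; the Jacobian is evaluated at
    the mean/equilibrium positions in ``coords``.
    """
    u = distance_jacobian(coords[i], coords[j])[:3]
    cii = enm.covariance_block(c, i, i)
    cjj = enm.covariance_block(c, j, j)
    cij = enm.covariance_block(c, i, j)
    return float(u @ cii @ u + u @ cjj @ u - 2.0 * u @ cij @ u)


def propagated_distance_variances(c: np.ndarray, coords: np.ndarray,
                                  pairs: np.ndarray) -> np.ndarray:
    """Vectorised :func:`propagated_distance_variance` over an (M, 2) array."""
    pairs = np.asarray(pairs, dtype=int)
    n = coords.shape[0]
    c4 = c.reshape(n, 3, n, 3)
    ii, jj = pairs[:, 0], pairs[:, 1]
    diff = coords[ii] - coords[jj]
    d = np.linalg.norm(diff, axis=1)
    if np.any(d <= 0):
        raise ValueError("coincident points in pair list")
    u = diff / d[:, None]
    cii = c4[ii, :, ii, :]
    cjj = c4[jj, :, jj, :]
    cij = c4[ii, :, jj, :]
    return (np.einsum("ma,mab,mb->m", u, cii, u)
            + np.einsum("ma,mab,mb->m", u, cjj, u)
            - 2.0 * np.einsum("ma,mab,mb->m", u, cij, u))


def decorrelate(c: np.ndarray) -> np.ndarray:
    """Zero all off-diagonal 3 × 3 blocks C_ij (i ≠ j) of a covariance."""
    n = c.shape[0] // 3
    out = np.zeros_like(c)
    for i in range(n):
        out[3 * i:3 * i + 3, 3 * i:3 * i + 3] = \
            c[3 * i:3 * i + 3, 3 * i:3 * i + 3]
    return out


def apparent_stiffness(variance: float, kBT: float = 1.0) -> float:
    """k_app = kBT / σ² (kBT/Å²)."""
    if not variance > 0:
        raise ValueError("zero or negative distance variance: apparent "
                         "stiffness is infinite/undefined")
    return kBT / variance


# ---------------------------------------------------------------------------
# Pair statistics for a whole protein
# ---------------------------------------------------------------------------

def compute_pair_statistics(ens: ConformerEnsemble,
                            rep_index: int | None = None,
                            model_covariance: np.ndarray | None = None,
                            include_uncorrelated: bool = True,
                            d_max: float | None = None,
                            d0_source: str = "mean") -> list[PairStatistics]:
    """All-pair distance statistics for one (superposed) ensemble.

    ``d0`` is the pair's equilibrium distance: by default the ensemble-mean
    distance (its standard error shrinks with the model count, so bin
    assignments are far less noisy than any single model's), or the
    representative model's distance with ``d0_source="representative"``.
    ``var_exp`` is the direct ensemble variance; ``var_unc`` propagates the
    decorrelated experimental coordinate covariance (Jacobian at the mean
    structure); ``var_pred`` propagates ``model_covariance`` (already
    temperature-scaled by the caller) at the representative coordinates.
    Pairs with d0 > ``d_max`` are skipped.
    """
    from .ensemble_io import select_representative

    if rep_index is None:
        rep_index = select_representative(ens)
    n = ens.n_residues
    rep = ens.coords[rep_index]
    mean = ens.mean_coords()
    seq = ens.sequence

    ii, jj = np.triu_indices(n, k=1)
    dists = np.linalg.norm(ens.coords[:, ii] - ens.coords[:, jj], axis=2)
    if d0_source == "mean":
        d0 = dists.mean(axis=0)
    elif d0_source == "representative":
        d0 = np.linalg.norm(rep[ii] - rep[jj], axis=1)
    else:
        raise ValueError("d0_source must be 'mean' or 'representative'")
    if d_max is not None:
        keep = d0 <= d_max
        # bonded pairs are kept so downstream consumers can see them flagged
        keep |= (jj - ii) == 1
        ii, jj, d0 = ii[keep], jj[keep], d0[keep]
        dists = dists[:, keep]
    pairs = np.column_stack([ii, jj])

    var_exp = dists.var(axis=0)  # population normalisation

    var_unc = np.full(len(ii), math.nan)
    if include_uncorrelated and ens.n_models >= 2:
        c_unc = decorrelate(ensemble_coordinate_covariance(ens))
        var_unc = propagated_distance_variances(c_unc, mean, pairs)

    var_pred = np.full(len(ii), math.nan)
    if model_covariance is not None:
        var_pred = propagated_distance_variances(model_covariance, rep, pairs)

    return [
        PairStatistics(ens.protein_id, int(i), int(j),
                       aa_pair_key(seq[i], seq[j]), float(d),
                       float(ve), float(vp), float(vu),
                       bonded=(j - i == 1), n_models=ens.n_models)
        for i, j, d, ve, vp, vu
        in zip(ii, jj, d0, var_exp, var_pred, var_unc)
    ]


# ---------------------------------------------------------------------------
# Aggregation into stiffness profiles
# ---------------------------------------------------------------------------

@dataclass
class StiffnessProfile:
    """Binned apparent-stiffness statistics per amino-acid pair type.

    ``counts`` and ``mean_var`` are keyed by (pair key, bin left edge); the
    pair key :data:`ALL_TYPES` holds the type-agnostic aggregate.  Counts
    are n_p-weighted occurrence numbers N_aa = Σ_p n_p N_{p,aa}.
    ``corrected_var`` (after :func:`sparse_corrected_stiffness`) holds the
    pseudo-count-blended variances.
    """

    binning: DistanceBinning
    kBT: float = 1.0
    counts: dict = field(default_factory=dict)
    mean_var: dict = field(default_factory=dict)
    corrected_var: dict | None = None
    n0: float | None = None
    overflow_count: float = 0.0      # pairs beyond d_max (diagnostic only)

    def keys(self):
        return self.mean_var.keys()

    def k_app(self, pair: str, left: float) -> float:
        return apparent_stiffness(self.mean_var[(pair, left)], self.kBT)

    def k_corr(self, pair: str, left: float) -> float:
        if self.corrected_var is None:
            raise ValueError("profile has no sparse-data correction; call "
                             "sparse_corrected_stiffness first")
        return apparent_stiffness(self.corrected_var[(pair, left)], self.kBT)

    def all_bins(self) -> list[float]:
        """Left edges of bins populated in the type-agnostic row."""
        return sorted(left for (pair, left) in self.mean_var
                      if pair == ALL_TYPES)


def aggregate_stiffness(pairs, binning: DistanceBinning,
                        kBT: float = 1.0,
                        variance_source: str = "exp") -> StiffnessProfile:
    """Pool per-pair variances into a mean-protein-environment profile.

    Bonded (consecutive-residue) pairs are dismissed, so only non-bonded
    interactions enter.  Within each (pair type, distance bin) cell the
    variance is averaged with weight n_p (the pair's protein model count)
    and converted to stiffness as k_app = kBT / ⟨σ²⟩ — the stiffness of the
    pooled fluctuation, robust to single near-rigid pairs.
    """
    if variance_source not in ("exp", "pred", "unc"):
        raise ValueError("variance_source must be one of exp/pred/unc")
    wsum: dict = {}
    vsum: dict = {}
    overflow = 0.0
    n_used = 0
    for p in pairs:
        if p.bonded:
            continue
        var = p.variance(variance_source)
        if not np.isfinite(var):
            continue
        left = binning.left_edge(p.d0)
        if left is None:
            if p.d0 >= binning.d_max:
                overflow += p.n_models
            continue
        w = float(p.n_models)
        for key in ((p.aa_pair, left), (ALL_TYPES, left)):
            wsum[key] = wsum.get(key, 0.0) + w
            vsum[key] = vsum.get(key, 0.0) + w * var
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable non-bonded pairs to aggregate")
    mean_var = {key: vsum[key] / wsum[key] for key in wsum}
    return StiffnessProfile(binning=binning, kBT=kBT, counts=wsum,
                            mean_var=mean_var, overflow_count=overflow)


def sparse_corrected_stiffness(profile: StiffnessProfile, n0: float = 500.0,
                               pair_types=None) -> StiffnessProfile:
    """Blend sparse pair-type cells toward the type-agnostic profile.

    For every bin populated in the ALL row and every requested pair type,
    ⟨σ²⟩_blend = (N_aa ⟨σ²⟩_aa + N₀ ⟨σ²⟩_ALL) / (N_aa + N₀): abundant types
    keep their own value, unseen types inherit the mean environment.  The
    ALL row is its own fixed point.
    """
    all_bins = profile.all_bins()
    if not all_bins:
        raise ValueError("profile has no type-agnostic (ALL) row")
    if pair_types is None:
        pair_types = sorted({pair for (pair, _) in profile.mean_var
                             if pair != ALL_TYPES})
    corrected: dict = {}
    for left in all_bins:
        v_all = profile.mean_var[(ALL_TYPES, left)]
        corrected[(ALL_TYPES, left)] = v_all
        for pair in pair_types:
            n_aa = profile.counts.get((pair, left), 0.0)
            v_aa = profile.mean_var.get((pair, left), 0.0)
            corrected[(pair, left)] = \
                (n_aa * v_aa + n0 * v_all) / (n_aa + n0)
    return replace(profile, corrected_var=corrected, n0=n0)


def write_profile(profile: StiffnessProfile, path,
                  header_comments: list[str] | None = None) -> None:
    """Write a profile as TSV: aa1 aa2 bin_left bin_right count k_app k_corr."""
    import pandas as pd

    rows = []
    for (pair, left), var in sorted(profile.mean_var.items()):
        k_corr = math.nan
        if profile.corrected_var is not None and \
                (pair, left) in profile.corrected_var:
            k_corr = profile.kBT / profile.corrected_var[(pair, left)]
        rows.append({
            "aa1": pair[0], "aa2": pair[1],
            "bin_left": left, "bin_right": round(left + profile.binning.width, 6),
            "count": profile.counts[(pair, left)],
            "k_app": profile.kBT / var if var > 0 else math.inf,
            "k_corr": k_corr,
        })
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.8g")
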
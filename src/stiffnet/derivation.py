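"""Iterative derivation of effective harmonic potentials from ensembles.

The derived spring tables make the elastic network's *predicted* apparent
stiffness in the mean protein environment match the *experimental* one.
Because a pair's apparent stiffness folds in the whole network, the spring
constants cannot be read off directly; instead they are refined
iteratively,

    k⁽ⁿ⁺¹⁾ = k⁽ⁿ⁾ · k_exp / k_pred⁽ⁿ⁾   (per pair type and distance bin),

the unique multiplicative update whose fixed point is k_pred = k_exp under
the equal-bond-energy argument.  Three table modes are supported:

* ``distance_only`` (dENM): one spring-constant curve k(d);
* ``sequence_only`` (sENM): one constant per amino-acid pair, applied below
  a fixed cutoff;
* ``sequence_distance`` (sdENM): k_aa(d) per amino-acid pair and bin,
  initialised from a dENM curve.

After every iteration the table is rescaled so the mean spring constant
over amino-acid types at 6 Å equals 1, and entries weaker than a cull
threshold are zeroed permanently (no direct interaction).  Confidence
intervals come from a bootstrap over proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble_io import ConformerEnsemble, Structure, superpose_ensemble, \
    select_representative, mean_square_residue_fluctuation
from . import enm
from .fluctuations import (ALL_TYPES, DistanceBinning, StiffnessProfile,
                           aa_pair_key,
                           compute_pair_statistics,
                           propagated_distance_variances,
                           sparse_corrected_stiffness)

__all__ = [
    "AA_ALPHABET",
    "MODES",
    "SpringTable",
    "DerivationConfig",
    "DerivationResult",
    "initialize_table",
    "update_table",
    "rescale_table",
    "cull_weak",
    "run_derivation",
    "bootstrap_confidence",
    "write_spring_table",
    "read_spring_table",
]

logger = logging.getLogger(__name__)

AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
MODES = ("distance_only", "sequence_only", "sequence_distance")

#: Reference distance (Å) at which the mean spring constant is set to 1.
RESCALE_REFERENCE_D = 6.0
#: Separation (Å) whose mean non-bonded spring constant defines bonded springs.
BONDED_REFERENCE_D = 3.5


class DerivationError(RuntimeError):
    """Raised when the iterative derivation cannot proceed."""


def _all_pairs(aa_types) -> list[str]:
    return [aa_pair_key(a, b) for ai, a in enumerate(aa_types)
            for b in aa_types[ai:]]


@dataclass
class SpringTable:
    """Effective harmonic potential k_aa(d) with cull flags and CIs.

    Entries are keyed by (amino-acid pair key or :data:`ALL_TYPES`, bin left
    edge); ``sequence_only`` tables use ``None`` as the bin coordinate and
    apply their single per-pair constant below ``cutoff``.  Lookups outside
    the table range, or on culled entries, give 0.
    """

    mode: str
    binning: DistanceBinning
    aa_types: tuple = AA_ALPHABET
    k: dict = field(default_factory=dict)
    culled: set = field(default_factory=set)
    ci: dict = field(default_factory=dict)       # key -> (low, high)
    cutoff: float | None = None                  # sequence_only only
    n_bootstrap: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown table mode {self.mode!r}")
        if self.mode == "sequence_only" and self.cutoff is None:
            raise ValueError("sequence_only table requires a cutoff")
        if any(v < 0 for v in self.k.values()):
            raise ValueError("spring constants must be >= 0")

    # -- key helpers --------------------------------------------------------

    def pair_keys(self) -> list[str]:
        if self.mode == "distance_only":
            return [ALL_TYPES]
        return _all_pairs(self.aa_types)

    def entry_keys(self) -> list[tuple]:
        if self.mode == "sequence_only":
            return [(p, None) for p in self.pair_keys()]
        return [(p, float(left)) for p in self.pair_keys()
                for left in self.binning.edges]

    def _pair_key(self, aa_i: str, aa_j: str) -> str:
        if self.mode == "distance_only":
            return ALL_TYPES
        if aa_i not in self.aa_types or aa_j not in self.aa_types:
            raise KeyError(f"unknown amino-acid code in pair "
                           f"({aa_i!r}, {aa_j!r}) for table lookup")
        return aa_pair_key(aa_i, aa_j)

    @property
    def max_range(self) -> float:
        return self.cutoff if self.mode == "sequence_only" \
            else self.binning.d_max

    # -- lookups ------------------------------------------------------------

    def lookup(self, aa_i: str, aa_j: str, d: float) -> float:
        """Spring constant for a non-bonded pair at distance ``d`` (Å)."""
        pair = self._pair_key(aa_i, aa_j)
        if self.mode == "sequence_only":
            if d >= self.cutoff:
                return 0.0
            return self.k.get((pair, None), 0.0)
        left = self.binning.left_edge(d)
        if left is None:
            return 0.0
        return self.k.get((pair, left), 0.0)

    def mean_k_at(self, left) -> float:
        """Mean spring constant over pair types in one bin (culled = 0)."""
        keys = [(p, left) for p in self.pair_keys()]
        return float(np.mean([self.k.get(key, 0.0) for key in keys]))

    def mean_k_near(self, d: float) -> float:
        """Mean spring constant over types at the bin nearest ``d``.

        Used for the bonded-spring rule (10 × mean non-bonded k at 3.5 Å):
        if the exact bin is empty/culled the nearest populated bin is used,
        so the rule stays total even when excluded volume empties the
        shortest bins.
        """
        if self.mode == "sequence_only":
            if d >= self.cutoff:
                return 0.0
            return self.mean_k_at(None)
        edges = self.binning.edges
        order = np.argsort(np.abs(edges + self.binning.width / 2 - d),
                           kind="stable")
        for idx in order:
            m = self.mean_k_at(float(edges[idx]))
            if m > 0:
                return m
        raise DerivationError("table has no populated bins")

    def reference_mean(self) -> float:
        """Mean k over amino-acid pair types at the 6 Å reference bin."""
        if self.mode == "sequence_only":
            return self.mean_k_at(None)
        left = self.binning.left_edge(RESCALE_REFERENCE_D)
        if left is None:
            raise DerivationError("6 Å reference distance outside table range")
        return self.mean_k_at(left)


@dataclass
class DerivationConfig:
    """Knobs of the iterative derivation (defaults follow the method)."""

    n0: float = 500.0                # sparse-data pseudo-count
    max_iterations: int = 5
    selection_iteration: int = 5     # iteration whose table is returned
    cull_threshold: float = 1e-3     # kBT/Å², after rescaling
    bootstrap_replicates: int = 100
    ci_level: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.n0 <= 0 or self.max_iterations <= 0 or \
                self.selection_iteration <= 0 or self.cull_threshold < 0 or \
                self.bootstrap_replicates <= 0:
            raise ValueError("derivation config fields must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.selection_iteration > self.max_iterations:
            raise ValueError("selection iteration beyond max_iterations")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "DerivationConfig":
        """Defaults per variant: dENM 5 iterations, sdENM 3, sENM 1."""
        its = {"distance_only": 5, "sequence_only": 1,
               "sequence_distance": 3}[mode]
        kwargs = dict(max_iterations=its, selection_iteration=its)
        kwargs.update(overrides)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Table construction and elementary updates
# ---------------------------------------------------------------------------

def _nearest_populated(profile: StiffnessProfile, left: float) -> float:
    """ALL-row variance at ``left``, falling back to the nearest ALL bin."""
    if (ALL_TYPES, left) in profile.mean_var:
        return profile.mean_var[(ALL_TYPES, left)]
    bins = profile.all_bins()
    if not bins:
        raise DerivationError("profile has no populated ALL bins")
    nearest = min(bins, key=lambda b: abs(b - left))
    return profile.mean_var[(ALL_TYPES, nearest)]


def _pooled_pair_variances(profile: StiffnessProfile, cutoff: float,
                           n0: float, pair_types) -> dict:
    """Per-pair-type variances pooled over bins below ``cutoff``, blended."""
    pooled_w: dict = {}
    pooled_v: dict = {}
    for (pair, left), w in profile.counts.items():
        if left >= cutoff:
            continue
        pooled_w[pair] = pooled_w.get(pair, 0.0) + w
        pooled_v[pair] = pooled_v.get(pair, 0.0) + \
            w * profile.mean_var[(pair, left)]
    if ALL_TYPES not in pooled_w:
        raise DerivationError("no pairs below the cutoff to pool")
    v_all = pooled_v[ALL_TYPES] / pooled_w[ALL_TYPES]
    out = {ALL_TYPES: v_all}
    for pair in pair_types:
        n_aa = pooled_w.get(pair, 0.0)
        v_aa = pooled_v.get(pair, 0.0) / n_aa if n_aa else 0.0
        out[pair] = (n_aa * v_aa + n0 * v_all) / (n_aa + n0)
    return out


def initialize_table(exp_profile: StiffnessProfile, mode: str,
                     binning: DistanceBinning | None = None,
                     aa_types=AA_ALPHABET, cutoff: float | None = None,
                     denm_table: SpringTable | None = None,
                     n0: float = 500.0) -> SpringTable:
    """Initial spring table from the experimental stiffness profile.

    ``distance_only`` / ``sequence_only`` start from the (sparse-corrected)
    experimental apparent stiffness; ``sequence_distance`` replicates a
    supplied dENM curve over all amino-acid pair types.  The returned table
    is rescaled to the 6 Å reference.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if binning is None:
        binning = DistanceBinning(width=0.5, d_min=3.0, d_max=15.0)
    kBT = exp_profile.kBT if exp_profile is not None else 1.0
    k: dict = {}

    if mode == "sequence_distance":
        if denm_table is None:
            raise DerivationError(
                "sequence_distance initialisation requires a dENM table "
                "(per-type constants start from the final dENM curve)")
        binning = denm_table.binning
        for left in binning.edges:
            base = denm_table.k.get((ALL_TYPES, float(left)), 0.0)
            for pair in _all_pairs(aa_types):
                k[(pair, float(left))] = base
        table = SpringTable(mode=mode, binning=binning,
                            aa_types=tuple(aa_types), k=k)
        return rescale_table(table)

    if not exp_profile.mean_var:
        raise DerivationError("empty experimental profile")

    if mode == "distance_only":
        for left in binning.edges:
            v = _nearest_populated(exp_profile, float(left))
            k[(ALL_TYPES, float(left))] = kBT / v
        table = SpringTable(mode=mode, binning=binning,
                            aa_types=tuple(aa_types), k=k)
    else:  # sequence_only
        if cutoff is None:
            raise DerivationError("sequence_only mode requires a cutoff")
        pooled = _pooled_pair_variances(exp_profile, cutoff, n0,
                                        _all_pairs(aa_types))
        for pair in _all_pairs(aa_types):
            k[(pair, None)] = kBT / pooled[pair]
        table = SpringTable(mode=mode, binning=binning,
                            aa_types=tuple(aa_types), k=k, cutoff=cutoff)
    return rescale_table(table)


def _corrected_variance(profile: StiffnessProfile, key) -> float | None:
    if profile.corrected_var is not None and key in profile.corrected_var:
        return profile.corrected_var[key]
    if key[0] == ALL_TYPES and key in profile.mean_var:
        return profile.mean_var[key]
    return None


def update_table(table: SpringTable, k_exp: StiffnessProfile,
                 k_pred: StiffnessProfile) -> SpringTable:
    """One multiplicative confrontation step, k ← k · k_exp / k_pred.

    Both profiles must be on the table's binning and sparse-corrected with
    the same pseudo-count.  Culled entries stay 0; entries missing from
    either profile are left unchanged.
    """
    new_k = dict(table.k)
    if table.mode == "sequence_only":
        pairs = table.pair_keys()
        ve = _pooled_pair_variances(k_exp, table.cutoff,
                                    k_exp.n0 or 500.0, pairs)
        vp = _pooled_pair_variances(k_pred, table.cutoff,
                                    k_pred.n0 or 500.0, pairs)
        for pair in pairs:
            key = (pair, None)
            if key in table.culled:
                continue
            _apply_ratio(new_k, key, ve.get(pair), vp.get(pair))
    else:
        for key in table.entry_keys():
            if key in table.culled or key not in new_k:
                continue
            pkey = key if table.mode == "sequence_distance" \
                else (ALL_TYPES, key[1])
            _apply_ratio(new_k, key, _corrected_variance(k_exp, pkey),
                         _corrected_variance(k_pred, pkey))
    return replace(table, k=new_k, culled=set(table.culled), ci=dict(table.ci))


def _apply_ratio(new_k: dict, key, v_exp, v_pred) -> None:
    if v_exp is None or v_pred is None:
        return                      # missing data: entry unchanged
    if not v_exp > 0:
        raise DerivationError(f"experimental variance <= 0 for entry {key}: "
                              "predicted stiffness ratio undefined")
    if not v_pred > 0:
        # k_pred would be infinite; the symmetric failure (k_pred = 0 with
        # k_exp > 0) appears as a non-finite ratio and is equally fatal
        raise DerivationError(f"predicted variance <= 0 for entry {key}")
    ratio = v_pred / v_exp           # = k_exp / k_pred
    if not math.isfinite(ratio):
        raise DerivationError(f"non-finite stiffness ratio for entry {key}")
    new_k[key] = new_k[key] * ratio


def rescale_table(table: SpringTable) -> SpringTable:
    """Normalise so the mean k over types in the 6 Å reference bin is 1."""
    ref = table.reference_mean()
    if not ref > 0:
        raise DerivationError("reference bin entirely culled or zero; "
                              "cannot rescale")
    factor = 1.0 / ref
    new_k = {key: v * factor for key, v in table.k.items()}
    new_ci = {key: (lo * factor, hi * factor)
              for key, (lo, hi) in table.ci.items()}
    return replace(table, k=new_k, ci=new_ci, culled=set(table.culled))


def cull_weak(table: SpringTable, threshold: float) -> SpringTable:
    """Zero and permanently flag entries with k < threshold (post-rescale)."""
    new_k = dict(table.k)
    culled = set(table.culled)
    for key, v in table.k.items():
        if key in culled:
            new_k[key] = 0.0
            continue
        if v < threshold:
            new_k[key] = 0.0
            culled.add(key)
    return replace(table, k=new_k, culled=culled, ci=dict(table.ci))


# ---------------------------------------------------------------------------
# The full iterative loop
# ---------------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    table: SpringTable
    mean_abs_log_change: float
    n_proteins: int
    n_skipped: int


@dataclass
class DerivationResult:
    table: SpringTable               # at the selection iteration
    history: list                    # list[IterationRecord]
    mode: str
    config: DerivationConfig


@dataclass
class _PreppedProtein:
    ens: ConformerEnsemble           # superposed
    rep_index: int
    rep: Structure
    msrf_exp: np.ndarray
    pairs: np.ndarray                # (M, 2) non-bonded, within table range
    d0: np.ndarray
    var_exp: np.ndarray
    bin_left: np.ndarray             # left edges (float), aligned with pairs
    aa_keys: list
    mean_dist: np.ndarray | None = None   # N x N ensemble-mean distances
    var_pred: np.ndarray | None = None


def _prepare(dataset, binning: DistanceBinning) -> list[_PreppedProtein]:
    prepped = []
    for ens in dataset:
        sup = ens if ens.superposed else superpose_ensemble(ens)
        rep_index = select_representative(sup)
        rep = sup.model(rep_index)
        msrf_exp = mean_square_residue_fluctuation(sup)
        stats = compute_pair_statistics(sup, rep_index=rep_index,
                                        include_uncorrelated=False,
                                        d_max=binning.d_max)
        usable = [p for p in stats if not p.bonded
                  and binning.left_edge(p.d0) is not None]
        # ensemble-mean distances: springs are assigned by the same
        # discretised equilibrium distance that bins the profiles
        mean_dist = np.linalg.norm(
            sup.coords[:, :, None, :] - sup.coords[:, None, :, :],
            axis=3).mean(axis=0)
        prepped.append(_PreppedProtein(
            ens=sup, rep_index=rep_index, rep=rep, msrf_exp=msrf_exp,
            pairs=np.array([[p.i, p.j] for p in usable], dtype=int),
            d0=np.array([p.d0 for p in usable]),
            var_exp=np.array([p.var_exp for p in usable]),
            bin_left=np.array([binning.left_edge(p.d0) for p in usable]),
            aa_keys=[p.aa_pair for p in usable], mean_dist=mean_dist))
    return prepped


def _profile_from_arrays(prepped, which: str, binning: DistanceBinning,
                         kBT: float, skip: set) -> StiffnessProfile:
    wsum: dict = {}
    vsum: dict = {}
    for idx, p in enumerate(prepped):
        if idx in skip:
            continue
        var = p.var_exp if which == "exp" else p.var_pred
        w = float(p.ens.n_models)
        for aa, left, v in zip(p.aa_keys, p.bin_left, var):
            if not np.isfinite(v):
                continue
            for key in ((aa, float(left)), (ALL_TYPES, float(left))):
                wsum[key] = wsum.get(key, 0.0) + w
                vsum[key] = vsum.get(key, 0.0) + w * v
    if not wsum:
        raise DerivationError("no usable pairs in dataset")
    mean_var = {key: vsum[key] / wsum[key] for key in wsum}
    return StiffnessProfile(binning=binning, kBT=kBT, counts=wsum,
                            mean_var=mean_var)


def _drop_sparse_bins(profile: StiffnessProfile, floor: float) -> StiffnessProfile:
    """Remove bins whose type-agnostic evidence is below ``floor``.

    A bin with only a handful of weighted occurrences (N₀ is "the number
    of occurrences needed to obtain a relevant estimation") cannot anchor
    even the ALL-row confrontation; entries in such bins are treated as
    unobserved and later mirrored from the nearest supported bin.
    """
    keep_bins = {left for (pair, left), w in profile.counts.items()
                 if pair == ALL_TYPES and w >= floor}
    counts = {key: w for key, w in profile.counts.items()
              if key[1] in keep_bins}
    mean_var = {key: v for key, v in profile.mean_var.items()
                if key[1] in keep_bins}
    return replace(profile, counts=counts, mean_var=mean_var)


def _predict_variances(prepped, table: SpringTable, kBT: float,
                       bonded_factor: float = 10.0) -> set:
    """Attach model-predicted pair variances to each prepped protein.

    Returns the set of protein indices skipped because their network was
    disconnected or degenerate under the current table.
    """
    model = enm.SpringModel(kind="table", table=table,
                            bonded_factor=bonded_factor)
    skip = set()
    for idx, p in enumerate(prepped):
        try:
            net = enm.build_network(p.rep, model, kBT=kBT,
                                    lookup_distances=p.mean_dist)
            h = enm.assemble_hessian(net)
            c = enm.compute_covariance(h, kBT=kBT, coords=p.rep.coords)
        except enm.NetworkError as err:
            logger.warning("skipping %s: %s", p.ens.protein_id, err)
            p.var_pred = np.full(len(p.d0), np.nan)
            skip.add(idx)
            continue
        scale = enm.fit_temperature_scale(enm.msrf_from_covariance(c),
                                          p.msrf_exp)
        p.var_pred = propagated_distance_variances(c * scale, p.rep.coords,
                                                   p.pairs)
    return skip


def run_derivation(dataset, config: DerivationConfig, mode: str,
                   aa_types=AA_ALPHABET,
                   binning: DistanceBinning | None = None,
                   cutoff: float | None = None,
                   denm_table: SpringTable | None = None,
                   initial_table: SpringTable | None = None,
                   kBT: float = 1.0) -> DerivationResult:
    """Derive a spring table by iterative stiffness confrontation.

    Each iteration builds a network per protein from the current table,
    fits the temperature factor per protein, confronts the predicted with
    the experimental apparent-stiffness profiles (both sparse-corrected),
    applies the multiplicative update, rescales and culls.  Proteins whose
    network degenerates under the current table are skipped with a logged
    warning; a derivation skipping more than 10 % of proteins aborts.

    ``initial_table`` bypasses profile-based initialisation (used, e.g.,
    for fixed-point analyses starting from a known ground-truth table).
    """
    if not dataset:
        raise DerivationError("empty dataset")
    if binning is None:
        binning = initial_table.binning if initial_table is not None else \
            DistanceBinning(width=0.5, d_min=3.0, d_max=15.0)

    prepped = _prepare(dataset, binning)
    exp_profile = _drop_sparse_bins(
        _profile_from_arrays(prepped, "exp", binning, kBT, set()), config.n0)
    populated = {float(left) for left in exp_profile.all_bins()}
    pair_types = _all_pairs(aa_types)
    exp_corr = sparse_corrected_stiffness(exp_profile, config.n0, pair_types)

    if initial_table is not None:
        table = initial_table
    else:
        table = initialize_table(exp_corr, mode, binning=binning,
                                 aa_types=aa_types, cutoff=cutoff,
                                 denm_table=denm_table, n0=config.n0)

    history: list[IterationRecord] = []
    for it in range(1, config.max_iterations + 1):
        skip = _predict_variances(prepped, table, kBT)
        if len(skip) > 0.10 * len(prepped):
            raise DerivationError(
                f"iteration {it}: {len(skip)}/{len(prepped)} proteins "
                "skipped (>10%); aborting derivation")
        pred_profile = _drop_sparse_bins(
            _profile_from_arrays(prepped, "pred", binning, kBT, skip),
            config.n0)
        pred_corr = sparse_corrected_stiffness(pred_profile, config.n0,
                                               pair_types)
        exp_it = exp_corr if not skip else sparse_corrected_stiffness(
            _drop_sparse_bins(
                _profile_from_arrays(prepped, "exp", binning, kBT, skip),
                config.n0), config.n0, pair_types)
        new_table = cull_weak(rescale_table(_refresh_unobserved(
            update_table(table, exp_it, pred_corr), populated)),
            config.cull_threshold)
        change = _mean_abs_log_change(table, new_table)
        table = new_table
        history.append(IterationRecord(it, table, change, len(prepped),
                                       len(skip)))

    selected = history[config.selection_iteration - 1].table
    return DerivationResult(table=selected, history=history, mode=mode,
                            config=config)


def _refresh_unobserved(table: SpringTable, populated: set) -> SpringTable:
    """Mirror data-empty bins from the nearest populated bin of each row.

    Bins never observed in the dataset (e.g. below the excluded-volume
    distance) cannot be confronted with data; leaving them frozen at their
    initial value would let the bonded-spring rule (mean k near 3.5 Å) lag
    arbitrarily far behind the refined short-range constants.
    """
    if table.mode == "sequence_only" or not populated:
        return table
    pops = sorted(populated)
    new_k = dict(table.k)
    for pair in table.pair_keys():
        for left in table.binning.edges:
            left = float(left)
            if left in populated:
                continue
            key = (pair, left)
            if key in table.culled:
                continue
            nearest = min(pops, key=lambda b: abs(b - left))
            new_k[key] = new_k.get((pair, nearest), 0.0)
    return replace(table, k=new_k, culled=set(table.culled),
                   ci=dict(table.ci))


def _mean_abs_log_change(old: SpringTable, new: SpringTable) -> float:
    logs = [abs(math.log(new.k[key] / old.k[key]))
            for key in old.k
            if old.k.get(key, 0) > 0 and new.k.get(key, 0) > 0]
    return float(np.mean(logs)) if logs else 0.0


def bootstrap_confidence(dataset, config: DerivationConfig, mode: str,
                         **kwargs) -> SpringTable:
    """Bootstrap CIs for every table entry by resampling proteins.

    Replicate datasets of the original size are drawn with replacement;
    the full derivation is rerun per replicate (restarting from the
    standard initialisation) and the empirical level quantiles of each
    entry across replicates give the confidence interval.  Deterministic
    for a fixed seed; failed replicates are logged and excluded.
    """
    point = run_derivation(dataset, config, mode, **kwargs)
    rng = np.random.default_rng(config.seed)
    samples: dict = {key: [] for key in point.table.k}
    n_ok = 0
    for rep in range(config.bootstrap_replicates):
        idx = rng.integers(0, len(dataset), size=len(dataset))
        resample = [dataset[i] for i in idx]
        try:
            result = run_derivation(resample, config, mode, **kwargs)
        except DerivationError as err:
            logger.warning("bootstrap replicate %d failed: %s", rep, err)
            continue
        n_ok += 1
        for key in samples:
            samples[key].append(result.table.k.get(key, 0.0))
    if n_ok == 0:
        raise DerivationError("all bootstrap replicates failed")
    lo_q = 100.0 * (1.0 - config.ci_level) / 2.0
    hi_q = 100.0 - lo_q
    ci = {key: (float(np.percentile(vals, lo_q)),
                float(np.percentile(vals, hi_q)))
          for key, vals in samples.items() if vals}
    return replace(point.table, ci=ci, n_bootstrap=n_ok)


# ---------------------------------------------------------------------------
# Table file format (TSV)
# ---------------------------------------------------------------------------

def write_spring_table(table: SpringTable, path,
                       header_comments: list[str] | None = None) -> None:
    """TSV with a mode header; rows aa1 aa2 bin_left bin_right k culled ci."""
    import pandas as pd

    rows = []
    for key in table.entry_keys():
        pair, left = key
        if key not in table.k:
            continue
        lo, hi = table.ci.get(key, (math.nan, math.nan))
        if left is None:
            bl, br = 0.0, table.cutoff
        else:
            bl, br = left, round(left + table.binning.width, 6)
        rows.append({"aa1": pair[0], "aa2": pair[1], "bin_left": bl,
                     "bin_right": br, "k": table.k[key],
                     "culled": int(key in table.culled),
                     "ci_low": lo, "ci_high": hi})
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# mode: {table.mode}\n")
        fh.write(f"# binning: width={table.binning.width} "
                 f"d_min={table.binning.d_min} d_max={table.binning.d_max}\n")
        if table.cutoff is not None:
            fh.write(f"# cutoff: {table.cutoff}\n")
        fh.write(f"# aa_types: {''.join(table.aa_types)}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_spring_table(path) -> SpringTable:
    """Read a spring table written by :func:`write_spring_table`."""
    import pandas as pd

    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if ":" in text:
                tag, _, value = text.partition(":")
                meta[tag.strip()] = value.strip()
    mode = meta.get("mode")
    if mode not in MODES:
        raise ValueError(f"{path}: missing or invalid mode header")
    bin_kv = dict(item.split("=") for item in meta["binning"].split())
    binning = DistanceBinning(width=float(bin_kv["width"]),
                              d_min=float(bin_kv["d_min"]),
                              d_max=float(bin_kv["d_max"]))
    cutoff = float(meta["cutoff"]) if "cutoff" in meta else None
    aa_types = tuple(meta.get("aa_types", "".join(AA_ALPHABET)))

    frame = pd.read_csv(path, sep="\t", comment="#",
                        dtype={"aa1": str, "aa2": str})
    k, culled, ci = {}, set(), {}
    for row in frame.itertuples(index=False):
        pair = aa_pair_key(row.aa1, row.aa2)
        left = None if mode == "sequence_only" else float(row.bin_left)
        key = (pair, left)
        k[key] = float(row.k)
        if int(row.culled):
            culled.add(key)
        if math.isfinite(row.ci_low) and math.isfinite(row.ci_high):
            ci[key] = (float(row.ci_low), float(row.ci_high))
    return SpringTable(mode=mode, binning=binning, aa_types=aa_types,
                       k=k, culled=culled, ci=ci, cutoff=cutoff)
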
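"""Scoring of ENM variants against conformational ensembles.

Two complementary measures are used.  The classic one, r_B, is the Pearson
correlation between predicted and experimental per-residue mean-square
fluctuations (MSRF, proportional to crystallographic B-factors).  Because
MSRF say nothing about cooperativity, the pairwise error

    ε_σ = (1/N_pairs) Σ_(i<j, non-bonded) min(1, |σ_pred − σ_exp| / σ_unc)

is also computed, where σ are standard deviations of inter-residue
distances and the normalisation by the decorrelated expectation σ_unc makes
every pair's contribution commensurate instead of letting highly flexible
regions dominate.  Per-pair signed deviations are clamped to ±1 (±100 %).
ε_σ is reported whole and split by equilibrium separation into short
(0–15 Å), mid (15–30 Å) and long (> 30 Å) range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .ensemble_io import (ConformerEnsemble, superpose_ensemble,
                          select_representative,
                          mean_square_residue_fluctuation)
from . import enm
from .fluctuations import compute_pair_statistics

__all__ = [
    "RANGES",
    "ProteinScore",
    "EvaluationReport",
    "pearson_msrf",
    "epsilon_sigma",
    "evaluate_variant",
    "write_report",
]

#: Equilibrium-distance ranges (Å) for the ε_σ decomposition.
RANGES = (("short", 0.0, 15.0), ("mid", 15.0, 30.0), ("long", 30.0, math.inf))


def pearson_msrf(exp_msrf, pred_msrf) -> float:
    """Pearson correlation r_B between experimental and predicted MSRF.

    Returns NaN (missing) when either side has zero variance.
    """
    exp = np.asarray(exp_msrf, dtype=float)
    pred = np.asarray(pred_msrf, dtype=float)
    if exp.shape != pred.shape or exp.ndim != 1:
        raise ValueError("MSRF vectors must share one length")
    if len(exp) < 3:
        raise ValueError("need at least 3 residues for a correlation")
    if np.ptp(exp) == 0 or np.ptp(pred) == 0:
        return math.nan
    return float(scipy.stats.pearsonr(exp, pred).statistic)


def epsilon_sigma(pairs, d_range: tuple[float, float] | None = None,
                  clamp: bool = True) -> float:
    """Mean normalised error on predicted distance fluctuations.

    Only non-bonded pairs with a positive decorrelated normalisation enter;
    ``d_range`` restricts to pairs whose equilibrium distance d0 falls in
    [low, high).  Returns NaN when the range holds no pairs.
    """
    terms = _epsilon_terms(pairs, d_range, clamp, signed=False)
    return float(np.mean(terms)) if len(terms) else math.nan


def epsilon_sigma_terms(pairs, d_range=None, clamp: bool = True) -> np.ndarray:
    """Per-pair signed deviations (σ_pred − σ_exp)/σ_unc, clamped to ±1."""
    return _epsilon_terms(pairs, d_range, clamp, signed=True)


def _epsilon_terms(pairs, d_range, clamp, signed) -> np.ndarray:
    out = []
    for p in pairs:
        if p.bonded:
            continue
        if not (np.isfinite(p.var_pred) and np.isfinite(p.var_exp)
                and np.isfinite(p.var_unc)):
            continue
        if p.var_unc <= 0:
            continue
        if d_range is not None and not (d_range[0] <= p.d0 < d_range[1]):
            continue
        dev = (math.sqrt(max(p.var_pred, 0.0))
               - math.sqrt(max(p.var_exp, 0.0))) / math.sqrt(p.var_unc)
        if clamp:
            dev = max(-1.0, min(1.0, dev))
        out.append(dev if signed else abs(dev))
    return np.asarray(out)


@dataclass
class ProteinScore:
    protein_id: str
    n_residues: int
    r_b: float
    eps_sigma: float
    eps_by_range: dict          # name -> value (NaN when range empty)
    pairs_by_range: dict        # name -> pair count
    n_pairs: int


@dataclass
class EvaluationReport:
    per_protein: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)    # protein_id -> reason

    @property
    def aggregate(self) -> dict:
        """Unweighted means over proteins (NaN-skipping)."""
        if not self.per_protein:
            return {}
        def nmean(values):
            arr = np.asarray(values, dtype=float)
            ok = np.isfinite(arr)
            return float(arr[ok].mean()) if ok.any() else math.nan

        agg = {
            "r_b": nmean([s.r_b for s in self.per_protein]),
            "eps_sigma": nmean([s.eps_sigma for s in self.per_protein]),
            "n_proteins": len(self.per_protein),
            "n_failed": len(self.failures),
        }
        for name, _, _ in RANGES:
            agg[f"eps_sigma_{name}"] = nmean(
                [s.eps_by_range[name] for s in self.per_protein])
        return agg


def evaluate_variant(dataset, model: enm.SpringModel, kBT: float = 1.0,
                     clamp: bool = True,
                     max_pair_distance: float | None = None) -> EvaluationReport:
    """Score a spring model on every ensemble of a dataset.

    Per protein: build the network from the representative structure,
    compute the model covariance, fit the temperature factor to the
    experimental MSRF, then score r_B and ε_σ (whole and by range).
    Proteins that fail (disconnected network, degenerate modes) are logged
    in the report and excluded from the aggregate.  Deterministic.
    """
    report = EvaluationReport()
    for ens in dataset:
        sup = ens if ens.superposed else superpose_ensemble(ens)
        try:
            score = _score_protein(sup, model, kBT, clamp, max_pair_distance)
        except (enm.NetworkError, ValueError) as err:
            report.failures[sup.protein_id] = str(err)
            continue
        report.per_protein.append(score)
    return report


def _score_protein(sup: ConformerEnsemble, model: enm.SpringModel,
                   kBT: float, clamp: bool,
                   max_pair_distance: float | None) -> ProteinScore:
    rep_index = select_representative(sup)
    rep = sup.model(rep_index)
    net = enm.build_network(rep, model, max_pair_distance=max_pair_distance,
                            kBT=kBT)
    h = enm.assemble_hessian(net)
    c = enm.compute_covariance(h, kBT=kBT, coords=rep.coords)
    msrf_pred = enm.msrf_from_covariance(c)
    msrf_exp = mean_square_residue_fluctuation(sup)
    scale = enm.fit_temperature_scale(msrf_pred, msrf_exp)
    stats = compute_pair_statistics(sup, rep_index=rep_index,
                                    model_covariance=c * scale,
                                    include_uncorrelated=True)
    r_b = pearson_msrf(msrf_exp, scale * msrf_pred)
    eps_by_range, pairs_by_range = {}, {}
    for name, lo, hi in RANGES:
        eps_by_range[name] = epsilon_sigma(stats, (lo, hi), clamp)
        pairs_by_range[name] = sum(
            1 for p in stats if not p.bonded and lo <= p.d0 < hi)
    return ProteinScore(
        protein_id=sup.protein_id, n_residues=sup.n_residues, r_b=r_b,
        eps_sigma=epsilon_sigma(stats, None, clamp),
        eps_by_range=eps_by_range, pairs_by_range=pairs_by_range,
        n_pairs=sum(1 for p in stats if not p.bonded))


def write_report(report: EvaluationReport, tsv_path=None, json_path=None,
                 header_comments: list[str] | None = None) -> None:
    """Write per-protein rows plus an AGGREGATE row (TSV), and/or JSON."""
    import pandas as pd

    rows = []
    for s in report.per_protein:
        row = {"protein_id": s.protein_id, "n_residues": s.n_residues,
               "r_b": s.r_b, "eps_sigma": s.eps_sigma, "n_pairs": s.n_pairs}
        for name, _, _ in RANGES:
            row[f"eps_sigma_{name}"] = s.eps_by_range[name]
            row[f"n_pairs_{name}"] = s.pairs_by_range[name]
        rows.append(row)
    agg = report.aggregate
    if tsv_path is not None:
        arow = {"protein_id": "AGGREGATE", "n_residues": "",
                "r_b": agg.get("r_b", math.nan),
                "eps_sigma": agg.get("eps_sigma", math.nan),
                "n_pairs": sum(s.n_pairs for s in report.per_protein)}
        for name, _, _ in RANGES:
            arow[f"eps_sigma_{name}"] = agg.get(f"eps_sigma_{name}", math.nan)
            arow[f"n_pairs_{name}"] = sum(s.pairs_by_range[name]
                                          for s in report.per_protein)
        frame = pd.DataFrame(rows + [arow])
        with open(tsv_path, "w") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        payload = {"aggregate": agg, "per_protein": rows,
                   "failures": report.failures}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
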
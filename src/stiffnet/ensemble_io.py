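"""Reading, validation and preprocessing of multi-model structural ensembles.

Solution-NMR depositions provide a protein as an ensemble of models sharing
one residue numbering.  This module reduces such an ensemble to a Cα trace
per model (:class:`ConformerEnsemble`), superposes the models onto their
mean structure, selects a representative model, trims unfolded terminal
tails, and applies the local quality filters (model count, chain length,
chain breaks) used to admit an ensemble into an analysis dataset.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.transform import Rotation

__all__ = [
    "ResidueLabel",
    "ConformerEnsemble",
    "Structure",
    "ValidationResult",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "superpose_ensemble",
    "select_representative",
    "mean_square_residue_fluctuation",
    "trim_flexible_tails",
    "validate_ensemble",
]

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_1TO3 = {v: k for k, v in _3TO1.items()}
_1TO3["X"] = "UNK"


class EnsembleError(ValueError):
    """Raised when an ensemble violates a structural requirement."""


class ResidueLabel(NamedTuple):
    res_id: int
    aa: str  # one-letter code, 'X' for non-standard
    chain: str


def _check_residues_coords(residues, coords, n_models):
    n = len(residues)
    if n < 2:
        raise EnsembleError(f"need at least 2 residues, got {n}")
    if coords.shape != (n_models, n, 3):
        raise EnsembleError(
            f"coords shape {coords.shape} does not match "
            f"{n_models} models x {n} residues"
        )
    if not np.all(np.isfinite(coords)):
        raise EnsembleError("non-finite coordinates")


@dataclass
class ConformerEnsemble:
    """Aligned multi-model Cα coordinate set with residue labels.

    ``coords`` has shape (n_models, N, 3) in Å.  ``superposed`` is True once
    every model has been rigidly fitted to the ensemble mean structure.
    """

    protein_id: str
    residues: list[ResidueLabel]
    coords: np.ndarray
    superposed: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise EnsembleError("coords must be a (n_models, N, 3) array")
        _check_residues_coords(self.residues, self.coords, self.coords.shape[0])

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def mean_coords(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def model(self, index: int) -> "Structure":
        return Structure(list(self.residues), self.coords[index].copy())


@dataclass
class Structure:
    """Single-model Cα trace (the representative / equilibrium structure)."""

    residues: list[ResidueLabel]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        _check_residues_coords(self.residues, self.coords[None], 1)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path, chain: str | None = None,
                        protein_id: str | None = None) -> ConformerEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a :class:`ConformerEnsemble`.

    One polymer chain is considered: ``chain`` if given, else chain A when
    present, else the first chain.  Every model must provide one Cα per
    residue, and all models must agree on the residue list; ensembles whose
    models differ in residue count are rejected outright.  Altloc
    duplicates resolve to the first/highest-occupancy conformer (Biopython's
    default); hydrogens and heteroatoms are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if protein_id is None:
        protein_id = path.stem
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(protein_id, str(path))
    models = list(structure)
    if not models:
        raise EnsembleError(f"{path}: no models found")

    chain_ids = [c.id for c in models[0]]
    if not chain_ids:
        raise EnsembleError(f"{path}: no chains in first model")
    if chain is None:
        chain = "A" if "A" in chain_ids else chain_ids[0]

    all_labels: list[list[ResidueLabel]] = []
    all_coords: list[np.ndarray] = []
    for model in models:
        if chain not in [c.id for c in model]:
            raise EnsembleError(f"{path}: model {model.id} lacks chain {chain}")
        labels, xyz = [], []
        for res in model[chain]:
            if res.id[0] != " ":  # skip heteroatoms and waters
                continue
            if "CA" not in res:
                raise EnsembleError(
                    f"{path}: model {model.id} residue {res.resname}{res.id[1]} "
                    f"has no CA atom"
                )
            labels.append(ResidueLabel(res.id[1],
                                       _3TO1.get(res.resname.upper(), "X"),
                                       chain))
            xyz.append(res["CA"].coord)
        all_labels.append(labels)
        all_coords.append(np.asarray(xyz, dtype=float))

    n0 = len(all_labels[0])
    for m, labels in enumerate(all_labels):
        if len(labels) != n0:
            raise EnsembleError(
                f"{path}: model {models[m].id} has {len(labels)} residues, "
                f"model {models[0].id} has {n0}; differing residue counts "
                f"between models"
            )
        if labels != all_labels[0]:
            raise EnsembleError(
                f"{path}: residue labels differ between models "
                f"{models[0].id} and {models[m].id}"
            )

    return ConformerEnsemble(protein_id, all_labels[0],
                             np.stack(all_coords), superposed=False)


def write_multimodel_pdb(ens: ConformerEnsemble, path) -> None:
    """Write a Cα-only multi-MODEL PDB file (fixed-width ATOM records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    n = ens.n_residues
    stack = struc.AtomArrayStack(ens.n_models, n)
    stack.coord = ens.coords.astype(np.float32)
    stack.chain_id = np.array([r.chain for r in ens.residues])
    stack.res_id = np.array([r.res_id for r in ens.residues])
    stack.res_name = np.array([_1TO3.get(r.aa, "UNK") for r in ens.residues])
    stack.atom_name = np.array(["CA"] * n)
    stack.element = np.array(["C"] * n)
    stack.hetero = np.array([False] * n)
    pdb = PDBFile()
    pdb.set_structure(stack)
    if ens.n_models == 1:
        # biotite drops the MODEL wrapper for a single model; keep the
        # multi-model framing so ensemble files are uniform.
        pdb.lines = ["MODEL        1"] + pdb.lines + ["ENDMDL"]
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and representative selection
# ---------------------------------------------------------------------------

def _fit_to(model: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body fit of ``model`` onto ``target`` (Kabsch)."""
    cm = model.mean(axis=0)
    ct = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, model - cm)
    return rot.apply(model - cm) + ct


def superpose_ensemble(ens: ConformerEnsemble, tol: float = 1e-9,
                       max_iter: int = 500) -> ConformerEnsemble:
    """Iteratively superpose all models onto the evolving mean structure.

    Each round fits every model to the current mean by optimal rotation and
    translation, then recomputes the mean; iteration stops once the mean
    shifts by less than ``tol`` Å (RMS).  The tight default keeps the
    operation idempotent to better than 1e-8 Å per coordinate.
    """
    coords = ens.coords.astype(float).copy()
    # seed from model 0 for raw ensembles (models may be arbitrarily
    # oriented); from the current mean when already aligned, which makes
    # the operation exactly idempotent
    mean = coords.mean(axis=0) if ens.superposed else coords[0].copy()
    centered = mean - mean.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise EnsembleError("degenerate (collinear) coordinates; "
                            "superposition is ill-defined")
    for _ in range(max_iter):
        for m in range(coords.shape[0]):
            coords[m] = _fit_to(coords[m], mean)
        new_mean = coords.mean(axis=0)
        shift = math.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return ConformerEnsemble(ens.protein_id, list(ens.residues), coords,
                             superposed=True)


def _rmsd_to_mean(ens: ConformerEnsemble) -> np.ndarray:
    mean = ens.mean_coords()
    return np.sqrt(np.mean(np.sum((ens.coords - mean) ** 2, axis=2), axis=1))


def select_representative(ens: ConformerEnsemble) -> int:
    """Index of the model with lowest RMSD to the mean structure.

    Ties break to the lowest index.  The ensemble must be superposed, else
    rigid-body offsets would contaminate the RMSD.
    """
    if not ens.superposed:
        raise EnsembleError("ensemble must be superposed before "
                            "representative selection")
    return int(np.argmin(_rmsd_to_mean(ens)))


def mean_square_residue_fluctuation(ens: ConformerEnsemble) -> np.ndarray:
    """Per-residue mean-square fluctuation about the ensemble mean (Å²)."""
    if not ens.superposed:
        raise EnsembleError("MSRF requires a superposed ensemble")
    mean = ens.mean_coords()
    return np.mean(np.sum((ens.coords - mean) ** 2, axis=2), axis=0)


# ---------------------------------------------------------------------------
# Tail trimming and validation
# ---------------------------------------------------------------------------

def trim_flexible_tails(ens: ConformerEnsemble, msrf: Sequence[float],
                        factor: float = 2.0) -> ConformerEnsemble:
    """Remove unfolded terminal tails flagged by high residue fluctuations.

    A residue is flagged when its MSRF exceeds ``factor`` times the mean
    MSRF over all residues (single pass: the mean is computed once, before
    any removal).  Only the maximal contiguous flagged runs at the N- and
    C-terminus are removed; flexible interior residues are never touched.
    """
    msrf = np.asarray(msrf, dtype=float)
    if msrf.shape != (ens.n_residues,):
        raise EnsembleError("msrf length must equal residue count")
    threshold = factor * msrf.mean()
    flagged = msrf > threshold
    start = 0
    while start < ens.n_residues and flagged[start]:
        start += 1
    end = ens.n_residues
    while end > start and flagged[end - 1]:
        end -= 1
    if end - start < 2:
        raise EnsembleError("tail trimming would leave fewer than 2 residues")
    if start == 0 and end == ens.n_residues:
        return ens
    return ConformerEnsemble(ens.protein_id, list(ens.residues[start:end]),
                             ens.coords[:, start:end].copy(),
                             superposed=ens.superposed)


@dataclass
class ValidationResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_ensemble(ens: ConformerEnsemble, min_models: int = 20,
                      min_residues: int = 50,
                      break_cutoff: float = 4.5) -> ValidationResult:
    """Check the local admission filters for an analysis dataset.

    Fails when the ensemble has too few models, too few residues, or a
    chain break — a consecutive-residue Cα–Cα distance above
    ``break_cutoff`` Å in the representative model (~3.8 Å is the trans
    peptide spacing; 4.5 Å tolerates cis peptides and strained geometry).
    """
    reasons = []
    if ens.n_models < min_models:
        reasons.append(f"model count {ens.n_models} < {min_models}")
    if ens.n_residues < min_residues:
        reasons.append(f"residue count {ens.n_residues} < {min_residues}")
    sup = ens if ens.superposed else superpose_ensemble(ens)
    rep = sup.coords[select_representative(sup)]
    gaps = np.linalg.norm(np.diff(rep, axis=0), axis=1)
    breaks = np.nonzero(gaps > break_cutoff)[0]
    for b in breaks:
        reasons.append(
            f"chain break: CA-CA distance {gaps[b]:.2f} A between residues "
            f"{ens.residues[b].res_id} and {ens.residues[b + 1].res_id}"
        )
    return ValidationResult(passed=not reasons, reasons=reasons)
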
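"""Quality gating of motif-receptor structure models.

AlphaFold2-style models store the per-residue confidence estimate pLDDT
(0-100) in the B-factor column of the emitted PDB file.  A model of a
motif-receptor complex is trusted only when

* the mean pLDDT over the motif residues exceeds 65 (strictly), and
* the motif-receptor interaction energy (an AnalyseComplex-style number
  supplied as input, kcal/mol) is strictly below -5.

Crystallographic (PDB-source) structures skip the gate: they are accepted a
priori.  The per-residue pLDDT is taken from the alpha-carbon record of each
motif residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrices import SASMatrix, matrix_variant_agreement
from .variants import VariantCall

PLDDT_MIN = 65.0
ENERGY_MAX = -5.0  # kcal/mol

__all__ = [
    "PLDDT_MIN",
    "ENERGY_MAX",
    "StructureModel",
    "ModelVerdict",
    "read_structure_model",
    "read_model_metadata",
    "motif_mean_plddt",
    "gate_model",
    "rank_accepted_models",
]


@dataclass
class StructureModel:
    """One motif-receptor complex model.

    ``plddt`` maps (chain id, residue number) to the per-residue B-factor
    value of the alpha-carbon; for AF2 models this is the pLDDT confidence.
    """

    model_id: str
    source: str  # pdb | af2
    motif_chain: str
    motif_range: tuple[int, int]  # 1-based inclusive residue numbers
    interaction_energy: float  # kcal/mol, precomputed
    plddt: Mapping[tuple[str, int], float]
    motif_class: str = ""
    recycles: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.motif_range
        if lo > hi:
            raise ValueError(f"{self.model_id}: empty motif range {self.motif_range}")


@dataclass(frozen=True)
class ModelVerdict:
    model_id: str
    mean_motif_plddt: float
    interaction_energy: float
    passed_plddt: bool
    passed_energy: bool
    accepted: bool
    agreement: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.accepted != (self.passed_plddt and self.passed_energy):
            raise ValueError("accepted must equal passed_plddt AND passed_energy")


def read_structure_model(
    pdb_path,
    model_id: str,
    source: str,
    motif_chain: str,
    motif_range: tuple[int, int],
    interaction_energy: float,
    motif_class: str = "",
    recycles: int | None = None,
) -> StructureModel:
    """Load a PDB-format model, keeping per-residue C-alpha B-factors."""
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate minimal fixture files
        structure = PDBParser(QUIET=True).get_structure(model_id, str(pdb_path))
    plddt: dict[tuple[str, int], float] = {}
    for chain in structure[0]:
        for residue in chain:
            if "CA" in residue:
                plddt[(chain.id, residue.id[1])] = float(residue["CA"].get_bfactor())
    return StructureModel(
        model_id=model_id,
        source=source,
        motif_chain=motif_chain,
        motif_range=motif_range,
        interaction_energy=interaction_energy,
        plddt=plddt,
        motif_class=motif_class,
        recycles=recycles,
    )


def read_model_metadata(path) -> pd.DataFrame:
    """Model metadata TSV: model_id, motif_class, source, motif_chain,
    motif_start, motif_end, interaction_energy[, recycles]."""
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str, "motif_chain": str})
    required = {
        "model_id",
        "motif_class",
        "source",
        "motif_chain",
        "motif_start",
        "motif_end",
        "interaction_energy",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"model metadata missing columns: {sorted(missing)}")
    return df


def motif_mean_plddt(model: StructureModel) -> float:
    """Mean pLDDT over the motif residues (one value per residue, C-alpha)."""
    lo, hi = model.motif_range
    values = []
    missing = []
    for resnum in range(lo, hi + 1):
        key = (model.motif_chain, resnum)
        if key not in model.plddt:
            missing.append(resnum)
        else:
            values.append(model.plddt[key])
    if missing:
        raise ValueError(
            f"{model.model_id}: motif residues missing from chain "
            f"{model.motif_chain}: {missing}"
        )
    return sum(values) / len(values)


def gate_model(
    model: StructureModel,
    plddt_min: float = PLDDT_MIN,
    energy_max: float = ENERGY_MAX,
) -> ModelVerdict:
    """Accept a model iff mean motif pLDDT > plddt_min and energy < energy_max.

    Both comparisons are strict; a model sitting exactly on either threshold
    is rejected.  PDB-source structures pass unconditionally (the gate
    applies to predicted models).
    """
    if model.source == "pdb":
        try:
            mean = motif_mean_plddt(model)
        except ValueError:
            mean = float("nan")
        return ModelVerdict(
            model.model_id, mean, model.interaction_energy, True, True, True
        )
    mean = motif_mean_plddt(model)
    passed_plddt = mean > plddt_min
    passed_energy = model.interaction_energy < energy_max
    return ModelVerdict(
        model_id=model.model_id,
        mean_motif_plddt=mean,
        interaction_energy=model.interaction_energy,
        passed_plddt=passed_plddt,
        passed_energy=passed_energy,
        accepted=passed_plddt and passed_energy,
    )


def rank_accepted_models(
    verdicts: Sequence[ModelVerdict],
    matrices: Mapping[str, SASMatrix],
    calls: Iterable[tuple[int, VariantCall]] = (),
) -> list[ModelVerdict]:
    """Order accepted models by observed-variant agreement, then energy.

    Each accepted model's tolerance matrix is scored against the observed
    calls; models sort by (agreement accuracy desc, interaction energy asc,
    model_id).  With no testable calls the ordering falls back to the
    interaction energy alone.
    """
    calls = list(calls)
    ranked = []
    for v in verdicts:
        if not v.accepted:
            continue
        agreement = None
        if v.model_id in matrices and calls:
            n_agree, n_tested, _ = matrix_variant_agreement(
                matrices[v.model_id], calls
            )
            agreement = (n_agree, n_tested)
        ranked.append(
            ModelVerdict(
                model_id=v.model_id,
                mean_motif_plddt=v.mean_motif_plddt,
                interaction_energy=v.interaction_energy,
                passed_plddt=v.passed_plddt,
                passed_energy=v.passed_energy,
                accepted=v.accepted,
                agreement=agreement,
            )
        )

    def sort_key(v: ModelVerdict):
        if v.agreement and v.agreement[1]:
            acc = v.agreement[0] / v.agreement[1]
        else:
            acc = -1.0  # fall back to energy ordering
        return (-acc, v.interaction_energy, v.model_id)

    ranked.sort(key=sort_key)
    return ranked
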
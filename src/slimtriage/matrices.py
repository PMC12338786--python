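"""Single-amino-acid-substitution (SAS) matrices for motif classes.

A SAS matrix is a 20 x L table: rows are the alternative amino acids (fixed
alphabetical one-letter order), columns the motif positions (1..L).  Three
evidence layers share this shape:

* ``clinical`` — sums of signed variant confidence scores per cell
  (positive = evidence of intolerance, negative = tolerance);
* ``ddg`` — mean FoldX-style stability free-energy change in kcal/mol
  (positive = destabilizing), averaged over the available structures;
* ``tolerance`` — categorical verdicts derived from the ddg layer by a
  source-specific threshold: 2.1 kcal/mol for crystallographic (PDB)
  structures, 1.6 kcal/mol for AlphaFold2 models.  The comparison is strict:
  a substitution is tolerated iff its ddG is strictly below the threshold.

A fourth layer, ``final_score``, adds the clinical sums to a capped
ddG-derived confidence score and yields per-cell verdicts via a symmetric
cutoff tau.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import AMINO_ACIDS, MotifClass
from .variants import VariantCall

#: Strict upper ddG bounds (kcal/mol) below which a substitution is tolerated.
DDG_THRESHOLDS = {"pdb": 2.1, "af2": 1.6}

TOLERATED = "tolerated"
NON_TOLERATED = "non-tolerated"
UNKNOWN = "unknown"

__all__ = [
    "DDG_THRESHOLDS",
    "TOLERATED",
    "NON_TOLERATED",
    "UNKNOWN",
    "DdGRecord",
    "SASMatrix",
    "parse_positionscan",
    "average_ddg",
    "tolerance_from_ddg",
    "build_clinical_matrix",
    "ddg_confidence_score",
    "final_matrix",
    "final_verdicts",
    "compare_ddg_matrices",
    "matrix_variant_agreement",
]


@dataclass(frozen=True)
class DdGRecord:
    """One substitution's stability change on one structure."""

    position: int  # 1-based motif position
    ref_aa: str
    alt_aa: str
    ddg: float  # kcal/mol
    structure_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise ValueError(f"non-finite ddG at position {self.position}")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class SASMatrix:
    """One evidence layer for one motif class (rows = 20 AAs, cols = 1..L)."""

    motif_class: str
    layer: str  # clinical | ddg | tolerance | final_score
    values: pd.DataFrame
    source: str = "none"  # pdb | af2 | merged | none
    n_structures: int = 0
    reference: str | None = None  # motif-length reference residue string

    def __post_init__(self) -> None:
        if list(self.values.index) != list(AMINO_ACIDS):
            raise ValueError("matrix rows must be the 20 amino acids, alphabetical")
        if self.reference is not None and len(self.reference) != self.values.shape[1]:
            raise ValueError("reference length must equal motif length")

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def cell(self, position: int, alt_aa: str):
        return self.values.at[alt_aa, position]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="alt_aa")

    @classmethod
    def from_tsv(cls, path, motif_class: str, layer: str, **kw) -> "SASMatrix":
        df = pd.read_csv(path, sep="\t", index_col="alt_aa")
        df.columns = [int(c) for c in df.columns]
        df = df.reindex(list(AMINO_ACIDS))
        df.index.name = None
        return cls(motif_class=motif_class, layer=layer, values=df, **kw)


def _empty_frame(length: int, fill=np.nan) -> pd.DataFrame:
    return pd.DataFrame(
        fill, index=list(AMINO_ACIDS), columns=list(range(1, length + 1))
    )


_MUTATION_LABEL = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([A-Za-z])$")


def parse_positionscan(
    path,
    structure_id: str = "",
    motif_start: int | None = None,
) -> list[DdGRecord]:
    """Parse a FoldX PositionScan-style table into ddG records.

    Two dialects are accepted.  The native dialect has lines
    ``<ref><chain><resnum><alt>\t<energy>`` (e.g. ``NA825D\t3.42``); residue
    numbers are mapped to motif positions via *motif_start* (the residue
    number of motif position 1; required for this dialect).  The simplified
    mirror is a TSV with header columns position, ref_aa, alt_aa, ddg.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    if lines[0].split("\t")[0] == "position":  # simplified TSV
        records = []
        for ln in lines[1:]:
            pos, ref, alt, ddg = ln.split("\t")[:4]
            records.append(DdGRecord(int(pos), ref, alt.upper(), float(ddg), structure_id))
        return records
    if motif_start is None:
        raise ValueError("native PositionScan dialect requires motif_start")
    records = []
    for i, ln in enumerate(lines, 1):
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {i}: expected label<TAB>energy")
        m = _MUTATION_LABEL.match(parts[0].strip())
        if not m:
            raise ValueError(f"{path}: line {i}: malformed mutation label {parts[0]!r}")
        ref, _chain, resnum, alt = m.groups()
        records.append(
            DdGRecord(
                position=int(resnum) - motif_start + 1,
                ref_aa=ref,
                alt_aa=alt.upper(),
                ddg=float(parts[1]),
                structure_id=structure_id,
            )
        )
    return records


def average_ddg(
    records_by_structure: Mapping[str, Sequence[DdGRecord]],
    motif_class: str,
    length: int,
    source: str = "pdb",
    reference: str | None = None,
) -> SASMatrix:
    """Cell-wise arithmetic mean of ddG over structures.

    A cell contributes to the mean only from structures that report it;
    cells absent from every structure stay empty (NaN).  Self-substitution
    records (ref == alt) are ignored; the reference row of each column is
    fixed at 0 when *reference* is known.
    """
    sums = _empty_frame(length, 0.0)
    counts = _empty_frame(length, 0)
    for sid, records in records_by_structure.items():
        seen: set[tuple[int, str]] = set()
        for r in records:
            if r.position > length:
                raise ValueError(
                    f"structure {sid}: position {r.position} exceeds motif length {length}"
                )
            if r.ref_aa == r.alt_aa:
                continue
            key = (r.position, r.alt_aa)
            if key in seen:
                raise ValueError(f"structure {sid}: duplicate cell {key}")
            seen.add(key)
            sums.at[r.alt_aa, r.position] += r.ddg
            counts.at[r.alt_aa, r.position] += 1
    values = sums.where(counts > 0) / counts.where(counts > 0)
    if reference is not None:
        for pos, ref in enumerate(reference, 1):
            values.at[ref, pos] = 0.0
    return SASMatrix(
        motif_class=motif_class,
        layer="ddg",
        values=values,
        source=source,
        n_structures=len(records_by_structure),
        reference=reference,
    )


def tolerance_from_ddg(
    matrix: SASMatrix, source: str | None = None, thresholds: Mapping[str, float] = DDG_THRESHOLDS
) -> SASMatrix:
    """Categorical tolerance verdicts from a ddG layer.

    tolerated iff ddG < threshold(source), strictly; empty cells are
    ``unknown``; reference-residue cells are tolerated by construction.
    """
    if matrix.layer != "ddg":
        raise ValueError("tolerance_from_ddg expects a ddg-layer matrix")
    src = source or matrix.source
    if src not in thresholds:
        raise ValueError(f"unknown structure source {src!r}")
    thr = thresholds[src]
    vals = matrix.values
    verdicts = pd.DataFrame(
        np.where(vals.isna(), UNKNOWN, np.where(vals < thr, TOLERATED, NON_TOLERATED)),
        index=vals.index,
        columns=vals.columns,
    )
    if matrix.reference is not None:
        for pos, ref in enumerate(matrix.reference, 1):
            verdicts.at[ref, pos] = TOLERATED
    return SASMatrix(
        motif_class=matrix.motif_class,
        layer="tolerance",
        values=verdicts,
        source=src,
        n_structures=matrix.n_structures,
        reference=matrix.reference,
    )


def build_clinical_matrix(
    calls: Iterable[tuple[int, VariantCall]],
    motif: MotifClass,
) -> SASMatrix:
    """Sum signed variant confidences into a clinical-layer matrix.

    *calls* pairs a 1-based motif position with a classified call; the cell
    (position, alt_aa) accumulates the sum of signed confidences.  Positive
    sums indicate intolerance.  Unresolved calls contribute nothing.
    """
    sums = _empty_frame(motif.length, 0.0)
    touched = _empty_frame(motif.length, False)
    for pos, call in calls:
        if not (1 <= pos <= motif.length):
            raise ValueError(f"call at motif position {pos} outside 1..{motif.length}")
        if call.label == "unresolved":
            continue
        alt = call.evidence.alt_aa
        sums.at[alt, pos] += call.confidence
        touched.at[alt, pos] = True
    values = sums.where(touched)
    return SASMatrix(motif_class=motif.identifier, layer="clinical", values=values)


def ddg_confidence_score(
    ddg: float, source: str, thresholds: Mapping[str, float] = DDG_THRESHOLDS
) -> float:
    """Capped signed score from a ddG value: positive = intolerance.

    Default mapping: clamp((ddG - threshold) / threshold, -1, +1); zero at
    the threshold, +1 at twice the threshold, -1 at ddG = 0 and below.
    """
    thr = thresholds[source]
    return float(np.clip((ddg - thr) / thr, -1.0, 1.0))


def final_matrix(
    clinical: SASMatrix | None,
    ddg: SASMatrix | None,
    source: str | None = None,
    thresholds: Mapping[str, float] = DDG_THRESHOLDS,
    score_fn: Callable[[float, str], float] | None = None,
) -> SASMatrix:
    """Combine clinical sums with ddG confidence scores cell-wise.

    Cells present in both layers add; cells present in one pass through.
    Interpretation of the combined score uses :func:`final_verdicts`.
    """
    if clinical is None and ddg is None:
        raise ValueError("at least one layer required")
    if clinical is not None and ddg is not None:
        if clinical.values.shape != ddg.values.shape:
            raise ValueError("clinical and ddg layers have different shapes")
        if clinical.motif_class != ddg.motif_class:
            raise ValueError("layers belong to different motif classes")
    score_fn = score_fn or (lambda d, s: ddg_confidence_score(d, s, thresholds))
    template = clinical if clinical is not None else ddg
    length = template.values.shape[1]
    out = _empty_frame(length)
    src = source or (ddg.source if ddg is not None else "none")
    for pos in range(1, length + 1):
        for aa in AMINO_ACIDS:
            c = clinical.values.at[aa, pos] if clinical is not None else np.nan
            d = ddg.values.at[aa, pos] if ddg is not None else np.nan
            ds = score_fn(float(d), src) if not pd.isna(d) else np.nan
            if not pd.isna(c) and not pd.isna(ds):
                out.at[aa, pos] = c + ds
            elif not pd.isna(c):
                out.at[aa, pos] = c
            elif not pd.isna(ds):
                out.at[aa, pos] = ds
    return SASMatrix(
        motif_class=template.motif_class,
        layer="final_score",
        values=out,
        source=src,
        n_structures=ddg.n_structures if ddg is not None else 0,
        reference=ddg.reference if ddg is not None else None,
    )


def final_verdicts(matrix: SASMatrix, tau: float = 0.5) -> SASMatrix:
    """Per-cell verdicts from a final-score layer via the symmetric tau rule.

    score > tau => non-tolerated; score < -tau => tolerated; otherwise (or
    empty) uncertain/unknown.
    """
    if matrix.layer != "final_score":
        raise ValueError("final_verdicts expects a final_score-layer matrix")
    vals = matrix.values
    verdicts = pd.DataFrame(
        np.where(
            vals.isna(),
            UNKNOWN,
            np.where(vals > tau, NON_TOLERATED, np.where(vals < -tau, TOLERATED, "uncertain")),
        ),
        index=vals.index,
        columns=vals.columns,
    )
    return SASMatrix(
        motif_class=matrix.motif_class,
        layer="tolerance",
        values=verdicts,
        source=matrix.source,
        n_structures=matrix.n_structures,
        reference=matrix.reference,
    )


def compare_ddg_matrices(
    a: SASMatrix, b: SASMatrix, thresholds: Mapping[str, float] = DDG_THRESHOLDS
) -> tuple[float, float]:
    """(Spearman rho, tolerance-agreement accuracy) over shared cells.

    Rho is computed over paired ddG values of cells present in both layers;
    accuracy is the fraction of shared cells whose tolerance verdicts (each
    under its own source threshold, *a* as reference) coincide.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("matrices have different shapes")
    mask = a.values.notna() & b.values.notna()
    xs = a.values.values[mask.values]
    ys = b.values.values[mask.values]
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} shared cells; correlation undefined")
    rho = float(stats.spearmanr(xs, ys).statistic)
    ta = tolerance_from_ddg(a, thresholds=thresholds).values.values[mask.values]
    tb = tolerance_from_ddg(b, thresholds=thresholds).values.values[mask.values]
    accuracy = float(np.mean(ta == tb))
    return rho, accuracy


def matrix_variant_agreement(
    tolerance: SASMatrix,
    calls: Iterable[tuple[int, VariantCall]],
) -> tuple[int, int, float | None]:
    """Concordance between a tolerance matrix and observed variant calls.

    A pathogenic call agrees with a non-tolerated cell, a benign call with a
    tolerated cell.  Unknown cells and unresolved calls are not tested.
    Returns (n_agree, n_tested, accuracy) with accuracy None when nothing
    was testable.
    """
    if tolerance.layer != "tolerance":
        raise ValueError("matrix_variant_agreement expects a tolerance-layer matrix")
    n_agree = n_tested = 0
    for pos, call in calls:
        if call.label == "unresolved":
            continue
        verdict = tolerance.cell(pos, call.evidence.alt_aa)
        if verdict not in (TOLERATED, NON_TOLERATED):
            continue
        n_tested += 1
        if (call.label == "pathogenic") == (verdict == NON_TOLERATED):
            n_agree += 1
    accuracy = n_agree / n_tested if n_tested else None
    return n_agree, n_tested, accuracy


def plot_matrix(matrix: SASMatrix, ax=None, **heatmap_kw):
    """Render a matrix layer as a heatmap (requires seaborn; optional)."""
    import seaborn as sns

    vals = matrix.values
    if matrix.layer == "tolerance":
        mapping = {TOLERATED: -1.0, "uncertain": 0.0, UNKNOWN: np.nan, NON_TOLERATED: 1.0}
        vals = vals.replace(mapping).astype(float)
    return sns.heatmap(vals, ax=ax, **heatmap_kw)
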
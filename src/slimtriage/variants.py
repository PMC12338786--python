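"""Clinical and population variant evidence, confidence scoring, and calls.

Missense variants inside candidate motifs come from two kinds of tables:

* ClinVar-like records carry a clinical classification, a review-status star
  rating (0-4) and a count of supporting submissions.  Only the six
  pathogenic-/benign-side labels are admitted; variants of uncertain
  significance never enter the pipeline.
* gnomAD-like records carry a population allele frequency.  A variant is
  considered benign on frequency grounds only when its AF reaches a per-gene
  threshold.

Evidence is converted to a signed confidence score: pathogenic positive,
benign negative.  Clinical scores are ``stars + 0.1 * submissions`` with the
sign of the classification.  Frequency scores use a monotone capped mapping
of AF relative to the gene threshold (configurable; the default is
``-min(2, 1 + log10(AF/threshold))``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .motifs import MotifMatch

PATHOGENIC_CLASSES = frozenset(
    ["Pathogenic", "Pathogenic/Likely pathogenic", "Likely pathogenic"]
)
BENIGN_CLASSES = frozenset(["Benign", "Benign/Likely benign", "Likely benign"])
ACCEPTED_CLASSES = PATHOGENIC_CLASSES | BENIGN_CLASSES

#: Allele-frequency defaults for genes with <10 pathogenic variants, by
#: inheritance model (autosomal recessive / autosomal dominant), and for
#: genes with no disease association.
AR_DEFAULT_AF = 10.0 ** -4.1
AD_DEFAULT_AF = 10.0 ** -4.28
NO_DISEASE_DEFAULT_AF = 10.0 ** -4.1

__all__ = [
    "PATHOGENIC_CLASSES",
    "BENIGN_CLASSES",
    "ACCEPTED_CLASSES",
    "AR_DEFAULT_AF",
    "AD_DEFAULT_AF",
    "NO_DISEASE_DEFAULT_AF",
    "UnsupportedClinicalClassError",
    "VariantEvidence",
    "GeneThreshold",
    "VariantCall",
    "AnnotatedMatch",
    "clinical_confidence_score",
    "gene_af_threshold",
    "gnomad_confidence_score",
    "classify_variant",
    "dedupe_clinvar",
    "attach_variants",
    "read_clinvar_table",
    "read_gnomad_table",
    "read_gene_metadata",
]


class UnsupportedClinicalClassError(ValueError):
    """Clinical classification outside the six admitted labels."""


@dataclass(frozen=True)
class VariantEvidence:
    """One missense variant observation (protein coordinates, 1-based)."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    source: str  # "clinvar" | "gnomad"
    clinical_class: str | None = None
    stars: int = 0
    submissions: int = 0
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.protein_id}:{self.position} ref equals alt")
        if self.source not in ("clinvar", "gnomad"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "clinvar" and self.clinical_class is None:
            raise ValueError("clinvar evidence requires a clinical class")
        if self.source == "gnomad" and self.allele_frequency is None:
            raise ValueError("gnomad evidence requires an allele frequency")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class GeneThreshold:
    """Per-gene allele-frequency threshold for benign-by-frequency calls."""

    protein_id: str
    threshold: float
    basis: str  # max-pathogenic-AF | AR-default | AD-default | no-disease-default


@dataclass(frozen=True)
class VariantCall:
    """A classified variant with its signed confidence score."""

    evidence: VariantEvidence
    label: str  # pathogenic | benign | unresolved
    confidence: float

    def __post_init__(self) -> None:
        if self.label == "pathogenic" and self.confidence < 0:
            raise ValueError("pathogenic call with negative confidence")
        if self.label == "benign" and self.confidence > 0:
            raise ValueError("benign call with positive confidence")
        if self.label == "unresolved" and self.confidence != 0:
            raise ValueError("unresolved call must carry zero confidence")


@dataclass
class AnnotatedMatch:
    """A motif match with the variant calls that fall inside it."""

    match: MotifMatch
    calls: list[tuple[int, VariantCall]] = field(default_factory=list)
    #: motif-relative 1-based position paired with each call

    @property
    def has_calls(self) -> bool:
        return bool(self.calls)


def clinical_confidence_score(
    clinical_class: str, stars: int, submissions: int
) -> float:
    """Signed score from a ClinVar-style classification.

    Magnitude is 1 point per review star plus 0.1 per supporting submission;
    the sign follows the classification side.  A two-star Pathogenic variant
    with three submissions scores +2.3; a one-star Benign variant with one
    submission scores -1.1.
    """
    if clinical_class not in ACCEPTED_CLASSES:
        raise UnsupportedClinicalClassError(
            f"clinical class {clinical_class!r} is not admitted "
            "(only pathogenic-/benign-side labels are scored)"
        )
    if stars < 0 or submissions < 0:
        raise ValueError("stars and submissions must be non-negative")
    magnitude = stars + 0.1 * submissions
    sign = 1.0 if clinical_class in PATHOGENIC_CLASSES else -1.0
    return sign * magnitude


def gene_af_threshold(
    pathogenic_variants: Sequence[VariantEvidence],
    inheritance: str = "unknown",
    disease_associated: bool = True,
    protein_id: str = "",
) -> GeneThreshold:
    """Allele-frequency threshold for one gene.

    With >=10 pathogenic variants carrying frequencies, the threshold is the
    maximum pathogenic AF; otherwise the inheritance-model default applies
    (AR 10^-4.1, AD 10^-4.28); genes without a disease association use the
    AR-side default.
    """
    with_af = [v for v in pathogenic_variants if v.allele_frequency is not None]
    if not disease_associated:
        return GeneThreshold(protein_id, NO_DISEASE_DEFAULT_AF, "no-disease-default")
    if len(with_af) >= 10:
        return GeneThreshold(
            protein_id,
            max(v.allele_frequency for v in with_af),
            "max-pathogenic-AF",
        )
    if inheritance == "AD":
        return GeneThreshold(protein_id, AD_DEFAULT_AF, "AD-default")
    return GeneThreshold(protein_id, AR_DEFAULT_AF, "AR-default")


def default_af_score(allele_frequency: float, threshold: float) -> float:
    return -min(2.0, 1.0 + math.log10(allele_frequency / threshold))


def gnomad_confidence_score(
    allele_frequency: float,
    threshold: float,
    mapping: Callable[[float, float], float] = default_af_score,
) -> float:
    """Benign-side (non-positive) score for a supra-threshold allele frequency.

    Monotonically more negative as AF/threshold grows; the default mapping is
    -min(2, 1 + log10(AF/threshold)).  Sub-threshold frequencies are an
    error: such variants must stay unresolved, not be scored benign.
    """
    if allele_frequency < threshold:
        raise ValueError(
            f"allele frequency {allele_frequency:g} below threshold {threshold:g}; "
            "sub-threshold variants are not scored"
        )
    score = mapping(allele_frequency, threshold)
    if score > 0:
        raise ValueError("allele-frequency mapping returned a positive score")
    return score


def classify_variant(
    evidence: VariantEvidence,
    gene_threshold: GeneThreshold,
    af_mapping: Callable[[float, float], float] = default_af_score,
) -> VariantCall:
    """Label one variant pathogenic / benign / unresolved with its score.

    A clinical classification always wins over frequency evidence.  Without
    one, the variant is benign iff its AF reaches the gene threshold;
    otherwise it is unresolved (confidence 0).
    """
    if evidence.clinical_class is not None:
        conf = clinical_confidence_score(
            evidence.clinical_class, evidence.stars, evidence.submissions
        )
        label = (
            "pathogenic" if evidence.clinical_class in PATHOGENIC_CLASSES else "benign"
        )
        return VariantCall(evidence, label, conf)
    af = evidence.allele_frequency
    if af is not None and af >= gene_threshold.threshold:
        return VariantCall(
            evidence,
            "benign",
            gnomad_confidence_score(af, gene_threshold.threshold, af_mapping),
        )
    return VariantCall(evidence, "unresolved", 0.0)


def dedupe_clinvar(records: Iterable[VariantEvidence]) -> list[VariantEvidence]:
    """Resolve conflicting clinical rows for the same variant.

    Among rows sharing (protein, position, ref, alt) with classifications on
    both sides, keep the row with most stars, then most submissions; an exact
    tie across sides demotes the variant to unresolved (dropped here).
    Same-side duplicates keep the strongest row.
    """
    by_key: dict[tuple, list[VariantEvidence]] = {}
    for r in records:
        by_key.setdefault(r.key, []).append(r)
    out: list[VariantEvidence] = []
    for key, rows in by_key.items():
        if len(rows) == 1:
            out.append(rows[0])
            continue
        rows = sorted(rows, key=lambda r: (r.stars, r.submissions), reverse=True)
        best = rows[0]
        sides = {r.clinical_class in PATHOGENIC_CLASSES for r in rows}
        if len(sides) > 1:
            rival = next(
                r
                for r in rows
                if (r.clinical_class in PATHOGENIC_CLASSES)
                != (best.clinical_class in PATHOGENIC_CLASSES)
            )
            if (rival.stars, rival.submissions) == (best.stars, best.submissions):
                warnings.warn(
                    f"variant {key}: tied conflicting classifications; dropped"
                )
                continue
        out.append(best)
    return out


def attach_variants(
    matches: Sequence[MotifMatch],
    calls: Sequence[VariantCall],
    proteome: Mapping[str, str] | None = None,
) -> list[AnnotatedMatch]:
    """Attach each call to every match whose span contains its position.

    When *proteome* is given, calls whose reference residue disagrees with
    the protein sequence are excluded with a warning.  The subset of
    annotated matches with at least one call is the candidate set S0.
    """
    usable: list[VariantCall] = []
    for call in calls:
        ev = call.evidence
        if proteome is not None and ev.protein_id in proteome:
            seq = proteome[ev.protein_id]
            if not (1 <= ev.position <= len(seq)) or seq[ev.position - 1] != ev.ref_aa:
                warnings.warn(
                    f"variant {ev.protein_id}:{ev.ref_aa}{ev.position}{ev.alt_aa} "
                    "disagrees with the protein sequence; excluded"
                )
                continue
        usable.append(call)
    by_protein: dict[str, list[VariantCall]] = {}
    for call in usable:
        by_protein.setdefault(call.evidence.protein_id, []).append(call)
    annotated: list[AnnotatedMatch] = []
    for match in matches:
        am = AnnotatedMatch(match)
        for call in by_protein.get(match.protein_id, ()):  # noqa: B905
            mp = match.motif_position(call.evidence.position)
            if mp is not None:
                am.calls.append((mp, call))
        am.calls.sort(key=lambda t: (t[0], t[1].evidence.alt_aa))
        annotated.append(am)
    return annotated


def read_clinvar_table(path) -> list[VariantEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    records = []
    for row in df.itertuples():
        if row.clinical_class not in ACCEPTED_CLASSES:
            raise UnsupportedClinicalClassError(
                f"{row.protein_id}:{row.position}: {row.clinical_class!r}"
            )
        records.append(
            VariantEvidence(
                protein_id=row.protein_id,
                position=int(row.position),
                ref_aa=row.ref_aa,
                alt_aa=row.alt_aa,
                source="clinvar",
                clinical_class=row.clinical_class,
                stars=int(row.stars),
                submissions=int(row.submissions),
            )
        )
    return records


def read_gnomad_table(path) -> list[VariantEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [
        VariantEvidence(
            protein_id=row.protein_id,
            position=int(row.position),
            ref_aa=row.ref_aa,
            alt_aa=row.alt_aa,
            source="gnomad",
            allele_frequency=float(row.allele_frequency),
        )
        for row in df.itertuples()
    ]


def read_gene_metadata(path) -> dict[str, dict]:
    """Gene metadata TSV: protein_id, inheritance (AR/AD/unknown), disease_associated."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out = {}
    for row in df.itertuples():
        out[row.protein_id] = {
            "inheritance": row.inheritance,
            "disease_associated": bool(row.disease_associated),
        }
    return out
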
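"""Candidate-motif feature gates: conservation, structure, exposure, GO.

True short linear motifs sit in conserved, disordered, solvent-exposed
stretches of proteins that share a subcellular compartment with the known
instances of their class.  Four feature gates operationalize this, each
comparing a candidate against the profile of the validated positive (P0)
instances:

* conservation — per-column Jensen-Shannon divergence (JSD) against a
  background residue distribution, mixing weight 1/2, log base 2, scaled by
  the column's non-gap fraction; motif score = mean over motif columns.
* secondary structure — fractions of helix/strand/other (H/E/C) over the
  motif; the candidate's dominant state must occur among the dominant
  states of the P0 instances.
* solvent exposure — per-residue SASA against residue-type thresholds
  (defaults: fraction of the theoretical maximum SASA); the motif's exposed
  fraction must reach the P0 minimum.
* GO cellular component — the is_a ancestor closures of candidate and P0
  term sets must intersect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motifs import AMINO_ACIDS, MotifMatch

GAP_CHARS = frozenset("-.")

#: Theoretical maximum SASA per residue type (Angstrom^2), Tien et al. 2013
#: theoretical values; used to build default exposed/buried thresholds.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

__all__ = [
    "MAX_SASA",
    "ConservationProfile",
    "ExposureProfile",
    "FeatureSet",
    "ReferenceProfile",
    "FeatureGateResult",
    "jsd_column_score",
    "motif_conservation",
    "default_sasa_thresholds",
    "classify_exposure",
    "sasa_from_structure",
    "ss_profile",
    "go_ancestor_closure",
    "go_cc_coherent",
    "build_reference_profile",
    "feature_gate",
]


@dataclass
class ConservationProfile:
    column_scores: list[float]  # one JSD score per motif column, in [0, 1]
    motif_mean: float
    n_sequences: int
    gap_fractions: list[float]


@dataclass
class ExposureProfile:
    sasa: list[float]  # per-residue, Angstrom^2
    relative: list[float]  # SASA / max SASA of the residue type
    classes: list[str]  # "exposed" | "buried"

    @property
    def exposed_fraction(self) -> float:
        return sum(c == "exposed" for c in self.classes) / len(self.classes)


@dataclass
class FeatureSet:
    """The four gate inputs for one candidate motif."""

    conservation: ConservationProfile | None = None
    ss_fractions: tuple[float, float, float] | None = None  # (H, E, C)
    exposure: ExposureProfile | None = None
    go_terms: frozenset[str] = frozenset()

    @property
    def dominant_ss(self) -> str | None:
        if self.ss_fractions is None:
            return None
        return "HEC"[int(np.argmax(self.ss_fractions))]


@dataclass
class ReferenceProfile:
    """Feature envelope of the validated positive (P0) instances."""

    min_conservation: float
    dominant_ss_classes: frozenset[str]
    min_exposed_fraction: float
    go_terms: frozenset[str]
    n_instances: int


@dataclass
class FeatureGateResult:
    conservation_pass: bool
    ss_pass: bool
    exposure_pass: bool
    go_pass: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return (
            self.conservation_pass
            and self.ss_pass
            and self.exposure_pass
            and self.go_pass
        )


def _normalize(dist: Mapping[str, float]) -> dict[str, float]:
    total = sum(dist.values())
    if total <= 0:
        raise ValueError("distribution sums to zero")
    return {k: v / total for k, v in dist.items()}


def jsd_column_score(
    column: Sequence[str] | Mapping[str, float],
    background: Mapping[str, float] | None = None,
) -> float:
    """Jensen-Shannon divergence conservation score of one alignment column.

    *column* is the residues of the column (gaps as ``-``/``.``) or an
    already-normalized residue distribution (then gap-free).  The JSD
    between the gap-free column distribution and the background (default
    uniform over the 20 amino acids) is computed with mixing weight 1/2 in
    log base 2 — bounded in [0, 1] — then multiplied by the column's
    non-gap fraction.
    """
    if background is None:
        background = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}
    background = _normalize(background)
    if isinstance(column, Mapping):
        col_counts = dict(column)
        gap_fraction = 0.0
    else:
        letters = [c.upper() for c in column]
        if not letters:
            raise ValueError("empty alignment column")
        n_gap = sum(c in GAP_CHARS for c in letters)
        gap_fraction = n_gap / len(letters)
        residues = [c for c in letters if c not in GAP_CHARS]
        if not residues:
            return 0.0  # all-gap column carries no signal
        col_counts = {aa: residues.count(aa) for aa in set(residues)}
    p = _normalize(col_counts)
    keys = set(p) | set(background)
    pv = np.array([p.get(k, 0.0) for k in keys])
    qv = np.array([background.get(k, 0.0) for k in keys])
    m = 0.5 * (pv + qv)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.nansum(np.where(pv > 0, pv * np.log2(pv / m), 0.0))
        kl_qm = np.nansum(np.where(qv > 0, qv * np.log2(qv / m), 0.0))
    jsd = 0.5 * kl_pm + 0.5 * kl_qm
    return float(np.clip(jsd, 0.0, 1.0) * (1.0 - gap_fraction))


def _query_columns(gapped_query: str, start: int, end: int) -> list[int]:
    """Alignment column indices (0-based) of query residues start..end (1-based)."""
    cols = []
    res = 0
    for i, c in enumerate(gapped_query):
        if c not in GAP_CHARS:
            res += 1
            if start <= res <= end:
                cols.append(i)
    if res < end:
        raise ValueError(
            f"match 1-based span {start}-{end} extends past the query row "
            f"({res} residues)"
        )
    return cols


def motif_conservation(
    msa: Mapping[str, str] | Sequence[tuple[str, str]],
    query_id: str,
    start: int,
    end: int,
    background: Mapping[str, float] | None = None,
) -> ConservationProfile:
    """Per-column JSD scores over a motif's columns in an MSA.

    The motif span (1-based, in ungapped query coordinates) is mapped to
    alignment columns through the query's gapped row.  A single-sequence MSA
    is scored but flagged by n_sequences = 1.
    """
    rows = dict(msa)
    if query_id not in rows:
        raise ValueError(f"query {query_id!r} not in the alignment")
    widths = {len(s) for s in rows.values()}
    if len(widths) != 1:
        raise ValueError("ragged alignment")
    cols = _query_columns(rows[query_id], start, end)
    seqs = list(rows.values())
    scores, gaps = [], []
    for c in cols:
        column = [s[c] for s in seqs]
        scores.append(jsd_column_score(column, background))
        gaps.append(sum(ch in GAP_CHARS for ch in column) / len(column))
    return ConservationProfile(
        column_scores=scores,
        motif_mean=float(np.mean(scores)),
        n_sequences=len(seqs),
        gap_fractions=gaps,
    )


def default_sasa_thresholds(relative_cutoff: float = 0.25) -> dict[str, float]:
    """Exposed/buried SASA thresholds as a fraction of the theoretical max."""
    return {aa: relative_cutoff * mx for aa, mx in MAX_SASA.items()}


def classify_exposure(
    sasa: Sequence[float],
    residues: str | Sequence[str],
    thresholds: Mapping[str, float] | None = None,
) -> ExposureProfile:
    """Exposed/buried call per residue: exposed iff SASA > its type threshold."""
    thresholds = thresholds if thresholds is not None else default_sasa_thresholds()
    if len(sasa) != len(residues):
        raise ValueError("sasa and residue lists differ in length")
    classes, relative = [], []
    for s, aa in zip(sasa, residues):
        if aa not in MAX_SASA:
            raise ValueError(f"unknown residue type {aa!r}")
        if aa not in thresholds:
            raise ValueError(f"thresholds table lacks residue type {aa!r}")
        if s < 0:
            raise ValueError("negative SASA")
        classes.append("exposed" if s > thresholds[aa] else "buried")
        relative.append(s / MAX_SASA[aa])
    return ExposureProfile(sasa=list(sasa), relative=relative, classes=classes)


def sasa_from_structure(pdb_path, chain_id: str, point_number: int = 200) -> dict[int, float]:
    """Per-residue SASA from raw coordinates (Shrake-Rupley sphere sampling).

    Probe radius 1.4 Angstrom; returns residue number -> SASA (Angstrom^2)
    for *chain_id*.  Lets fixture models be scored with no external tool.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    array = pdb.PDBFile.read(str(pdb_path)).get_structure(model=1)
    atom_sasa = struc.sasa(
        array, probe_radius=1.4, point_number=point_number, vdw_radii="Single"
    )
    out: dict[int, float] = {}
    for res_id in np.unique(array.res_id[array.chain_id == chain_id]):
        mask = (array.chain_id == chain_id) & (array.res_id == res_id)
        out[int(res_id)] = float(np.nansum(atom_sasa[mask]))
    return out


def ss_profile(ss_string: str, match: MotifMatch) -> tuple[float, float, float]:
    """(helix, strand, other) fractions over the motif residues.

    *ss_string* is the protein-length per-residue H/E/C string.
    """
    if match.end > len(ss_string):
        raise ValueError(
            f"secondary-structure string length {len(ss_string)} shorter than "
            f"match end {match.end}"
        )
    segment = ss_string[match.start - 1 : match.end].upper()
    bad = set(segment) - set("HEC")
    if bad:
        raise ValueError(f"unknown secondary-structure codes {sorted(bad)}")
    n = len(segment)
    return (
        segment.count("H") / n,
        segment.count("E") / n,
        segment.count("C") / n,
    )


def go_ancestor_closure(
    terms: Iterable[str], ontology, namespace: str = "cellular_component"
) -> frozenset[str]:
    """is_a ancestor closure (terms included) within one GO namespace.

    *ontology* is an obonet-style networkx graph whose edges point child ->
    parent.  Unknown terms are skipped with a warning.  The namespace root
    (a node with no parents) is excluded: every term reaches it, so keeping
    it would make any two closures trivially intersect.
    """
    import networkx as nx

    closure: set[str] = set()
    for term in terms:
        if term not in ontology:
            warnings.warn(f"unknown GO term {term!r}; skipped")
            continue
        if ontology.nodes[term].get("namespace", namespace) != namespace:
            continue
        closure.add(term)
        for anc in nx.descendants(ontology, term):  # edges child->parent
            if ontology.nodes[anc].get("namespace", namespace) == namespace:
                closure.add(anc)
    return frozenset(t for t in closure if ontology.out_degree(t) > 0)


def go_cc_coherent(
    candidate_terms: Iterable[str],
    reference_terms: Iterable[str],
    ontology,
) -> bool:
    """True iff candidate and reference cellular-component closures intersect."""
    cand = go_ancestor_closure(candidate_terms, ontology)
    ref = go_ancestor_closure(reference_terms, ontology)
    return bool(cand & ref)


def build_reference_profile(p0_features: Sequence[FeatureSet]) -> ReferenceProfile:
    """Feature envelope over the P0 instances of a motif class."""
    if not p0_features:
        raise ValueError("reference profile needs at least one P0 instance")
    cons = [
        f.conservation.motif_mean for f in p0_features if f.conservation is not None
    ]
    dominant = {f.dominant_ss for f in p0_features if f.dominant_ss is not None}
    exposed = [
        f.exposure.exposed_fraction for f in p0_features if f.exposure is not None
    ]
    terms: set[str] = set()
    for f in p0_features:
        terms |= f.go_terms
    return ReferenceProfile(
        min_conservation=min(cons) if cons else 0.0,
        dominant_ss_classes=frozenset(dominant) or frozenset("HEC"),
        min_exposed_fraction=min(exposed) if exposed else 0.0,
        go_terms=frozenset(terms),
        n_instances=len(p0_features),
    )


def feature_gate(
    candidate: FeatureSet,
    reference: ReferenceProfile,
    ontology=None,
) -> FeatureGateResult:
    """Gate a candidate against the P0 feature envelope.

    Missing candidate features pass their gate vacuously (no evidence
    against); every failed gate contributes a reason.  GO coherence needs an
    ontology; without one, identical-term overlap is used.
    """
    reasons: list[str] = []
    conservation_pass = True
    if candidate.conservation is not None:
        conservation_pass = (
            candidate.conservation.motif_mean >= reference.min_conservation
        )
        if not conservation_pass:
            reasons.append(
                f"conservation {candidate.conservation.motif_mean:.3f} below "
                f"P0 minimum {reference.min_conservation:.3f}"
            )
    ss_pass = True
    if candidate.dominant_ss is not None:
        ss_pass = candidate.dominant_ss in reference.dominant_ss_classes
        if not ss_pass:
            reasons.append(
                f"dominant secondary structure {candidate.dominant_ss!r} not "
                f"seen in P0 ({sorted(reference.dominant_ss_classes)})"
            )
    exposure_pass = True
    if candidate.exposure is not None:
        exposure_pass = (
            candidate.exposure.exposed_fraction >= reference.min_exposed_fraction
        )
        if not exposure_pass:
            reasons.append(
                f"exposed fraction {candidate.exposure.exposed_fraction:.2f} below "
                f"P0 minimum {reference.min_exposed_fraction:.2f}"
            )
    go_pass = True
    if candidate.go_terms and reference.go_terms:
        if ontology is not None:
            go_pass = go_cc_coherent(candidate.go_terms, reference.go_terms, ontology)
        else:
            go_pass = bool(candidate.go_terms & reference.go_terms)
        if not go_pass:
            reasons.append("GO cellular-component terms disjoint from P0")
    return FeatureGateResult(
        conservation_pass=conservation_pass,
        ss_pass=ss_pass,
        exposure_pass=exposure_pass,
        go_pass=go_pass,
        reasons=reasons,
    )
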
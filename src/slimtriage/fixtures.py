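"""Synthetic input bundles with planted ground truth.

The generator emits, under one directory, every file the triage pipeline
consumes — proteome FASTA, motif-class TSV, validated-instance TSV,
ClinVar-/gnomAD-style variant tables, gene metadata, per-model PDB files
with pLDDT in the B-factor column, per-model stability (ddG) tables, MSAs,
secondary-structure strings, per-residue SASA tables, a toy GO ontology
with annotations — plus a manifest recording the planted role of every
entity, so the whole system is testable at desk scale with no downloads.

Planted signal:

* Each motif class gets validated (P0) instances, true candidates (variants
  consistent with the class's substitution-tolerance structure, features
  matching P0), decoy candidates (one contradicting variant), and
  undecidable candidates (only a sub-threshold-frequency variant).
* ddG values are drawn per cell from two components: tolerated
  substitutions ~ N(0.5, 0.5) and non-tolerated ~ N(4.0, 1.0), both
  truncated below at -2 kcal/mol, so the 2.1 / 1.6 kcal/mol thresholds sit
  between the components.
* Correct-pose models draw motif pLDDT ~ N(82.8, 10.0) and interaction
  energy ~ N(-12.1, 4.1); incorrect poses ~ N(40.9, 14.0) and N(-3.1, 6.6).
  A planted correct pose is redrawn until it passes the quality gate, an
  incorrect pose until it fails: the planted role is "passes / fails QC".

Candidate variants are placed on cells whose *realized* averaged-ddG
verdict (over the correct-pose models the generator itself emits) matches
the intended tolerance, which is what makes noise-free recovery exact.
A ``variant_noise`` rate flips planted variant labels at random; the
manifest always records the pre-noise truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .matrices import DDG_THRESHOLDS, NON_TOLERATED, TOLERATED, average_ddg, tolerance_from_ddg
from .matrices import DdGRecord
from .motifs import AMINO_ACIDS, MotifClass, compile_motif_pattern, scan_proteome

GO_ROOT = "GO:0000001"
GO_REFERENCE_TERM = "GO:0000002"  # "membrane"; annotated on P0 proteins
GO_CANDIDATE_TERM = "GO:0000003"  # "plasma membrane", child of the reference
GO_UNRELATED_TERM = "GO:0000004"  # "nucleus"; no shared non-root ancestor

_TOY_OBO = """format-version: 1.2
ontology: toy-cc

[Term]
id: GO:0000001
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0000002
name: membrane
namespace: cellular_component
is_a: GO:0000001 ! cellular_component

[Term]
id: GO:0000003
name: plasma membrane
namespace: cellular_component
is_a: GO:0000002 ! membrane

[Term]
id: GO:0000004
name: nucleus
namespace: cellular_component
is_a: GO:0000001 ! cellular_component
"""

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "generate",
    "write_bundle",
    "read_manifest",
]


@dataclass
class FixtureSpec:
    """Generation parameters; the defaults define the study conditions."""

    seed: int
    n_proteins: int = 50
    protein_length: tuple[int, int] = (80, 200)
    motif_classes: dict[str, str] = field(
        default_factory=lambda: {
            "LIG_A": "NP.[YF]",
            "LIG_B": "W[^P][^P][^P][IL][^P][AGS][AT]",
        }
    )
    n_p0: int = 3
    n_true: int = 3
    n_decoy: int = 3
    n_undecidable: int = 4
    variant_noise: float = 0.0
    structure_source: str = "af2"
    n_correct_models: int = 3
    n_incorrect_models: int = 3
    # ddG generative components (kcal/mol)
    ddg_tolerated: tuple[float, float] = (0.5, 0.5)
    ddg_non_tolerated: tuple[float, float] = (4.0, 1.0)
    ddg_floor: float = -2.0
    # model-quality components for correct / incorrect poses
    plddt_correct: tuple[float, float] = (82.8, 10.0)
    plddt_incorrect: tuple[float, float] = (40.9, 14.0)
    energy_correct: tuple[float, float] = (-12.1, 4.1)
    energy_incorrect: tuple[float, float] = (-3.1, 6.6)
    msa_depth: int = 8
    benign_af: float = 0.01
    subthreshold_af: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_p0", "n_true", "n_decoy", "n_undecidable"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.variant_noise <= 1.0:
            raise ValueError("variant_noise must lie in [0, 1]")


@dataclass
class FixtureBundle:
    """In-memory bundle: file payloads plus the ground-truth manifest."""

    spec: FixtureSpec
    proteome: dict[str, str]
    motif_classes: dict[str, str]
    p0_instances: list[dict]
    clinvar_rows: list[dict]
    gnomad_rows: list[dict]
    gene_rows: list[dict]
    models: list[dict]  # metadata incl. pdb_text and ddg rows
    msas: dict[str, list[tuple[str, str]]]
    ss: dict[str, str]
    sasa: dict[str, list[tuple[int, str, float]]]
    go_annotations: list[tuple[str, str]]
    manifest: dict


def _draw_trunc(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return float(x)
    return floor


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]


def _plant_sequence(rng: np.random.Generator, motif: MotifClass) -> str:
    return "".join(
        sorted(p.allowed)[rng.integers(0, len(p.allowed))] for p in motif.positions
    )


def _choose(rng: np.random.Generator, items: list):
    if not items:
        raise ValueError("no eligible cells for the requested planting")
    return items[int(rng.integers(0, len(items)))]


def _shuffled(rng: np.random.Generator, items: list) -> list:
    order = rng.permutation(len(items))
    return [items[int(i)] for i in order]


def generate(spec: FixtureSpec) -> FixtureBundle:  # noqa: C901
    """Build a complete planted-truth bundle, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    motifs = {
        ident: compile_motif_pattern(regex, identifier=ident)
        for ident, regex in spec.motif_classes.items()
    }
    per_class = spec.n_p0 + spec.n_true + spec.n_decoy + spec.n_undecidable
    total_planted = per_class * len(motifs)
    if total_planted > spec.n_proteins:
        raise ValueError(
            f"spec plants {total_planted} motifs but provides only "
            f"{spec.n_proteins} proteins (one planted motif per protein)"
        )

    # --- reference motif sequences and structure models with ddG tables ----
    reference_seq = {ident: _plant_sequence(rng, m) for ident, m in motifs.items()}
    models: list[dict] = []
    realized_tolerance: dict[str, object] = {}
    ddg_by_class: dict[str, dict[str, list[DdGRecord]]] = {}
    thr = DDG_THRESHOLDS[spec.structure_source]
    for ident, motif in motifs.items():
        ref = reference_seq[ident]
        correct_tables: dict[str, list[DdGRecord]] = {}
        for k in range(spec.n_correct_models + spec.n_incorrect_models):
            correct = k < spec.n_correct_models
            model_id = f"{ident}_m{k + 1}"
            plddt_mu, plddt_sd = (
                spec.plddt_correct if correct else spec.plddt_incorrect
            )
            e_mu, e_sd = spec.energy_correct if correct else spec.energy_incorrect
            for _ in range(200):  # enforce the planted QC role
                mean_plddt = round(float(np.clip(rng.normal(plddt_mu, plddt_sd), 0, 100)), 2)
                energy = round(float(rng.normal(e_mu, e_sd)), 3)
                passes = mean_plddt > 65.0 and energy < -5.0
                if passes == correct:
                    break
            records = []
            for pos, p in enumerate(motif.positions, 1):
                for alt in AMINO_ACIDS:
                    if alt == ref[pos - 1]:
                        continue
                    tolerated = alt in p.allowed
                    if correct:
                        mu, sd = (
                            spec.ddg_tolerated if tolerated else spec.ddg_non_tolerated
                        )
                    else:  # pose-independent scramble: mixture component at random
                        mu, sd = (
                            spec.ddg_tolerated
                            if rng.random() < 0.5
                            else spec.ddg_non_tolerated
                        )
                    records.append(
                        DdGRecord(
                            pos, ref[pos - 1], alt,
                            round(_draw_trunc(rng, mu, sd, spec.ddg_floor), 4),
                            model_id,
                        )
                    )
            models.append(
                {
                    "model_id": model_id,
                    "motif_class": ident,
                    "source": spec.structure_source,
                    "motif_chain": "B",
                    "motif_start": 101,
                    "motif_end": 100 + motif.length,
                    "interaction_energy": energy,
                    "recycles": 24,
                    "mean_plddt": mean_plddt,
                    "correct_pose": correct,
                    "ddg_records": records,
                }
            )
            if correct:
                correct_tables[model_id] = records
        ddg_by_class[ident] = correct_tables
        avg = average_ddg(
            correct_tables, ident, motif.length,
            source=spec.structure_source, reference=ref,
        )
        realized_tolerance[ident] = tolerance_from_ddg(avg)

    # --- proteome with planted, scrubbed matches ---------------------------
    roles = (
        ["p0"] * spec.n_p0
        + ["true"] * spec.n_true
        + ["decoy"] * spec.n_decoy
        + ["undecidable"] * spec.n_undecidable
    )
    lengths = rng.integers(
        spec.protein_length[0], spec.protein_length[1] + 1, size=spec.n_proteins
    )
    sequences = {f"SYN{i + 1:04d}": _random_sequence(rng, int(n)) for i, n in enumerate(lengths)}
    protein_ids = sorted(sequences)
    planted: list[dict] = []
    slot = 0
    for ident, motif in motifs.items():
        for j, role in enumerate(roles):
            pid = protein_ids[slot]
            slot += 1
            seq = sequences[pid]
            start0 = int(rng.integers(5, len(seq) - motif.length - 5))
            if role == "p0":
                inst = reference_seq[ident]
            else:
                inst = _plant_sequence(rng, motif)
            seq[start0 : start0 + motif.length] = list(inst)
            planted.append(
                {
                    "protein_id": pid,
                    "motif_class": ident,
                    "start": start0 + 1,
                    "end": start0 + motif.length,
                    "sequence": inst,
                    "role": role,
                }
            )
    planted_spans = {
        (p["protein_id"], i)
        for p in planted
        for i in range(p["start"], p["end"] + 1)
    }
    # scrub accidental regex matches outside the planted spans
    for _ in range(100):
        proteome = {pid: "".join(seq) for pid, seq in sequences.items()}
        extra = [
            m
            for m in scan_proteome(proteome, list(motifs.values()))
            if not any(
                p["protein_id"] == m.protein_id
                and p["motif_class"] == m.motif_class
                and p["start"] == m.start
                for p in planted
            )
        ]
        if not extra:
            break
        for m in extra:
            motif = motifs[m.motif_class]
            fixed = False
            for p in motif.positions:
                site = m.start + p.index - 1
                if (m.protein_id, site) in planted_spans:
                    continue
                disallowed = sorted(set(AMINO_ACIDS) - p.allowed)
                if not disallowed:
                    continue
                sequences[m.protein_id][site - 1] = _choose(rng, disallowed)
                fixed = True
                break
            if not fixed:  # every free position is fully degenerate; rewrite one
                site = m.start
                sequences[m.protein_id][site - 1] = _choose(rng, list(AMINO_ACIDS))
    else:
        raise RuntimeError("could not scrub spurious matches from the proteome")
    proteome = {pid: "".join(seq) for pid, seq in sequences.items()}

    # --- variants ----------------------------------------------------------
    clinvar_rows: list[dict] = []
    gnomad_rows: list[dict] = []
    variant_truth: list[dict] = []
    clinical_cells: dict[str, dict[tuple[int, str], str]] = {
        ident: {} for ident in motifs
    }

    def realized(ident: str, pos: int, alt: str) -> str:
        return realized_tolerance[ident].cell(pos, alt)

    def cells_with(ident: str, positions, verdict: str, exclude=frozenset()):
        out = []
        for pos in positions:
            for alt in AMINO_ACIDS:
                if (pos, alt) in exclude:
                    continue
                if realized(ident, pos, alt) == verdict:
                    out.append((pos, alt))
        return out

    def add_clinvar(p, pos, alt, side, stars, subs, truth, noisy=True):
        flipped = noisy and rng.random() < spec.variant_noise
        eff = ("Benign" if side == "Pathogenic" else "Pathogenic") if flipped else side
        clinvar_rows.append(
            {
                "protein_id": p["protein_id"],
                "position": p["start"] + pos - 1,
                "ref_aa": p["sequence"][pos - 1],
                "alt_aa": alt,
                "clinical_class": eff,
                "stars": int(stars),
                "submissions": int(subs),
            }
        )
        variant_truth.append(
            {
                "protein_id": p["protein_id"],
                "position": p["start"] + pos - 1,
                "ref_aa": p["sequence"][pos - 1],
                "alt_aa": alt,
                "true_label": truth,
                "flipped": bool(flipped),
                "match_role": p["role"],
            }
        )

    def add_gnomad(p, pos, alt, af, truth, noisy=True):
        flipped = noisy and truth == "benign" and rng.random() < spec.variant_noise
        if flipped:  # label noise: the frequency evidence shows up as clinical
            add_clinvar(p, pos, alt, "Pathogenic", 1, 0, truth, noisy=False)
            variant_truth[-1]["flipped"] = True
            return
        gnomad_rows.append(
            {
                "protein_id": p["protein_id"],
                "position": p["start"] + pos - 1,
                "ref_aa": p["sequence"][pos - 1],
                "alt_aa": alt,
                "allele_frequency": af,
            }
        )
        variant_truth.append(
            {
                "protein_id": p["protein_id"],
                "position": p["start"] + pos - 1,
                "ref_aa": p["sequence"][pos - 1],
                "alt_aa": alt,
                "true_label": truth,
                "flipped": False,
                "match_role": p["role"],
            }
        )

    true_cycle: dict[str, int] = {}
    for ident, motif in motifs.items():
        rigid = list(motif.rigid_indices)
        flexible = list(motif.flexible_indices)
        cls_planted = [p for p in planted if p["motif_class"] == ident]
        cells = clinical_cells[ident]
        # P0: seed the clinical matrix with consistent evidence
        for p in (q for q in cls_planted if q["role"] == "p0"):
            non_tol = [
                c
                for c in _shuffled(rng, cells_with(ident, rigid, NON_TOLERATED))
                if p["sequence"][c[0] - 1] != c[1]
            ]
            for pos, alt in non_tol[:2]:
                add_clinvar(
                    p, pos, alt, "Pathogenic",
                    rng.integers(1, 4), rng.integers(0, 6), "pathogenic",
                )
                cells[(pos, alt)] = NON_TOLERATED
            tol = [
                c
                for c in _shuffled(rng, cells_with(ident, rigid, TOLERATED))
                if p["sequence"][c[0] - 1] != c[1]
            ]
            for pos, alt in tol[:2]:
                add_clinvar(
                    p, pos, alt, "Benign",
                    rng.integers(1, 4), rng.integers(0, 6), "benign",
                )
                cells[(pos, alt)] = TOLERATED
        # true candidates, cycled through CSC / SAC / FPC decidability
        cycle_options = [1, 2] + ([3] if flexible else [])
        for i, p in enumerate(q for q in cls_planted if q["role"] == "true"):
            cycle = cycle_options[i % len(cycle_options)]
            key = f"{p['protein_id']}:{ident}:{p['start']}-{p['end']}"
            if cycle == 1:
                options = [
                    (pos, alt)
                    for (pos, alt), v in sorted(cells.items())
                    if p["sequence"][pos - 1] != alt
                ]
                if not options:  # no usable clinically covered cell
                    cycle = 2
            true_cycle[key] = cycle
            if cycle == 1:  # reuse a clinically covered cell, same sign
                pos, alt = _choose(rng, options)
                if cells[(pos, alt)] == NON_TOLERATED:
                    add_clinvar(p, pos, alt, "Pathogenic", 2, 1, "pathogenic")
                else:
                    add_clinvar(p, pos, alt, "Benign", 2, 1, "benign")
            elif cycle == 2:  # fresh rigid cell: silent in CSC, decided in SAC
                options = [
                    (pos, alt)
                    for pos, alt in cells_with(
                        ident, rigid, NON_TOLERATED, exclude=set(cells)
                    )
                    if p["sequence"][pos - 1] != alt
                ]
                pos, alt = _choose(rng, options)
                add_clinvar(p, pos, alt, "Pathogenic", 2, 1, "pathogenic")
            else:  # flexible cell, decided only in FPC
                non_tol = [
                    (pos, alt)
                    for pos, alt in cells_with(
                        ident, flexible, NON_TOLERATED, exclude=set(cells)
                    )
                    if p["sequence"][pos - 1] != alt
                ]
                if non_tol:
                    pos, alt = _choose(rng, non_tol)
                    add_clinvar(p, pos, alt, "Pathogenic", 2, 1, "pathogenic")
                else:
                    tol = [
                        (pos, alt)
                        for pos, alt in cells_with(
                            ident, flexible, TOLERATED, exclude=set(cells)
                        )
                        if p["sequence"][pos - 1] != alt
                    ]
                    pos, alt = _choose(rng, tol)
                    add_gnomad(p, pos, alt, spec.benign_af, "benign")
        # decoys: one contradicting variant (benign at a non-tolerated cell)
        for p in (q for q in cls_planted if q["role"] == "decoy"):
            options = [
                (pos, alt)
                for pos, alt in cells_with(ident, rigid, NON_TOLERATED)
                if p["sequence"][pos - 1] != alt
            ]
            pos, alt = _choose(rng, options)
            add_gnomad(p, pos, alt, spec.benign_af, "contradiction")
        # undecidables: a single sub-threshold-frequency variant
        for p in (q for q in cls_planted if q["role"] == "undecidable"):
            pos = int(_choose(rng, list(range(1, motif.length + 1))))
            alt = _choose(rng, [a for a in AMINO_ACIDS if a != p["sequence"][pos - 1]])
            add_gnomad(p, pos, alt, spec.subthreshold_af, None, noisy=False)

    gene_rows = [
        {
            "protein_id": pid,
            "inheritance": _choose(rng, ["AR", "AD"]),
            "disease_associated": True,
        }
        for pid in protein_ids
    ]

    # --- feature inputs ----------------------------------------------------
    msas: dict[str, list[tuple[str, str]]] = {}
    ss: dict[str, str] = {}
    sasa: dict[str, list[tuple[int, str, float]]] = {}
    go_annotations: list[tuple[str, str]] = []
    from .features import MAX_SASA

    planted_by_protein = {p["protein_id"]: p for p in planted}
    for pid in protein_ids:
        seq = proteome[pid]
        ss[pid] = "C" * len(seq)
        p = planted_by_protein.get(pid)
        motif_sites = set(range(p["start"], p["end"] + 1)) if p else set()
        sasa[pid] = [
            (
                i,
                seq[i - 1],
                round(
                    (0.8 if i in motif_sites else 0.1) * MAX_SASA[seq[i - 1]], 2
                ),
            )
            for i in range(1, len(seq) + 1)
        ]
        if p is None:
            continue
        rows = [(pid, seq)]
        for k in range(spec.msa_depth - 1):
            row = _random_sequence(rng, len(seq))
            for i in motif_sites:
                row[i - 1] = seq[i - 1]  # conserved motif columns
            # sprinkle gaps outside the motif
            for gpos in rng.integers(0, len(seq), size=3).tolist():
                if (gpos + 1) not in motif_sites:
                    row[gpos] = "-"
            rows.append((f"{pid}_h{k + 1}", "".join(row)))
        msas[pid] = rows
        go_annotations.append(
            (pid, GO_REFERENCE_TERM if p["role"] == "p0" else GO_CANDIDATE_TERM)
        )

    for p in planted:
        p["expected_set"] = {
            "p0": "P",
            "true": "P",
            "decoy": "N",
            "undecidable": "R",
        }[p["role"]]
        key = f"{p['protein_id']}:{p['motif_class']}:{p['start']}-{p['end']}"
        p["key"] = key
        if p["role"] == "true":
            p["planted_cycle"] = true_cycle[key]

    manifest = {
        "spec": {
            **asdict(spec),
            "protein_length": list(spec.protein_length),
        },
        "seed": spec.seed,
        "reference_sequences": reference_seq,
        "matches": sorted(planted, key=lambda p: p["key"]),
        "variants": sorted(
            variant_truth,
            key=lambda v: (v["protein_id"], v["position"], v["alt_aa"]),
        ),
        "models": [
            {
                "model_id": m["model_id"],
                "motif_class": m["motif_class"],
                "correct_pose": m["correct_pose"],
                "mean_plddt": m["mean_plddt"],
                "interaction_energy": m["interaction_energy"],
            }
            for m in models
        ],
        "counts": {
            "n_p0": spec.n_p0,
            "n_true": spec.n_true,
            "n_decoy": spec.n_decoy,
            "n_undecidable": spec.n_undecidable,
            "n_classes": len(motifs),
        },
    }
    return FixtureBundle(
        spec=spec,
        proteome=proteome,
        motif_classes=dict(spec.motif_classes),
        p0_instances=[p for p in planted if p["role"] == "p0"],
        clinvar_rows=clinvar_rows,
        gnomad_rows=gnomad_rows,
        gene_rows=gene_rows,
        models=models,
        msas=msas,
        ss=ss,
        sasa=sasa,
        go_annotations=go_annotations,
        manifest=manifest,
    )


def _pdb_text(model: dict, proteome_free_len: int = 30) -> str:
    """Minimal two-chain C-alpha PDB: receptor chain A, motif chain B with
    the per-residue pLDDT in the B-factor column."""
    lines = []
    serial = 1
    x = 0.0
    for resnum in range(1, proteome_free_len + 1):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA A{resnum:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{90.00:6.2f}           C"
        )
        serial += 1
        x += 3.8
    lines.append("TER")
    ref = model["reference_seq"]
    for i, aa in enumerate(ref):
        resnum = model["motif_start"] + i
        lines.append(
            f"ATOM  {serial:5d}  CA  {AA3[aa]} B{resnum:4d}    "
            f"{x:8.3f}{4.0:8.3f}{0.0:8.3f}{1.00:6.2f}{model['plddt_per_residue'][i]:6.2f}           C"
        )
        serial += 1
        x += 3.8
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: FixtureBundle, directory) -> Path:
    """Serialize a bundle to standard text formats under *directory*."""
    root = Path(directory)
    for sub in ("ddg", "models", "msa", "sasa"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    with open(root / "proteome.fasta", "w") as fh:
        for pid in sorted(bundle.proteome):
            fh.write(f">sp|{pid}|{pid}_SYN synthetic protein\n{bundle.proteome[pid]}\n")
    with open(root / "motif_classes.tsv", "w") as fh:
        fh.write("elm_identifier\tregex\n")
        for ident in sorted(bundle.motif_classes):
            fh.write(f"{ident}\t{bundle.motif_classes[ident]}\n")
    with open(root / "elm_instances.tsv", "w") as fh:
        fh.write("protein_id\tmotif_class\tstart\tend\n")
        for p in sorted(bundle.p0_instances, key=lambda q: q["key"]):
            fh.write(f"{p['protein_id']}\t{p['motif_class']}\t{p['start']}\t{p['end']}\n")
    with open(root / "clinvar.tsv", "w") as fh:
        fh.write("protein_id\tposition\tref_aa\talt_aa\tclinical_class\tstars\tsubmissions\n")
        for r in bundle.clinvar_rows:
            fh.write(
                f"{r['protein_id']}\t{r['position']}\t{r['ref_aa']}\t{r['alt_aa']}\t"
                f"{r['clinical_class']}\t{r['stars']}\t{r['submissions']}\n"
            )
    with open(root / "gnomad.tsv", "w") as fh:
        fh.write("protein_id\tposition\tref_aa\talt_aa\tallele_frequency\n")
        for r in bundle.gnomad_rows:
            fh.write(
                f"{r['protein_id']}\t{r['position']}\t{r['ref_aa']}\t{r['alt_aa']}\t"
                f"{r['allele_frequency']:.8g}\n"
            )
    with open(root / "gene_meta.tsv", "w") as fh:
        fh.write("protein_id\tinheritance\tdisease_associated\n")
        for r in bundle.gene_rows:
            fh.write(f"{r['protein_id']}\t{r['inheritance']}\t{r['disease_associated']}\n")

    reference_seq = bundle.manifest["reference_sequences"]
    with open(root / "models.tsv", "w") as fh:
        fh.write(
            "model_id\tmotif_class\tsource\tmotif_chain\tmotif_start\tmotif_end\t"
            "interaction_energy\trecycles\n"
        )
        for m in bundle.models:
            fh.write(
                f"{m['model_id']}\t{m['motif_class']}\t{m['source']}\t{m['motif_chain']}\t"
                f"{m['motif_start']}\t{m['motif_end']}\t{m['interaction_energy']}\t"
                f"{m['recycles']}\n"
            )
            ref = reference_seq[m["motif_class"]]
            # per-residue pLDDT: constant at the drawn motif mean
            pdb_model = {
                **m,
                "reference_seq": ref,
                "plddt_per_residue": [m["mean_plddt"]] * len(ref),
            }
            with open(root / "models" / f"{m['model_id']}.pdb", "w") as pf:
                pf.write(_pdb_text(pdb_model))
            with open(root / "ddg" / f"{m['model_id']}.tsv", "w") as df:
                df.write("position\tref_aa\talt_aa\tddg\n")
                for r in m["ddg_records"]:
                    df.write(f"{r.position}\t{r.ref_aa}\t{r.alt_aa}\t{r.ddg}\n")

    for pid in sorted(bundle.msas):
        with open(root / "msa" / f"{pid}.fasta", "w") as fh:
            for name, row in bundle.msas[pid]:
                fh.write(f">{name}\n{row}\n")
    with open(root / "ss.tsv", "w") as fh:
        fh.write("protein_id\tss\n")
        for pid in sorted(bundle.ss):
            fh.write(f"{pid}\t{bundle.ss[pid]}\n")
    for pid in sorted(bundle.sasa):
        with open(root / "sasa" / f"{pid}.tsv", "w") as fh:
            fh.write("position\tresidue\tsasa\n")
            for pos, res, val in bundle.sasa[pid]:
                fh.write(f"{pos}\t{res}\t{val}\n")
    with open(root / "go.obo", "w") as fh:
        fh.write(_TOY_OBO)
    with open(root / "go_annotations.tsv", "w") as fh:
        fh.write("protein_id\tterm\n")
        for pid, term in sorted(bundle.go_annotations):
            fh.write(f"{pid}\t{term}\n")

    tmp = root / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    tmp.replace(root / "manifest.json")  # manifest last, atomically
    return root


def read_manifest(directory) -> dict:
    """Load a bundle's ground-truth manifest, verifying the files it names."""
    root = Path(directory)
    path = root / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"missing manifest.json under {root}")
    with open(path) as fh:
        manifest = json.load(fh)
    required = [
        "proteome.fasta", "motif_classes.tsv", "elm_instances.tsv",
        "clinvar.tsv", "gnomad.tsv", "gene_meta.tsv", "models.tsv",
        "ss.tsv", "go.obo", "go_annotations.tsv",
    ]
    for name in required:
        if not (root / name).exists():
            raise FileNotFoundError(f"bundle file missing: {name}")
    for m in manifest["models"]:
        for rel in (f"models/{m['model_id']}.pdb", f"ddg/{m['model_id']}.tsv"):
            if not (root / rel).exists():
                raise FileNotFoundError(f"bundle file missing: {rel}")
    return manifest
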
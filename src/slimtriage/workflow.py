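"""End-to-end runs: load a bundle directory, triage, emit verdicts.

A *bundle* is a directory of standard text files (the layout written by
:mod:`slimtriage.fixtures` and documented in the README): proteome FASTA,
motif-class TSV, validated instances, ClinVar-/gnomAD-style variant tables,
gene metadata, structure models with metadata and per-model ddG tables, and
the feature inputs (MSAs, secondary structure, SASA, GO).  Real data
prepared in the same layout runs through the identical code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .evaluation import build_confusion, compute_metrics, holdout_split
from .features import (
    FeatureSet,
    build_reference_profile,
    classify_exposure,
    default_sasa_thresholds,
    motif_conservation,
    ss_profile,
)
from .matrices import SASMatrix, average_ddg, parse_positionscan, tolerance_from_ddg
from .modelqc import ModelVerdict, gate_model, read_model_metadata, read_structure_model
from .motifs import MotifClass, read_motif_classes, read_proteome, scan_proteome
from .pipeline import (
    Candidate,
    TriageResult,
    TriageSession,
    per_variant_verdicts,
    run_pipeline,
)
from .variants import (
    PATHOGENIC_CLASSES,
    VariantCall,
    attach_variants,
    classify_variant,
    dedupe_clinvar,
    gene_af_threshold,
    read_clinvar_table,
    read_gene_metadata,
    read_gnomad_table,
)

__all__ = ["RunResult", "load_ontology", "run_bundle", "evaluate_bundle"]


@dataclass
class RunResult:
    """Everything a bundle run produced."""

    result: TriageResult
    verdicts: pd.DataFrame
    session: TriageSession
    candidates: list[Candidate]
    s0: list[Candidate]
    p0: list[Candidate]
    n_initial: int
    model_verdicts: list[ModelVerdict] = field(default_factory=list)

    def write_outputs(self, directory) -> None:
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        by_key = {c.key: c for c in self.candidates}
        rows = []
        for which, keys in [
            ("positive", self.result.final_positives),
            ("negative", self.result.final_negatives),
            ("remaining", self.result.final_remaining),
        ]:
            for key in keys:
                c = by_key.get(key)
                m = c.annotated.match if c else None
                rows.append(
                    {
                        "match": key,
                        "set": which,
                        "protein_id": m.protein_id if m else "",
                        "motif_class": m.motif_class if m else "",
                        "start": m.start if m else "",
                        "end": m.end if m else "",
                        "sequence": m.sequence if m else "",
                    }
                )
        pd.DataFrame(rows).to_csv(out / "triage_sets.tsv", sep="\t", index=False)
        self.verdicts.to_csv(out / "variant_verdicts.tsv", sep="\t", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            fh.write(self.result.to_json())


def load_ontology(path):
    import obonet

    return obonet.read_obo(str(path))


def _feature_set(
    root: Path,
    match,
    proteome: dict[str, str],
    ss_table: dict[str, str],
    go_terms: dict[str, set[str]],
    config: PipelineConfig,
) -> FeatureSet | None:
    pid = match.protein_id
    msa_path = root / "msa" / f"{pid}.fasta"
    sasa_path = root / "sasa" / f"{pid}.tsv"
    if not msa_path.exists() and pid not in ss_table and not sasa_path.exists():
        return None
    conservation = None
    if msa_path.exists():
        from Bio import SeqIO

        rows = [(r.id, str(r.seq)) for r in SeqIO.parse(str(msa_path), "fasta")]
        conservation = motif_conservation(rows, pid, match.start, match.end)
    ss_fractions = None
    if pid in ss_table:
        ss_fractions = ss_profile(ss_table[pid], match)
    exposure = None
    if sasa_path.exists():
        df = pd.read_csv(sasa_path, sep="\t")
        sub = df[(df["position"] >= match.start) & (df["position"] <= match.end)]
        sub = sub.sort_values("position")
        exposure = classify_exposure(
            sub["sasa"].tolist(),
            "".join(sub["residue"]),
            default_sasa_thresholds(config.sasa_relative_cutoff),
        )
    return FeatureSet(
        conservation=conservation,
        ss_fractions=ss_fractions,
        exposure=exposure,
        go_terms=frozenset(go_terms.get(pid, ())),
    )


def _build_calls(root: Path, config: PipelineConfig) -> list[VariantCall]:
    clinvar = dedupe_clinvar(read_clinvar_table(root / "clinvar.tsv"))
    gnomad = read_gnomad_table(root / "gnomad.tsv")
    gene_meta = read_gene_metadata(root / "gene_meta.tsv")

    pathogenic_by_gene: dict[str, list] = {}
    for ev in clinvar:
        if ev.clinical_class in PATHOGENIC_CLASSES:
            pathogenic_by_gene.setdefault(ev.protein_id, []).append(ev)

    def threshold_for(pid: str):
        meta = gene_meta.get(pid, {"inheritance": "unknown", "disease_associated": False})
        return gene_af_threshold(
            pathogenic_by_gene.get(pid, []),
            inheritance=meta["inheritance"],
            disease_associated=meta["disease_associated"],
            protein_id=pid,
        )

    evidence = {ev.key: ev for ev in gnomad}
    evidence.update({ev.key: ev for ev in clinvar})  # clinical assertion wins
    return [
        classify_variant(ev, threshold_for(ev.protein_id))
        for ev in sorted(evidence.values(), key=lambda e: e.key)
    ]


def _build_structures(
    root: Path, motifs: dict[str, MotifClass], config: PipelineConfig
) -> tuple[dict[str, SASMatrix], dict[str, SASMatrix], list[ModelVerdict]]:
    tolerance: dict[str, SASMatrix] = {}
    ddg_mats: dict[str, SASMatrix] = {}
    verdicts: list[ModelVerdict] = []
    models_path = root / "models.tsv"
    if not models_path.exists():
        return tolerance, ddg_mats, verdicts
    meta = read_model_metadata(models_path)
    accepted_by_class: dict[str, dict[str, list]] = {}
    source_by_class: dict[str, str] = {}
    for row in meta.itertuples():
        model = read_structure_model(
            root / "models" / f"{row.model_id}.pdb",
            model_id=row.model_id,
            source=row.source,
            motif_chain=row.motif_chain,
            motif_range=(int(row.motif_start), int(row.motif_end)),
            interaction_energy=float(row.interaction_energy),
            motif_class=row.motif_class,
        )
        verdict = gate_model(model, config.plddt_min, config.energy_max)
        verdicts.append(verdict)
        source_by_class.setdefault(row.motif_class, row.source)
        if verdict.accepted:
            records = parse_positionscan(
                root / "ddg" / f"{row.model_id}.tsv", structure_id=row.model_id
            )
            accepted_by_class.setdefault(row.motif_class, {})[row.model_id] = records
    for cls, tables in accepted_by_class.items():
        if cls not in motifs:
            warnings.warn(f"models for unknown motif class {cls!r}; skipped")
            continue
        some = next(iter(tables.values()))
        reference = "".join(
            r.ref_aa
            for r in sorted({rec.position: rec for rec in some}.values(), key=lambda r: r.position)
        )
        avg = average_ddg(
            tables,
            cls,
            motifs[cls].length,
            source=source_by_class[cls],
            reference=reference or None,
        )
        ddg_mats[cls] = avg
        tolerance[cls] = tolerance_from_ddg(avg, thresholds=config.ddg_thresholds)
    return tolerance, ddg_mats, verdicts


def run_bundle(
    directory,
    config: PipelineConfig | None = None,
    calls: list[VariantCall] | None = None,
) -> RunResult:
    """Load every input under *directory* and run the full triage pipeline.

    *calls* overrides the variant calls built from the bundle's tables
    (used by hold-out evaluation to keep evaluation variants out of the
    matrices).
    """
    root = Path(directory)
    config = config or PipelineConfig()
    proteome = read_proteome(root / "proteome.fasta")
    motif_list = read_motif_classes(root / "motif_classes.tsv")
    motifs = {m.identifier: m for m in motif_list}
    initial = scan_proteome(proteome, motif_list)
    if calls is None:
        calls = _build_calls(root, config)
    annotated = attach_variants(initial, calls, proteome)

    p0_df = pd.read_csv(root / "elm_instances.tsv", sep="\t", dtype={"protein_id": str})
    p0_keys = {
        f"{r.protein_id}:{r.motif_class}:{r.start}-{r.end}" for r in p0_df.itertuples()
    }

    ss_table: dict[str, str] = {}
    ss_path = root / "ss.tsv"
    if ss_path.exists():
        df = pd.read_csv(ss_path, sep="\t", dtype=str)
        ss_table = dict(zip(df["protein_id"], df["ss"]))
    go_terms: dict[str, set[str]] = {}
    go_path = root / "go_annotations.tsv"
    if go_path.exists():
        df = pd.read_csv(go_path, sep="\t", dtype=str)
        for r in df.itertuples():
            go_terms.setdefault(r.protein_id, set()).add(r.term)
    ontology = load_ontology(root / "go.obo") if (root / "go.obo").exists() else None

    candidates: list[Candidate] = []
    for am in annotated:
        features = _feature_set(root, am.match, proteome, ss_table, go_terms, config)
        candidates.append(
            Candidate(annotated=am, features=features, is_p0=am.match.key in p0_keys)
        )
    p0 = [c for c in candidates if c.is_p0]
    s0 = [c for c in candidates if c.annotated.has_calls and not c.is_p0]

    tolerance, ddg_mats, model_verdicts = _build_structures(root, motifs, config)
    profiles = {}
    for cls in motifs:
        feats = [c.features for c in p0 if c.motif_class == cls and c.features]
        if feats:
            profiles[cls] = build_reference_profile(feats)
    session = TriageSession(
        motifs=motifs,
        tolerance_matrices=tolerance,
        reference_profiles=profiles,
        ontology=ontology,
        config=config,
        ddg_matrices=ddg_mats,
    )
    result = run_pipeline(s0, p0, session)
    verdicts = per_variant_verdicts(result, candidates, session)
    return RunResult(
        result=result,
        verdicts=verdicts,
        session=session,
        candidates=candidates,
        s0=s0,
        p0=p0,
        n_initial=len(initial),
        model_verdicts=model_verdicts,
    )


def evaluate_bundle(
    directory,
    config: PipelineConfig | None = None,
    fraction: float = 0.2,
    seed: int = 0,
):
    """Hold-out evaluation on a bundle.

    A stratified 20% (by label) of the classified variants is set aside;
    the pipeline and all matrices are built from the rest, and the held-out
    variants inside final-positive motifs are scored through the final
    matrices.  Returns (RunResult, confusion, MetricReport, n_evaluable).
    """
    root = Path(directory)
    config = config or PipelineConfig()
    all_calls = _build_calls(root, config)
    labeled = [c for c in all_calls if c.label in ("pathogenic", "benign")]
    rest = [c for c in all_calls if c.label == "unresolved"]
    working, held = holdout_split(
        labeled, [c.label for c in labeled], fraction=fraction, seed=seed
    )
    run = run_bundle(directory, config, calls=working + rest)

    held_keys = {c.evidence.key: c for c in held}
    eval_verdicts = _score_held_out(run, held)
    truths = {k: held_keys[k].label for k in eval_verdicts}
    confusion = build_confusion(eval_verdicts, truths)
    report = compute_metrics(confusion) if confusion.n_total else None
    return run, confusion, report, len(eval_verdicts)


def _score_held_out(run: RunResult, held: list[VariantCall]) -> dict:
    """Verdicts for held-out variants that land in final-positive motifs."""
    from .matrices import NON_TOLERATED, TOLERATED, final_matrix, final_verdicts

    positives = set(run.result.final_positives)
    session = run.session
    mats = {}
    for cls in session.motifs:
        clinical = session.clinical_matrix(cls)
        ddg = session.ddg_matrices.get(cls)
        if clinical is None and ddg is None:
            continue
        scores = final_matrix(clinical, ddg, thresholds=session.config.ddg_thresholds)
        mats[cls] = final_verdicts(scores, tau=session.config.final_tau)
    out = {}
    for cand in run.candidates:
        if cand.key not in positives or cand.motif_class not in mats:
            continue
        verdict_matrix = mats[cand.motif_class]
        for call in held:
            ev = call.evidence
            if ev.protein_id != cand.annotated.match.protein_id:
                continue
            pos = cand.annotated.match.motif_position(ev.position)
            if pos is None:
                continue
            v = verdict_matrix.cell(pos, ev.alt_aa)
            out[ev.key] = (
                "pathogenic"
                if v == NON_TOLERATED
                else "benign" if v == TOLERATED else "uncertain"
            )
    return out
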
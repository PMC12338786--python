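"""Three-cycle iterative triage of candidate motifs.

Candidates carrying at least one interpretable variant (set S0) are
partitioned against the evidence of the validated positive instances (P0)
in three sequential cycles:

1. **Clinical significance cycle (CSC)** — variants at *rigid* motif
   positions are checked against the clinical-confidence matrix built from
   the P0 variants.
2. **Structural analysis cycle (SAC)** — the survivors' rigid-position
   variants are checked against the ddG-derived tolerance matrix of the
   class (from quality-gated structures).
3. **Flexible position cycle (FPC)** — finally, variants at *flexible*
   positions are checked against the same tolerance matrix.

In every cycle a candidate whose informative variants all agree with the
matrix — and whose conservation / secondary-structure / exposure / GO
features match the P0 envelope — joins the positive set; one contradicting
variant sends it to the negative set; anything else remains.  Newly accepted
candidates' variants refine the clinical matrices before the next iteration,
and each cycle iterates until the positive set stops growing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .features import FeatureSet, ReferenceProfile, feature_gate
from .matrices import (
    NON_TOLERATED,
    TOLERATED,
    SASMatrix,
    build_clinical_matrix,
    final_matrix,
    final_verdicts,
)
from .motifs import MotifClass
from .variants import AnnotatedMatch, VariantCall

CYCLE_NAMES = {1: "CSC", 2: "SAC", 3: "FPC"}

__all__ = [
    "CYCLE_NAMES",
    "Candidate",
    "DecisionRecord",
    "TriageResult",
    "evaluate_match",
    "TriageSession",
    "run_pipeline",
    "per_variant_verdicts",
]


@dataclass
class Candidate:
    """One annotated motif match entering triage."""

    annotated: AnnotatedMatch
    features: FeatureSet | None = None
    is_p0: bool = False

    @property
    def key(self) -> str:
        return self.annotated.match.key

    @property
    def motif_class(self) -> str:
        return self.annotated.match.motif_class

    @property
    def calls(self) -> list[tuple[int, VariantCall]]:
        return self.annotated.calls


@dataclass(frozen=True)
class DecisionRecord:
    match_key: str
    cycle: int
    iteration: int
    decision: str  # positive | negative | remaining | seed-positive
    rule: str
    n_calls_consulted: int = 0


@dataclass
class TriageResult:
    """Per-cycle P/N/R partition with full decision provenance."""

    cycles: dict[int, dict[str, list[str]]]
    iterations: dict[int, int]
    decision_log: list[DecisionRecord]
    config: PipelineConfig

    @property
    def final_positives(self) -> list[str]:
        out: list[str] = []
        for x in sorted(self.cycles):
            out.extend(self.cycles[x]["P"])
        return sorted(set(out))

    @property
    def final_negatives(self) -> list[str]:
        out: list[str] = []
        for x in sorted(self.cycles):
            out.extend(self.cycles[x]["N"])
        return sorted(set(out))

    @property
    def final_remaining(self) -> list[str]:
        last = max(self.cycles)
        return sorted(self.cycles[last]["R"])

    def to_json(self) -> str:
        payload = {
            "cycles": {
                str(x): {k: sorted(v) for k, v in sets.items()}
                for x, sets in self.cycles.items()
            },
            "iterations": {str(k): v for k, v in self.iterations.items()},
            "seed": self.config.seed,
            "decisions": [
                {
                    "match": d.match_key,
                    "cycle": d.cycle,
                    "iteration": d.iteration,
                    "decision": d.decision,
                    "rule": d.rule,
                    "n_calls": d.n_calls_consulted,
                }
                for d in self.decision_log
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def evaluate_match(
    calls: Sequence[tuple[int, VariantCall]],
    matrix: SASMatrix,
    positions: Iterable[int],
) -> str:
    """Judge a candidate's calls against one matrix layer.

    Only calls at the given motif positions are consulted.  Against a
    clinical layer, a pathogenic call agrees with a positive cell sum and
    contradicts a negative one (benign: mirrored); empty or zero-sum cells
    are uninformative.  Against a tolerance layer, pathogenic agrees with
    non-tolerated, benign with tolerated; unknown cells are uninformative.
    Returns "contradicted" iff any consulted call disagrees, else
    "consistent" iff at least one agrees, else "uninformative".
    """
    if matrix.layer not in ("clinical", "tolerance"):
        raise ValueError(f"cannot evaluate against layer {matrix.layer!r}")
    wanted = set(positions)
    n_agree = n_disagree = 0
    for pos, call in calls:
        if pos not in wanted or call.label == "unresolved":
            continue
        cell = matrix.cell(pos, call.evidence.alt_aa)
        if matrix.layer == "clinical":
            if pd.isna(cell) or cell == 0:
                continue
            cell_intolerant = cell > 0
        else:
            if cell == TOLERATED:
                cell_intolerant = False
            elif cell == NON_TOLERATED:
                cell_intolerant = True
            else:
                continue
        if (call.label == "pathogenic") == cell_intolerant:
            n_agree += 1
        else:
            n_disagree += 1
    if n_disagree:
        return "contradicted"
    if n_agree:
        return "consistent"
    return "uninformative"


class TriageSession:
    """Holds per-class matrices and reference profiles across the cycles."""

    def __init__(
        self,
        motifs: Mapping[str, MotifClass],
        tolerance_matrices: Mapping[str, SASMatrix] | None = None,
        reference_profiles: Mapping[str, ReferenceProfile] | None = None,
        ontology=None,
        config: PipelineConfig | None = None,
        ddg_matrices: Mapping[str, SASMatrix] | None = None,
    ) -> None:
        self.motifs = dict(motifs)
        self.tolerance_matrices = dict(tolerance_matrices or {})
        self.ddg_matrices = dict(ddg_matrices or {})
        self.reference_profiles = dict(reference_profiles or {})
        self.ontology = ontology
        self.config = config or PipelineConfig()
        self._clinical_calls: dict[str, list[tuple[int, VariantCall]]] = {
            cls: [] for cls in self.motifs
        }
        self._gate_cache: dict[str, bool] = {}
        self.warnings: list[str] = []

    def fold_calls(self, candidate: Candidate) -> None:
        """Fold an accepted candidate's calls into its class clinical matrix."""
        self._clinical_calls.setdefault(candidate.motif_class, []).extend(
            candidate.calls
        )

    def clinical_matrix(self, motif_class: str) -> SASMatrix | None:
        calls = self._clinical_calls.get(motif_class)
        if not calls:
            return None
        return build_clinical_matrix(calls, self.motifs[motif_class])

    def matrix_for(self, motif_class: str, layer: str) -> SASMatrix | None:
        if layer == "clinical":
            return self.clinical_matrix(motif_class)
        return self.tolerance_matrices.get(motif_class)

    def features_pass(self, candidate: Candidate) -> bool:
        """Feature-gate verdict, cached: a failure is final across cycles."""
        if candidate.key in self._gate_cache:
            return self._gate_cache[candidate.key]
        profile = self.reference_profiles.get(candidate.motif_class)
        if candidate.features is None or profile is None:
            verdict = True  # no feature evidence against the candidate
        else:
            verdict = feature_gate(candidate.features, profile, self.ontology).passed
        self._gate_cache[candidate.key] = verdict
        return verdict

    def run_cycle(
        self,
        cycle: int,
        inputs: Sequence[Candidate],
        layer: str,
        positions_kind: str,
        log: list[DecisionRecord],
    ) -> tuple[list[Candidate], list[Candidate], list[Candidate]]:
        """One triage cycle, iterated to convergence.

        Returns (P, N, R) over *inputs*.  Candidates evaluate against the
        cycle's matrix layer at rigid or flexible positions; accepted ones
        refine the clinical matrices before the next iteration.
        """
        remaining = sorted(inputs, key=lambda c: c.key)
        positives: list[Candidate] = []
        negatives: list[Candidate] = []
        iteration = 0
        while True:
            iteration += 1
            if iteration > self.config.max_iterations:
                self.warnings.append(
                    f"cycle {cycle}: iteration cap {self.config.max_iterations} "
                    "reached; returning partial result"
                )
                iteration -= 1
                break
            new_p: list[Candidate] = []
            new_n: list[Candidate] = []
            still: list[Candidate] = []
            for cand in remaining:
                motif = self.motifs.get(cand.motif_class)
                matrix = self.matrix_for(cand.motif_class, layer)
                if motif is None or matrix is None:
                    if iteration == 1:
                        self.warnings.append(
                            f"{cand.key}: no {layer} matrix for class "
                            f"{cand.motif_class}; passed through"
                        )
                    still.append(cand)
                    continue
                positions = (
                    motif.rigid_indices
                    if positions_kind == "rigid"
                    else motif.flexible_indices
                )
                status = evaluate_match(cand.calls, matrix, positions)
                n_consulted = sum(1 for p, _ in cand.calls if p in set(positions))
                if status == "contradicted":
                    new_n.append(cand)
                    log.append(
                        DecisionRecord(
                            cand.key, cycle, iteration, "negative",
                            f"{layer}-matrix contradiction at {positions_kind} positions",
                            n_consulted,
                        )
                    )
                elif status == "consistent" and self.features_pass(cand):
                    new_p.append(cand)
                    log.append(
                        DecisionRecord(
                            cand.key, cycle, iteration, "positive",
                            f"{layer}-matrix agreement at {positions_kind} positions"
                            " + feature gates",
                            n_consulted,
                        )
                    )
                else:
                    still.append(cand)
            for cand in new_p:
                self.fold_calls(cand)
            positives.extend(new_p)
            negatives.extend(new_n)
            remaining = still
            if not new_p:
                break
        self.iterations_run = iteration
        for cand in remaining:
            log.append(
                DecisionRecord(
                    cand.key, cycle, iteration, "remaining",
                    "no informative agreeing variant (or feature gate failed)",
                    len(cand.calls),
                )
            )
        return positives, negatives, remaining


def run_pipeline(
    s0: Sequence[Candidate],
    p0: Sequence[Candidate],
    session: TriageSession,
) -> TriageResult:
    """Run CSC, SAC and FPC sequentially over the candidate set S0.

    *p0* are the validated instances: they seed the clinical matrices,
    bypass evaluation, and are reported inside the cycle-1 positive set.
    Final positives are P1 u P2 u P3, final negatives N1 u N2 u N3, and the
    final remaining set is R3.
    """
    log: list[DecisionRecord] = []
    p0_keys = {c.key for c in p0}
    for cand in p0:
        session.fold_calls(cand)
        log.append(
            DecisionRecord(cand.key, 1, 0, "seed-positive", "validated P0 instance")
        )
    inputs = sorted((c for c in s0 if c.key not in p0_keys), key=lambda c: c.key)
    for cand in inputs:
        if not cand.annotated.has_calls:
            raise ValueError(f"{cand.key}: S0 members must carry at least one call")

    cycles: dict[int, dict[str, list[str]]] = {}
    iterations: dict[int, int] = {}

    plan = [(1, "clinical", "rigid"), (2, "tolerance", "rigid"), (3, "tolerance", "flexible")]
    current = inputs
    for cycle, layer, positions_kind in plan:
        P, N, R = session.run_cycle(cycle, current, layer, positions_kind, log)
        p_keys = sorted(c.key for c in P)
        if cycle == 1:
            p_keys = sorted(set(p_keys) | p0_keys)
        cycles[cycle] = {
            "P": p_keys,
            "N": sorted(c.key for c in N),
            "R": sorted(c.key for c in R),
        }
        iterations[cycle] = session.iterations_run
        current = R
    return TriageResult(
        cycles=cycles,
        iterations=iterations,
        decision_log=log,
        config=session.config,
    )


def per_variant_verdicts(
    result: TriageResult,
    candidates: Sequence[Candidate],
    session: TriageSession,
) -> pd.DataFrame:
    """Final verdict table for every motif-located variant.

    Variants inside final-positive motifs are called through the class's
    final-score matrix (clinical sums + capped ddG confidence) and the tau
    rule; variants in non-positive motifs are flagged out of scope rather
    than called.  Columns: protein_id, position, ref_aa, alt_aa, motif
    identity and coordinates, verdict, score.
    """
    positives = set(result.final_positives)
    final_mats: dict[str, tuple[SASMatrix, SASMatrix]] = {}
    for cls in session.motifs:
        clinical = session.clinical_matrix(cls)
        ddg = session.ddg_matrices.get(cls)
        if clinical is None and ddg is None:
            continue
        scores = final_matrix(clinical, ddg, thresholds=session.config.ddg_thresholds)
        final_mats[cls] = (scores, final_verdicts(scores, tau=session.config.final_tau))
    rows = []
    for cand in candidates:
        in_scope = cand.key in positives
        mats = final_mats.get(cand.motif_class)
        for pos, call in cand.calls:
            ev = call.evidence
            verdict, score = "out-of-scope", float("nan")
            if in_scope and mats is not None:
                scores, verdicts = mats
                cell = scores.cell(pos, ev.alt_aa)
                v = verdicts.cell(pos, ev.alt_aa)
                if v == NON_TOLERATED:
                    verdict = "pathogenic"
                elif v == TOLERATED:
                    verdict = "benign"
                else:
                    verdict = "uncertain"
                score = float(cell) if not pd.isna(cell) else float("nan")
            rows.append(
                {
                    "protein_id": ev.protein_id,
                    "position": ev.position,
                    "ref_aa": ev.ref_aa,
                    "alt_aa": ev.alt_aa,
                    "motif_class": cand.motif_class,
                    "match": cand.key,
                    "motif_position": pos,
                    "verdict": verdict,
                    "score": score,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "position", "ref_aa", "alt_aa", "motif_class",
            "match", "motif_position", "verdict", "score",
        ],
    )
    return df.sort_values(["protein_id", "position", "alt_aa", "match"]).reset_index(
        drop=True
    )
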
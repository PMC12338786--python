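"""Quality-gate predicted motif-receptor models.

A predicted complex is trusted only when the mean pLDDT of the motif
residues exceeds 65 and the motif-receptor interaction energy is below
-5 kcal/mol; both comparisons are strict.
"""

from slimtriage import gate_model, motif_mean_plddt, rank_accepted_models
from slimtriage.modelqc import StructureModel


def model(model_id, plddts, energy):
    table = {("B", 101 + i): v for i, v in enumerate(plddts)}
    return StructureModel(model_id, "af2", "B", (101, 100 + len(plddts)),
                          energy, table)


candidates = [
    model("pose1", [84, 81, 86, 80], -12.4),   # confident, tight binder
    model("pose2", [42, 39, 45, 38], -3.0),    # low confidence, weak binder
    model("pose3", [66, 64, 67, 65], -5.2),    # borderline
]
verdicts = []
for m in candidates:
    v = gate_model(m)
    verdicts.append(v)
    print(f"{m.model_id}: mean motif pLDDT {motif_mean_plddt(m):5.1f}, "
          f"energy {m.interaction_energy:6.1f} kcal/mol -> "
          f"{'ACCEPTED' if v.accepted else 'rejected'}")

ranked = rank_accepted_models(verdicts, {}, [])
print("\naccepted models ranked by interaction energy:",
      [v.model_id for v in ranked])
print("Only accepted models contribute their ddG matrices to the pipeline.")
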
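"""Convert variant evidence into signed confidence scores.

Clinical classifications score stars + 0.1 x submissions with the sign of
the classification side; population allele frequencies above the per-gene
threshold score benign on a capped log scale.
"""

from slimtriage import (
    classify_variant,
    clinical_confidence_score,
    gene_af_threshold,
    gnomad_confidence_score,
)
from slimtriage.variants import VariantEvidence

print("clinical scores (sign: + pathogenic-side, - benign-side):")
print("  Pathogenic, 2 stars, 3 submissions ->",
      clinical_confidence_score("Pathogenic", 2, 3))
print("  Benign, 1 star, 1 submission      ->",
      clinical_confidence_score("Benign", 1, 1))

thr = gene_af_threshold([], inheritance="AD")
print(f"\nallele-frequency threshold for a sparse autosomal-dominant gene: "
      f"{thr.threshold:.3g} ({thr.basis})")
print("  AF = threshold     ->", gnomad_confidence_score(thr.threshold, thr.threshold))
print("  AF = 10x threshold ->",
      gnomad_confidence_score(10 * thr.threshold, thr.threshold), "(capped)")

ev = VariantEvidence("LDLR", 826, "P", "S", "clinvar",
                     clinical_class="Pathogenic", stars=2, submissions=3)
call = classify_variant(ev, thr)
print(f"\nclassified {ev.ref_aa}{ev.position}{ev.alt_aa}: "
      f"label={call.label}, confidence={call.confidence:+.1f}")
print("A positive confidence is evidence the substitution disrupts the motif.")
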
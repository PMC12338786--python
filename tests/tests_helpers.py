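"""Small shared constructors for test objects."""

from slimtriage.variants import VariantCall, VariantEvidence


def pathogenic_call(alt, pid="P1", pos=10, ref="N", confidence=2.0):
    ev = VariantEvidence(
        pid, pos, ref, alt, "clinvar", clinical_class="Pathogenic", stars=2
    )
    return VariantCall(ev, "pathogenic", confidence)


def benign_call(alt, pid="P1", pos=10, ref="N", confidence=-1.0):
    ev = VariantEvidence(
        pid, pos, ref, alt, "clinvar", clinical_class="Benign", stars=1
    )
    return VariantCall(ev, "benign", confidence)


def unresolved_call(alt, pid="P1", pos=10, ref="N"):
    ev = VariantEvidence(pid, pos, ref, alt, "gnomad", allele_frequency=1e-9)
    return VariantCall(ev, "unresolved", 0.0)
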
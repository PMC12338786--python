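"""Scan protein sequences for short-linear-motif candidates.

Compiles two ELM-style fixed-length patterns and scans a toy proteome,
printing every match with its coordinates and rigid/flexible typing.
"""

from slimtriage import compile_motif_pattern, scan_proteome

ptb = compile_motif_pattern("NP.[YF]", identifier="LIG_PTB_like")
cam = compile_motif_pattern("W[^P][^P][^P][IL][^P][AGS][AT]", identifier="LIG_CaM_like")

for motif in (ptb, cam):
    print(f"{motif.identifier}: length {motif.length}, "
          f"rigid positions {motif.rigid_indices}, flexible {motif.flexible_indices}")

proteome = {
    "PROT1": "MKNPAYQSTWLDKAIQGATVC",   # one PTB-type site at 3-6
    "PROT2": "GGNPQFNPAFCC",            # two overlapping-class hits
    "PROT3": "AAAAAAAA",                # background
}
matches = scan_proteome(proteome, [ptb, cam])
print(f"\n{len(matches)} matches (the Initial Set):")
for m in matches:
    print(f"  {m.protein_id}  {m.motif_class}  {m.start}-{m.end}  {m.sequence}")
print("\nEach line is one candidate motif; coordinates are 1-based inclusive.")
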
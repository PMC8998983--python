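"""Encode a protein's per-residue annotations into structural property words.

Each 4-letter word summarises one secondary-structure segment: structure
(A/B/C), majority solvent exposure (E/N), dominant residue class (G/T/D/K)
and a length bucket (S/M/L).
"""

from cpinet import ResidueAnnotation, encode_sps, render_sps, segment_protein

# a toy protein: an exposed basic helix, a buried hydrophobic strand, a loop
annotations = (
    [ResidueAnnotation("K", "alpha", True)] * 6
    + [ResidueAnnotation("L", "beta", False)] * 9
    + [ResidueAnnotation("G", "coil", True)] * 2
)

segments = segment_protein(annotations)
words = render_sps(encode_sps(annotations))

print(f"{len(annotations)} residues -> {len(words)} segments")
for (start, end, structure), word in zip(segments, words):
    print(f"  residues [{start:2d},{end:2d})  {structure:<5s} -> {word}")

# The helix reads AEKM: alpha, exposed, basic, medium (6 residues).
# The strand reads BNGL: beta, buried, non-polar, long (9 residues).
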
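"""Structural property sequence (SPS) encoding of proteins.

A protein is summarised as a sequence of 4-letter words, one per
secondary-structure segment, instead of one symbol per residue.  Each word
reads, in order:

1. secondary structure of the segment — A (alpha helix), B (beta strand),
   C (coil);
2. solvent exposure by per-residue majority — N (not exposed), E (exposed);
3. dominant physicochemical class of the residues — G (non-polar),
   T (polar), D (acidic), K (basic);
4. segment length bucket — S (short), M (medium), L (long).

The 3 x 2 x 4 x 3 product gives 72 legal words; the word "AEKM", for
example, is an exposed, predominantly basic alpha segment of medium length.
This compresses a protein roughly by the typical segment length while
keeping the structural layout readable, and it keeps recurrent encoders well
inside their stable sequence-length regime.

The per-residue annotations (secondary structure, exposure) are expected
from an external structure-annotation tool; this module only re-codes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

SS_LETTERS = {"alpha": "A", "beta": "B", "coil": "C"}
EXPOSURE_LETTERS = {False: "N", True: "E"}
PROPERTY_LETTERS = {"non-polar": "G", "polar": "T", "acidic": "D", "basic": "K"}
LENGTH_LETTERS = ("S", "M", "L")

# Residue physicochemical classes (config-overridable via classify_residue's
# ``table`` argument).  Glycine is grouped with the polar class here so the
# four classes cover all 20 standard residues.
DEFAULT_PROPERTY_TABLE: dict[str, str] = {}
for _aa in "DE":
    DEFAULT_PROPERTY_TABLE[_aa] = "acidic"
for _aa in "KRH":
    DEFAULT_PROPERTY_TABLE[_aa] = "basic"
for _aa in "STNQCYG":
    DEFAULT_PROPERTY_TABLE[_aa] = "polar"
for _aa in "AVLIPFMW":
    DEFAULT_PROPERTY_TABLE[_aa] = "non-polar"

# majority-vote tie-break priority for the property letter
PROPERTY_PRIORITY = ("acidic", "basic", "polar", "non-polar")

# segment length buckets (residue counts); unstated upstream, so these are
# package defaults: short <= 3, medium 4-7, long >= 8
DEFAULT_SHORT_MAX = 3
DEFAULT_LONG_MIN = 8

# 8-class secondary structure (DSSP letters) collapsed to 3 classes
SS8_TO_3 = {"H": "alpha", "G": "alpha", "I": "alpha",
            "E": "beta", "B": "beta",
            "C": "coil", "T": "coil", "S": "coil", "-": "coil"}
SS3 = {"H": "alpha", "E": "beta", "C": "coil"}


@dataclass(frozen=True)
class ResidueAnnotation:
    """One residue: amino acid, 3-class secondary structure, exposure flag."""

    amino_acid: str
    secondary_structure: str  # "alpha" | "beta" | "coil"
    exposed: bool

    def __post_init__(self):
        if self.secondary_structure not in SS_LETTERS:
            raise ValueError(f"bad secondary structure {self.secondary_structure!r}")


@dataclass(frozen=True)
class SPSWord:
    ss_letter: str
    exposure_letter: str
    property_letter: str
    length_letter: str

    def render(self) -> str:
        return self.ss_letter + self.exposure_letter + self.property_letter + self.length_letter


def classify_residue(aa: str, table: dict[str, str] | None = None,
                     strict: bool = True) -> str:
    """Physicochemical class of a one-letter residue code."""
    table = table or DEFAULT_PROPERTY_TABLE
    aa = aa.upper()
    if aa in table:
        return table[aa]
    if strict:
        raise ValueError(f"unknown residue code {aa!r}")
    return "non-polar"


def segment_protein(annotations: Sequence[ResidueAnnotation]) -> list[tuple[int, int, str]]:
    """Partition residues into runs of constant secondary structure.

    Returns half-open (start, end, structure) intervals that tile
    ``range(len(annotations))`` exactly.
    """
    if len(annotations) == 0:
        raise ValueError("empty protein")
    segments: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, len(annotations) + 1):
        if (i == len(annotations)
                or annotations[i].secondary_structure != annotations[start].secondary_structure):
            segments.append((start, i, annotations[start].secondary_structure))
            start = i
    return segments


def _length_letter(count: int, short_max: int, long_min: int) -> str:
    if count <= short_max:
        return "S"
    if count >= long_min:
        return "L"
    return "M"


def encode_sps(annotations: Sequence[ResidueAnnotation],
               short_max: int = DEFAULT_SHORT_MAX,
               long_min: int = DEFAULT_LONG_MIN,
               property_table: dict[str, str] | None = None) -> list[SPSWord]:
    """Encode per-residue annotations into one SPSWord per structural segment.

    Exposure and property letters are per-residue majority votes within the
    segment; ties resolve to exposed and, for the property, by the fixed
    priority acidic > basic > polar > non-polar so the encoding is
    deterministic.
    """
    words: list[SPSWord] = []
    for start, end, structure in segment_protein(annotations):
        run = annotations[start:end]
        n = len(run)
        exposed_count = sum(1 for r in run if r.exposed)
        exposure = EXPOSURE_LETTERS[exposed_count * 2 >= n]  # tie -> exposed
        votes = {cls: 0 for cls in PROPERTY_PRIORITY}
        for r in run:
            votes[classify_residue(r.amino_acid, property_table)] += 1
        best = max(PROPERTY_PRIORITY, key=lambda cls: (votes[cls], -PROPERTY_PRIORITY.index(cls)))
        words.append(SPSWord(
            ss_letter=SS_LETTERS[structure],
            exposure_letter=exposure,
            property_letter=PROPERTY_LETTERS[best],
            length_letter=_length_letter(n, short_max, long_min),
        ))
    return words


def render_sps(words: Iterable[SPSWord]) -> list[str]:
    return [w.render() for w in words]


def enumerate_sps_alphabet() -> list[str]:
    """All 72 legal SPS words, in the fixed column order of the letter table."""
    return ["".join(combo) for combo in product("ABC", "NE", "GTDK", "SML")]


def parse_ss_letter(letter: str) -> str:
    """Map an H/E/C (3-class) or DSSP 8-class letter to a structure category."""
    letter = letter.upper()
    if letter in SS3:
        return SS3[letter]
    if letter in SS8_TO_3:
        return SS8_TO_3[letter]
    raise ValueError(f"unknown secondary-structure letter {letter!r}")
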
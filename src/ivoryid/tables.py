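"""Embedded reference data for the 116 bp cytochrome b ivory assay.

The marker is an internal fragment of the mitochondrial cytochrome b gene
spanning rCRS positions 15124-15239 (the human revised Cambridge Reference
Sequence provides the coordinate frame), amplified by the elephantid-
universal degenerate primer pair L15123/H15240.  Three tables are embedded:

* the primer sequences (IUPAC codes R = A/G, Y = C/T);
* the haplotype variant table: per species/clade group, the states at the
  14 polymorphic positions of the fragment (``X/Y`` lists an intraspecific
  polymorphism, first allele first);
* the primer-region panel: for 13 species, the template bases in the two
  22 nt primer-binding regions, written against the primer 5'->3' with a
  dot for "identical to the primer".

The four elephantid groups used for assignment are Asian elephant
(E. maximus), S-clade savanna elephant (L. africana), the Loxodonta F clade
(all forest elephants plus introgressed savanna elephants) and woolly
mammoth (M. primigenius).
"""

from __future__ import annotations

import re

# --- coordinate frame -------------------------------------------------------

RCRS_INSERT_START = 15124  # first base of the 116 bp insert (1-based, rCRS)
RCRS_INSERT_END = 15239    # last base of the insert
INSERT_LENGTH = 116
PRIMER_LENGTH = 22
AMPLICON_LENGTH = 160      # 22 + 116 + 22

# --- primers ----------------------------------------------------------------

FORWARD_PRIMER_NAME = "L15123"
FORWARD_PRIMER = "TACTACTRATYACYATAGCCAC"
REVERSE_PRIMER_NAME = "H15240"
REVERSE_PRIMER = "TTATCTACYGAAAAGCCTCCTC"

# --- species / group labels -------------------------------------------------

ASIAN_ELEPHANT = "E. maximus"
SAVANNA_ELEPHANT = "L. africana"
FOREST_ELEPHANT = "L. cyclotis"
WOOLLY_MAMMOTH = "M. primigenius"

# Assignment groups (the resolution of the assay; F-clade calls are
# genus-level because forest and introgressed savanna elephants share
# forest-derived mtDNA and cannot be separated on this marker).
GROUP_EMAX = "E. maximus"
GROUP_LAFR_S = "L. africana (S clade)"
GROUP_LOX_F = "Loxodonta F clade (forest or introgressed savanna)"
GROUP_MPRI = "M. primigenius"
GROUP_UNASSIGNED = "unassigned"

ASSIGNMENT_GROUPS = (GROUP_EMAX, GROUP_LAFR_S, GROUP_LOX_F, GROUP_MPRI)

# --- haplotype variant table ------------------------------------------------

TABLE1_POSITIONS = (
    15124, 15148, 15151, 15160, 15184, 15190, 15193,
    15205, 15208, 15210, 15211, 15221, 15222, 15238,
)

# (species, clade) -> states at TABLE1_POSITIONS.  "X/Y" = intraspecific
# polymorphism (within that group); a single letter is fixed in the group.
TABLE1_GROUPS: dict[tuple[str, str | None], tuple[str, ...]] = {
    (FOREST_ELEPHANT, "F"): (
        "T/C", "G", "G/A", "A/G", "C", "C", "C",
        "T", "C", "A", "C", "A", "G/A", "C",
    ),
    (SAVANNA_ELEPHANT, "F"): (
        "C", "G", "A/G", "A/G", "C", "C", "C",
        "T", "C", "A", "C", "A", "A/G", "C",
    ),
    (SAVANNA_ELEPHANT, "S"): (
        "C", "G", "A", "A", "C", "C", "T",
        "C", "T", "A/G", "T", "A", "A", "C",
    ),
    (WOOLLY_MAMMOTH, None): (
        "C", "G", "A", "A", "C", "C/T", "C",
        "T", "C", "A", "C", "G", "A", "C",
    ),
    (ASIAN_ELEPHANT, None): (
        "C", "A", "A", "A", "T", "C", "C",
        "T", "C", "A", "C", "A", "A", "T",
    ),
}

# --- primer-region panel ----------------------------------------------------

# species -> (forward-region row, reverse-region row); rows are written
# against the primer 5'->3' ("." = identical to the primer base, "X/Y" =
# polymorphic in that species).  The reverse row is in primer orientation,
# i.e. it reads the template minus strand.
TABLE3_ROWS: dict[str, tuple[str, str]] = {
    ASIAN_ELEPHANT: (".......A..C/T..C........", "........C............."),
    SAVANNA_ELEPHANT: (".......A..C..C........", "........C/T............."),
    FOREST_ELEPHANT: (".......A/G..C..C/T........", "........C............."),
    WOOLLY_MAMMOTH: (".......A..C..C........", "........C/T............."),
    "H. amphibius": (".......C.CA..C.....T..", "..G.....G............."),
    "M. monoceros": (".......A..A.TC........", "........A.....C..A...."),
    "P. aethiopicus": (".......C.CTGTT.....A..", "..G.....A..G..A..C...."),
    "P. catodon": (".C...A.C.CAGTA........", "........G..G..A..G...."),
    "O. orca": (".......AGCAGTT........", "........G.....C..A...."),
    "O. rosmarus": ("..T....C.CT.TT........", ".....A..T.....C..C...."),
    "C. simum": (".....T.C.CTCTA........", ".....A..G.....T......."),
    "B. taurus": (".T..GT.C.CAGTA........", "........T..G..T..G...."),
    "H. sapiens": (".C..G..TGCA..T.....A..", "C.G.....T..GT........."),
}

ELEPHANTID_SPECIES = (
    ASIAN_ELEPHANT, SAVANNA_ELEPHANT, FOREST_ELEPHANT, WOOLLY_MAMMOTH,
)
NONTARGET_SPECIES = tuple(
    sp for sp in TABLE3_ROWS if sp not in ELEPHANTID_SPECIES
)

_TOKEN_RE = re.compile(r"[ACGT]/[ACGT]|[ACGT]|\.")


def tokenize_primer_region_row(row: str) -> list[str]:
    """Split a dotted primer-region row into 22 per-position tokens."""
    tokens = _TOKEN_RE.findall(row)
    if "".join(tokens) != row or len(tokens) != PRIMER_LENGTH:
        raise ValueError(f"malformed primer-region row: {row!r}")
    return tokens


def _check_tables() -> None:
    for states in TABLE1_GROUPS.values():
        assert len(states) == len(TABLE1_POSITIONS)
    for fwd, rev in TABLE3_ROWS.values():
        tokenize_primer_region_row(fwd)
        tokenize_primer_region_row(rev)


_check_tables()
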
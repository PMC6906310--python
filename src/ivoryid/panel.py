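"""Reference panel: reconstructed 116 bp haplotypes and primer regions.

The panel reconstructs, from the embedded variant table, every combination
of the intraspecific variants within each species/clade group (Cartesian
expansion), laid over a shared constant background.  Only the tabulated
polymorphic positions carry real sequence information; the background is a
synthetic placeholder (all ``A``, which deamination cannot alter) and one
background position is marked ``N`` by default so that pairwise-deletion
distances run over 115 compared sites, the denominator under which the
published distance extremes reproduce exactly.

Coordinates are 1-based rCRS positions throughout the public surface; the
insert spans rCRS 15124-15239 (116 bases).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from . import tables as T
from .errors import CoordinateError, PanelIntegrityError

#: background base at every non-tabulated insert position (damage-inert).
BACKGROUND_BASE = "A"

#: background position marked N so pairwise deletion compares 115 sites.
DEFAULT_EXCLUDED_SITE = 15130

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide sequence (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rcrs_to_fragment_index(pos: int) -> int:
    """Map a 1-based rCRS coordinate to a 0-based offset within the insert.

    Valid inserts span rCRS 15124-15239; offset = pos - 15124.
    """
    if not T.RCRS_INSERT_START <= pos <= T.RCRS_INSERT_END:
        raise CoordinateError(
            f"rCRS position {pos} outside the insert interval "
            f"[{T.RCRS_INSERT_START}, {T.RCRS_INSERT_END}]"
        )
    return pos - T.RCRS_INSERT_START


def fragment_index_to_rcrs(index: int) -> int:
    """Inverse of :func:`rcrs_to_fragment_index`."""
    if not 0 <= index < T.INSERT_LENGTH:
        raise CoordinateError(
            f"fragment offset {index} outside [0, {T.INSERT_LENGTH - 1}]"
        )
    return index + T.RCRS_INSERT_START


@dataclass(frozen=True)
class MitoPosition:
    """A position expressed both in rCRS and insert-offset coordinates."""

    rcrs: int

    @property
    def fragment_index(self) -> int:
        return rcrs_to_fragment_index(self.rcrs)


@dataclass(frozen=True)
class PrimerPair:
    """The degenerate primer pair flanking the insert."""

    forward_name: str = T.FORWARD_PRIMER_NAME
    forward: str = T.FORWARD_PRIMER
    reverse_name: str = T.REVERSE_PRIMER_NAME
    reverse: str = T.REVERSE_PRIMER

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if len(seq) != T.PRIMER_LENGTH:
                raise PanelIntegrityError(
                    f"primer {seq} is not {T.PRIMER_LENGTH} nt"
                )


@dataclass(frozen=True)
class HaplotypeRecord:
    """One reconstructed 116 bp haplotype.

    ``variants`` holds the states at the tabulated polymorphic positions
    (rCRS -> base); ``sequence`` is those states applied over the shared
    background.
    """

    species: str
    clade: str | None
    haplotype_id: str
    variants: dict[int, str]
    sequence: str

    @property
    def group(self) -> str:
        """The assignment group (the resolution level of the assay)."""
        if self.clade == "F":
            return T.GROUP_LOX_F
        if self.clade == "S":
            return T.GROUP_LAFR_S
        if self.species == T.WOOLLY_MAMMOTH:
            return T.GROUP_MPRI
        return T.GROUP_EMAX


def _resolve_region(species: str, which: str) -> str:
    """Concrete primer-region template sequence for a species.

    Dots resolve to the primer base; polymorphic tokens resolve to their
    first listed allele.  The returned sequence is in primer orientation
    (for the reverse region, the template minus strand).
    """
    fwd_row, rev_row = T.TABLE3_ROWS[species]
    row = fwd_row if which == "forward" else rev_row
    primer = T.FORWARD_PRIMER if which == "forward" else T.REVERSE_PRIMER
    out = []
    for code, token in zip(primer, T.tokenize_primer_region_row(row)):
        if token == ".":
            if code in "RY":  # dots never sit under degenerate codes
                raise PanelIntegrityError(
                    f"{species} {which} region leaves degenerate {code} "
                    "unresolved"
                )
            out.append(code)
        else:
            out.append(token.split("/")[0])
    return "".join(out)


@dataclass
class ReferencePanel:
    """Clade-structured haplotype panel plus non-target primer regions."""

    haplotypes: list[HaplotypeRecord]
    interspecific_sites: tuple[int, ...]
    s_clade_sites: tuple[int, ...]
    nontarget_primer_regions: dict[str, tuple[str, str]]
    primers: PrimerPair = field(default_factory=PrimerPair)
    excluded_site: int | None = DEFAULT_EXCLUDED_SITE

    # -- access helpers ------------------------------------------------

    def by_group(self, group: str) -> list[HaplotypeRecord]:
        return [h for h in self.haplotypes if h.group == group]

    def by_species(self, species: str, clade: str | None = None
                   ) -> list[HaplotypeRecord]:
        return [
            h for h in self.haplotypes
            if h.species == species and (clade is None or h.clade == clade)
        ]

    def get(self, haplotype_id: str) -> HaplotypeRecord:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(haplotype_id)

    def group_states(self, group: str, pos: int) -> set[str]:
        """Observed states of an assignment group at an rCRS position."""
        i = rcrs_to_fragment_index(pos)
        return {h.sequence[i] for h in self.by_group(group)}

    # -- template construction -----------------------------------------

    def elephantid_flanks(self, species: str) -> tuple[str, str]:
        """(forward flank, reverse flank) on the template plus strand."""
        fwd = _resolve_region(species, "forward")
        rev = reverse_complement(_resolve_region(species, "reverse"))
        return fwd, rev

    def template_for(self, hap: HaplotypeRecord) -> str:
        """Full 160 bp plus-strand template: flank + insert + flank."""
        fwd, rev = self.elephantid_flanks(hap.species)
        return fwd + hap.sequence + rev

    def nontarget_template(self, species: str,
                           insert: str | None = None) -> str:
        """A 160 bp template for a non-elephantid species.

        The primer-binding flanks come from the embedded primer-region
        panel; the internal 116 bases are a synthetic spacer (the assay
        never reads non-target inserts because such templates fail to
        amplify).
        """
        if species not in self.nontarget_primer_regions:
            raise KeyError(species)
        fwd_region, rev_region = self.nontarget_primer_regions[species]
        if insert is None:
            insert = BACKGROUND_BASE * T.INSERT_LENGTH
        return fwd_region + insert + reverse_complement(rev_region)

    # -- subsets and export --------------------------------------------

    def distance_set(self) -> tuple[list[str], list[str]]:
        """(sequences, species labels) mirroring the published sampling.

        The published pairwise-distance analysis covered four groups:
        Asian elephant, S-clade savanna elephant, forest elephant and
        woolly mammoth; savanna sequences were all S clade.  Introgressed
        savanna (F clade) haplotypes are therefore left out of this
        subset.
        """
        seqs, labels = [], []
        for h in self.haplotypes:
            if h.species == T.SAVANNA_ELEPHANT and h.clade == "F":
                continue
            seqs.append(h.sequence)
            labels.append(h.species)
        return seqs, labels

    def representative_haplotypes(self) -> list[HaplotypeRecord]:
        """Up to two haplotypes per assignment group (for tree examples).

        The full Cartesian expansion contains variant combinations whose
        pairwise distances are artifacts of the expansion; this subset
        keeps the first two enumerated haplotypes per group, which differ
        by at most one transition within a group.
        """
        out: list[HaplotypeRecord] = []
        for group in T.ASSIGNMENT_GROUPS:
            members = self.by_group(group)
            if group == T.GROUP_LOX_F:  # representatives from L. cyclotis
                members = self.by_species(T.FOREST_ELEPHANT)
            out.extend(members[:2])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Panel as a table: species, clade, haplotype_id, one column per
        tabulated rCRS position."""
        rows = []
        for h in self.haplotypes:
            row = {"species": h.species, "clade": h.clade or "",
                   "haplotype_id": h.haplotype_id}
            for pos in T.TABLE1_POSITIONS:
                row[str(pos)] = h.sequence[rcrs_to_fragment_index(pos)]
            rows.append(row)
        return pd.DataFrame(rows)

    def export_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _group_state_sets() -> dict[tuple[str, str | None], list[set[str]]]:
    return {
        key: [set(token.split("/")) for token in states]
        for key, states in T.TABLE1_GROUPS.items()
    }


def _interspecific_sites() -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Derive the diagnostic site sets from the variant table.

    A position is interspecific when at least one group carries a fixed
    state found in no other group; it is S-clade-specific when that group
    is the S-clade savanna elephant.
    """
    state_sets = _group_state_sets()
    inter: list[int] = []
    s_only: list[int] = []
    for i, pos in enumerate(T.TABLE1_POSITIONS):
        for key, sets in state_sets.items():
            if len(sets[i]) != 1:
                continue  # polymorphic within the group: not diagnostic
            state = next(iter(sets[i]))
            others = set().union(
                *(s[i] for k, s in state_sets.items() if k != key)
            )
            if state not in others:
                inter.append(pos)
                if key == (T.SAVANNA_ELEPHANT, "S"):
                    s_only.append(pos)
                break
    return tuple(inter), tuple(s_only)


def verify_panel_integrity(haplotypes: list[HaplotypeRecord]) -> None:
    """Raise :class:`PanelIntegrityError` on cross-group duplicates.

    Identical sequences are tolerated between the two F-clade groups
    (forest elephants and introgressed savanna elephants share
    forest-derived mtDNA) but not across assignment groups.
    """
    seen: dict[str, HaplotypeRecord] = {}
    for h in haplotypes:
        prior = seen.get(h.sequence)
        if prior is not None and prior.group != h.group:
            raise PanelIntegrityError(
                f"identical sequence in {prior.haplotype_id} "
                f"({prior.group}) and {h.haplotype_id} ({h.group})"
            )
        seen.setdefault(h.sequence, h)


_GROUP_PREFIX = {
    (T.FOREST_ELEPHANT, "F"): "LCYC-F",
    (T.SAVANNA_ELEPHANT, "F"): "LAFR-F",
    (T.SAVANNA_ELEPHANT, "S"): "LAFR-S",
    (T.WOOLLY_MAMMOTH, None): "MPRI",
    (T.ASIAN_ELEPHANT, None): "EMAX",
}


def build_reference_panel(
    excluded_site: int | None = DEFAULT_EXCLUDED_SITE,
) -> ReferencePanel:
    """Construct the reference panel from the embedded tables.

    Parameters
    ----------
    excluded_site:
        rCRS coordinate of one background position written as ``N`` so
        that pairwise comparisons run over 115 sites (the published
        denominator).  Pass ``None`` for a fully concrete 116-site
        background.
    """
    if excluded_site is not None:
        if excluded_site in T.TABLE1_POSITIONS:
            raise PanelIntegrityError(
                "excluded_site must be a background position"
            )
        rcrs_to_fragment_index(excluded_site)  # bounds check

    background = [BACKGROUND_BASE] * T.INSERT_LENGTH
    if excluded_site is not None:
        background[rcrs_to_fragment_index(excluded_site)] = "N"

    haplotypes: list[HaplotypeRecord] = []
    for (species, clade), states in T.TABLE1_GROUPS.items():
        alleles = [token.split("/") for token in states]
        prefix = _GROUP_PREFIX[(species, clade)]
        for k, combo in enumerate(itertools.product(*alleles), start=1):
            seq = background.copy()
            variants: dict[int, str] = {}
            for pos, base in zip(T.TABLE1_POSITIONS, combo):
                seq[rcrs_to_fragment_index(pos)] = base
                variants[pos] = base
            haplotypes.append(HaplotypeRecord(
                species=species, clade=clade,
                haplotype_id=f"{prefix}-{k:02d}",
                variants=variants, sequence="".join(seq),
            ))

    verify_panel_integrity(haplotypes)
    inter, s_only = _interspecific_sites()
    nontarget = {
        sp: (_resolve_region(sp, "forward"), _resolve_region(sp, "reverse"))
        for sp in T.NONTARGET_SPECIES
    }
    return ReferencePanel(
        haplotypes=haplotypes,
        interspecific_sites=inter,
        s_clade_sites=s_only,
        nontarget_primer_regions=nontarget,
        excluded_site=excluded_site,
    )
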
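"""IUPAC-aware in-silico PCR with the degenerate primer pair.

A template position is a mismatch when its base falls outside the IUPAC
expansion of the primer code at that position; degenerate codes (R, Y)
therefore absorb the elephantid haplotype variation they were designed
for.  Amplification is predicted from per-primer mismatch totals with a
separate, stricter budget for the five positions nearest the primer 3'
end, where mismatches disproportionately block extension.  The predicted
amplicon is flank + insert + flank (160 = 22 + 116 + 22 nt for this
assay); trimming both primer regions recovers the 116 bp insert.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import tables as T
from .errors import ValidationError
from .panel import PrimerPair, ReferencePanel, reverse_complement

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

THREE_PRIME_WINDOW = 5


def iupac_compatible(primer_code: str, template_base: str) -> bool:
    """True iff the template base lies inside the primer code's expansion.

    A template ``N`` is treated as incompatible with every code: for
    forensic prediction an unread base must not be credited as a match.
    """
    try:
        expansion = IUPAC_EXPANSION[primer_code]
    except KeyError:
        raise ValidationError(
            f"{primer_code!r} is not an IUPAC nucleotide code"
        ) from None
    if template_base == "N":
        return False
    if template_base not in "ACGT":
        raise ValidationError(
            f"template base must be A/C/G/T/N, got {template_base!r}"
        )
    return template_base in expansion


@dataclass(frozen=True)
class PrimerMatch:
    """Mismatch accounting for one primer against one binding region."""

    primer_name: str
    total_mismatches: int
    three_prime_mismatches: int
    mismatch_positions: tuple[tuple[int, str, str], ...]
    location: int | None = None   # template offset of the binding site
    strand: str = "+"


def count_mismatches(primer: str, region: str, *, primer_name: str = "",
                     location: int | None = None,
                     strand: str = "+") -> PrimerMatch:
    """Compare a primer against a same-length template region.

    The region must be oriented 5'->3' along the primer (for the reverse
    primer, that is the template minus strand).
    """
    if len(region) != len(primer):
        raise ValidationError(
            f"region length {len(region)} != primer length {len(primer)}"
        )
    positions = []
    three_prime = 0
    cutoff = len(primer) - THREE_PRIME_WINDOW
    for i, (code, base) in enumerate(zip(primer, region)):
        if not iupac_compatible(code, base):
            positions.append((i, code, base))
            if i >= cutoff:
                three_prime += 1
    return PrimerMatch(
        primer_name=primer_name,
        total_mismatches=len(positions),
        three_prime_mismatches=three_prime,
        mismatch_positions=tuple(positions),
        location=location,
        strand=strand,
    )


@dataclass(frozen=True)
class AmplificationPolicy:
    """Thresholds separating predicted success from failure.

    The assay's validation data pin down only the endpoints (0 mismatches
    amplify, >=6 never do); the defaults sit between them, with the 3'
    rule reflecting the outsized effect of terminal mismatches.
    """

    max_total_mismatches: int = 3
    max_three_prime_mismatches: int = 1


DEFAULT_POLICY = AmplificationPolicy()


def predict_amplification(forward: PrimerMatch, reverse: PrimerMatch,
                          policy: AmplificationPolicy = DEFAULT_POLICY
                          ) -> bool:
    """Amplification verdict from the two per-primer match records."""
    return all(_passes(m, policy) for m in (forward, reverse))


def _passes(m: PrimerMatch, policy: AmplificationPolicy) -> bool:
    return (m.total_mismatches <= policy.max_total_mismatches
            and m.three_prime_mismatches
            <= policy.max_three_prime_mismatches)


@dataclass(frozen=True)
class AmpliconResult:
    """Outcome of in-silico PCR on one template."""

    template_id: str
    amplified: bool
    forward_match: PrimerMatch | None = None
    reverse_match: PrimerMatch | None = None
    amplicon: str = ""
    insert: str = ""
    strand: str = "+"


def _scan_strand(seq: str, primers: PrimerPair,
                 policy: AmplificationPolicy):
    """Best policy-passing (forward site, reverse site) pair on one strand.

    Candidate sites are exact-position (ungapped) windows passing the
    policy; among valid pairs the one minimising summed mismatches wins,
    ties going to the leftmost pair.
    """
    plen = len(primers.forward)
    fwd_sites = []
    rev_sites = []
    for i in range(len(seq) - plen + 1):
        window = seq[i:i + plen]
        fm = count_mismatches(primers.forward, window,
                              primer_name=primers.forward_name, location=i)
        if _passes(fm, policy):
            fwd_sites.append(fm)
        # reverse primer anneals to the minus strand of this window
        rm = count_mismatches(primers.reverse, reverse_complement(window),
                              primer_name=primers.reverse_name, location=i,
                              strand="-")
        if _passes(rm, policy):
            rev_sites.append(rm)
    best = None
    for fm in fwd_sites:
        for rm in rev_sites:
            if rm.location < fm.location + plen:
                continue  # reverse site must lie downstream of the forward
            key = (fm.total_mismatches + rm.total_mismatches,
                   fm.location, rm.location)
            if best is None or key < best[0]:
                best = (key, fm, rm)
    return best


def run_insilico_pcr(template: str, primers: PrimerPair | None = None,
                     policy: AmplificationPolicy = DEFAULT_POLICY,
                     template_id: str = "template") -> AmpliconResult:
    """Predict amplification of one template, scanning both strands.

    The amplicon runs from the forward-primer 5' end through the
    reverse-primer binding site and is reported 5'->3' on the strand the
    forward primer matched; the insert is the amplicon with both 22 nt
    primer regions removed.  Absence of a usable site pair yields
    ``amplified=False`` (not an exception).
    """
    primers = primers or PrimerPair()
    template = template.upper().replace("U", "T")
    plen = len(primers.forward)
    for strand, seq in (("+", template), ("-", reverse_complement(template))):
        hit = _scan_strand(seq, primers, policy)
        if hit is not None:
            _, fm, rm = hit
            amplicon = seq[fm.location:rm.location + plen]
            return AmpliconResult(
                template_id=template_id, amplified=True,
                forward_match=fm, reverse_match=rm,
                amplicon=amplicon, insert=amplicon[plen:-plen],
                strand=strand,
            )
    return AmpliconResult(template_id=template_id, amplified=False)


def tabulate_primer_mismatches(ref: ReferencePanel) -> pd.DataFrame:
    """Mismatch totals per species over both primer-binding regions.

    Counts come from the embedded primer-region panel rows; a position
    counts as differential when any of its listed alleles falls outside
    the IUPAC expansion of the primer code (for the rows in the panel the
    polymorphic tokens are all degenerate-compatible, so the convention
    only matters for elephantids, which count zero).
    """
    present_elephantids = {h.species for h in ref.haplotypes}
    rows = []
    for species, (fwd_row, rev_row) in T.TABLE3_ROWS.items():
        if species in T.ELEPHANTID_SPECIES:
            if species not in present_elephantids:
                continue
        elif species not in ref.nontarget_primer_regions:
            continue
        counts = {}
        for label, row, primer in (
            ("forward", fwd_row, ref.primers.forward),
            ("reverse", rev_row, ref.primers.reverse),
        ):
            n = 0
            for code, token in zip(primer,
                                   T.tokenize_primer_region_row(row)):
                if token == ".":
                    continue
                if any(not iupac_compatible(code, allele)
                       for allele in token.split("/")):
                    n += 1
            counts[label] = n
        rows.append({
            "species": species,
            "elephantid": species in T.ELEPHANTID_SPECIES,
            "forward_mismatches": counts["forward"],
            "reverse_mismatches": counts["reverse"],
            "total": counts["forward"] + counts["reverse"],
        })
    return pd.DataFrame(rows)
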
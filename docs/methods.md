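# Methods

This note records what `ivoryid` models, the choices made where the
design was open, and what the synthetic fixtures can and cannot show
about real ivory casework.

## Marker and coordinate frame

The assay targets a 116 bp internal fragment of mitochondrial
cytochrome *b*, rCRS positions 15124–15239 (the human revised Cambridge
Reference Sequence numbers the alignment; the fragment offset is
`rcrs − 15124`). The degenerate primers L15123/H15240 (22 nt each; three
IUPAC codes in the forward primer, one in the reverse) flank the
fragment, giving a 160 bp amplicon. All public interfaces report rCRS
coordinates, never 0-based offsets.

## Reference panel reconstruction

The panel is rebuilt at runtime from two embedded tables: the variant
table (14 polymorphic positions with per-group states for five
species/clade groups) and the primer-region panel (per-species template
bases in both primer-binding regions for 13 species, elephantid and
non-target).

**Cartesian expansion.** The variant table gives per-site intraspecific
polymorphism without haplotype phase. The panel therefore enumerates
every combination of intraspecific variants within a group (1 Asian
elephant, 2 mammoth, 2 S-clade savanna, 8 introgressed-savanna F-clade,
16 forest-elephant haplotypes; 29 in total). Expansion guarantees the
extreme pairs that drive the published range bounds but also creates
variant combinations that real, linked haplotypes do not realise:
within-group maxima (up to 4 transitions in the forest elephant) exceed
the empirically observed intraspecific maximum (~1 transition), and
some between-group ranges widen symmetrically (forest-elephant vs
mammoth pairs can come as close as 1 transition, forest vs S-clade as
far as 9). The comparisons driven purely by fixed differences — Asian
elephant vs S-clade (7–8 transitions, the published overall maxima of
6.96 % p / 7.49 % K2P) and Asian elephant vs mammoth (4–5) — are exact.
Distance checks against published extremes therefore use those pair
classes; tree-shape demonstrations use a two-representatives-per-group
subset on which within-group distances (≤ 1 transition) are well below
between-group ones.

**Background.** Non-tabulated positions carry a single shared
placeholder base, chosen as `A`. Because the background is synthetic,
any damage sensitivity it contributed would be an artifact of the
filler choice rather than of the marker; a damage-inert base confines
simulated deamination effects to the positions actually transcribed
from data (variant sites and primer regions), which is what the
robustness results are meant to probe. Distances, diagnostics and
amplicon arithmetic are unaffected by the choice, since every haplotype
shares the background.

**Compared-site denominator.** The published pairwise distances
reproduce exactly at 115 compared sites, not 116 (8/115 = 6.96 % p;
−½ ln(1 − 16/115) = 7.49 % K2P). Whether this reflects one excluded
alignment column or a shorter effective fragment is not determinable,
so the default panel marks one background position (rCRS 15130) with
`N`; pairwise deletion then yields 115 compared sites for panel-derived
fragments. `build_reference_panel(excluded_site=None)` restores a fully
concrete 116-site background. One published value resists either
reading: the E. maximus–L. africana p-distance lower bound prints
6.10 % where 7/115 gives 6.09 % (its K2P analogue, 6.49 %, reproduces);
the panel validator checks the K2P bound only.

**Integrity.** Identical sequences across assignment groups raise a
panel-integrity error, with one deliberate exception: forest-elephant
and introgressed-savanna expansions generate identical F-clade
sequences, which is precisely the introgression that makes F-clade
calls genus-level, so duplicates within the F clade are expected and
retained.

**Templates.** Full 160 bp plus-strand templates are the haplotype
flanked by its species' primer-region sequences (degenerate codes
resolved per the species' row, first listed allele at polymorphic
tokens); non-target templates use the non-target rows with a synthetic
spacer insert (their inserts are never read because they fail to
amplify).

## In-silico PCR

A template base mismatches a primer position iff it lies outside the
IUPAC expansion of the primer code; template `N` never matches
(conservative for forensic prediction). Binding-site search is
exact-position scanning on both strands — no gapped alignment, so
primer-region indels are out of scope. The default amplification policy
(per primer: total mismatches ≤ 3 and ≤ 1 within the five 3′-terminal
positions) is a modeling choice: the validation data pin only the
endpoints (0 mismatches always amplified; every species with ≥ 6 never
did), and the 3′ rule reflects the disproportionate effect of terminal
mismatches on extension. Both thresholds are configurable. Among
multiple candidate site pairs, the pair minimising summed mismatches
wins, ties resolving to the leftmost — deterministic output.

One borderline case follows from the embedded data: the narwhal row
totals 5 differential nucleotides (2 forward, interior; 3 reverse, one
at the 3′ end), inside the default tolerance, so a narwhal template is
*predicted* to amplify. Narwhal was never wet-lab tested; the validated
exclusion range starts at 6. The prediction is reported as-is rather
than tightening the policy around a single untested row.

## Distances and diversity

Transitions-only p-distance and K2P are used throughout
(`p = P`, `K2P = −½ ln(1 − 2P − Q) + ¼ ln(1 − 2Q)` with pairwise
deletion), matching the distance convention of the source analysis;
nucleotide diversity π instead counts all substitution types (DnaSP
convention). That asymmetry is deliberate and inherited. Note that the
K2P ≥ p domination property holds in the transitions-only regime
(Q = 0) that this marker occupies; with appreciable transversions the
transitions-only K2P component can drop below P.

Summaries report per-class and overall min/max/mean/SD (sample SD,
ddof = 1). A class with one sequence contributes no pairs but is
reported with a degenerate 0–0 range, matching how published matrices
print invariant species. The barcoding gap is
`lower_inter − upper_intra`, reported even when negative. The
"species-pair sampling" subset used for published-range checks excludes
introgressed-savanna haplotypes, mirroring the original sampling in
which all savanna sequences were S clade.

Neighbour joining is delegated to scikit-bio (the matrix is validated
and pre-sorted by label, making the output permutation-invariant);
monophyly is decided by edge bipartitions of the unrooted tree, so a
label covering all leaves but one is a valid split. Bootstrap supports
come from site resampling with a seeded generator and are for
inspection only — they are not comparable to likelihood or Bayesian
supports.

## Classification

Diagnostic rules over the eight interspecific positions: Asian elephant
≥ 2 of its 3 diagnostic states; S-clade savanna ≥ 3 of 4; mammoth its
unique G at 15221 with no other rule satisfied; F clade the full
8-state profile. Majorities rather than exact profiles tolerate a
single deamination hit; any observed off-group diagnostic state is
flagged as a conflict even on a successful call (e.g. C→T at 15238 on a
mammoth fragment mimics the Asian-elephant state and yields a flagged
mammoth call, never a confident Asian-elephant one). Satisfying zero or
multiple rules yields `unassigned` with per-position flags.

Two structural fragilities are worth knowing. The mammoth and F-clade
profiles differ at a single position (15221), so a G→A lesion there
converts a mammoth fragment into an exact or near-exact F-clade
sequence — the combined caller then abstains or, for the matching
variant combination, miscalls F; at the default interior rate this
affects ~0.5 % of molecules. Similarly the F-clade rule is exact-match,
so any single lesion on an F-clade diagnostic position forces
abstention for that fragment.

The distance assigner takes the nearest reference haplotype by
transitions-only K2P, requiring the minimum distance to clear a
threshold that defaults to 1.35 % — the midpoint of the published
barcoding gap (0.89–1.80 %), configurable because the gap, not a
cutoff, is the published quantity. Group ties at the minimum yield
`unassigned` ("ambiguous nearest neighbor"). The combined caller
assigns only on agreement; any disagreement (including one-sided
abstention) is reported as `unassigned` with both verdicts recorded.

## Damage simulation

Deamination is applied per site independently on a single strand
representation where both C→T and G→A can occur, approximating
double-strand library damage without modeling 5′/3′ strand asymmetry
(the phenomenon is characterised at exactly this level for this assay's
purposes). Defaults — terminal rate 0.05 within 10-site end windows,
interior rate 0.005 — are this toolkit's testing conventions, sized so
a damaged fragment typically carries zero or one interior lesion; the
damage literature quantifies the end-enrichment only qualitatively.
UNG treatment is a ×0.001 rate multiplier, not a sequence operation. A
and T sites are never altered, and all randomness flows through a
seeded NumPy generator, making simulations bit-reproducible.

`simulate_samples` draws a pool of `n` templates: contaminant species
take `round(fraction · n)` records each (built from their primer-region
rows), the remainder drawn uniformly from the panel haplotypes; all
pass through the damage model, and truth labels are emitted alongside.

Copy-number arithmetic uses
`copies = mass[g] · 6.022×10²³ / (length · 660 g·mol⁻¹·bp⁻¹)` (330 for
single strands); dilution series are real-valued geometric
expectations. Empirical qPCR measurements (detection limits, measured
copy numbers) are laboratory observations and are never asserted by
this package — the utilities only support designing analogous in-silico
experiments.

## What the synthetic data do and do not show

The generator emulates template pools with realistic damage structure,
contamination ratios and truth labels, but its sequences are panel
haplotypes over a placeholder background: no fragmentation-length
distribution, no sequencing error or chromatogram noise, no
heteroplasmy, and no haplotypes beyond the tabulated variation.
Passing end-to-end tests therefore demonstrates the internal
consistency and damage tolerance of the decision logic on the known
haplotype space — not sensitivity or success rates on real ivory
extracts, which are empirical properties of laboratory workflows.
Problem sizes in the test suite (500 end-to-end replicates per
condition, 10⁴ replicates for damage-rate calibration checks) were
chosen to hold Monte-Carlo error comfortably below the asserted
margins.

## Numerical conventions

Saturated pairs (K2P log argument ≤ 0) raise a dedicated error naming
the offending quantities; the distance assigner treats saturated
references as unusable rather than failing the call. Distance ties in
nearest-neighbour search break lexicographically by haplotype id; NJ
input ties are handled by the scikit-bio implementation on the
label-sorted matrix. Exit codes of the CLI: 0 success, 1 validation
failure, 2 usage/input error.
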
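"""Ancient-DNA deamination simulator and sensitivity-design arithmetic.

Post-mortem cytosine deamination reads as C->T (or G->A on the
complementary strand).  It concentrates on the outermost ~10 bases of a
degraded template but occurs at a low rate along its whole length; the
simulator applies independent per-site lesions at a high terminal rate
within a configurable end window and a low interior rate elsewhere,
on a single strand representation where both C->T and G->A can occur.
A and T sites are never altered.  Optional UNG (uracil N-glycosylase)
treatment is modelled as a 1000-fold multiplicative rate reduction.

Also here: plasmid-standard copy-number arithmetic
(copies = mass[g] * N_A / (length * 660 g/mol/bp) for double-stranded
standards) and serial-dilution series used to design sensitivity-style
in-silico experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .fastaio import write_fasta
from .panel import HaplotypeRecord, ReferencePanel

AVOGADRO = 6.022e23
MEAN_BP_WEIGHT_DS = 660.0   # g/mol per base pair, double-stranded
MEAN_BP_WEIGHT_SS = 330.0

UNG_RATE_FACTOR = 1e-3

_DEAMINATION = {"C": "T", "G": "A"}


@dataclass(frozen=True)
class DamageModel:
    """Two-zone deamination model.

    ``terminal_rate`` applies within ``terminal_window`` sites of either
    molecule end, ``interior_rate`` elsewhere; both are per-site lesion
    probabilities.  The default rates are testing conventions of this
    toolkit (the damage literature quantifies the end-enrichment only
    qualitatively), sized so that a damaged fragment typically carries
    zero or one interior lesion.
    """

    terminal_rate: float = 0.05
    interior_rate: float = 0.005
    terminal_window: int = 10
    ung_treated: bool = False

    def __post_init__(self) -> None:
        for rate in (self.terminal_rate, self.interior_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rate {rate} outside [0, 1]")
        if self.terminal_window < 0:
            raise ValidationError("terminal_window must be >= 0")

    def rate_at(self, index: int, length: int) -> float:
        in_window = (index < self.terminal_window
                     or index >= length - self.terminal_window)
        rate = self.terminal_rate if in_window else self.interior_rate
        return rate * UNG_RATE_FACTOR if self.ung_treated else rate


def apply_deamination(seq: str, model: DamageModel,
                      rng: np.random.Generator
                      ) -> tuple[str, list[tuple[int, str, str]]]:
    """Damage one molecule; returns (sequence, [(position, from, to)])."""
    out = list(seq)
    events = []
    n = len(seq)
    draws = rng.random(n)
    for i, base in enumerate(seq):
        to = _DEAMINATION.get(base)
        if to is None:
            continue
        if draws[i] < model.rate_at(i, n):
            out[i] = to
            events.append((i, base, to))
    return "".join(out), events


@dataclass(frozen=True)
class SimulatedSample:
    record_id: str
    species: str
    clade: str | None
    truth_group: str
    sequence: str
    damage_events: tuple[tuple[int, str, str], ...]


def simulate_samples(panel: ReferencePanel, n: int,
                     model: DamageModel | None = None,
                     contamination: dict[str, float] | None = None,
                     seed: int | None = None,
                     fasta_path=None, truth_path=None
                     ) -> list[SimulatedSample]:
    """Draw damaged elephantid templates, optionally mixed with
    non-target contaminants.

    ``n`` is the total pool size.  ``contamination`` maps non-target
    species to their fraction of the pool (fractions must sum to <= 1);
    the remainder are templates drawn uniformly from the panel
    haplotypes, flanked with their species' primer regions.  All
    templates (elephantid and contaminant) pass through the damage
    model.  With ``fasta_path``/``truth_path`` the pool and its truth
    labels are also written to disk.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    model = model or DamageModel(terminal_rate=0.0, interior_rate=0.0)
    contamination = contamination or {}
    for sp in contamination:
        if sp not in panel.nontarget_primer_regions:
            raise ConfigurationError(f"unknown contaminant species {sp!r}")
    if sum(contamination.values()) > 1.0 + 1e-9:
        raise ConfigurationError("contaminant fractions sum above 1")

    counts = {sp: round(frac * n) for sp, frac in contamination.items()}
    n_elephantid = n - sum(counts.values())
    if n_elephantid < 0:
        raise ConfigurationError("contaminant fractions leave no templates")

    rng = np.random.default_rng(seed)
    samples: list[SimulatedSample] = []
    haplotypes = panel.haplotypes
    picks = rng.integers(0, len(haplotypes), size=n_elephantid)
    for k, idx in enumerate(picks, start=1):
        hap: HaplotypeRecord = haplotypes[int(idx)]
        damaged, events = apply_deamination(panel.template_for(hap),
                                            model, rng)
        samples.append(SimulatedSample(
            record_id=f"sim-{k:04d}|{hap.haplotype_id}",
            species=hap.species, clade=hap.clade,
            truth_group=hap.group, sequence=damaged,
            damage_events=tuple(events),
        ))
    k = n_elephantid
    for sp in sorted(counts):
        for _ in range(counts[sp]):
            k += 1
            damaged, events = apply_deamination(
                panel.nontarget_template(sp), model, rng)
            samples.append(SimulatedSample(
                record_id=f"sim-{k:04d}|{sp.replace(' ', '_')}",
                species=sp, clade=None, truth_group="non-target",
                sequence=damaged, damage_events=tuple(events),
            ))

    if fasta_path is not None:
        write_fasta([(s.record_id, s.sequence) for s in samples],
                    fasta_path)
    if truth_path is not None:
        import pandas as pd

        pd.DataFrame([
            {"record_id": s.record_id, "species": s.species,
             "clade": s.clade or "", "group": s.truth_group,
             "n_damage_events": len(s.damage_events)}
            for s in samples
        ]).to_csv(truth_path, sep="\t", index=False)
    return samples


def copies_from_mass(mass_ng: float, length_bp: int,
                     double_stranded: bool = True) -> float:
    """Template copy number in a DNA mass (the plasmid-standard formula)."""
    if mass_ng <= 0 or length_bp <= 0:
        raise ValidationError("mass and length must be positive")
    per_bp = MEAN_BP_WEIGHT_DS if double_stranded else MEAN_BP_WEIGHT_SS
    return mass_ng * 1e-9 * AVOGADRO / (length_bp * per_bp)


def serial_dilution(start_copies: float, factor: float,
                    steps: int) -> list[float]:
    """Expected copy numbers along a geometric dilution series
    (``steps + 1`` values including the starting stock)."""
    if factor <= 1:
        raise ValidationError("dilution factor must be > 1")
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    return [start_copies / factor ** i for i in range(steps + 1)]
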
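"""End-to-end identification pipeline: templates -> PCR -> trim -> call.

This is the library form of the command-line ``identify`` workflow: each
input record is screened by in-silico PCR with the elephantid primers;
records yielding no amplicon are reported as "no elephantid amplicon"
(the assay's exclusion behaviour for non-target species), and amplifying
records have their trimmed insert classified against the reference
panel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd

from . import __version__
from .classify import ClassifierConfig, SpeciesCall, classify
from .panel import ReferencePanel, build_reference_panel
from .pcr import AmplificationPolicy, AmpliconResult, run_insilico_pcr

NO_AMPLICON = "no elephantid amplicon"


@dataclass
class IdentifyResult:
    record_id: str
    pcr: AmpliconResult
    call: SpeciesCall | None

    @property
    def verdict(self) -> str:
        return self.call.taxon if self.call is not None else NO_AMPLICON


def identify_records(records: list[tuple[str, str]],
                     panel: ReferencePanel | None = None,
                     policy: AmplificationPolicy | None = None,
                     config: ClassifierConfig | None = None
                     ) -> list[IdentifyResult]:
    """Run the full assay on (id, template-or-fragment) records.

    Records of exactly 116 nt are taken as pre-trimmed inserts and
    classified directly; longer records go through in-silico PCR first.
    """
    panel = panel or build_reference_panel()
    policy = policy or AmplificationPolicy()
    results = []
    for record_id, seq in records:
        if len(seq) == 116:
            pcr = AmpliconResult(template_id=record_id, amplified=True,
                                 amplicon=seq, insert=seq)
        else:
            pcr = run_insilico_pcr(seq, panel.primers, policy,
                                   template_id=record_id)
        call = None
        if pcr.amplified:
            call = classify(pcr.insert, panel, config, seq_id=record_id)
        results.append(IdentifyResult(record_id, pcr, call))
    return results


def results_to_frame(results: list[IdentifyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        call = r.call
        rows.append({
            "record_id": r.record_id,
            "amplified": r.pcr.amplified,
            "fwd_mm": (r.pcr.forward_match.total_mismatches
                       if r.pcr.forward_match else ""),
            "fwd_3p_mm": (r.pcr.forward_match.three_prime_mismatches
                          if r.pcr.forward_match else ""),
            "rev_mm": (r.pcr.reverse_match.total_mismatches
                       if r.pcr.reverse_match else ""),
            "rev_3p_mm": (r.pcr.reverse_match.three_prime_mismatches
                          if r.pcr.reverse_match else ""),
            "amplicon_len": len(r.pcr.amplicon),
            "insert_len": len(r.pcr.insert),
            "taxon": r.verdict,
            "method": call.method if call else "",
            "min_distance": (f"{call.min_distance:.6f}"
                             if call and call.min_distance is not None
                             else ""),
            "nearest_reference": call.nearest_reference
            if call and call.nearest_reference else "",
            "diagnostic_states": ";".join(
                f"{pos}={base}"
                for pos, base in sorted(call.diagnostic_states.items())
            ) if call else "",
            "conflicts": "; ".join(call.conflicts) if call else "",
        })
    return pd.DataFrame(rows)


def results_to_json(results: list[IdentifyResult], seed=None) -> str:
    payload = {
        "schema_version": 1,
        "tool_version": __version__,
        "seed": seed,
        "calls": [
            {
                "record_id": r.record_id,
                "amplified": r.pcr.amplified,
                "taxon": r.verdict,
                **({"call": _call_dict(r.call)} if r.call else {}),
            }
            for r in results
        ],
    }
    return json.dumps(payload, indent=2)


def _call_dict(call: SpeciesCall) -> dict:
    d = asdict(call)
    d["diagnostic_states"] = {
        str(k): v for k, v in call.diagnostic_states.items()
    }
    return d
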
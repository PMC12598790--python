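"""Rule-based aggregation of multi-technique evidence into a binding-mode call.

The call formalizes how solution studies are synthesized in practice: a
binding constant of 1e3-1e5 1/M, a small melting-temperature shift, flat
relative viscosity, displacement of a groove-selective probe and
hyperchromism without a large red shift each argue for groove binding;
Kb >= 1e6, dTm >= 10 C, rising viscosity and displacement of an
intercalator probe argue for intercalation.  Each available rule casts at
most one vote; the majority wins, with ties or fewer than two votes left
indeterminate.  Thermodynamic force classification is recorded but casts no
vote - interaction forces describe chemistry, not binding-site geometry; an
"electrostatic" mode is called only when the force class is electrostatic
and no structural evidence is available at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

from .errors import ValidationError
from .melting import DeltaTmCall, interpret_delta_tm
from .types import BindingModeReport, ModeCall

__all__ = ["RuleThresholds", "aggregate_evidence"]

log = logging.getLogger(__name__)

GROOVE = "groove"
INTERCALATION = "intercalation"

#: Evidence keys recognised by the rules.
EVIDENCE_KEYS = (
    "kb_by_method",       # {method name: Kb 1/M}
    "delta_tm_c",         # float
    "viscosity_trend",    # "flat" | "increasing" | "decreasing"
    "displacement",       # "groove_probe_displaced" | "intercalator_probe_displaced" | ...
    "spectral_change",    # "hyperchromic" | "hypochromic" | "none"
    "peak_shift_nm",      # optional float, red shift positive
    "force_class",        # "hydrophobic" | "vdw_or_hbond" | "electrostatic" | ...
)


@dataclass(frozen=True)
class RuleThresholds:
    """Tunable cutoffs for the voting rules."""

    kb_groove_range: tuple[float, float] = (1e3, 1e5)  # [lo, hi)
    kb_intercalation_min: float = 1e6
    dtm_intercalation_min: float = 10.0
    dtm_groove_max: float = 6.0
    large_red_shift_nm: float = 10.0
    min_votes: int = 2


def _structural_keys_present(evidence: dict[str, Any]) -> bool:
    return any(
        k in evidence
        for k in ("kb_by_method", "delta_tm_c", "viscosity_trend", "displacement", "spectral_change")
    )


def aggregate_evidence(
    evidence: dict[str, Any], thresholds: RuleThresholds | None = None
) -> BindingModeReport:
    """Apply the voting rules to the available evidence.

    Parameters
    ----------
    evidence : mapping of evidence keys (see EVIDENCE_KEYS) to findings; any
        subset may be present but it must be non-empty.
    thresholds : rule cutoffs; defaults reproduce the conventional reading.

    Returns
    -------
    BindingModeReport whose rule_trace lists, in firing order, each rule
    with the evidence key and value it consumed and the vote it cast.
    """
    if not evidence:
        raise ValidationError("empty evidence: nothing to aggregate")
    th = thresholds or RuleThresholds()
    trace: list[dict[str, Any]] = []
    votes: list[str] = []

    def fire(rule: str, key: str, value: Any, vote: str | None) -> None:
        trace.append({"rule": rule, "evidence_key": key, "input": value, "vote": vote})
        if vote is not None:
            votes.append(vote)

    # R1: binding-constant magnitude (any method)
    kb_map = evidence.get("kb_by_method")
    if kb_map:
        kbs = {m: float(k) for m, k in kb_map.items()}
        if any(k >= th.kb_intercalation_min for k in kbs.values()):
            fire("kb_magnitude", "kb_by_method", kbs, INTERCALATION)
        elif any(th.kb_groove_range[0] <= k < th.kb_groove_range[1] for k in kbs.values()):
            fire("kb_magnitude", "kb_by_method", kbs, GROOVE)
        else:
            fire("kb_magnitude", "kb_by_method", kbs, None)

    # R2: melting-temperature shift
    if "delta_tm_c" in evidence:
        dtm = float(evidence["delta_tm_c"])
        call = interpret_delta_tm(dtm, th.dtm_intercalation_min, th.dtm_groove_max)
        vote = {
            DeltaTmCall.GROOVE: GROOVE,
            DeltaTmCall.INTERCALATION: INTERCALATION,
            DeltaTmCall.AMBIGUOUS: None,
        }[call]
        fire("delta_tm", "delta_tm_c", dtm, vote)

    # R3: viscosity trend
    if "viscosity_trend" in evidence:
        trend = str(evidence["viscosity_trend"])
        vote = GROOVE if trend == "flat" else INTERCALATION if trend == "increasing" else None
        fire("viscosity_trend", "viscosity_trend", trend, vote)

    # R4: probe displacement
    if "displacement" in evidence:
        disp = str(evidence["displacement"])
        vote = (
            GROOVE
            if disp == "groove_probe_displaced"
            else INTERCALATION
            if disp == "intercalator_probe_displaced"
            else None
        )
        fire("displacement", "displacement", disp, vote)

    # R5: spectral change; hyperchromism without a large red shift is
    # inconsistent with intercalation (which hypochromically red-shifts)
    if "spectral_change" in evidence:
        change = str(evidence["spectral_change"])
        shift = evidence.get("peak_shift_nm")
        large_red = shift is not None and float(shift) >= th.large_red_shift_nm
        vote = GROOVE if (change == "hyperchromic" and not large_red) else None
        key = "spectral_change"
        fire("spectral", key, {"change": change, "peak_shift_nm": shift}, vote)

    # R6: thermodynamic force class is descriptive only
    if "force_class" in evidence:
        fire("force_class", "force_class", str(evidence["force_class"]), None)

    groove_votes = votes.count(GROOVE)
    intercalation_votes = votes.count(INTERCALATION)
    total = groove_votes + intercalation_votes
    if total < th.min_votes or groove_votes == intercalation_votes:
        mode = ModeCall.INDETERMINATE
        if (
            str(evidence.get("force_class", "")) == "electrostatic"
            and not _structural_keys_present(evidence)
        ):
            mode = ModeCall.ELECTROSTATIC
    elif groove_votes > intercalation_votes:
        mode = ModeCall.MINOR_GROOVE
    else:
        mode = ModeCall.INTERCALATION

    log.info(
        "mode call: %s (groove %d, intercalation %d of %d fired rules)",
        mode.value, groove_votes, intercalation_votes, len(trace),
    )
    return BindingModeReport(evidence=dict(evidence), mode_call=mode, rule_trace=trace)
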
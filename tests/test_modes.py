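"""Evidence aggregation rules for the binding-mode call."""

import pytest

from dnabind import ModeCall, aggregate_evidence
from dnabind.errors import ValidationError

PAPER_EVIDENCE = {
    "kb_by_method": {
        "benesi_hildebrand": 3.22e4,
        "double_log": 2.57e4,
        "electrochemical": 6.02e4,
    },
    "delta_tm_c": 5.4,
    "viscosity_trend": "flat",
    "displacement": "groove_probe_displaced",
    "spectral_change": "hyperchromic",
    "force_class": "electrostatic",
}

INTERCALATOR_EVIDENCE = {
    "kb_by_method": {"electrochemical": 1.0e7},
    "delta_tm_c": 11.0,
    "viscosity_trend": "increasing",
    "displacement": "intercalator_probe_displaced",
}


def _votes(report, which):
    return sum(1 for t in report.rule_trace if t["vote"] == which)


def test_full_solution_evidence_calls_minor_groove():
    report = aggregate_evidence(PAPER_EVIDENCE)
    assert report.mode_call is ModeCall.MINOR_GROOVE
    assert _votes(report, "groove") == 5
    assert _votes(report, "intercalation") == 0


def test_intercalator_evidence_calls_intercalation():
    report = aggregate_evidence(INTERCALATOR_EVIDENCE)
    assert report.mode_call is ModeCall.INTERCALATION
    assert _votes(report, "intercalation") == 4


def test_single_evidence_item_is_indeterminate():
    report = aggregate_evidence({"delta_tm_c": 11.6})
    assert report.mode_call is ModeCall.INDETERMINATE
    assert len(report.rule_trace) == 1


def test_tie_is_indeterminate():
    report = aggregate_evidence({"delta_tm_c": 11.0, "viscosity_trend": "flat"})
    assert report.mode_call is ModeCall.INDETERMINATE


def test_force_class_is_descriptive_not_a_vote():
    report = aggregate_evidence({**INTERCALATOR_EVIDENCE, "force_class": "electrostatic"})
    assert report.mode_call is ModeCall.INTERCALATION
    fired = {t["rule"]: t["vote"] for t in report.rule_trace}
    assert fired["force_class"] is None


def test_electrostatic_mode_only_without_structural_evidence():
    assert (
        aggregate_evidence({"force_class": "electrostatic"}).mode_call
        is ModeCall.ELECTROSTATIC
    )
    assert (
        aggregate_evidence({"force_class": "electrostatic", "delta_tm_c": 5.0}).mode_call
        is ModeCall.INDETERMINATE
    )


def test_hyperchromism_with_large_red_shift_casts_no_vote():
    report = aggregate_evidence(
        {"spectral_change": "hyperchromic", "peak_shift_nm": 15.0, "delta_tm_c": 5.0}
    )
    spectral = next(t for t in report.rule_trace if t["rule"] == "spectral")
    assert spectral["vote"] is None


def test_kb_magnitude_rule_prefers_intercalation_when_any_method_is_huge():
    report = aggregate_evidence(
        {"kb_by_method": {"double_log": 2.0e4, "electrochemical": 1.0e7}, "delta_tm_c": 11.0}
    )
    assert report.mode_call is ModeCall.INTERCALATION


def test_determinism_identical_evidence_identical_report():
    a = aggregate_evidence(PAPER_EVIDENCE)
    b = aggregate_evidence(PAPER_EVIDENCE)
    assert a.to_dict() == b.to_dict()


@pytest.mark.parametrize(
    "extra",
    [
        {"viscosity_trend": "flat"},
        {"displacement": "groove_probe_displaced"},
        {"spectral_change": "hyperchromic"},
        {"kb_by_method": {"double_log": 5.0e3}},
    ],
)
def test_adding_groove_evidence_never_flips_a_groove_call(extra):
    base = {"delta_tm_c": 5.4, "viscosity_trend": "flat"}
    before = aggregate_evidence(base)
    assert before.mode_call is ModeCall.MINOR_GROOVE
    after = aggregate_evidence({**base, **extra})
    assert after.mode_call is ModeCall.MINOR_GROOVE


def test_empty_evidence_rejected():
    with pytest.raises(ValidationError):
        aggregate_evidence({})


def test_trace_references_only_present_evidence():
    report = aggregate_evidence(PAPER_EVIDENCE)
    for fired in report.rule_trace:
        assert fired["evidence_key"] in report.evidence
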
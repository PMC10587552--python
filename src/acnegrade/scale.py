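"""The 8-level treatment-intensity severity scale.

Severity is expressed as the treatment a patient at that level should
receive, which improves inter-rater agreement over purely descriptive
labels. The scale has exactly eight levels; the top level merges the two
most severe grades of the original nine-level intensity list because
extremely severe cases are rare.
"""

from __future__ import annotations

from .errors import InvalidGradeError

N_GRADES = 8

#: grade -> (severity description, treatment intensity)
SEVERITY_SCALE: dict[int, tuple[str, str]] = {
    1: ("Clear", "No treatment necessary"),
    2: ("Almost clear", "BPO or a mild topical retinoid"),
    3: ("Mild", "BPO and a topical retinoid"),
    4: (
        "Mild to moderate",
        "BPO and a stronger topical retinoid or a topical retinoid and "
        "consideration of an oral antibiotics",
    ),
    5: ("Moderate", "Topical treatment and an oral antibiotics"),
    6: ("Moderate to less severe", "Same as 5, but start considering isotretinoin"),
    7: ("Less severe", "Same as 5, but recommend isotretinoin"),
    8: ("Severe or very severe", "Should be on isotretinoin"),
}


def validate_grade(grade: int) -> int:
    g = int(grade)
    if not 1 <= g <= N_GRADES:
        raise InvalidGradeError(f"grade must be in 1..{N_GRADES}, got {grade}")
    return g


def grade_to_treatment(grade: int) -> str:
    """Treatment-intensity text for an ordinal severity grade (1..8)."""
    return SEVERITY_SCALE[validate_grade(grade)][1]


def grade_description(grade: int) -> str:
    """Severity description text for an ordinal grade (1..8)."""
    return SEVERITY_SCALE[validate_grade(grade)][0]
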
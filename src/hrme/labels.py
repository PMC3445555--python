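"""Histopathologic diagnosis labels and their diagnostic-category grouping.

Six histopathologic diagnoses are grouped into three diagnostic categories.
High-grade dysplasia (CIN 2 and CIN 3) is the neoplastic (positive) class;
all other diagnoses — including HPV effect and CIN 1 (low-grade dysplasia)
— are non-neoplastic.
"""

from __future__ import annotations

NORMAL_BENIGN = "Normal/Benign"
LOW_GRADE = "Low Grade"
HIGH_GRADE = "High Grade"

CATEGORIES = (NORMAL_BENIGN, LOW_GRADE, HIGH_GRADE)

#: diagnosis -> diagnostic category
DIAGNOSIS_CATEGORY = {
    "Normal": NORMAL_BENIGN,
    "Inflammation": NORMAL_BENIGN,
    "HPV effect": LOW_GRADE,
    "CIN 1": LOW_GRADE,
    "CIN 2": HIGH_GRADE,
    "CIN 3": HIGH_GRADE,
}

DIAGNOSES = tuple(DIAGNOSIS_CATEGORY)


def category_of(diagnosis: str) -> str:
    """Return the diagnostic category for a histopathologic diagnosis."""
    try:
        return DIAGNOSIS_CATEGORY[diagnosis]
    except KeyError:
        raise ValueError(f"unknown histopathologic diagnosis: {diagnosis!r}") from None


def is_neoplastic(diagnosis_or_category: str) -> bool:
    """True iff the label belongs to the high-grade (neoplastic) class."""
    label = diagnosis_or_category
    if label in DIAGNOSIS_CATEGORY:
        label = DIAGNOSIS_CATEGORY[label]
    if label not in CATEGORIES:
        raise ValueError(f"unknown label: {diagnosis_or_category!r}")
    return label == HIGH_GRADE
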
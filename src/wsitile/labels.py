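"""The closed label set and its diagnostic priority order.

A slide may carry regions of several labels; the slide-level diagnosis is
the highest-priority label present (malignant > benign > everything else).
"""

ADENOCARCINOMA = "adenocarcinoma"
ADENOMA = "adenoma"
NON_NEOPLASTIC = "non_neoplastic"

#: Closed label set, in priority order (highest first).
LABELS = (ADENOCARCINOMA, ADENOMA, NON_NEOPLASTIC)

#: label -> rank; lower rank wins when assigning a slide-level diagnosis.
LABEL_PRIORITY = {label: rank for rank, label in enumerate(LABELS)}


def check_label(label: str) -> str:
    if label not in LABEL_PRIORITY:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    return label
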
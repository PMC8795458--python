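"""Canonical class labels for the three-way glioma grading task.

The fixed order (LGG, HGG, HEALTHY) is used everywhere a vector or matrix
is indexed by class: loss weights, confusion matrices, reports.
"""

CLASSES: tuple[str, ...] = ("LGG", "HGG", "HEALTHY")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}


def validate_label(label: str) -> str:
    if label not in CLASS_TO_INDEX:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return label
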
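"""Label schema for the six cardiac substructures plus background.

The fixed 7-class label space used throughout the package:

====  =====  ==========================
id    abbr   structure
====  =====  ==========================
0     BG     background
1     LVM    left ventricular myocardium
2     LV     left ventricle (blood pool)
3     LA     left atrium
4     RV     right ventricle
5     RA     right atrium
6     AO     aorta
====  =====  ==========================
"""

from __future__ import annotations

BACKGROUND = 0
LVM = 1
LV = 2
LA = 3
RV = 4
RA = 5
AO = 6

#: label id -> short name
LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "BG",
    LVM: "LVM",
    LV: "LV",
    LA: "LA",
    RV: "RV",
    RA: "RA",
    AO: "AO",
}

#: the six foreground structures, in reporting order
STRUCTURES: tuple[int, ...] = (LVM, LV, LA, RV, RA, AO)

N_CLASSES = 7


def validate_labels(values) -> None:
    """Raise ``ValueError`` listing any label values outside the schema."""
    import numpy as np

    uniq = np.unique(np.asarray(values))
    bad = [int(v) for v in uniq if int(v) not in LABEL_NAMES]
    if bad:
        raise ValueError(
            f"mask contains label values outside the schema {sorted(LABEL_NAMES)}: {bad}"
        )
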
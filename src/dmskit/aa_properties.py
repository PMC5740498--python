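"""Fixed chemicophysical property scales for the 20 amino acids.

Scales used for the wt-vs-mutant delta features:

* ``mass`` — average residue mass in Da;
* ``volume`` — side-chain volume in cubic Angstrom (Zamyatnin, 1972);
* ``polarity`` — Grantham (1974) polarity index;
* ``charge`` — formal side-chain charge at pH 7 (His counted +0.1 for
  its partial protonation);
* ``hydropathy`` — Kyte & Doolittle (1982) index.
"""

from __future__ import annotations

import pandas as pd

_ROWS = {
    #         mass    volume polarity charge hydropathy
    "A": (71.08, 88.6, 8.1, 0.0, 1.8),
    "R": (156.19, 173.4, 10.5, 1.0, -4.5),
    "N": (114.10, 114.1, 11.6, 0.0, -3.5),
    "D": (115.09, 111.1, 13.0, -1.0, -3.5),
    "C": (103.14, 108.5, 5.5, 0.0, 2.5),
    "Q": (128.13, 143.8, 10.5, 0.0, -3.5),
    "E": (129.12, 138.4, 12.3, -1.0, -3.5),
    "G": (57.05, 60.1, 9.0, 0.0, -0.4),
    "H": (137.14, 153.2, 10.4, 0.1, -3.2),
    "I": (113.16, 166.7, 5.2, 0.0, 4.5),
    "L": (113.16, 166.7, 4.9, 0.0, 3.8),
    "K": (128.17, 168.6, 11.3, 1.0, -3.9),
    "M": (131.19, 162.9, 5.7, 0.0, 1.9),
    "F": (147.18, 189.9, 5.2, 0.0, 2.8),
    "P": (97.12, 112.7, 8.0, 0.0, -1.6),
    "S": (87.08, 89.0, 9.2, 0.0, -0.8),
    "T": (101.10, 116.1, 8.6, 0.0, -0.7),
    "W": (186.21, 227.8, 5.4, 0.0, -0.9),
    "Y": (163.18, 193.6, 6.2, 0.0, -1.3),
    "V": (99.13, 140.0, 5.9, 0.0, 4.2),
}

PROPERTIES = pd.DataFrame.from_dict(
    _ROWS, orient="index",
    columns=["mass", "volume", "polarity", "charge", "hydropathy"],
)
PROPERTIES.index.name = "aa"

PROPERTY_NAMES = list(PROPERTIES.columns)


def delta(prop: str, wt_aa: str, mut_aa: str) -> float:
    """Signed property difference mut - wt (antisymmetric under swap).

    Returns NaN for stop codons, which have no residue properties.
    """
    if wt_aa not in PROPERTIES.index or mut_aa not in PROPERTIES.index:
        return float("nan")
    return float(PROPERTIES.loc[mut_aa, prop] - PROPERTIES.loc[wt_aa, prop])
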
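"""Small curated genus matrices for calibration and worked examples.

These tiny presence/absence tables transcribe per-genus observations reported
in the comparative-genomics literature on Firmicutes engulfment proteins:

* ``desulfitobacterium_profiles`` — a 5-species genus in which one species
  (D. dehalogenans) lacks SpoIIIAA and SpoIID and two others
  (D. metallireducens, D. dichloroeliminans) lack GerM, while the rest carry
  the full complement. Under the species-rows checkerboard convention this
  genus scores C = 0.4 (not significant at the 0.2 threshold).
* ``geobacillus_profiles`` — a 16-species genus with identical profiles
  (everything except SpoIIB), scoring C = 0 with signature
  ``Spo0A-Q:AH-DMP-GerM``.

They are inputs for calibration of the orientation convention, not outputs
of this package's predictor.
"""

from __future__ import annotations

import pandas as pd

PROTEIN_UNIVERSE = [
    "Spo0A",
    "SpoIIIAA", "SpoIIIAB", "SpoIIIAC", "SpoIIIAD",
    "SpoIIIAE", "SpoIIIAF", "SpoIIIAG", "SpoIIIAH",
    "SpoIIQ", "SpoIID", "SpoIIM", "SpoIIP", "SpoIIB", "GerM",
]


def _profiles(rows: dict[str, set[str]]) -> pd.DataFrame:
    """Build a binary frame from per-species sets of ABSENT proteins."""
    data = {
        sp: [0 if p in absent else 1 for p in PROTEIN_UNIVERSE]
        for sp, absent in rows.items()
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=PROTEIN_UNIVERSE)
    df.index.name = "species_id"
    return df


def desulfitobacterium_profiles() -> pd.DataFrame:
    return _profiles(
        {
            "D_dehalogenans_ATCC51507": {"SpoIIIAA", "SpoIID"},
            "D_metallireducens_DSM15288": {"GerM"},
            "D_dichloroeliminans_LMGP21439": {"GerM"},
            "D_hafniense_Y51": set(),
            "D_hafniense_DCB2": set(),
        }
    )


def geobacillus_profiles() -> pd.DataFrame:
    return _profiles({f"Geobacillus_sp_{i:02d}": {"SpoIIB"} for i in range(1, 17)})
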
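"""Reference mature miRNA sequences (miRBase release 19, human).

The mir-16 family plus the two other blood-cell-derived species used in
the worked examples.  The family shares its 5' sequence — the first
nine bases are identical in four members, while hsa-miR-424-5p and
hsa-miR-497-5p carry a cytosine instead of a uracil at position 1 —
which is exactly the structure that drives on-family blocking and
first-position escape.
"""

from __future__ import annotations

from .sequence_io import MatureMiRNA

MIRBASE_V19 = {
    "hsa-miR-16-5p": "UAGCAGCACGUAAAUAUUGGCG",
    "hsa-miR-15a-5p": "UAGCAGCACAUAAUGGUUUGUG",
    "hsa-miR-15b-5p": "UAGCAGCACAUCAUGGUUUACA",
    "hsa-miR-195-5p": "UAGCAGCACAGAAAUAUUGGC",
    "hsa-miR-424-5p": "CAGCAGCAAUUCAUGUUUUGAA",
    "hsa-miR-497-5p": "CAGCAGCACACUGUGGUUUGU",
    "hsa-miR-503-5p": "UAGCAGCGGGAACAGUUCUGCAG",
    "hsa-miR-451a": "AAACCGUUACCAUUACUGAGUU",
}

MIR16_FAMILY = (
    "hsa-miR-16-5p",
    "hsa-miR-15a-5p",
    "hsa-miR-15b-5p",
    "hsa-miR-195-5p",
    "hsa-miR-424-5p",
    "hsa-miR-497-5p",
)


def mirna(name: str) -> MatureMiRNA:
    return MatureMiRNA(name=name, sequence=MIRBASE_V19[name])


def mir16_family() -> list[MatureMiRNA]:
    """The six mir-16 family members, canonical order."""
    return [mirna(n) for n in MIR16_FAMILY]
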
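"""Small registry of antibacterial drugs used by the example knowledge base.

Maps drug identifiers to WHO ATC codes (all systemic antibacterials, J01)
and to the allergy-relevant drug class used for deviation decisions.
"""

from __future__ import annotations

#: drug id -> (ATC code, drug class)
DRUGS: dict[str, tuple[str, str]] = {
    "piperacillin-tazobactam": ("J01CR05", "penicillin"),
    "amoxicillin": ("J01CA04", "penicillin"),
    "amoxicillin-clavulanate": ("J01CR02", "penicillin"),
    "flucloxacillin": ("J01CF05", "penicillin"),
    "pheneticillin": ("J01CE05", "penicillin"),
    "ceftriaxone": ("J01DD04", "cephalosporin"),
    "cefazolin": ("J01DB04", "cephalosporin"),
    "ciprofloxacin": ("J01MA02", "fluoroquinolone"),
    "gentamicin": ("J01GB03", "aminoglycoside"),
    "nitrofurantoin": ("J01XE01", "nitrofuran"),
    "doxycycline": ("J01AA02", "tetracycline"),
    "cotrimoxazole": ("J01EE01", "sulfonamide"),
    "metronidazole": ("J01XD01", "nitroimidazole"),
    "meropenem": ("J01DH02", "carbapenem"),
    "vancomycin": ("J01XA01", "glycopeptide"),
}


def atc_for(drug: str) -> str:
    """ATC code for a registered drug id."""
    return DRUGS[drug][0]


def class_for(drug: str) -> str:
    """Allergy drug class for a registered drug id."""
    return DRUGS[drug][1]
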
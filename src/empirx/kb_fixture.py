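"""Illustrative example knowledge base.

Seven diagnosis pathways (sepsis, pneumonia, urinary tract infection, fever
of unknown origin, meningitis, secondary peritonitis, liver abscess), each
with an IgE-allergy question and an obligatory antibiogram-review gate
before the advice; the pneumonia pathway splits hospital- vs
community-acquired and grades community-acquired severity by CURB-65 risk.

The content is ILLUSTRATIVE, not a clinical product: drug choices follow
common empirical patterns (piperacillin-tazobactam first choice for
hospital-acquired and severe community-acquired pneumonia, nitrofurantoin
for uncomplicated urinary tract infection) but dose amounts and eGFR band
thresholds are placeholders, not guideline values.
"""

from __future__ import annotations

from .knowledge_base import KnowledgeBase, load_kb


def _q(prompt, edges, binding=None, answers=None):
    node = {"kind": "question", "prompt": prompt, "edges": edges,
            "answers": answers or sorted(edges)}
    if binding:
        node["data_binding"] = binding
    return node


def _gate(next_node, window_days=183):
    return {"kind": "gate", "gate_kind": "antibiogram_review",
            "window_days": window_days, "next": next_node}


def _adv(drugs, duration, alternatives=(), notes=""):
    def reg(drug_list, dur):
        return {
            "drugs": [{"drug": d, "route": r} for d, r in drug_list],
            "duration_days": dur,
        }

    regimen = reg(drugs, duration)
    regimen["alternatives"] = [reg(a, duration) for a in alternatives]
    if notes:
        regimen["notes"] = notes
    return {"kind": "advice", "regimen": regimen}


_CONSULT = {"kind": "advice", "consult": True}

_ALLERGY_PROMPT = "Does the patient have an IgE-mediated beta-lactam allergy?"

_RAW = {
    "version": "example-1",
    "diagnoses": {
        "pneumonia": {
            "root": "q_acquired",
            "nodes": {
                "q_acquired": _q(
                    "Where was the pneumonia acquired?",
                    {"hospital": "q_allergy_hap", "community": "q_curb"},
                ),
                "q_curb": _q(
                    "CURB-65 risk level?",
                    {"low": "q_allergy_cap_low",
                     "moderate": "q_allergy_cap_sev",
                     "high": "q_allergy_cap_sev"},
                ),
                "q_allergy_hap": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_hap", "yes": "gate_hap_a"},
                    binding="ige_allergy",
                ),
                "gate_hap": _gate("adv_hap"),
                "gate_hap_a": _gate("adv_hap_a"),
                "adv_hap": _adv(
                    [("piperacillin-tazobactam", "iv")], 7,
                    alternatives=[[("ceftriaxone", "iv")], [("ciprofloxacin", "iv")]],
                ),
                "adv_hap_a": _adv(
                    [("ciprofloxacin", "iv")], 7,
                    alternatives=[[("gentamicin", "iv")]],
                ),
                "q_allergy_cap_low": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_cap_low", "yes": "gate_cap_low_a"},
                    binding="ige_allergy",
                ),
                "gate_cap_low": _gate("adv_cap_low"),
                "gate_cap_low_a": _gate("adv_cap_low_a"),
                "adv_cap_low": _adv(
                    [("doxycycline", "oral")], 5,
                    alternatives=[[("amoxicillin", "oral")]],
                ),
                "adv_cap_low_a": _adv([("doxycycline", "oral")], 5,
                                      alternatives=[[("ciprofloxacin", "oral")]]),
                "q_allergy_cap_sev": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_cap_sev", "yes": "gate_cap_sev_a"},
                    binding="ige_allergy",
                ),
                "gate_cap_sev": _gate("adv_cap_sev"),
                "gate_cap_sev_a": _gate("adv_cap_sev_a"),
                "adv_cap_sev": _adv(
                    [("piperacillin-tazobactam", "iv")], 7,
                    alternatives=[[("ceftriaxone", "iv")]],
                ),
                "adv_cap_sev_a": _adv(
                    [("ciprofloxacin", "iv")], 7,
                    alternatives=[[("gentamicin", "iv")]],
                ),
            },
        },
        "urinary_tract_infection": {
            "root": "q_complicated",
            "nodes": {
                "q_complicated": _q(
                    "Is this a complicated urinary tract infection?",
                    {"no": "q_pregnant", "yes": "q_allergy_uti_c"},
                ),
                "q_pregnant": _q(
                    "Is the patient pregnant?",
                    {"no": "gate_uti_u", "yes": "gate_uti_p"},
                    binding="pregnant",
                ),
                "gate_uti_u": _gate("adv_uti_u"),
                "gate_uti_p": _gate("adv_uti_p"),
                "adv_uti_u": _adv(
                    [("nitrofurantoin", "oral")], 5,
                    alternatives=[[("ciprofloxacin", "oral")]],
                ),
                "adv_uti_p": _adv(
                    [("amoxicillin-clavulanate", "oral")], 5,
                    alternatives=[[("nitrofurantoin", "oral")]],
                ),
                "q_allergy_uti_c": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_uti_c", "yes": "gate_uti_ca"},
                    binding="ige_allergy",
                ),
                "gate_uti_c": _gate("adv_uti_c"),
                "gate_uti_ca": _gate("adv_uti_ca"),
                "adv_uti_c": _adv(
                    [("ciprofloxacin", "iv")], 10,
                    alternatives=[[("gentamicin", "iv")]],
                ),
                "adv_uti_ca": _adv([("gentamicin", "iv")], 7),
            },
        },
        "sepsis": {
            "root": "q_allergy_sep",
            "nodes": {
                "q_allergy_sep": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_sep", "yes": "gate_sep_a"},
                    binding="ige_allergy",
                ),
                "gate_sep": _gate("adv_sep"),
                "gate_sep_a": _gate("adv_sep_a"),
                "adv_sep": _adv(
                    [("piperacillin-tazobactam", "iv"), ("gentamicin", "iv")], 7,
                    alternatives=[[("ceftriaxone", "iv"), ("gentamicin", "iv")]],
                ),
                "adv_sep_a": _adv(
                    [("ciprofloxacin", "iv"), ("gentamicin", "iv")], 7,
                ),
            },
        },
        "fever_of_unknown_origin": {
            "root": "q_neutro",
            "nodes": {
                "q_neutro": _q(
                    "Is the patient neutropenic (< 0.5 x 10^9/L)?",
                    {"no": "q_allergy_fuo", "yes": "adv_fuo_consult"},
                    binding="neutropenic",
                ),
                "adv_fuo_consult": dict(_CONSULT),
                "q_allergy_fuo": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_fuo", "yes": "gate_fuo_a"},
                    binding="ige_allergy",
                ),
                "gate_fuo": _gate("adv_fuo"),
                "gate_fuo_a": _gate("adv_fuo_a"),
                "adv_fuo": _adv(
                    [("amoxicillin-clavulanate", "iv")], 7,
                    alternatives=[[("ciprofloxacin", "iv")]],
                ),
                "adv_fuo_a": _adv(
                    [("ciprofloxacin", "iv")], 7,
                    alternatives=[[("gentamicin", "iv")]],
                ),
            },
        },
        "meningitis": {
            "root": "q_allergy_men",
            "nodes": {
                "q_allergy_men": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_men", "yes": "adv_men_consult"},
                    binding="ige_allergy",
                ),
                "gate_men": _gate("adv_men"),
                "adv_men": _adv([("ceftriaxone", "iv")], 14),
                "adv_men_consult": dict(_CONSULT),
            },
        },
        "secondary_peritonitis": {
            "root": "q_allergy_per",
            "nodes": {
                "q_allergy_per": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_per", "yes": "gate_per_a"},
                    binding="ige_allergy",
                ),
                "gate_per": _gate("adv_per"),
                "gate_per_a": _gate("adv_per_a"),
                "adv_per": _adv(
                    [("ceftriaxone", "iv"), ("metronidazole", "iv")], 7,
                    alternatives=[[("ciprofloxacin", "iv"), ("metronidazole", "iv")]],
                ),
                "adv_per_a": _adv(
                    [("ciprofloxacin", "iv"), ("metronidazole", "iv")], 7,
                ),
            },
        },
        "liver_abscess": {
            "root": "q_allergy_liv",
            "nodes": {
                "q_allergy_liv": _q(
                    _ALLERGY_PROMPT,
                    {"no": "gate_liv", "yes": "adv_liv_consult"},
                    binding="ige_allergy",
                ),
                "gate_liv": _gate("adv_liv"),
                "adv_liv": _adv(
                    [("amoxicillin-clavulanate", "iv"), ("gentamicin", "iv")], 14,
                    alternatives=[[("ceftriaxone", "iv"), ("metronidazole", "iv")]],
                ),
                "adv_liv_consult": dict(_CONSULT),
            },
        },
    },
    "dose_rules": {
        "piperacillin-tazobactam": {
            "drug_class": "penicillin",
            "rows": [
                {"egfr_min": 50, "dose_amount": 4.5, "dose_unit": "g", "interval_hours": 8},
                {"egfr_min": 30, "egfr_max": 50, "dose_amount": 4.5, "dose_unit": "g",
                 "interval_hours": 12},
                {"egfr_min": 10, "egfr_max": 30, "dose_amount": 2.25, "dose_unit": "g",
                 "interval_hours": 12},
                {"egfr_min": 0, "egfr_max": 10, "consult": True},
            ],
        },
        "ceftriaxone": {
            "drug_class": "cephalosporin",
            "rows": [{"dose_amount": 2, "dose_unit": "g", "interval_hours": 24}],
        },
        "ciprofloxacin": {
            "drug_class": "fluoroquinolone",
            "rows": [
                {"egfr_min": 50, "dose_amount": 400, "dose_unit": "mg",
                 "interval_hours": 12, "pregnancy_allowed": False},
                {"egfr_min": 30, "egfr_max": 50, "dose_amount": 400, "dose_unit": "mg",
                 "interval_hours": 24, "pregnancy_allowed": False},
                {"egfr_min": 10, "egfr_max": 30, "dose_amount": 400, "dose_unit": "mg",
                 "interval_hours": 24, "pregnancy_allowed": False},
                {"egfr_min": 0, "egfr_max": 10, "consult": True},
            ],
        },
        "gentamicin": {
            "drug_class": "aminoglycoside",
            "rows": [
                {"egfr_min": 50, "dose_amount": 5, "dose_unit": "mg/kg",
                 "interval_hours": 24, "weight_basis": "ideal",
                 "pregnancy_allowed": False},
                {"egfr_min": 30, "egfr_max": 50, "dose_amount": 5, "dose_unit": "mg/kg",
                 "interval_hours": 36, "weight_basis": "ideal",
                 "pregnancy_allowed": False},
                {"egfr_min": 10, "egfr_max": 30, "dose_amount": 5, "dose_unit": "mg/kg",
                 "interval_hours": 48, "weight_basis": "ideal",
                 "pregnancy_allowed": False},
                {"egfr_min": 0, "egfr_max": 10, "consult": True},
            ],
        },
        "nitrofurantoin": {
            "drug_class": "nitrofuran",
            "rows": [
                {"egfr_min": 30, "dose_amount": 100, "dose_unit": "mg",
                 "interval_hours": 12},
                {"egfr_min": 0, "egfr_max": 30, "consult": True},
            ],
        },
        "amoxicillin-clavulanate": {
            "drug_class": "penicillin",
            "rows": [
                {"egfr_min": 50, "dose_amount": 625, "dose_unit": "mg",
                 "interval_hours": 8},
                {"egfr_min": 30, "egfr_max": 50, "dose_amount": 625, "dose_unit": "mg",
                 "interval_hours": 12},
                {"egfr_min": 10, "egfr_max": 30, "dose_amount": 625, "dose_unit": "mg",
                 "interval_hours": 12},
                {"egfr_min": 0, "egfr_max": 10, "consult": True},
            ],
        },
        "amoxicillin": {
            "drug_class": "penicillin",
            "rows": [
                {"egfr_min": 30, "dose_amount": 500, "dose_unit": "mg",
                 "interval_hours": 8},
                {"egfr_min": 10, "egfr_max": 30, "dose_amount": 500, "dose_unit": "mg",
                 "interval_hours": 12},
                {"egfr_min": 0, "egfr_max": 10, "consult": True},
            ],
        },
        "doxycycline": {
            "drug_class": "tetracycline",
            "rows": [{"dose_amount": 100, "dose_unit": "mg", "interval_hours": 12,
                      "pregnancy_allowed": False}],
        },
        "metronidazole": {
            "drug_class": "nitroimidazole",
            "rows": [{"dose_amount": 500, "dose_unit": "mg", "interval_hours": 8}],
        },
    },
}


def example_kb() -> KnowledgeBase:
    """Build and load the example knowledge base."""
    return load_kb(_RAW)


def example_kb_dict() -> dict:
    """The raw (pre-load) mapping, for schema/serialization tests."""
    import copy

    return copy.deepcopy(_RAW)
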
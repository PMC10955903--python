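"""Template banks for synthetic discharge summaries.

Two parallel banks (English-like, default, and a minimal French one) exercise
identical span/qualifier geometry: each template embeds exactly one keyword
slot ``{kw}`` inside the requested qualification context — e.g. a negation
trigger from the shipped trigger lexicon within the scope window before the
keyword.  The banks are ordinary module data and can be edited or replaced;
they aim at geometric coverage of the detection rules, not at realistic
clinical language.

Keyword surfaces listed here are literal strings matched by the shipped
lexicons; generator and detector are developed against the same geometry so
that corpora built from these templates round-trip exactly.
"""

from __future__ import annotations

AFFIRMED = "affirmed"

#: qualification contexts a synthetic mention can be embedded in
CONTEXTS = ("affirmed", "negation", "family", "history", "hypothesis", "reported_speech")

# -- suicide-attempt keyword surfaces by modality ---------------------------

SA_SURFACES: dict[str, dict[str, list[str]]] = {
    "en": {
        "other": ["suicide attempt", "attempted suicide"],
        "intentional-drug-overdose": ["intentional drug overdose",
                                      "voluntary drug intoxication"],
        "hanging": ["attempted hanging", "hanging attempt"],
        "jump-from-height": ["jumped from a height", "voluntary defenestration"],
        "phlebotomy": ["self-inflicted wrist laceration"],
        "firearm": ["self-inflicted gunshot wound"],
        "drowning": ["intentional drowning"],
    },
    "fr": {
        "other": ["tentative de suicide"],
        "intentional-drug-overdose": ["intoxication médicamenteuse volontaire",
                                      "ingestion médicamenteuse volontaire"],
        "hanging": ["tentative de pendaison"],
        "jump-from-height": ["défenestration volontaire"],
        "phlebotomy": ["phlébotomie"],
        "firearm": ["plaie par arme à feu auto-infligée"],
        "drowning": ["noyade volontaire"],
    },
}

# -- sentence templates by qualification context ----------------------------

SA_TEMPLATES: dict[str, dict[str, list[str]]] = {
    "en": {
        "affirmed": [
            "Admission for {kw} on the day of arrival.",
            "The clinical examination confirmed a {kw}.",
            "Emergency admission following a {kw} requiring close monitoring.",
        ],
        "negation": [
            "The interview found no {kw} during this stay.",
            "The team noted there was no {kw} to report.",
        ],
        "family": [
            "Her mother experienced a {kw} in her youth.",
            "His brother survived a {kw} two winters back.",
        ],
        "history": [
            "History of {kw} noted in the chart.",
            "A previous {kw} was documented at another centre.",
        ],
        "hypothesis": [
            "A possible {kw} could not be ruled out.",
            "There is a risk of {kw} to monitor closely.",
        ],
        "reported_speech": [
            "The patient reports a {kw} that was not witnessed.",
            "According to the companion a {kw} may have occurred.",
        ],
    },
    "fr": {
        "affirmed": [
            "Hospitalisation pour {kw} le jour même.",
            "L'examen clinique confirme une {kw}.",
            "Admission en urgence après une {kw} nécessitant une surveillance.",
        ],
        "negation": [
            "L'entretien ne retrouve pas de {kw} pendant le séjour.",
        ],
        "family": [
            "Sa mère a présenté une {kw} dans sa jeunesse.",
        ],
        "history": [
            "Antécédent de {kw} noté dans le dossier.",
        ],
        "hypothesis": [
            "Suspicion de {kw} à l'arrivée.",
        ],
        "reported_speech": [
            "Le patient rapporte une {kw} non témoignée.",
        ],
    },
}

# -- risk factor surfaces and affirmed sentences ----------------------------

RF_SURFACES: dict[str, dict[str, str]] = {
    "en": {
        "social_isolation": "social isolation",
        "domestic_violence": "domestic violence",
        "sexual_violence": "sexual violence",
        "physical_violence": "physical violence",
        "sa_history": "previous suicide attempt",
    },
    "fr": {
        "social_isolation": "isolement social",
        "domestic_violence": "violence conjugale",
        "sexual_violence": "agression sexuelle",
        "physical_violence": "violence physique",
        "sa_history": "antécédent de tentative de suicide",
    },
}

RF_TEMPLATES: dict[str, dict[str, list[str]]] = {
    "en": {
        "social_isolation": ["The assessment highlighted {kw} at home."],
        "domestic_violence": ["She disclosed ongoing {kw} within the household."],
        "sexual_violence": ["The examination documented {kw} occurring recently."],
        "physical_violence": ["The patient suffered repeated {kw} at home."],
        "sa_history": ["{kw} noted in the chart, managed elsewhere."],
    },
    "fr": {
        "social_isolation": ["L'évaluation retrouve un {kw} marqué."],
        "domestic_violence": ["Elle décrit une {kw} persistante au domicile."],
        "sexual_violence": ["L'examen documente une {kw} récente."],
        "physical_violence": ["La patiente a subi une {kw} répétée."],
        "sa_history": ["{kw} noté dans le dossier, pris en charge ailleurs."],
    },
}

# -- boilerplate ------------------------------------------------------------

OPENINGS = {
    "en": ["Hospitalisation summary.", "Discharge summary of the stay."],
    "fr": ["Compte rendu d'hospitalisation.", "Synthèse du séjour."],
}

CLOSINGS = {
    "en": ["Follow-up organised with the referring team.",
           "Outpatient follow-up planned."],
    "fr": ["Suivi organisé avec l'équipe référente.",
           "Suivi ambulatoire programmé."],
}

BACKGROUND_BODY = {
    "en": ["Scheduled management of a chronic condition. The stay proceeded "
           "uneventfully and the patient returned home.",
           "Elective procedure performed as planned. Simple postoperative course."],
    "fr": ["Prise en charge programmée d'une pathologie chronique. Séjour "
           "simple, retour au domicile.",
           "Geste programmé réalisé comme prévu. Suites simples."],
}

ADMISSION_NOTE_SA = {
    "en": "Admitted after a suicide attempt. Full report to follow.",
    "fr": "Admission après tentative de suicide. Compte rendu à venir.",
}

ADMISSION_NOTE_PLAIN = {
    "en": "Admission note. Clinical details to follow.",
    "fr": "Note d'admission. Précisions cliniques à venir.",
}

DRAFT_SUMMARY = {
    "en": "Preliminary summary. Hospitalisation in progress, report pending.",
    "fr": "Synthèse préliminaire. Hospitalisation en cours, compte rendu en attente.",
}
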
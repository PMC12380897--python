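"""Synthetic SmPC corpus generator with paired gold minimal-IDMP records.

Real SmPC corpora are proprietary, so every pipeline stage is exercised on
grammar-generated documents instead: each document follows the EMA QRD
chapter layout (numbered chapters 1-10 with subsections), describes a single
dosage form and packaging configuration, and embeds every gold value verbatim
(or in a deterministic surface variant) in the chapter the rule-based
retriever maps to that field.

The generator deliberately produces exactly the surface variations the
normalization stage exists to undo: ranged vs. enumerated authorization
numbers, four date renderings, salt-vs-base active-substance phrasing,
default-vs-explicit storage phrases, and nested packaging narratives with
measuring-spoon components (the level-4 complexity class).  The grammar is
invertible — the deterministic reference extraction backend recovers the gold
values from the rendered text — which gives the test suite a closed loop with
a known answer.

Documents also include the standard safety chapters (4.3-4.9, 5.2-5.3, 6.2,
6.6) filled with generic prose so that documents are long enough for top-k
chunk retrieval to be a real ranking problem rather than a whole-document
pass-through.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .idmp_model import record_skeleton, STORAGE_DEFAULT_PHRASE
from .smpc_io import SmpcDocument, parse_smpc, write_idmp_json

__all__ = ["CorpusProfile", "generate_document", "generate_corpus", "write_corpus"]


@dataclass(frozen=True)
class CorpusProfile:
    """Knobs controlling corpus composition; defaults mirror the study corpus
    (81 single-form documents, all four complexity levels represented)."""

    n_documents: int = 81
    seed: int = 0
    # probability that a document carries level-3 (salt/base + container
    # detail) and, given level 3 and a powder form, level-4 packaging content
    level_mix: tuple[float, float] = (0.8, 0.85)
    range_probability: float = 0.5
    # weights over (iso, long_eu, long_us, numeric_day_first) date renderings
    date_format_mix: tuple[float, float, float, float] = (0.3, 0.4, 0.2, 0.1)
    packaging_complexity: int = 3  # max number of measuring-spoon components

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        for p in (*self.level_mix, self.range_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# --- lexicons ---------------------------------------------------------------

_BRAND_PRE = ["Zel", "Nor", "Vel", "Axo", "Lum", "Teb", "Ori", "Cal", "Dex",
              "Fir", "Gal", "Hel", "Ixa", "Jov", "Kel", "Mir", "Nev", "Oza",
              "Pral", "Quin", "Rud", "Sol", "Tav", "Ulm", "Vor"]
_BRAND_MID = ["va", "ti", "ro", "ne", "mi", "da", "lu", "sa", "ve", "co"]
_BRAND_SUF = ["tra", "xil", "don", "zine", "vir", "lol", "stat", "min", "pra", "dex"]

_BASES = ["aripiprazole", "pantoprazole", "metformin", "sitagliptin", "olanzapine",
          "rivaroxaban", "levofloxacin", "duloxetine", "rosuvastatin", "candesartan",
          "escitalopram", "dapagliflozin", "lamotrigine", "voriconazole",
          "pregabalin", "montelukast", "ezetimibe", "quetiapine", "valsartan",
          "tenofovir"]
_SALT_SUFFIXES = ["hydrochloride", "sodium", "maleate", "hemifumarate",
                  "tartrate", "mesylate", "besylate", "succinate"]

_EXCIPIENTS = ["Lactose monohydrate", "Magnesium stearate",
               "Microcrystalline cellulose", "Maize starch", "Povidone",
               "Croscarmellose sodium", "Sucrose", "Talc",
               "Colloidal anhydrous silica", "Hypromellose", "Titanium dioxide",
               "Sodium starch glycolate"]

_CONDITIONS = ["major depressive episodes", "type 2 diabetes mellitus",
               "chronic obstructive pulmonary disease",
               "moderate to severe plaque psoriasis", "partial-onset seizures",
               "essential hypertension", "acute bacterial sinusitis",
               "generalised anxiety disorder", "venous thromboembolism",
               "schizophrenia"]

_PHARM_GROUPS = ["antipsychotics", "proton pump inhibitors",
                 "blood glucose lowering drugs", "antithrombotic agents",
                 "antidepressants", "lipid modifying agents",
                 "antiepileptics", "quinolone antibacterials"]

# (company, street, postal line, country) kept coherent per index
_HOLDERS = [
    ("Les Laboratoires Delmare", "12, avenue des Tilleuls", "92284 Suresnes cedex", "France"),
    ("Nordheim Pharma GmbH", "Industriestrasse 45", "80331 Munchen", "Germany"),
    ("Iberis Farmaceutica S.L.", "Calle Mayor 8", "28013 Madrid", "Spain"),
    ("Danubia Pharma Kft.", "Fo utca 9", "1051 Budapest", "Hungary"),
    ("Tirrenia Farmaceutici S.p.A.", "Via Roma 23", "00184 Roma", "Italy"),
    ("Koldinghus Laegemidler ApS", "Hovedgaden 17", "2000 Frederiksberg", "Denmark"),
    ("Batavia Medicines B.V.", "Keizersgracht 201", "1015 Amsterdam", "Netherlands"),
    ("Alba Pharmaceuticals Ltd.", "Harbour Lane 4", "D02 XY45 Dublin", "Ireland"),
]

# (authorized form capitalised, product-name form phrase, administrable form,
#  unit of presentation, is_powder)
_FORMS = [
    ("Film-coated tablet", "film-coated tablets", "film-coated tablet", "tablet", False),
    ("Gastro-resistant tablet", "gastro-resistant tablets", "gastro-resistant tablet", "tablet", False),
    ("Hard capsule", "hard capsules", "hard capsule", "capsule", False),
    ("Prolonged-release tablet", "prolonged-release tablets", "prolonged-release tablet", "tablet", False),
    ("Powder for oral suspension", "powder for oral suspension", "oral suspension", "dose", True),
    ("Powder for oral solution", "powder for oral solution", "oral solution", "dose", True),
]

_CONTAINERS = [("bottle", "HDPE"), ("bottle", "glass"), ("jar", "polypropylene")]
_CONTAINER_COLORS = ["White opaque", "Amber", "Clear"]
_CAP_MATERIALS = ["polypropylene", "polyethylene"]
_SPOON_COLORS = ["green", "blue", "purple", "red", "yellow"]
_SPOON_DOSES = ["100 mg", "150 mg", "250 mg", "500 mg", "1 g"]
_COUNT_WORDS = {1: "one", 2: "two", 3: "three", 4: "four"}

_SHELF_LIVES = ["3 years", "2 years", "30 months", "6 years", "18 months"]
_STORAGE_EXPLICIT = [
    "Store below 25 °C.",
    "Store in the original package in order to protect from moisture.",
    "Store in a refrigerator (2 °C - 8 °C).",
    "Do not freeze.",
]

# generic safety prose; avoids the key query terms of the extracted fields
_FILLER = [
    "Caution is advised in patients with hepatic impairment.",
    "Renal function should be monitored periodically during prolonged therapy.",
    "Concomitant intake of strong CYP3A4 inhibitors may increase plasma exposure.",
    "Patients should be advised to report any unexplained muscle pain or weakness.",
    "No clinically relevant interaction with food was observed in clinical studies.",
    "The most frequently reported adverse reactions were headache and nausea.",
    "Dizziness and somnolence have been reported; patients should exercise caution when driving.",
    "There are limited data from the use of this substance in pregnant women.",
    "Animal studies do not indicate direct or indirect harmful effects with respect to reproductive toxicity.",
    "A risk to newborns and infants cannot be excluded during breast-feeding.",
    "In the event of overdose, treatment should be symptomatic and supportive.",
    "Haemodialysis is unlikely to remove significant quantities of the active moiety.",
    "Hypersensitivity to the active substance or to any of the excipients listed in section 6.1.",
    "Absorption is rapid, with peak plasma concentrations reached within two hours.",
    "Elimination occurs predominantly via the faeces, with a terminal half-life of about twelve hours.",
    "Plasma protein binding is approximately ninety-four percent.",
    "Steady state is reached after approximately five days of once daily dosing.",
    "Non-clinical data reveal no special hazard for humans based on conventional studies of safety pharmacology.",
    "Carcinogenicity studies in rodents showed no treatment-related neoplastic findings.",
    "In the absence of compatibility studies, this product must not be mixed with other products.",
    "Any unused product or waste material should be disposed of in accordance with local requirements.",
    "Elderly patients do not require an adjustment of the recommended amount.",
    "Treatment should be initiated under the supervision of a physician experienced in the relevant therapeutic area.",
    "Periodic liver function testing is recommended during the first six months of treatment.",
]


def _filler_block(rng: random.Random, n_lo: int = 9, n_hi: int = 14) -> str:
    n = rng.randint(n_lo, n_hi)
    return " ".join(rng.choice(_FILLER) for _ in range(n))


def _render_date(iso: str, rng: random.Random, mix) -> str:
    from datetime import date

    d = date.fromisoformat(iso)
    style = rng.choices(["iso", "long_eu", "long_us", "numeric"], weights=mix)[0]
    if style == "iso":
        return iso
    if style == "long_eu":
        return f"{d.day} {d.strftime('%B')} {d.year}"
    if style == "long_us":
        return f"{d.strftime('%B')} {d.day}, {d.year}"
    return f"{d.day:02d}/{d.month:02d}/{d.year}"


def _random_date(rng: random.Random, lo_year: int, hi_year: int) -> str:
    from datetime import date

    return date(rng.randint(lo_year, hi_year), rng.randint(1, 12),
                rng.randint(1, 28)).isoformat()


def _brand(index: int) -> str:
    """Distinct brand name from a combinatorial syllable space (prefix varies
    fastest; unique for the first 2500 indices)."""
    n_pre, n_mid = len(_BRAND_PRE), len(_BRAND_MID)
    pre = _BRAND_PRE[index % n_pre]
    mid = _BRAND_MID[(index // n_pre) % n_mid]
    suf = _BRAND_SUF[(index // (n_pre * n_mid)) % len(_BRAND_SUF)]
    return pre + mid + suf


def generate_document(
    profile: CorpusProfile, rng: random.Random, index: int = 0
) -> tuple[SmpcDocument, dict]:
    """Render one SmPC and its gold record; gold is canonical (already
    normalized)."""
    gold = record_skeleton()

    brand = _brand(rng.randrange(len(_BRAND_PRE) * len(_BRAND_MID) * len(_BRAND_SUF))
                   if profile.n_documents == 1 else index)
    auth_form, name_form, admin_form, unit, is_powder = rng.choice(_FORMS)
    base = rng.choice(_BASES)
    base_dose_mg = rng.choice([5, 10, 20, 25, 50, 100, 250, 500])
    strength = f"{base_dose_mg} mg"
    product_name = f"{brand} {strength} {name_form}"

    include_l3 = rng.random() < profile.level_mix[0]
    include_l4 = is_powder and include_l3 and rng.random() < profile.level_mix[1]

    atc = (rng.choice("ABCDGHJLMNPRSV") + f"{rng.randint(1, 16):02d}"
           + rng.choice("ABCDEF") + rng.choice("ABCDEFGHX")
           + f"{rng.randint(1, 99):02d}")
    group = rng.choice(_PHARM_GROUPS)

    holder = rng.choice(_HOLDERS)
    condition = rng.choice(_CONDITIONS)
    route = "oral use"

    # --- composition ---
    if include_l3:
        salt = f"{base} {rng.choice(_SALT_SUFFIXES)}"
        salt_dose = f"{round(base_dose_mg * rng.choice([1.07, 1.14, 1.23]), 1)} mg"
        comp_sentence = (
            f"Each {unit} contains {salt_dose} of {salt} "
            f"equivalent to {strength} of {base}."
        )
        active = {
            "active_substance_salt": {"value": salt, "dosage": salt_dose},
            "active_substance_base": {"value": base, "dosage": strength},
        }
    else:
        comp_sentence = f"Each {unit} contains {strength} of {base}."
        active = {
            "active_substance_salt": {"value": "", "dosage": ""},
            "active_substance_base": {"value": base, "dosage": strength},
        }

    n_exc = rng.randint(2, 4)
    excipients = rng.sample(_EXCIPIENTS, n_exc)
    exc_doses = [f"{rng.choice([1, 2, 5, 10, 25, 40, 54, 80, 120])} mg"
                 for _ in range(n_exc)]

    # --- authorization ---
    first_auth = _random_date(rng, 2005, 2020)
    has_renewal = rng.random() < 0.6
    renewal = ""
    if has_renewal:
        renewal = f"{int(first_auth[:4]) + 5}{first_auth[4:]}"
    yy = int(first_auth[2:4])
    ma_prefix = f"EU/1/{yy:02d}/{rng.randint(1, 2999):04d}/"
    ranged = rng.random() < profile.range_probability
    n_pres = rng.randint(2, 5) if ranged else rng.randint(1, 5)
    gold_numbers = [f"{ma_prefix}{i:03d}" for i in range(1, n_pres + 1)]
    if ranged and n_pres >= 3:
        ma_surface = f"{ma_prefix}001, {ma_prefix}002-{n_pres:03d}"
    elif ranged:
        ma_surface = f"{ma_prefix}001-{n_pres:03d}"
    else:
        ma_surface = ", ".join(gold_numbers)

    # --- packaging ---
    container, material = rng.choice(_CONTAINERS)
    color = rng.choice(_CONTAINER_COLORS)
    cap = rng.choice(_CAP_MATERIALS)
    if is_powder:
        grams = rng.choice([90, 120, 180, 240])
        contents = f"{grams} g of powder"
    else:
        contents = f"{rng.choice([14, 28, 30, 56, 60, 90])} {unit}s"
    package_description = f"1 {container} of {contents}"

    container_sentences = []
    container_description = container_type = item_material = ""
    components: list[dict] = []
    if include_l3:
        container_description = (
            f"{color} {material} {container} with a child-resistant {cap} cap"
        )
        container_sentences.append(container_description + ".")
        container_type = container
        item_material = material
    if include_l4:
        n_comp = rng.randint(2, max(2, profile.packaging_complexity))
        colors = rng.sample(_SPOON_COLORS, n_comp)
        doses = rng.sample(_SPOON_DOSES, n_comp)
        container_sentences.append(
            f"Each pack contains 1 {container} with {contents} and "
            f"{_COUNT_WORDS[n_comp]} {cap} measuring spoons."
        )
        for c, d in zip(colors, doses):
            container_sentences.append(f"The {c} measuring spoon dispenses {d}.")
            components.append(
                {"value": d, "component": f"{c} measuring spoon", "material": cap}
            )
    container_sentences.append(f"Pack size: {package_description}.")

    shelf_life = rng.choice(_SHELF_LIVES)
    if rng.random() < 0.5:
        storage_surface = STORAGE_DEFAULT_PHRASE
        storage_gold = ""
    else:
        storage_surface = rng.choice(_STORAGE_EXPLICIT)
        storage_gold = storage_surface

    indication = (
        f"{brand} is indicated for the treatment of {condition} in adults."
    )

    first_auth_surface = _render_date(first_auth, rng, profile.date_format_mix)
    renewal_surface = (
        _render_date(renewal, rng, profile.date_format_mix) if has_renewal else ""
    )

    # --- gold record ---
    mp = gold["medicinal_product"]
    mp["product_name"] = product_name
    mp["atc_code"] = atc
    mp["authorized_pharmaceutical_form"] = auth_form
    ma = gold["marketing_authorization"]
    ma["marketing_authorization_number"] = gold_numbers
    ma["date_of_first_authorization"] = first_auth
    ma["date_of_latest_renewal"] = renewal
    mah = ma["marketing_authorization_holder"]
    mah["name"], mah["address"], mah["postal"], mah["country"] = holder
    gold["therapeutic_indications"]["therapeutic_indications_information"] = indication
    pk = gold["packaged_medicinal_product"]
    pk["package"]["package_description"] = package_description
    pc = pk["package"]["package_composition"]
    pc["container_description"] = container_description
    pc["container_type"] = container_type
    pc["package_item_material"] = item_material
    pc["package_component"] = components
    pk["shelf_life"]["value"] = shelf_life
    pk["shelf_life"]["special_precautions_for_storage"] = storage_gold
    gold["ingredients"]["composition_active"] = [active]
    gold["ingredients"]["composition_excipient"] = [
        {"excipient": e, "dosage": d} for e, d in zip(excipients, exc_doses)
    ]
    pp = gold["pharmaceutical_product"]
    pp["administrable_dose_form"] = admin_form
    pp["unit_of_presentation"] = unit
    pp["route_of_administration"] = route

    # --- document text ---
    lines: list[str] = []
    lines.append("SUMMARY OF PRODUCT CHARACTERISTICS")
    lines.append("")
    lines.append("1. NAME OF THE MEDICINAL PRODUCT")
    lines.append(product_name)
    lines.append("")
    lines.append("2. QUALITATIVE AND QUANTITATIVE COMPOSITION")
    lines.append(comp_sentence)
    lines.append(f"Excipient with known effect: {excipients[0].lower()}.")
    lines.append("For the full list of excipients, see section 6.1.")
    lines.append("")
    lines.append("3. PHARMACEUTICAL FORM")
    lines.append(f"{auth_form}.")
    lines.append(
        f"The administrable dose form is the {admin_form}, "
        f"presented as one {unit} per dose, for {route}."
    )
    lines.append("")
    lines.append("4. CLINICAL PARTICULARS")
    lines.append("4.1 Therapeutic indications")
    lines.append(indication)
    lines.append("4.2 Posology and method of administration")
    lines.append(f"The recommended amount is one {unit} daily. For {route}.")
    lines.append(_filler_block(rng, 2, 4))
    lines.append("4.3 Contraindications")
    lines.append(_filler_block(rng, 2, 4))
    lines.append("4.4 Special warnings and precautions for use")
    lines.append(_filler_block(rng))
    lines.append("4.5 Interaction with other medicinal products and other forms of interaction")
    lines.append(_filler_block(rng))
    lines.append("4.6 Fertility, pregnancy and lactation")
    lines.append(_filler_block(rng))
    lines.append("4.7 Effects on ability to drive and use machines")
    lines.append(_filler_block(rng, 2, 4))
    lines.append("4.8 Undesirable effects")
    lines.append(_filler_block(rng))
    lines.append("4.9 Overdose")
    lines.append(_filler_block(rng, 2, 4))
    lines.append("")
    lines.append("5. PHARMACOLOGICAL PROPERTIES")
    lines.append("5.1 Pharmacodynamic properties")
    lines.append(f"Pharmacotherapeutic group: {group}, ATC code: {atc}.")
    lines.append(_filler_block(rng, 2, 4))
    lines.append("5.2 Pharmacokinetic properties")
    lines.append(_filler_block(rng))
    lines.append("5.3 Preclinical safety data")
    lines.append(_filler_block(rng, 3, 5))
    lines.append("")
    lines.append("6. PHARMACEUTICAL PARTICULARS")
    lines.append("6.1 List of excipients")
    lines.extend(f"{e} ({d})" for e, d in zip(excipients, exc_doses))
    lines.append("6.2 Incompatibilities")
    lines.append(_filler_block(rng, 1, 2))
    lines.append("6.3 Shelf life")
    lines.append(f"Shelf life: {shelf_life}.")
    lines.append("6.4 Special precautions for storage")
    lines.append(storage_surface)
    lines.append("6.5 Nature and contents of container")
    lines.append(" ".join(container_sentences))
    lines.append("6.6 Special precautions for disposal")
    lines.append(_filler_block(rng, 1, 2))
    lines.append("")
    lines.append("7. MARKETING AUTHORISATION HOLDER")
    lines.extend(holder)
    lines.append("")
    lines.append("8. MARKETING AUTHORISATION NUMBER(S)")
    lines.append(ma_surface)
    lines.append("")
    lines.append("9. DATE OF FIRST AUTHORISATION/RENEWAL OF THE AUTHORISATION")
    lines.append(f"Date of first authorisation: {first_auth_surface}")
    if has_renewal:
        lines.append(f"Date of latest renewal: {renewal_surface}")
    lines.append("")
    lines.append("10. DATE OF REVISION OF THE TEXT")
    lines.append(
        "Date of revision: "
        + _render_date(_random_date(rng, 2021, 2024), rng, profile.date_format_mix)
    )
    lines.append("")

    doc_id = f"synth-{index:03d}"
    doc = parse_smpc("\n".join(lines), doc_id)
    return doc, gold


def generate_corpus(profile: CorpusProfile) -> list[tuple[SmpcDocument, dict]]:
    """Deterministic corpus of mutually distinct document/gold pairs."""
    rng = random.Random(profile.seed)
    return [generate_document(profile, rng, i) for i in range(profile.n_documents)]


def write_corpus(
    pairs: list[tuple[SmpcDocument, dict]], outdir: str | Path, profile: CorpusProfile
) -> None:
    """Write docs/<id>.txt + gold/<id>.json + manifest.json."""
    outdir = Path(outdir)
    (outdir / "docs").mkdir(parents=True, exist_ok=True)
    (outdir / "gold").mkdir(parents=True, exist_ok=True)
    for doc, gold in pairs:
        (outdir / "docs" / f"{doc.doc_id}.txt").write_text(
            doc.raw_text, encoding="utf-8"
        )
        write_idmp_json(gold, outdir / "gold" / f"{doc.doc_id}.json")
    manifest = {
        "seed": profile.seed,
        "n_documents": profile.n_documents,
        "level_mix": list(profile.level_mix),
        "range_probability": profile.range_probability,
        "date_format_mix": list(profile.date_format_mix),
        "packaging_complexity": profile.packaging_complexity,
        "documents": [doc.doc_id for doc, _ in pairs],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
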
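"""Controlled vocabularies for tumor types and normal tissues.

The pipeline operates over the 20 tumor types of the pathology atlas and
45 normal tissues of the tissue atlas.  Thirteen of the normal tissues are
"critical": lung, the seven gastrointestinal-tract sub-tissues (oral mucosa,
esophagus, stomach, duodenum, small intestine, colon, rectum), liver, kidney,
heart muscle, skin and bone marrow.  High protein expression in any of them
disqualifies a gene as an antibody-drug-conjugate target because of
on-target off-tumor toxicity.
"""

from __future__ import annotations

TUMOR_TYPES: tuple[str, ...] = (
    "breast cancer",
    "carcinoid",
    "cervical cancer",
    "colorectal cancer",
    "endometrial cancer",
    "glioma",
    "head and neck cancer",
    "liver cancer",
    "lung cancer",
    "lymphoma",
    "melanoma",
    "ovarian cancer",
    "pancreatic cancer",
    "prostate cancer",
    "renal cancer",
    "skin cancer",
    "stomach cancer",
    "testis cancer",
    "thyroid cancer",
    "urothelial cancer",
)

#: Tumor types with transcript-level (FPKM) data available; carcinoid,
#: lymphoma and non-melanoma skin cancer have no matched RNA-seq cohort.
FPKM_TUMOR_TYPES: tuple[str, ...] = tuple(
    t for t in TUMOR_TYPES if t not in ("carcinoid", "lymphoma", "skin cancer")
)

NORMAL_TISSUES: tuple[str, ...] = (
    "adipose tissue",
    "adrenal gland",
    "appendix",
    "bone marrow",
    "breast",
    "bronchus",
    "caudate",
    "cerebellum",
    "cerebral cortex",
    "cervix, uterine",
    "colon",
    "duodenum",
    "endometrium",
    "epididymis",
    "esophagus",
    "fallopian tube",
    "gallbladder",
    "heart muscle",
    "hippocampus",
    "kidney",
    "liver",
    "lung",
    "lymph node",
    "nasopharynx",
    "oral mucosa",
    "ovary",
    "pancreas",
    "parathyroid gland",
    "placenta",
    "prostate",
    "rectum",
    "salivary gland",
    "seminal vesicle",
    "skeletal muscle",
    "skin",
    "small intestine",
    "smooth muscle",
    "soft tissue",
    "spleen",
    "stomach",
    "testis",
    "thyroid gland",
    "tonsil",
    "urinary bladder",
    "vagina",
)

#: The GI tract expands into its seven sub-tissues, giving 13 critical tissues.
CRITICAL_TISSUES: frozenset[str] = frozenset(
    {
        "lung",
        "oral mucosa",
        "esophagus",
        "stomach",
        "duodenum",
        "small intestine",
        "colon",
        "rectum",
        "liver",
        "kidney",
        "heart muscle",
        "skin",
        "bone marrow",
    }
)

assert len(NORMAL_TISSUES) == 45
assert len(CRITICAL_TISSUES) == 13
assert CRITICAL_TISSUES <= set(NORMAL_TISSUES)
assert len(TUMOR_TYPES) == 20 and len(FPKM_TUMOR_TYPES) == 17
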
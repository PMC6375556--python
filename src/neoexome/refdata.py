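"""Bundled reference data: a synthetic signature catalog, demo gene sets, and
the motivating trial's reported cohort marginals.

The 30-signature reference matrix produced here is **synthetic**: a
deterministic stand-in with the same shape, naming scheme and row semantics as
the widely used 30-signature base-substitution catalog, built so refitting
exercises are meaningful (a CpG-deamination-like signature, a flat
HR-deficiency-like signature, a T>G-rich signature, and sparse random rows for
the rest). It is not the real catalog; any matrix in the documented CSV schema
can be supplied in its place.
"""

from __future__ import annotations

import numpy as np

from .contexts import BASES, SBS96_CLASSES, SUBSTITUTIONS
from .io_formats import GeneSetCollection, SignatureMatrix

_N_SIGNATURES = 30
_MATRIX_SEED = 960030  # fixed: the synthetic catalog is a constant of the package


def _class_mask(substitution: str | None = None, three: str | None = None, five: str | None = None):
    mask = np.zeros(96, dtype=bool)
    for i, label in enumerate(SBS96_CLASSES):
        f, rest = label.split("[")
        sub, t = rest.split("]")
        if substitution is not None and sub != substitution:
            continue
        if three is not None and t != three:
            continue
        if five is not None and f != five:
            continue
        mask[i] = True
    return mask


def synthetic_signature_catalog(n_signatures: int = _N_SIGNATURES) -> SignatureMatrix:
    """Deterministic synthetic 30-signature reference matrix.

    Row 1 concentrates C>T mass at 3'-G flanks (spontaneous-deamination-like),
    row 3 is near-flat (HR-deficiency-like), row 17 concentrates T>G mass at
    C..T contexts; all other rows are sparse Dirichlet draws from a fixed
    stream, giving mutually distinctive profiles.
    """
    rng = np.random.default_rng(_MATRIX_SEED)
    rows = np.empty((n_signatures, 96))
    for i in range(n_signatures):
        # draw for every row so adding/removing handcrafted rows upstream
        # never perturbs the others
        draw = rng.dirichlet(np.full(96, 0.08))
        rows[i] = draw
    if n_signatures >= 1:
        v = np.full(96, 0.1)
        v[_class_mask("C>T", three="G")] = 18.0
        rows[0] = v / v.sum()
    if n_signatures >= 3:
        v = np.ones(96) + 0.15 * np.sin(np.arange(96) / 7.0)  # gently rippled flat row
        rows[2] = v / v.sum()
    if n_signatures >= 17:
        v = np.full(96, 0.05)
        v[_class_mask("T>G", five="C")] = 10.0
        v[_class_mask("T>G", five="C", three="T")] += 25.0
        rows[16] = v / v.sum()
    ids = [f"Signature {i + 1}" for i in range(n_signatures)]
    return SignatureMatrix(ids, rows)


# ---------------------------------------------------------------------------
# gene sets

#: Genes commonly tied to homologous-recombination deficiency.
HRD_GENES = (
    "BRCA1", "BRCA2", "PALB2", "CHEK2", "RAD51D", "RAD51C", "EMSY", "PTEN",
    "BRIP1", "ATM", "ATR", "FAM175A", "BARD1", "NBN", "FANCA", "FANCM", "RAD50",
)

#: Genes commonly tied to mismatch-repair deficiency.
MMR_GENES = ("MLH1", "MLH3", "MSH2", "MSH3", "MSH6", "PMS1", "PMS2", "POLH")

#: A compact ATM-signalling pathway set (DNA double-strand-break response).
ATM_SIGNALLING_GENES = (
    "ATM", "TP53", "CHEK2", "BRCA1", "NBN", "MDM2", "ABL1", "RAD50", "RAD51", "MRE11",
)


def demo_gene_sets(n_filler_sets: int = 20, seed: int = 77, background_size: int = 0) -> GeneSetCollection:
    """Curated pathway sets plus random filler sets over a synthetic gene universe."""
    rng = np.random.default_rng(seed)
    filler_universe = [f"GENE{i:04d}" for i in range(1, 801)]
    sets: dict[str, frozenset[str]] = {
        "ATM_SIGNALLING": frozenset(ATM_SIGNALLING_GENES),
        "HRD_CORE": frozenset(HRD_GENES),
        "MMR_CORE": frozenset(MMR_GENES),
    }
    for i in range(n_filler_sets):
        size = int(rng.integers(8, 40))
        members = rng.choice(len(filler_universe), size=size, replace=False)
        sets[f"PATHWAY_{i + 1:02d}"] = frozenset(filler_universe[j] for j in members)
    return GeneSetCollection(sets=sets, background_size=background_size)


# ---------------------------------------------------------------------------
# motivating trial marginals (reported outcome counts for the 40-patient cohort)

SUBTYPE_DENOMINATORS = {"HER2_amplified": 15, "TNBC": 15, "HR_pos_HER2_neg_RS_ge_25": 10}

#: Breast-only pCR counts by subtype (HER2-amplified, TNBC, HR+ RS>=25).
BREAST_PCR_COUNTS = {"HER2_amplified": 12, "TNBC": 7, "HR_pos_HER2_neg_RS_ge_25": 3}

#: Breast-and-lymph-node pCR counts by subtype.
BREAST_LN_PCR_COUNTS = {"HER2_amplified": 12, "TNBC": 5, "HR_pos_HER2_neg_RS_ge_25": 1}

N_YPT0_YPN0 = 13  # no residual invasive or in-situ disease, node-negative
N_NCR = 4  # scattered residual tumour cells only (non-pCR patients)
N_BREAST_CONSERVING = 19
#: Documented recurrences at data cut-off, by subtype.
DFS_EVENT_COUNTS = {"TNBC": 4, "HER2_amplified": 1, "HR_pos_HER2_neg_RS_ge_25": 2}
MEDIAN_FOLLOWUP_MONTHS = 18.6
FOLLOWUP_RANGE_MONTHS = (11.52, 31.56)
N_RDI_GE_085 = 35  # patients receiving >=85% of the scheduled taxane dose

#: Adverse-event summary rows: term -> (any-grade patients, grade>=3 patients).
AE_MARGINALS = {
    "Alopecia": (38, 0),
    "Anxiety": (6, 0),
    "Bone pain": (6, 0),
    "Constipation": (9, 0),
    "Deranged transaminases": (2, 2),
    "Diarrhoea": (8, 1),
    "Dysgeusia": (6, 0),
    "Dyspepsia": (4, 0),
    "Fatigue": (27, 1),
    "Febrile neutropenia": (3, 3),
    "Gastro-oesophageal reflux": (8, 0),
    "Headache": (6, 0),
    "Insomnia": (7, 0),
    "Nausea": (25, 0),
    "Neutropenia": (23, 7),
    "Sensory neuropathy": (22, 2),
    "Pneumothorax": (1, 1),
}
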
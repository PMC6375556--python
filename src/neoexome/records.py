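"""Core domain types shared across the pipeline.

A :class:`VariantRecord` is one somatic call from a tumour/germline pair,
carrying the tumour evidence (depth, alt reads, VAF, caller q-value), the
matched-germline evidence (depth, mismatch fraction, nearby germline INDELs),
the functional annotation (consequence class, gene symbol, trinucleotide
context) and the verdicts of six in-silico functional predictors. INDEL calls
additionally carry the read-support geometry used by the five-condition INDEL
filter (total support, support with the event well inside the read, local
mismatch rate, adjacent repetitive regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

SNV = "SNV"
INS = "INS"
DEL = "DEL"
KINDS = (SNV, INS, DEL)

CONSEQUENCES = (
    "missense",
    "stop_gained",
    "splice_site",
    "synonymous",
    "intronic",
    "intergenic",
    "other",
)
NONSYNONYMOUS = ("missense", "stop_gained", "splice_site")

#: The six functional predictors whose calls feed the HFI consensus vote.
PREDICTORS = ("SIFT", "PolyPhen", "PROVEAN", "MutationTaster", "MutationAssessor", "LRT")
VERDICTS = ("deleterious", "tolerated", "unknown")

SUBTYPES = ("HER2_amplified", "TNBC", "HR_pos_HER2_neg_RS_ge_25")
SURGERIES = ("mastectomy", "breast_conserving")

# Tolerance on the stored VAF vs alt/depth (records may carry a rounded VAF).
VAF_CONSISTENCY_TOL = 0.005


@dataclass
class VariantRecord:
    sample_id: str
    chrom: str
    pos: int  # 1-based, fully closed
    ref: str
    alt: str
    kind: str  # SNV | INS | DEL
    call_quality: float  # caller q-value, phred-like
    tumour_depth: int
    tumour_alt_reads: int
    vaf: float
    germline_depth: int
    germline_mismatch_fraction: float
    consequence: str = "other"
    gene: str = ""
    context: str = ""  # pyrimidine-normalised trinucleotide, SNVs only
    predictor_verdicts: dict[str, str] = field(default_factory=dict)
    # INDEL read-support geometry (left at 0 for SNVs)
    indel_support_total: int = 0
    indel_support_interior: int = 0  # support with event >= 25 bp from both read ends
    germline_cover_at_site: int = 0
    germline_indels_within_20bp: int = 0
    local_mismatch_rate_10bp: float = 0.0
    adjacent_repeat_regions: int = 0
    passthrough: dict[str, str] = field(default_factory=dict)

    @property
    def uid(self) -> str:
        """Stable identifier used by audits and cluster memberships."""
        return f"{self.sample_id}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return self.kind == SNV

    @property
    def is_indel(self) -> bool:
        return self.kind in (INS, DEL)

    def verdict(self, tool: str) -> str:
        return self.predictor_verdicts.get(tool, "unknown")

    def violations(self) -> list[str]:
        """Invariant violations, empty when the record is well formed."""
        out: list[str] = []
        if self.kind not in KINDS:
            out.append(f"unknown kind {self.kind!r}")
        if self.tumour_alt_reads > self.tumour_depth:
            out.append("tumour_alt_reads > tumour_depth")
        if not 0.0 <= self.vaf <= 1.0:
            out.append("vaf outside [0, 1]")
        if self.tumour_depth > 0:
            implied = self.tumour_alt_reads / self.tumour_depth
            if abs(self.vaf - implied) > VAF_CONSISTENCY_TOL:
                out.append("vaf inconsistent with alt/depth")
        if self.kind == SNV:
            if len(self.context) != 3 or self.context[1] not in "CT":
                out.append("SNV context not a pyrimidine-centred 3-mer")
        for tool, verdict in self.predictor_verdicts.items():
            if verdict not in VERDICTS:
                out.append(f"unknown verdict {verdict!r} for {tool}")
        return out


#: Fixed column order of the MAF-like TSV dialect (stable diffs).
VARIANT_TSV_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "kind",
    "call_quality",
    "tumour_depth",
    "tumour_alt_reads",
    "vaf",
    "germline_depth",
    "germline_mismatch_fraction",
    "consequence",
    "gene",
    "context",
    *PREDICTORS,
    "indel_support_total",
    "indel_support_interior",
    "germline_cover_at_site",
    "germline_indels_within_20bp",
    "local_mismatch_rate_10bp",
    "adjacent_repeat_regions",
)

_SCALAR_FIELDS = tuple(
    f.name for f in fields(VariantRecord) if f.name not in ("predictor_verdicts", "passthrough")
)


@dataclass
class PatientOutcome:
    """One trial patient: subtype, pathological response, surgery, DFS, exposure."""

    patient_id: str
    subtype: str
    breast_pcr: bool  # ypT0/is ypN0-3: no invasive tumour cells in the breast
    breast_ln_pcr: bool  # additionally no invasive/non-invasive disease in nodes
    ypt0_ypn0: bool  # strictest category: no residual invasive or in-situ disease
    ncr: bool  # scattered residual tumour cells only
    surgery: str
    dfs_months: float
    dfs_event: bool
    planned_dose: float  # mg/m^2, protocol-planned taxane dose
    delivered_dose: float
    adverse_events: list[tuple[str, int]] = field(default_factory=list)
    progressed_on_treatment: bool = False  # primary progression: not a DFS event

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.subtype not in SUBTYPES:
            out.append(f"unknown subtype {self.subtype!r}")
        if self.breast_ln_pcr and not self.breast_pcr:
            out.append("breast_ln_pcr without breast_pcr")
        if self.ypt0_ypn0 and not self.breast_ln_pcr:
            out.append("ypt0_ypn0 without breast_ln_pcr")
        if self.ncr and self.breast_pcr:
            out.append("ncr set on a pCR patient")
        if self.dfs_months < 0:
            out.append("negative dfs_months")
        for term, grade in self.adverse_events:
            if not 1 <= grade <= 5:
                out.append(f"grade {grade} outside 1..5 for {term!r}")
        return out
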
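"""Somatic SNV and INDEL filtering with a complete per-record audit.

SNVs are kept when the caller q-value, tumour depth, matched-germline depth,
germline mismatch fraction and VAF all clear their thresholds. INDELs are kept
under the five-condition rule (total and interior read support, germline
coverage with no germline INDELs in a surrounding window, local mismatch rate)
plus the VAF cut and the repeat-adjacency exclusion. Boundary semantics follow
the thresholds' wording literally: "at least"/"minimum" comparisons are
inclusive, "less/lower than" comparisons are strict — so a record at VAF
exactly 0.10 is kept while one at germline mismatch exactly 0.10 is rejected.

Every failing reason is recorded for every rejected record (not just the
first), so audits of synthetic data with multiple planted defects are
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .records import INS, DEL, SNV, VariantRecord

# reason codes ---------------------------------------------------------------
R_CALL_QUALITY = "call_quality"
R_TUMOUR_DEPTH = "tumour_depth"
R_GERMLINE_DEPTH = "germline_depth"
R_GERMLINE_MISMATCH = "germline_mismatch"
R_VAF = "vaf"
R_INDEL_SUPPORT = "indel_support"
R_INDEL_INTERIOR = "indel_interior_support"
R_GERMLINE_COVER = "germline_cover"
R_GERMLINE_INDEL_WINDOW = "germline_indel_window"
R_LOCAL_MISMATCH = "local_mismatch"
R_REPEAT_ADJACENCY = "repeat_adjacency"

SNV_REASONS = (R_CALL_QUALITY, R_TUMOUR_DEPTH, R_GERMLINE_DEPTH, R_GERMLINE_MISMATCH, R_VAF)
INDEL_REASONS = (
    R_INDEL_SUPPORT,
    R_INDEL_INTERIOR,
    R_GERMLINE_COVER,
    R_GERMLINE_INDEL_WINDOW,
    R_LOCAL_MISMATCH,
    R_VAF,
    R_REPEAT_ADJACENCY,
)


@dataclass
class FilterParams:
    """Thresholds of the somatic filters; defaults are the analysis' values."""

    min_call_quality: float = 12.0
    min_tumour_depth_snv: int = 50
    min_germline_depth_snv: int = 20
    max_germline_mismatch: float = 0.10  # strict: mismatch must be < this
    min_vaf: float = 0.10  # inclusive: VAF < this is rejected
    min_indel_support: int = 20
    min_indel_interior_support: int = 5
    indel_interior_margin_bp: int = 25
    min_germline_cover_indel: int = 20
    germline_indel_window_bp: int = 20
    max_local_mismatch_10bp: float = 0.10  # strict
    max_adjacent_repeats: int = 5  # inclusive: more than 5 rejects
    drop_consequences_for_gene_analysis: tuple[str, ...] = ("intronic", "intergenic")

    def __post_init__(self) -> None:
        for name in (
            "min_call_quality",
            "min_tumour_depth_snv",
            "min_germline_depth_snv",
            "min_indel_support",
            "min_indel_interior_support",
            "min_germline_cover_indel",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_germline_mismatch", "min_vaf", "max_local_mismatch_10bp"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class FilterAudit:
    """Partition of the input into kept and rejected record ids with reasons."""

    kept: list[str]
    rejected: dict[str, list[str]]  # uid -> ordered reason codes
    params: FilterParams
    reason_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reason_counts:
            counts: dict[str, int] = {}
            for reasons in self.rejected.values():
                for r in reasons:
                    counts[r] = counts.get(r, 0) + 1
            self.reason_counts = counts

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"uid": u, "fate": "kept", "reasons": ""} for u in self.kept]
        rows += [
            {"uid": u, "fate": "rejected", "reasons": ",".join(rs)}
            for u, rs in self.rejected.items()
        ]
        return pd.DataFrame(rows, columns=["uid", "fate", "reasons"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        summary = {
            "n_input": self.n_input,
            "n_kept": len(self.kept),
            "n_rejected": len(self.rejected),
            "reason_counts": self.reason_counts,
            "params": asdict(self.params),
        }
        Path(path).write_text(json.dumps(summary, indent=2, default=list) + "\n")


def snv_failure_reasons(rec: VariantRecord, params: FilterParams) -> list[str]:
    reasons = []
    if rec.call_quality < params.min_call_quality:
        reasons.append(R_CALL_QUALITY)
    if rec.tumour_depth < params.min_tumour_depth_snv:
        reasons.append(R_TUMOUR_DEPTH)
    if rec.germline_depth < params.min_germline_depth_snv:
        reasons.append(R_GERMLINE_DEPTH)
    if not rec.germline_mismatch_fraction < params.max_germline_mismatch:
        reasons.append(R_GERMLINE_MISMATCH)
    if rec.vaf < params.min_vaf:
        reasons.append(R_VAF)
    return reasons


def indel_failure_reasons(rec: VariantRecord, params: FilterParams) -> list[str]:
    reasons = []
    if rec.indel_support_total < params.min_indel_support:
        reasons.append(R_INDEL_SUPPORT)
    if rec.indel_support_interior < params.min_indel_interior_support:
        reasons.append(R_INDEL_INTERIOR)
    if rec.germline_cover_at_site < params.min_germline_cover_indel:
        reasons.append(R_GERMLINE_COVER)
    if rec.germline_indels_within_20bp != 0:
        reasons.append(R_GERMLINE_INDEL_WINDOW)
    if not rec.local_mismatch_rate_10bp < params.max_local_mismatch_10bp:
        reasons.append(R_LOCAL_MISMATCH)
    if rec.vaf < params.min_vaf:
        reasons.append(R_VAF)
    if rec.adjacent_repeat_regions > params.max_adjacent_repeats:
        reasons.append(R_REPEAT_ADJACENCY)
    return reasons


def _run_filter(records, params, expected_kinds, reason_fn, label) -> FilterAudit:
    kept: list[str] = []
    rejected: dict[str, list[str]] = {}
    for rec in records:
        if rec.kind not in expected_kinds:
            raise ValueError(f"{label} filter given a {rec.kind} record ({rec.uid})")
        reasons = reason_fn(rec, params)
        if reasons:
            rejected[rec.uid] = reasons
        else:
            kept.append(rec.uid)
    return FilterAudit(kept=kept, rejected=rejected, params=params)


def filter_snvs(records: list[VariantRecord], params: FilterParams | None = None) -> FilterAudit:
    """Audit SNVs against quality, depth, germline-evidence and VAF thresholds."""
    return _run_filter(records, params or FilterParams(), (SNV,), snv_failure_reasons, "SNV")


def filter_indels(records: list[VariantRecord], params: FilterParams | None = None) -> FilterAudit:
    """Audit INDELs against the five support/germline/mismatch conditions, the
    VAF cut and the repeat-adjacency exclusion."""
    return _run_filter(records, params or FilterParams(), (INS, DEL), indel_failure_reasons, "INDEL")


def filter_variants(records: list[VariantRecord], params: FilterParams | None = None) -> FilterAudit:
    """Audit a mixed table, routing each record to the filter for its kind."""
    params = params or FilterParams()
    snv_audit = filter_snvs([r for r in records if r.kind == SNV], params)
    indel_audit = filter_indels([r for r in records if r.kind != SNV], params)
    order = {r.uid: i for i, r in enumerate(records)}
    kept = sorted(snv_audit.kept + indel_audit.kept, key=order.__getitem__)
    rejected = {**snv_audit.rejected, **indel_audit.rejected}
    return FilterAudit(kept=kept, rejected=rejected, params=params)


def apply_audit(records: list[VariantRecord], audit: FilterAudit) -> list[VariantRecord]:
    keep = set(audit.kept)
    return [r for r in records if r.uid in keep]


def restrict_for_gene_analysis(
    records: list[VariantRecord], params: FilterParams | None = None
) -> list[VariantRecord]:
    """Drop intronic/intergenic records ahead of gene-level analyses; order kept."""
    drop = set((params or FilterParams()).drop_consequences_for_gene_analysis)
    return [r for r in records if r.consequence not in drop]
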
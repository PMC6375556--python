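"""High-functional-impact (HFI) classification by predictor consensus.

An SNV is HFI when at least three of the six in-silico predictors (SIFT,
PolyPhen, PROVEAN, MutationTaster, MutationAssessor, LRT) call it deleterious;
"unknown" verdicts are non-votes, so the denominator is always six. Every
retained INDEL is HFI by rule, regardless of verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import NONSYNONYMOUS, PREDICTORS, SNV, VariantRecord

HFI_VOTE_THRESHOLD = 3


@dataclass
class ImpactCall:
    uid: str
    n_deleterious_votes: int
    hfi: bool
    basis: str  # consensus_vote | indel_rule


def classify_hfi(record: VariantRecord) -> ImpactCall:
    """HFI call for one record: consensus vote for SNVs, automatic for INDELs."""
    votes = sum(1 for tool in PREDICTORS if record.verdict(tool) == "deleterious")
    if record.kind == SNV:
        return ImpactCall(record.uid, votes, votes >= HFI_VOTE_THRESHOLD, "consensus_vote")
    return ImpactCall(record.uid, votes, True, "indel_rule")


def select_nonsynonymous(records: list[VariantRecord]) -> list[VariantRecord]:
    """Keep non-synonymous SNVs (missense, stop-gained, splice-site) and all INDELs."""
    return [r for r in records if r.kind != SNV or r.consequence in NONSYNONYMOUS]


def hfi_gene_list(records: list[VariantRecord]) -> list[str]:
    """Uppercased, de-duplicated genes carrying an HFI variant, first-seen order."""
    seen: dict[str, None] = {}
    for rec in records:
        if rec.gene and classify_hfi(rec).hfi:
            seen.setdefault(rec.gene.upper(), None)
    return list(seen)


def impact_table(records: list[VariantRecord]) -> pd.DataFrame:
    calls = [classify_hfi(r) for r in records]
    return pd.DataFrame(
        {
            "uid": [c.uid for c in calls],
            "n_deleterious_votes": [c.n_deleterious_votes for c in calls],
            "hfi": [c.hfi for c in calls],
            "basis": [c.basis for c in calls],
        }
    )
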
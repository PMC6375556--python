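import numpy as np
import pytest

from neoexome import refdata
from neoexome.records import DEL, INS, SNV, PREDICTORS, VariantRecord


@pytest.fixture(scope="session")
def matrix():
    return refdata.synthetic_signature_catalog()


def make_snv(**overrides) -> VariantRecord:
    """A boundary-passing SNV; override any field to probe a filter."""
    base = dict(
        sample_id="T1",
        chrom="chr1",
        pos=1000,
        ref="C",
        alt="T",
        kind=SNV,
        call_quality=30.0,
        tumour_depth=100,
        tumour_alt_reads=30,
        vaf=0.30,
        germline_depth=40,
        germline_mismatch_fraction=0.02,
        consequence="missense",
        gene="TP53",
        context="ACA",
        predictor_verdicts={t: "tolerated" for t in PREDICTORS},
    )
    base.update(overrides)
    return VariantRecord(**base)


def make_indel(**overrides) -> VariantRecord:
    base = dict(
        sample_id="T1",
        chrom="chr1",
        pos=2000,
        ref="A",
        alt="AT",
        kind=INS,
        call_quality=30.0,
        tumour_depth=120,
        tumour_alt_reads=40,
        vaf=40 / 120,
        germline_depth=45,
        germline_mismatch_fraction=0.02,
        consequence="other",
        gene="BRCA1",
        indel_support_total=40,
        indel_support_interior=15,
        germline_cover_at_site=45,
        germline_indels_within_20bp=0,
        local_mismatch_rate_10bp=0.03,
        adjacent_repeat_regions=1,
    )
    base.update(overrides)
    return VariantRecord(**base)


def random_records(n: int, seed: int) -> list[VariantRecord]:
    """Records with fields straddling every filter boundary, for property tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        depth = int(rng.integers(20, 300))
        alt = int(rng.integers(0, depth + 1))
        common = dict(
            call_quality=float(rng.uniform(0, 60)),
            tumour_depth=depth,
            tumour_alt_reads=alt,
            vaf=alt / depth,
            germline_depth=int(rng.integers(0, 80)),
            germline_mismatch_fraction=float(rng.uniform(0, 0.3)),
            pos=1000 + i,
        )
        if rng.random() < 0.6:
            out.append(make_snv(**common))
        else:
            support = int(rng.integers(0, depth + 1))
            out.append(
                make_indel(
                    kind=INS if rng.random() < 0.5 else DEL,
                    indel_support_total=support,
                    indel_support_interior=int(rng.integers(0, support + 1)),
                    germline_cover_at_site=int(rng.integers(0, 80)),
                    germline_indels_within_20bp=int(rng.integers(0, 3)),
                    local_mismatch_rate_10bp=float(rng.uniform(0, 0.3)),
                    adjacent_repeat_regions=int(rng.integers(0, 10)),
                    **common,
                )
            )
    return out
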
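"""Synthetic tumour/germline data with known ground truth.

Everything the pipeline consumes can be generated here: paired variant tables
with records planted to fail specific filters, mutation catalogs drawn from
known signature mixtures, two-timepoint multi-clone VAF structure, per-base
depth tracks at a target callable fraction, and a 40-patient outcome table
matching the motivating trial's reported marginals.

Determinism: one global seed; each generator component draws from its own
stream derived by a fixed offset (``default_rng([seed, offset])``), so adding
a component never perturbs another's draws. Depth is sampled as Poisson around
the configured mean and then clamped to satisfy planted fates; intended-pass
records clear every filter threshold with at least one unit of margin (for the
VAF cut, binomially drawn alt counts are clamped up to one VAF point above the
threshold; the clamp is recorded in the ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import filters as F
from .contexts import SBS96_CLASSES, class_components
from .io_formats import DepthTrack, SignatureMatrix
from .records import DEL, INS, PREDICTORS, SNV, PatientOutcome, VariantRecord
from . import refdata

# per-component stream offsets (fixed: see module docstring)
_STREAM_SNV = 1
_STREAM_INDEL = 2
_STREAM_DEPTH = 3
_STREAM_COHORT = 4
_STREAM_TIMEPOINT = 5

_SNV_REASONS = set(F.SNV_REASONS)
_INDEL_REASONS = set(F.INDEL_REASONS) - {F.R_VAF}
#: Reason codes accepted in ``planted_failures`` ("vaf" plants an SNV failure;
#: "indel_vaf" the INDEL counterpart).
PLANTABLE_REASONS = tuple(sorted(_SNV_REASONS | _INDEL_REASONS | {"indel_vaf"}))

_CONSEQUENCE_PROBS = {
    "missense": 0.33,
    "synonymous": 0.15,
    "intronic": 0.22,
    "intergenic": 0.10,
    "stop_gained": 0.06,
    "splice_site": 0.06,
    "other": 0.08,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    sample_id: str = "S01"
    n_snvs: int = 200
    n_indels: int = 40
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"Signature 1": 0.5, "Signature 3": 0.5}
    )
    clone_vafs_diagnostic: list[float] = field(default_factory=lambda: [0.45, 0.20])
    clone_vafs_residual: list[float] = field(default_factory=lambda: [0.40])
    clone_map_residual: list[int | None] | None = None  # residual idx -> diagnostic idx
    planted_failures: dict[str, int] = field(default_factory=dict)
    mean_tumour_depth: float = 150.0
    mean_germline_depth: float = 50.0
    hfi_fraction: float = 0.30  # latent damaging-variant rate driving predictor verdicts
    gene_pool: list[str] | None = None

    def validate(self) -> None:
        total = sum(self.signature_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature weights sum to {total}, not 1")
        for v in [*self.clone_vafs_diagnostic, *self.clone_vafs_residual]:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"clone VAF {v} outside (0, 1]")
        for code, count in self.planted_failures.items():
            if code not in PLANTABLE_REASONS:
                raise ValueError(f"unknown reason code {code!r}")
            if count < 0:
                raise ValueError(f"negative planted count for {code!r}")
        if self.n_snvs < 0 or self.n_indels < 0:
            raise ValueError("negative record counts")


@dataclass
class GroundTruth:
    """Per-record intended fates and generating processes; per-clone fates."""

    fates: dict[str, tuple[str, list[str]]] = field(default_factory=dict)  # uid -> (pass/fail, reasons)
    signatures: dict[str, str] = field(default_factory=dict)  # uid -> generating signature
    clones: dict[str, str | None] = field(default_factory=dict)  # uid -> clone label
    clone_fates: dict[str, str] = field(default_factory=dict)  # clone label -> fate
    vaf_clamped: set[str] = field(default_factory=set)

    def n_planted(self, reason: str) -> int:
        return sum(1 for fate, reasons in self.fates.values() if fate == "fail" and reason in reasons)


def _default_gene_pool() -> list[str]:
    pool = [f"GENE{i:04d}" for i in range(1, 801)]
    pool.extend(refdata.HRD_GENES)
    pool.extend(refdata.MMR_GENES)
    return pool


class _RecordFactory:
    """Draws intended-pass records; planted failures are derived by breaking one field."""

    def __init__(self, config: SimulationConfig, matrix: SignatureMatrix, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.matrix = matrix
        self.sig_ids = list(config.signature_weights)
        for sid in self.sig_ids:
            if sid not in matrix.signature_ids:
                raise ValueError(f"signature {sid!r} not in the reference matrix")
        self.sig_probs = np.array([config.signature_weights[s] for s in self.sig_ids])
        self.genes = config.gene_pool or _default_gene_pool()
        self.conseq = list(_CONSEQUENCE_PROBS)
        self.conseq_p = np.array(list(_CONSEQUENCE_PROBS.values()))
        self.conseq_p = self.conseq_p / self.conseq_p.sum()
        self.pos = 1000

    def _next_pos(self) -> int:
        self.pos += int(self.rng.integers(50, 500))
        return self.pos

    def _verdicts(self) -> dict[str, str]:
        damaging = self.rng.random() < self.cfg.hfi_fraction
        p_del = 0.8 if damaging else 0.12
        verdicts = {}
        for tool in PREDICTORS:
            u = self.rng.random()
            if u < p_del:
                verdicts[tool] = "deleterious"
            elif u < p_del + 0.08:
                verdicts[tool] = "unknown"
            else:
                verdicts[tool] = "tolerated"
        return verdicts

    def _depth(self, mean: float, floor: int) -> int:
        return max(int(self.rng.poisson(mean)), floor)

    def _alt_for_vaf(self, depth: int, clone_vaf: float, min_vaf: float | None) -> tuple[int, bool]:
        alt = int(self.rng.binomial(depth, clone_vaf))
        if min_vaf is None:
            return alt, False
        floor = int(np.ceil(min_vaf * depth))
        if alt < floor:
            return floor, True
        return alt, False

    def draw_snv(self, clone_idx: int | None = None) -> tuple[VariantRecord, str, bool]:
        """One intended-pass SNV; returns (record, generating signature, vaf_clamped)."""
        cfg = self.cfg
        sig = self.sig_ids[int(self.rng.choice(len(self.sig_ids), p=self.sig_probs))]
        klass = SBS96_CLASSES[int(self.rng.choice(96, p=self.matrix.row(sig)))]
        ref, alt_base, context = class_components(klass)
        if clone_idx is None:
            clone_idx = int(self.rng.integers(len(cfg.clone_vafs_diagnostic)))
        clone_vaf = cfg.clone_vafs_diagnostic[clone_idx]
        depth = self._depth(cfg.mean_tumour_depth, 51)
        alt_reads, clamped = self._alt_for_vaf(depth, clone_vaf, 0.11)
        conseq = self.conseq[int(self.rng.choice(len(self.conseq), p=self.conseq_p))]
        gene = "" if conseq == "intergenic" else str(self.rng.choice(self.genes))
        rec = VariantRecord(
            sample_id=cfg.sample_id,
            chrom="chr1",
            pos=self._next_pos(),
            ref=ref,
            alt=alt_base,
            kind=SNV,
            call_quality=float(np.round(self.rng.uniform(25.0, 60.0), 1)),
            tumour_depth=depth,
            tumour_alt_reads=alt_reads,
            vaf=alt_reads / depth,
            germline_depth=self._depth(cfg.mean_germline_depth, 21),
            germline_mismatch_fraction=float(np.round(self.rng.uniform(0.0, 0.08), 4)),
            consequence=conseq,
            gene=gene,
            context=context,
            predictor_verdicts=self._verdicts(),
        )
        return rec, sig, clamped

    def draw_indel(self) -> VariantRecord:
        cfg = self.cfg
        kind = INS if self.rng.random() < 0.5 else DEL
        unit = "ACGT"[int(self.rng.integers(4))]
        ins = "ACGT"[int(self.rng.integers(4))]
        ref, alt = (unit, unit + ins) if kind == INS else (unit + ins, unit)
        depth = self._depth(cfg.mean_tumour_depth, 60)
        clone_vaf = float(self.rng.choice(cfg.clone_vafs_diagnostic))
        support = int(self.rng.binomial(depth, clone_vaf))
        support = max(support, 21, int(np.ceil(0.11 * depth)))
        support = min(support, depth)
        interior = max(int(self.rng.binomial(support, 0.5)), 6)
        conseq = self.conseq[int(self.rng.choice(len(self.conseq), p=self.conseq_p))]
        gene = "" if conseq == "intergenic" else str(self.rng.choice(self.genes))
        return VariantRecord(
            sample_id=cfg.sample_id,
            chrom="chr1",
            pos=self._next_pos(),
            ref=ref,
            alt=alt,
            kind=kind,
            call_quality=float(np.round(self.rng.uniform(25.0, 60.0), 1)),
            tumour_depth=depth,
            tumour_alt_reads=support,
            vaf=support / depth,
            germline_depth=self._depth(cfg.mean_germline_depth, 21),
            germline_mismatch_fraction=float(np.round(self.rng.uniform(0.0, 0.08), 4)),
            consequence=conseq,
            gene=gene,
            predictor_verdicts=self._verdicts(),
            indel_support_total=support,
            indel_support_interior=min(interior, support),
            germline_cover_at_site=self._depth(cfg.mean_germline_depth, 21),
            germline_indels_within_20bp=0,
            local_mismatch_rate_10bp=float(np.round(self.rng.uniform(0.0, 0.08), 4)),
            adjacent_repeat_regions=int(self.rng.integers(0, 5)),
        )

    # -- planted failures ----------------------------------------------------

    def break_snv(self, rec: VariantRecord, reason: str) -> None:
        rng = self.rng
        if reason == F.R_CALL_QUALITY:
            rec.call_quality = float(np.round(rng.uniform(1.0, 11.0), 1))
        elif reason == F.R_TUMOUR_DEPTH:
            depth = int(rng.integers(10, 50))
            rec.tumour_depth = depth
            rec.tumour_alt_reads = max(int(np.ceil(0.11 * depth)), min(depth, rec.tumour_alt_reads))
            rec.tumour_alt_reads = min(rec.tumour_alt_reads, depth)
            rec.vaf = rec.tumour_alt_reads / depth
        elif reason == F.R_GERMLINE_DEPTH:
            rec.germline_depth = int(rng.integers(1, 20))
        elif reason == F.R_GERMLINE_MISMATCH:
            rec.germline_mismatch_fraction = float(np.round(rng.uniform(0.10, 0.5), 4))
        elif reason == F.R_VAF:
            frac = rng.uniform(0.01, 0.09)
            rec.tumour_alt_reads = max(int(frac * rec.tumour_depth), 1)
            if rec.tumour_alt_reads / rec.tumour_depth >= 0.10:
                rec.tumour_alt_reads = int(0.09 * rec.tumour_depth)
            rec.vaf = rec.tumour_alt_reads / rec.tumour_depth
        else:
            raise ValueError(f"{reason!r} is not an SNV reason code")

    def break_indel(self, rec: VariantRecord, reason: str) -> VariantRecord | None:
        """Break one INDEL condition; returns a germline INDEL record when the
        failure involves the matched germline."""
        rng = self.rng
        if reason == F.R_INDEL_SUPPORT:
            total = int(rng.integers(6, 20))
            rec.indel_support_total = total
            rec.indel_support_interior = int(rng.integers(5, total + 1))
            rec.tumour_alt_reads = total
            rec.tumour_depth = max(rec.tumour_depth, int(total / 0.3))
            rec.tumour_depth = min(rec.tumour_depth, int(total / 0.11))
            rec.vaf = total / rec.tumour_depth
        elif reason == F.R_INDEL_INTERIOR:
            rec.indel_support_interior = int(rng.integers(0, 5))
        elif reason == F.R_GERMLINE_COVER:
            rec.germline_cover_at_site = int(rng.integers(0, 20))
        elif reason == F.R_GERMLINE_INDEL_WINDOW:
            rec.germline_indels_within_20bp = int(rng.integers(1, 4))
            offset = int(rng.integers(-20, 21))
            return VariantRecord(
                sample_id=f"{rec.sample_id}_GL",
                chrom=rec.chrom,
                pos=max(rec.pos + offset, 1),
                ref=rec.ref,
                alt=rec.alt,
                kind=rec.kind,
                call_quality=rec.call_quality,
                tumour_depth=rec.germline_cover_at_site,
                tumour_alt_reads=min(rec.germline_cover_at_site, 10),
                vaf=min(rec.germline_cover_at_site, 10) / max(rec.germline_cover_at_site, 1),
                germline_depth=0,
                germline_mismatch_fraction=0.0,
            )
        elif reason == F.R_LOCAL_MISMATCH:
            rec.local_mismatch_rate_10bp = float(np.round(rng.uniform(0.10, 0.4), 4))
        elif reason == "indel_vaf":
            rec.tumour_depth = max(rec.tumour_depth, 250)
            rec.indel_support_total = max(21, int(0.08 * rec.tumour_depth))
            if rec.indel_support_total / rec.tumour_depth >= 0.10:
                rec.tumour_depth = int(rec.indel_support_total / 0.08)
            rec.indel_support_interior = max(6, int(rec.indel_support_total * 0.5))
            rec.tumour_alt_reads = rec.indel_support_total
            rec.vaf = rec.tumour_alt_reads / rec.tumour_depth
        elif reason == F.R_REPEAT_ADJACENCY:
            rec.adjacent_repeat_regions = int(rng.integers(6, 11))
        else:
            raise ValueError(f"{reason!r} is not an INDEL reason code")
        return None


def generate_pair(
    config: SimulationConfig, matrix: SignatureMatrix | None = None
) -> tuple[list[VariantRecord], list[VariantRecord], GroundTruth]:
    """Tumour and germline variant tables plus ground truth for one sample.

    ``config.n_snvs``/``n_indels`` intended-pass records are drawn, then one
    extra record per planted failure, broken on exactly the planted condition.
    The germline table carries the germline INDELs that explain planted
    germline-window failures.
    """
    config.validate()
    matrix = matrix or refdata.synthetic_signature_catalog()
    truth = GroundTruth()
    tumour: list[VariantRecord] = []
    germline: list[VariantRecord] = []

    snv_rng = np.random.default_rng([config.seed, _STREAM_SNV])
    snv_factory = _RecordFactory(config, matrix, snv_rng)
    for _ in range(config.n_snvs):
        rec, sig, clamped = snv_factory.draw_snv()
        tumour.append(rec)
        truth.fates[rec.uid] = ("pass", [])
        truth.signatures[rec.uid] = sig
        if clamped:
            truth.vaf_clamped.add(rec.uid)
    for reason in sorted(set(config.planted_failures) & _SNV_REASONS):
        for _ in range(config.planted_failures[reason]):
            rec, sig, _ = snv_factory.draw_snv()
            snv_factory.break_snv(rec, reason)
            tumour.append(rec)
            truth.fates[rec.uid] = ("fail", [reason])
            truth.signatures[rec.uid] = sig

    indel_rng = np.random.default_rng([config.seed, _STREAM_INDEL])
    indel_factory = _RecordFactory(config, matrix, indel_rng)
    indel_factory.pos = 10_000_000  # keep INDEL loci clear of the SNV block
    for _ in range(config.n_indels):
        rec = indel_factory.draw_indel()
        tumour.append(rec)
        truth.fates[rec.uid] = ("pass", [])
    for reason in sorted(set(config.planted_failures) & (_INDEL_REASONS | {"indel_vaf"})):
        for _ in range(config.planted_failures[reason]):
            rec = indel_factory.draw_indel()
            germ = indel_factory.break_indel(rec, reason)
            tumour.append(rec)
            audit_reason = F.R_VAF if reason == "indel_vaf" else reason
            truth.fates[rec.uid] = ("fail", [audit_reason])
            if germ is not None:
                germline.append(germ)
    return tumour, germline, truth


def generate_depth_track(length_bp: int, callable_fraction: float, seed: int = 0) -> DepthTrack:
    """Per-base depth track whose callable fraction (depth >= 20) is exact to 1 bp."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= callable_fraction <= 1.0:
        raise ValueError("callable fraction outside [0, 1]")
    rng = np.random.default_rng([seed, _STREAM_DEPTH])
    n_callable = int(round(length_bp * callable_fraction))
    depths = np.empty(length_bp, dtype=int)
    depths[:n_callable] = 20 + rng.poisson(30.0, size=n_callable)
    depths[n_callable:] = rng.integers(0, 20, size=length_bp - n_callable)
    rng.shuffle(depths)
    return DepthTrack.from_per_base(depths)


def generate_timepoint_pair(
    config: SimulationConfig,
    matrix: SignatureMatrix | None = None,
    variants_per_clone: int = 40,
) -> tuple[list[VariantRecord], list[VariantRecord], GroundTruth]:
    """Diagnostic and residual variant tables with known clone structure.

    Diagnostic clone *i* carries ``variants_per_clone`` SNVs at VAF
    ``clone_vafs_diagnostic[i]``. Residual clone *j* either redraws the same
    loci at ``clone_vafs_residual[j]`` (persistent; mapped positionally or via
    ``clone_map_residual``) or introduces new loci (emergent). Diagnostic
    clones with no residual counterpart are extinct. Alt counts are pure
    binomial draws — no VAF clamping — since clone VAFs are the object under
    study here.
    """
    config.validate()
    matrix = matrix or refdata.synthetic_signature_catalog()
    rng = np.random.default_rng([config.seed, _STREAM_TIMEPOINT])
    factory = _RecordFactory(config, matrix, rng)
    truth = GroundTruth()

    diag_id = f"{config.sample_id}_D"
    resid_id = f"{config.sample_id}_R"
    mapping = config.clone_map_residual
    if mapping is None:
        mapping = [i if i < len(config.clone_vafs_diagnostic) else None
                   for i in range(len(config.clone_vafs_residual))]
    if len(mapping) != len(config.clone_vafs_residual):
        raise ValueError("clone_map_residual length mismatch")

    diagnostic: list[VariantRecord] = []
    diag_loci: dict[int, list[VariantRecord]] = {}
    for i, dvaf in enumerate(config.clone_vafs_diagnostic):
        label = f"D{i}"
        mapped = i in [m for m in mapping if m is not None]
        truth.clone_fates[label] = "persistent" if mapped else "extinct"
        diag_loci[i] = []
        for _ in range(variants_per_clone):
            rec, sig, _ = factory.draw_snv(clone_idx=0)
            rec.sample_id = diag_id
            depth = max(int(rng.poisson(config.mean_tumour_depth)), 20)
            alt = int(rng.binomial(depth, dvaf))
            rec.tumour_depth, rec.tumour_alt_reads, rec.vaf = depth, alt, alt / depth
            diagnostic.append(rec)
            diag_loci[i].append(rec)
            truth.clones[rec.uid] = label
            truth.signatures[rec.uid] = sig
            truth.fates[rec.uid] = ("pass", [])

    residual: list[VariantRecord] = []
    for j, rvaf in enumerate(config.clone_vafs_residual):
        src = mapping[j]
        label = f"R{j}" if src is None else f"D{src}"
        if src is None:
            truth.clone_fates[label] = "emergent"
        for m in range(variants_per_clone):
            if src is not None:
                base = diag_loci[src][m]
                rec = VariantRecord(**{**base.__dict__, "sample_id": resid_id,
                                       "predictor_verdicts": dict(base.predictor_verdicts),
                                       "passthrough": dict(base.passthrough)})
                sig = truth.signatures[base.uid]
            else:
                rec, sig, _ = factory.draw_snv(clone_idx=0)
                rec.sample_id = resid_id
            depth = max(int(rng.poisson(config.mean_tumour_depth)), 20)
            alt = int(rng.binomial(depth, rvaf))
            rec.tumour_depth, rec.tumour_alt_reads, rec.vaf = depth, alt, alt / depth
            residual.append(rec)
            truth.clones[rec.uid] = label
            truth.signatures[rec.uid] = sig
            truth.fates[rec.uid] = ("pass", [])
    return diagnostic, residual, truth


# ---------------------------------------------------------------------------
# clinical cohort


@dataclass
class CohortSpec:
    """Target marginals for the synthetic 40-patient outcome table.

    Defaults are the motivating trial's reported counts; any field may be
    overridden, subject to the subtype denominators.
    """

    seed: int = 0
    denominators: dict[str, int] = field(default_factory=lambda: dict(refdata.SUBTYPE_DENOMINATORS))
    breast_pcr: dict[str, int] = field(default_factory=lambda: dict(refdata.BREAST_PCR_COUNTS))
    breast_ln_pcr: dict[str, int] = field(default_factory=lambda: dict(refdata.BREAST_LN_PCR_COUNTS))
    n_ypt0_ypn0: int = refdata.N_YPT0_YPN0
    n_ncr: int = refdata.N_NCR
    n_breast_conserving: int = refdata.N_BREAST_CONSERVING
    dfs_events: dict[str, int] = field(default_factory=lambda: dict(refdata.DFS_EVENT_COUNTS))
    followup_range_months: tuple[float, float] = refdata.FOLLOWUP_RANGE_MONTHS
    n_rdi_ge_085: int = refdata.N_RDI_GE_085
    ae_marginals: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(refdata.AE_MARGINALS))
    planned_dose: float = 125.0

    def validate(self) -> None:
        n = sum(self.denominators.values())
        for st, k in self.breast_pcr.items():
            if k > self.denominators[st]:
                raise ValueError(f"breast pCR count {k} exceeds {st} denominator")
        for st, k in self.breast_ln_pcr.items():
            if k > self.breast_pcr.get(st, 0):
                raise ValueError(f"breast+LN pCR count {k} exceeds breast pCR for {st}")
        if self.n_ypt0_ypn0 > sum(self.breast_ln_pcr.values()):
            raise ValueError("ypT0 ypN0 count exceeds breast+LN pCR total")
        if self.n_ncr > n - sum(self.breast_pcr.values()):
            raise ValueError("nCR count exceeds non-pCR patients")
        if self.n_breast_conserving > n or self.n_rdi_ge_085 > n:
            raise ValueError("count exceeds cohort size")
        for st, k in self.dfs_events.items():
            if k > self.denominators[st]:
                raise ValueError(f"DFS event count {k} exceeds {st} denominator")
        for term, (any_n, ge3_n) in self.ae_marginals.items():
            if ge3_n > any_n or any_n > n:
                raise ValueError(f"inconsistent AE counts for {term!r}")


def generate_cohort(spec: CohortSpec | None = None) -> list[PatientOutcome]:
    """Patient outcome table whose marginals equal the requested counts exactly.

    Within each subtype, responders are the first patients in enumeration
    order; everything without a specified joint distribution (which patients
    conserve the breast, recur, or under-dose, and event/censoring times) is
    drawn from the cohort stream. DFS events are assigned to non-pCR patients
    first.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_COHORT])
    patients: list[PatientOutcome] = []
    lo, hi = spec.followup_range_months

    idx = 0
    for st, denom in spec.denominators.items():
        n_pcr = spec.breast_pcr.get(st, 0)
        n_ln = spec.breast_ln_pcr.get(st, 0)
        for i in range(denom):
            idx += 1
            patients.append(
                PatientOutcome(
                    patient_id=f"P{idx:03d}",
                    subtype=st,
                    breast_pcr=i < n_pcr,
                    breast_ln_pcr=i < n_ln,
                    ypt0_ypn0=False,  # assigned below across subtypes
                    ncr=False,
                    surgery="mastectomy",
                    dfs_months=float(np.round(rng.uniform(lo, hi), 2)),
                    dfs_event=False,
                    planned_dose=spec.planned_dose,
                    delivered_dose=spec.planned_dose,
                )
            )

    ln_pcr_patients = [p for p in patients if p.breast_ln_pcr]
    for p in ln_pcr_patients[: spec.n_ypt0_ypn0]:
        p.ypt0_ypn0 = True
    non_pcr = [p for p in patients if not p.breast_pcr]
    for p in non_pcr[: spec.n_ncr]:
        p.ncr = True

    order = rng.permutation(len(patients))
    for j in order[: spec.n_breast_conserving]:
        patients[j].surgery = "breast_conserving"

    for st, n_events in spec.dfs_events.items():
        group = [p for p in patients if p.subtype == st and not p.breast_pcr]
        group += [p for p in patients if p.subtype == st and p.breast_pcr]
        for p in group[:n_events]:
            p.dfs_event = True
            p.dfs_months = float(np.round(rng.uniform(3.0, lo), 2))

    order = rng.permutation(len(patients))
    low_dose = order[spec.n_rdi_ge_085:]
    for j in order[: spec.n_rdi_ge_085]:
        patients[j].delivered_dose = float(np.round(spec.planned_dose * rng.uniform(0.85, 1.0), 1))
    for j in low_dose:
        patients[j].delivered_dose = float(np.round(spec.planned_dose * rng.uniform(0.40, 0.849), 1))

    for term, (any_n, ge3_n) in spec.ae_marginals.items():
        order = rng.permutation(len(patients))
        chosen = order[:any_n]
        for pos, j in enumerate(chosen):
            grade = int(rng.integers(3, 5)) if pos < ge3_n else int(rng.integers(1, 3))
            patients[j].adverse_events.append((term, grade))
    return patients
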
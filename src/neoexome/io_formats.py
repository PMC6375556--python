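"""Readers and writers for the project's file formats.

Formats handled:

* **MAF-like variant TSV** — one row per somatic call, fixed documented column
  order (:data:`neoexome.records.VARIANT_TSV_COLUMNS`); unknown extra columns
  are preserved in a passthrough map and re-emitted after the known ones.
* **Minimal VCF 4.2 subset** — CHROM POS ID REF ALT QUAL FILTER INFO FORMAT
  with per-sample DP/AD (tumour first, matched germline second); the remaining
  record fields travel as INFO keys. Read through :mod:`cyvcf2`.
* **BED-like depth track** — ``chrom  start  end  depth`` with 0-based
  half-open intervals, converted internally to closed per-base semantics.
* **Signature CSV** — rows are signatures, columns the 96 canonical context
  classes; every row must sum to 1.
* **GMT** — tab-separated ``name  description  gene…`` gene-set files.

Coordinates in memory are 1-based fully closed, VCF-style; INDELs are expected
left-aligned with an anchor base. VAF is stored as a fraction in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import SBS96_CLASSES
from .records import PREDICTORS, VARIANT_TSV_COLUMNS, VariantRecord

_INT_FIELDS = {
    "pos",
    "tumour_depth",
    "tumour_alt_reads",
    "germline_depth",
    "indel_support_total",
    "indel_support_interior",
    "germline_cover_at_site",
    "germline_indels_within_20bp",
    "adjacent_repeat_regions",
}
_FLOAT_FIELDS = {"call_quality", "vaf", "germline_mismatch_fraction", "local_mismatch_rate_10bp"}


class FormatError(ValueError):
    """A file failed to parse under the named dialect."""


# ---------------------------------------------------------------------------
# variant tables


def _record_to_row(rec: VariantRecord) -> dict[str, object]:
    row: dict[str, object] = {}
    for col in VARIANT_TSV_COLUMNS:
        if col in PREDICTORS:
            row[col] = rec.predictor_verdicts.get(col, "unknown")
        else:
            row[col] = getattr(rec, col)
    row.update(rec.passthrough)
    return row


def _row_to_record(row: dict[str, object]) -> VariantRecord:
    kwargs: dict[str, object] = {}
    verdicts: dict[str, str] = {}
    passthrough: dict[str, str] = {}
    for key, raw in row.items():
        if key in PREDICTORS:
            verdicts[key] = str(raw)
        elif key in _INT_FIELDS:
            kwargs[key] = int(raw)
        elif key in _FLOAT_FIELDS:
            kwargs[key] = float(raw)
        elif key in VARIANT_TSV_COLUMNS:
            kwargs[key] = "" if pd.isna(raw) else str(raw)
        else:
            passthrough[key] = str(raw)
    return VariantRecord(predictor_verdicts=verdicts, passthrough=passthrough, **kwargs)


def write_variants(records: list[VariantRecord], path: str | Path, dialect: str = "maf_tsv") -> None:
    path = Path(path)
    if dialect == "maf_tsv":
        rows = [_record_to_row(r) for r in records]
        extra = sorted({k for r in rows for k in r} - set(VARIANT_TSV_COLUMNS))
        df = pd.DataFrame(rows, columns=list(VARIANT_TSV_COLUMNS) + extra)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "vcf_minimal":
        _write_vcf(records, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_variants_with_report(
    path: str | Path, dialect: str = "maf_tsv"
) -> tuple[list[VariantRecord], list[tuple[int, str]]]:
    """Parse a variant file; invariant-violating rows are skipped and reported.

    Returns the parsed records and a list of ``(line_number, reason)`` for
    every skipped row. A row that cannot be parsed at all raises
    :class:`FormatError` naming the line.
    """
    path = Path(path)
    if dialect == "maf_tsv":
        raw = _read_maf_rows(path)
    elif dialect == "vcf_minimal":
        raw = _read_vcf_rows(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    records: list[VariantRecord] = []
    skipped: list[tuple[int, str]] = []
    for lineno, row in raw:
        try:
            rec = _row_to_record(row)
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
        problems = rec.violations()
        if problems:
            reason = "; ".join(problems)
            warnings.warn(f"{path}:{lineno}: skipping record {rec.uid}: {reason}", stacklevel=2)
            skipped.append((lineno, reason))
        else:
            records.append(rec)
    return records, skipped


def read_variants(path: str | Path, dialect: str = "maf_tsv") -> list[VariantRecord]:
    records, _ = read_variants_with_report(path, dialect)
    return records


def _read_maf_rows(path: Path) -> list[tuple[int, dict[str, object]]]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = set(VARIANT_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    # line 1 is the header, data starts on line 2
    return [(i + 2, row) for i, row in enumerate(df.to_dict("records"))]


# VCF INFO keys used for fields that have no standard VCF home.
_VCF_INFO_KEYS = {
    "kind": "KIND",
    "consequence": "CSQCLASS",
    "gene": "GENE",
    "context": "CTX",
    "germline_mismatch_fraction": "GMF",
    "indel_support_total": "IST",
    "indel_support_interior": "ISI",
    "germline_cover_at_site": "GCS",
    "germline_indels_within_20bp": "GIW",
    "local_mismatch_rate_10bp": "LMR",
    "adjacent_repeat_regions": "ARR",
}

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    '##INFO=<ID=KIND,Number=1,Type=String,Description="SNV, INS or DEL">',
    '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CTX,Number=1,Type=String,Description="Pyrimidine-normalised trinucleotide context">',
    '##INFO=<ID=GMF,Number=1,Type=Float,Description="Germline mismatch fraction at site">',
    '##INFO=<ID=IST,Number=1,Type=Integer,Description="INDEL supporting reads, total">',
    '##INFO=<ID=ISI,Number=1,Type=Integer,Description="INDEL supporting reads >=25bp from both read ends">',
    '##INFO=<ID=GCS,Number=1,Type=Integer,Description="Germline reads covering the site">',
    '##INFO=<ID=GIW,Number=1,Type=Integer,Description="Germline INDELs within 20bp">',
    '##INFO=<ID=LMR,Number=1,Type=Float,Description="Mismatch rate in surrounding 10bp">',
    '##INFO=<ID=ARR,Number=1,Type=Integer,Description="Adjacent repetitive regions">',
]
for _tool in PREDICTORS:
    _VCF_HEADER_LINES.append(
        f'##INFO=<ID={_tool},Number=1,Type=String,Description="{_tool} verdict">'
    )


def _write_vcf(records: list[VariantRecord], path: Path) -> None:
    sample = records[0].sample_id if records else "TUMOUR"
    lines = list(_VCF_HEADER_LINES)
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\tGERMLINE")
    for rec in records:
        info_parts = []
        for attr, key in _VCF_INFO_KEYS.items():
            val = getattr(rec, attr)
            if val == "" and attr in ("gene", "context"):
                continue
            info_parts.append(f"{key}={val}")
        for tool in PREDICTORS:
            info_parts.append(f"{tool}={rec.predictor_verdicts.get(tool, 'unknown')}")
        tum_ref = rec.tumour_depth - rec.tumour_alt_reads
        tumour = f"{rec.tumour_depth}:{tum_ref},{rec.tumour_alt_reads}"
        germ = f"{rec.germline_depth}:.,."
        qual = f"{rec.call_quality:g}"
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t{qual}\tPASS\t"
            + ";".join(info_parts)
            + f"\tDP:AD\t{tumour}\t{germ}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf_rows(path: Path) -> list[tuple[int, dict[str, object]]]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot open as VCF ({exc})") from exc
    sample = vcf.samples[0] if vcf.samples else "TUMOUR"
    rows: list[tuple[int, dict[str, object]]] = []
    for i, v in enumerate(vcf):
        dp = v.format("DP")
        ad = v.format("AD")
        tumour_depth = int(dp[0][0])
        tumour_alt = int(ad[0][1])
        germ_depth = int(dp[1][0]) if dp.shape[0] > 1 else 0
        row: dict[str, object] = {
            "sample_id": sample,
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
            "call_quality": v.QUAL if v.QUAL is not None else 0.0,
            "tumour_depth": tumour_depth,
            "tumour_alt_reads": tumour_alt,
            "vaf": tumour_alt / tumour_depth if tumour_depth else 0.0,
            "germline_depth": germ_depth,
        }
        for attr, key in _VCF_INFO_KEYS.items():
            val = v.INFO.get(key)
            if val is not None:
                row[attr] = val
        row.setdefault("gene", "")
        row.setdefault("context", "")
        row.setdefault("germline_mismatch_fraction", 0.0)
        for tool in PREDICTORS:
            verdict = v.INFO.get(tool)
            if verdict is not None:
                row[tool] = verdict
        rows.append((i + 1, row))  # record ordinal, not physical line
    return rows


# ---------------------------------------------------------------------------
# depth tracks


@dataclass
class DepthTrack:
    """Per-base sequencing depth as 0-based half-open constant-depth intervals."""

    intervals: pd.DataFrame  # columns chrom, start, end, depth

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "depth"]
        if list(self.intervals.columns)[:4] != required:
            raise ValueError(f"depth track needs columns {required}")
        if (self.intervals["end"] <= self.intervals["start"]).any():
            raise ValueError("empty or inverted interval in depth track")

    @property
    def length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def bases_at_least(self, min_depth: int) -> int:
        sel = self.intervals["depth"] >= min_depth
        return int((self.intervals.loc[sel, "end"] - self.intervals.loc[sel, "start"]).sum())

    @classmethod
    def from_per_base(cls, depths: np.ndarray, chrom: str = "chr1", offset: int = 0) -> "DepthTrack":
        """Run-length encode a per-base depth vector into intervals."""
        depths = np.asarray(depths)
        if depths.size == 0:
            raise ValueError("empty depth vector")
        change = np.flatnonzero(np.diff(depths)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [depths.size]))
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts + offset,
                "end": ends + offset,
                "depth": depths[starts].astype(int),
            }
        )
        return cls(df)

    def per_base(self) -> np.ndarray:
        return np.repeat(
            self.intervals["depth"].to_numpy(), (self.intervals["end"] - self.intervals["start"]).to_numpy()
        )


def write_depth_track(track: DepthTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", index=False, header=False)


def read_depth_track(path: str | Path) -> DepthTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": int},
    )
    if df.empty:
        raise FormatError(f"{path}: empty depth track")
    return DepthTrack(df)


# ---------------------------------------------------------------------------
# signature matrices


@dataclass
class SignatureMatrix:
    """Reference signatures: rows are signatures, columns the 96 context classes."""

    signature_ids: list[str]
    values: np.ndarray  # (n_signatures, 96), rows sum to 1

    ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 96:
            raise ValueError("signature matrix must be n_signatures x 96")
        if len(self.signature_ids) != self.values.shape[0]:
            raise ValueError("signature id count does not match rows")
        if (self.values < 0).any():
            raise ValueError("negative signature probability")
        bad = np.flatnonzero(np.abs(self.values.sum(axis=1) - 1.0) > self.ROW_SUM_TOL)
        if bad.size:
            raise ValueError(
                f"signature rows do not sum to 1: {[self.signature_ids[i] for i in bad]}"
            )

    def row(self, signature_id: str) -> np.ndarray:
        return self.values[self.signature_ids.index(signature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signature_ids, columns=list(SBS96_CLASSES))


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "signature"
    df.to_csv(path, float_format="%.8g")


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, index_col=0)
    missing = set(SBS96_CLASSES) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing context classes, e.g. {sorted(missing)[:3]}")
    df = df[list(SBS96_CLASSES)]  # canonical column order
    try:
        return SignatureMatrix(list(df.index.astype(str)), df.to_numpy())
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe size used for enrichment."""

    sets: dict[str, frozenset[str]]
    background_size: int = 0  # 0: default to the distinct-gene universe
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {name!r}")
        self.sets = {name: frozenset(g.upper() for g in genes) for name, genes in self.sets.items()}
        if self.background_size == 0:
            self.background_size = len(self.universe())

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path, background_size: int = 0) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, desc, *genes = parts
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = frozenset(g.upper() for g in genes if g)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, background_size=background_size, descriptions=descriptions)
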
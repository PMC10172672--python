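"""Readers and writers for the tabular formats the pipeline touches.

Internal conventions: genomic coordinates are 1-based inclusive (BED input is
shifted on ingest); chromosome labels are compared after stripping an optional
``chr`` prefix; beta matrices may contain explicit NA values, which are
propagated, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CONSEQUENCES = {"synonymous", "nonsynonymous", "other"}
VALID_VCLASSES = {"SNV", "MNV", "INS", "DEL"}
VALID_TISSUES = {"metastasis", "adjacent_liver", "control_colon"}
VALID_CHRONICITY = {"synchronous", "metachronous", "none"}
VALID_MATRIX_KINDS = {"counts", "normalized", "beta"}


class ParseError(ValueError):
    """Malformed content in an input file (carries file/line context)."""


class SchemaError(ValueError):
    """A required column or field is missing."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


def norm_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix so mixed-source labels compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant in one sample.

    ``context`` is the 3-letter trinucleotide context on the reference strand,
    centred on the reference base; it is set for SNVs only (empty otherwise).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    context: str
    consequence: str
    vclass: str
    sample_id: str
    clonality: str = "clonal"

    def validate(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError(f"depth {self.depth} negative")
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValidationError(f"consequence {self.consequence!r} invalid")
        if self.vclass not in VALID_VCLASSES:
            raise ValidationError(f"vclass {self.vclass!r} invalid")
        if self.vclass == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValidationError("SNV requires single-base ref and alt")
            if len(self.context) != 3 or self.context[1] != self.ref:
                raise ValidationError(
                    f"SNV context {self.context!r} does not centre on ref {self.ref!r}"
                )


@dataclass(frozen=True)
class SegmentRecord:
    """A copy-number segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    copy_number: int
    sample_id: str

    def validate(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.copy_number < 0:
            raise ValidationError(f"copy_number {self.copy_number} negative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureMatrix:
    """Features x samples matrix of one of the pipeline's value kinds."""

    values: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in VALID_MATRIX_KINDS:
            raise ValidationError(f"matrix kind {self.kind!r} invalid")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if self.kind == "counts" and np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("counts matrix contains negative values")
        if self.kind == "beta":
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError("beta matrix has values outside [0, 1]")
        elif self.kind == "normalized" and np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("normalized matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    tissue: str
    chronicity: str = "none"

    def validate(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise ValidationError(f"tissue {self.tissue!r} invalid")
        if self.chronicity not in VALID_CHRONICITY:
            raise ValidationError(f"chronicity {self.chronicity!r} invalid")
        if self.tissue == "control_colon" and self.chronicity != "none":
            raise ValidationError("control_colon samples have chronicity 'none'")


@dataclass
class GeneAnnotation:
    """A gene span plus the methylation probes mapped to it."""

    gene_id: str
    chrom: str
    start: int
    end: int
    probe_ids: dict[str, str] = field(default_factory=dict)  # probe -> region label

    def validate(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")


@dataclass
class VariantParseResult:
    """Accepted records plus a rejection report of (line_number, reason)."""

    records: list[VariantRecord]
    rejected: list[tuple[int, str]]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth",
    "context", "consequence", "vclass", "clonality",
]


def infer_vclass(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in info.split(";"):
        if not item:
            continue
        if "=" in item:
            key, _, val = item.partition("=")
            out[key] = val
        else:
            out[item] = ""
    return out


def parse_variants(
    path: str | Path, dialect: str = "tsv", default_sample: str | None = None
) -> VariantParseResult:
    """Parse a variant table (``tsv``) or a minimal VCF (``vcf``).

    Records violating invariants (vaf outside [0,1], malformed SNV context, ...)
    are rejected and listed in the returned report rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _parse_variants_vcf(path, default_sample)
    if dialect == "tsv":
        return _parse_variants_tsv(path, default_sample)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _finish_record(raw: VariantRecord, lineno: int, records, rejected) -> None:
    try:
        raw.validate()
    except ValidationError as exc:
        rejected.append((lineno, str(exc)))
        return
    records.append(raw)


def _parse_variants_vcf(path: Path, default_sample: str | None) -> VariantParseResult:
    records: list[VariantRecord] = []
    rejected: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: VCF line has {len(fields)} fields (expected >= 8)")
            chrom, pos, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            info = _parse_info(fields[7])
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer POS {pos!r}") from exc
            missing = [k for k in ("VAF", "DP") if k not in info]
            if missing:
                raise SchemaError(f"{path}:{lineno}: INFO lacks required keys {missing}")
            vclass = info.get("VCLASS") or infer_vclass(ref, alt)
            try:
                rec = VariantRecord(
                    chrom=chrom,
                    pos=pos_i,
                    ref=ref,
                    alt=alt,
                    vaf=float(info["VAF"]),
                    depth=int(info["DP"]),
                    context=info.get("CTX", "") if vclass == "SNV" else "",
                    consequence=info.get("CSQ", "other"),
                    vclass=vclass,
                    sample_id=info.get("SAMPLE", default_sample or ""),
                    clonality=info.get("CLONALITY", "clonal"),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            _finish_record(rec, lineno, records, rejected)
    if rejected:
        logger.warning("%s: rejected %d variant records", path, len(rejected))
    return VariantParseResult(records, rejected)


def _parse_variants_tsv(path: Path, default_sample: str | None) -> VariantParseResult:
    records: list[VariantRecord] = []
    rejected: list[tuple[int, str]] = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        required = {"chrom", "pos", "ref", "alt", "vaf", "depth"}
        if not required.issubset(header):
            raise SchemaError(
                f"{path}: missing required columns {sorted(required - set(header))}"
            )
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: {len(fields)} fields, header has {len(header)}"
                )

            def get(name: str, default: str = "") -> str:
                return fields[col[name]] if name in col else default

            ref, alt = get("ref"), get("alt")
            vclass = get("vclass") or infer_vclass(ref, alt)
            try:
                rec = VariantRecord(
                    chrom=get("chrom"),
                    pos=int(get("pos")),
                    ref=ref,
                    alt=alt,
                    vaf=float(get("vaf")),
                    depth=int(get("depth")),
                    context=get("context") if vclass == "SNV" else "",
                    consequence=get("consequence", "other") or "other",
                    vclass=vclass,
                    sample_id=get("sample_id", default_sample or "") or (default_sample or ""),
                    clonality=get("clonality", "clonal") or "clonal",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            _finish_record(rec, lineno, records, rejected)
    if rejected:
        logger.warning("%s: rejected %d variant records", path, len(rejected))
    return VariantParseResult(records, rejected)


def write_variants(records: Iterable[VariantRecord], path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        rows = [
            [r.sample_id, r.chrom, str(r.pos), r.ref, r.alt, repr(r.vaf), str(r.depth),
             r.context, r.consequence, r.vclass, r.clonality]
            for r in records
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(VARIANT_TSV_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in records:
                info = (
                    f"VAF={r.vaf!r};DP={r.depth};CSQ={r.consequence};"
                    f"VCLASS={r.vclass};SAMPLE={r.sample_id};CLONALITY={r.clonality}"
                )
                if r.context:
                    info += f";CTX={r.context}"
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n"
                )
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

def parse_segments(path: str | Path, dialect: str = "seg") -> list[SegmentRecord]:
    """Parse copy-number segments from SEG (1-based, with header) or BED.

    BED intervals (0-based half-open) are shifted to the internal 1-based
    inclusive convention: start+1, end unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    segments: list[SegmentRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith(("#", "track", "browser"))]
    if not lines:
        logger.warning("%s: empty segment file", path)
        return []
    if dialect == "seg":
        header = lines[0].split("\t")
        required = {"sample", "chrom", "start", "end", "copy_number"}
        if not required.issubset(header):
            raise SchemaError(f"{path}: SEG header missing {sorted(required - set(header))}")
        col = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(lines[1:], start=2):
            f = line.split("\t")
            try:
                seg = SegmentRecord(
                    chrom=f[col["chrom"]],
                    start=int(f[col["start"]]),
                    end=int(f[col["end"]]),
                    copy_number=int(f[col["copy_number"]]),
                    sample_id=f[col["sample"]],
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            seg.validate()
            segments.append(seg)
    elif dialect == "bed":
        for lineno, line in enumerate(lines, start=1):
            f = line.split()
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: BED line needs >= 4 fields")
            try:
                seg = SegmentRecord(
                    chrom=f[0],
                    start=int(f[1]) + 1,  # 0-based half-open -> 1-based inclusive
                    end=int(f[2]),
                    copy_number=int(f[3]),
                    sample_id=f[4] if len(f) > 4 else "",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            seg.validate()
            segments.append(seg)
    else:
        raise ValueError(f"unknown segment dialect {dialect!r}")
    return segments


def write_segments(segments: Iterable[SegmentRecord], path: str | Path, dialect: str = "seg") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "seg":
            fh.write("sample\tchrom\tstart\tend\tcopy_number\n")
            for s in segments:
                fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.copy_number}\n")
        elif dialect == "bed":
            for s in segments:
                fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.copy_number}\t{s.sample_id}\n")
        else:
            raise ValueError(f"unknown segment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Matrices, gene sets, annotation, metadata
# ---------------------------------------------------------------------------

def parse_matrix(path: str | Path, kind: str = "counts") -> FeatureMatrix:
    """Parse a TSV feature-by-sample matrix (first column = feature ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for j, c in enumerate(df.columns):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna() & (df[c].astype(str).str.upper() != "NA")
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric cell at feature {df.index[i]!r}, sample {c!r}"
            )
        df[c] = col
    df.index = df.index.astype(str)
    return FeatureMatrix(values=df, kind=kind)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def parse_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> gene..., deduplicated."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >= 1 gene")
            name = f[0]
            seen: dict[str, None] = {}
            for g in f[2:]:
                if g:
                    seen.setdefault(g)
            sets[name] = list(seen)
    return sets


def write_gene_sets(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def parse_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient_id", "tissue"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    metas = []
    for _, row in df.iterrows():
        m = SampleMeta(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            tissue=str(row["tissue"]),
            chronicity=str(row.get("chronicity", "none") or "none"),
        )
        m.validate()
        metas.append(m)
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpatient_id\ttissue\tchronicity\n")
        for m in metas:
            fh.write(f"{m.sample_id}\t{m.patient_id}\t{m.tissue}\t{m.chronicity}\n")


def parse_gene_annotation(
    genes_path: str | Path, probes_path: str | Path | None = None
) -> dict[str, GeneAnnotation]:
    """Read gene spans (TSV: gene_id chrom start end) and an optional probe map
    (TSV: probe_id gene_id region)."""
    genes_df = pd.read_csv(genes_path, sep="\t")
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(genes_df.columns):
        raise SchemaError(f"{genes_path}: missing columns {sorted(required - set(genes_df.columns))}")
    ann: dict[str, GeneAnnotation] = {}
    for _, row in genes_df.iterrows():
        g = GeneAnnotation(
            gene_id=str(row["gene_id"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
        )
        g.validate()
        ann[g.gene_id] = g
    if probes_path is not None:
        probes_df = pd.read_csv(probes_path, sep="\t")
        for _, row in probes_df.iterrows():
            gid = str(row["gene_id"])
            if gid in ann:
                ann[gid].probe_ids[str(row["probe_id"])] = str(row["region"])
    return ann


def write_gene_annotation(
    annotation: dict[str, GeneAnnotation],
    genes_path: str | Path,
    probes_path: str | Path | None = None,
) -> None:
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\n")
        for g in annotation.values():
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\n")
    if probes_path is not None:
        with open(probes_path, "w") as fh:
            fh.write("probe_id\tgene_id\tregion\n")
            for g in annotation.values():
                for probe, region in g.probe_ids.items():
                    fh.write(f"{probe}\t{g.gene_id}\t{region}\n")
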
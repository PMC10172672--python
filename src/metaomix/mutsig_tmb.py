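"""Mutation catalogs, signature refitting, and tumor mutational burden.

Single-base substitutions are collapsed to the pyrimidine-reference convention
and binned into the standard 96 trinucleotide-context categories (six classes
C>A, C>G, C>T, T>A, T>C, T>G; within each class the 5' then 3' flanking bases
run alphabetically). Exposures of reference signatures are refit per sample by
non-negative least squares; signatures above a 5% proportion are reported.

aTMB counts SNVs, MNVs and indels per megabase of callable territory including
synonymous variants; fTMB excludes synonymous variants, so fTMB <= aTMB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import VariantRecord

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 context labels, e.g. "A[C>A]A", in the standard order.
CONTEXTS_96: list[str] = [
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
]
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}

TRANSITION_CLASSES = {"C>T", "T>C"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_snv(ref: str, alt: str, context: str) -> str:
    """Map an SNV to its 96-bin label, reverse-complementing purine references.

    Raises ValueError for non-ACGT alleles or a context not centred on ref.
    """
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid SNV alleles {ref}>{alt}")
    if len(context) != 3 or context[1] != ref or any(b not in _BASES for b in context):
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in "AG":
        ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalog:
    """96-bin SNV catalog for one sample; bin total equals accepted SNVs."""

    sample_id: str
    counts: np.ndarray
    rejected: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CONTEXTS_96, name=self.sample_id)


@dataclass
class SignatureFit:
    sample_id: str
    signature_names: list[str]
    exposures: np.ndarray
    proportions: np.ndarray
    residual: float
    reported: list[str]

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.signature_names, name=self.sample_id)


@dataclass
class TmbResult:
    sample_id: str
    atmb: float
    ftmb: float
    region_mb: float
    n_variants: int


def build_96_catalog(
    variants: list[VariantRecord],
    sample_id: str | None = None,
    include_subclonal: bool = True,
) -> MutationCatalog:
    """Bin one sample's SNVs into the 96 trinucleotide-context categories.

    Non-SNV records are ignored; SNVs whose context does not centre on the
    reference base are rejected and listed in the report. When
    ``include_subclonal`` is false, records flagged subclonal are skipped.
    """
    counts = np.zeros(96, dtype=int)
    rejected: list[str] = []
    sid = sample_id
    for v in variants:
        if v.vclass != "SNV":
            continue
        if not include_subclonal and v.clonality == "subclonal":
            continue
        if sid is None:
            sid = v.sample_id
        try:
            label = collapse_snv(v.ref, v.alt, v.context)
        except ValueError as exc:
            rejected.append(f"{v.chrom}:{v.pos} {exc}")
            continue
        counts[_CONTEXT_INDEX[label]] += 1
    if rejected:
        logger.warning("catalog %s: rejected %d SNVs", sid, len(rejected))
    return MutationCatalog(sample_id=sid or "", counts=counts, rejected=rejected)


def fit_signature_exposures(
    catalog: MutationCatalog | np.ndarray,
    signatures: pd.DataFrame,
    report_threshold: float = 0.05,
    column_tol: float = 1e-6,
) -> SignatureFit:
    """Refit signature exposures by NNLS: e = argmin_{e>=0} ||c - S e||_2.

    ``signatures`` is a 96 x k column-stochastic matrix (rows in the standard
    context order). Signatures whose exposure proportion exceeds
    ``report_threshold`` form the reported set, mirroring the usual >5% rule.
    """
    if isinstance(catalog, MutationCatalog):
        c = catalog.counts.astype(float)
        sid = catalog.sample_id
    else:
        c = np.asarray(catalog, dtype=float)
        sid = ""
    if c.shape != (96,):
        raise ValueError(f"catalog must have 96 bins, got {c.shape}")
    if (c < 0).any():
        raise ValueError("catalog contains negative counts")
    S = signatures.to_numpy(dtype=float)
    if S.shape[0] != 96:
        raise ValueError(f"signature matrix must have 96 rows, got {S.shape[0]}")
    colsums = S.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > column_tol):
        raise ValueError("signature matrix columns must sum to 1")
    names = list(signatures.columns)
    if c.sum() == 0:
        logger.warning("empty catalog %s: zero exposures", sid)
        zeros = np.zeros(len(names))
        return SignatureFit(sid, names, zeros, zeros, 0.0, [])
    exposures, residual = nnls(S, c)
    total = exposures.sum()
    proportions = exposures / total if total > 0 else np.zeros_like(exposures)
    reported = [n for n, p in zip(names, proportions) if p > report_threshold]
    return SignatureFit(sid, names, exposures, proportions, float(residual), reported)


def compute_tmb(
    variants: list[VariantRecord],
    region_mb: float,
    sample_id: str | None = None,
) -> TmbResult:
    """Mutations per megabase: aTMB over all SNV/MNV/indel records, fTMB
    excluding synonymous ones."""
    if region_mb <= 0:
        raise ValueError(f"region_mb must be positive, got {region_mb}")
    n_all = len(variants)
    n_func = sum(1 for v in variants if v.consequence != "synonymous")
    sid = sample_id or (variants[0].sample_id if variants else "")
    return TmbResult(
        sample_id=sid,
        atmb=n_all / region_mb,
        ftmb=n_func / region_mb,
        region_mb=region_mb,
        n_variants=n_all,
    )


def substitution_class_summary(
    variants: list[VariantRecord],
) -> tuple[dict[str, int], float | None]:
    """Pyrimidine-collapsed six-class counts and the transition/transversion
    ratio (None when no transversions are present)."""
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for v in variants:
        if v.vclass != "SNV":
            continue
        ref, alt = v.ref, v.alt
        if ref in "AG":
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        key = f"{ref}>{alt}"
        if key in counts:
            counts[key] += 1
    ti = counts["C>T"] + counts["T>C"]
    tv = sum(counts.values()) - ti
    ratio = (ti / tv) if tv > 0 else None
    return counts, ratio
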
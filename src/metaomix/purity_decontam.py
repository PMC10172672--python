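"""Tumor purity, stromal/immune scoring, and liver-contamination correction.

A metastasis expression profile is modelled as the mixture
``met = f * liver + (1 - f) * tumor`` where f is the fraction of signal from
admixed normal liver. Purity is read off somatic VAFs in copy-neutral regions
(clonal heterozygous expectation p/2); contamination is estimated either from
liver-marker genes (expression ratio) or from DNA-vs-RNA VAF dilution, and the
liver component is then subtracted and (optionally) rescaled by 1/(1 - f) so
cleaned profiles sit on the tumor scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import VariantRecord, norm_chrom

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few variants or marker genes to estimate the quantity."""


class FullContaminationError(ZeroDivisionError):
    """f = 1 with rescaling requested: no tumor signal to recover."""


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: str
    purity: float
    n_variants: int
    method: str = "vaf_median"


@dataclass
class ContaminationEstimate:
    sample_id: str
    fraction: float
    method: str  # marker_ratio | variant_ratio | least_squares
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EnrichmentScore:
    sample_id: str
    set_name: str
    score: float
    alpha: float


# ---------------------------------------------------------------------------
# Purity
# ---------------------------------------------------------------------------

def copy_neutral_variants(
    variants: list[VariantRecord],
    segments=None,
    ploidy: int = 2,
) -> list[VariantRecord]:
    """Keep variants not covered by any copy-aberrant segment of their sample."""
    if not segments:
        return list(variants)
    aberrant: dict[str, list[tuple[str, int, int]]] = {}
    for s in segments:
        if s.copy_number != ploidy:
            aberrant.setdefault(s.sample_id, []).append(
                (norm_chrom(s.chrom), s.start, s.end)
            )
    kept = []
    for v in variants:
        c = norm_chrom(v.chrom)
        hits = aberrant.get(v.sample_id, [])
        if not any(c == sc and a <= v.pos <= b for sc, a, b in hits):
            kept.append(v)
    return kept


def estimate_purity_vaf(
    variants: list[VariantRecord],
    neutral_regions: list[tuple[str, int, int]] | None = None,
    min_variants: int = 10,
    clonal_only: bool = True,
) -> PurityEstimate:
    """p = clip(2 * median VAF, 0, 1) over copy-neutral heterozygous SNVs.

    ``neutral_regions`` (chrom, start, end; 1-based inclusive) restricts the
    variants used; pass None when the input is already copy-neutral.
    """
    snvs = [v for v in variants if v.vclass == "SNV"]
    if clonal_only:
        snvs = [v for v in snvs if v.clonality != "subclonal"]
    if neutral_regions is not None:
        regions = [(norm_chrom(c), a, b) for c, a, b in neutral_regions]
        snvs = [
            v for v in snvs
            if any(norm_chrom(v.chrom) == c and a <= v.pos <= b for c, a, b in regions)
        ]
    if len(snvs) < min_variants:
        raise InsufficientDataError(
            f"only {len(snvs)} usable variants (need >= {min_variants})"
        )
    vafs = np.array([v.vaf for v in snvs])
    p = float(np.clip(2.0 * np.median(vafs), 0.0, 1.0))
    sid = snvs[0].sample_id
    return PurityEstimate(sample_id=sid, purity=p, n_variants=len(snvs))


# ---------------------------------------------------------------------------
# Single-sample enrichment (ssGSEA-style running sum)
# ---------------------------------------------------------------------------

def ssgsea_score(
    expression: pd.Series,
    gene_set: set[str] | list[str],
    alpha: float = 0.25,
    set_name: str = "",
    sample_id: str = "",
) -> EnrichmentScore:
    """Weighted running-sum enrichment of one gene set in one sample.

    Genes are ranked by descending expression (ties broken by stable input
    order). Walking down the ranking, in-set genes add their normalized rank
    weight ``r^alpha`` (r = N..1 from top to bottom) and out-of-set genes add
    1/(N - |G|); the score is the sum over positions of the difference of the
    two cumulative sums. A set spanning all features scores 0 by definition.
    """
    genes = list(expression.index)
    n = len(genes)
    in_set = np.array([g in set(gene_set) for g in genes])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise InsufficientDataError(f"gene set {set_name!r} does not intersect features")
    if n_in == n:
        return EnrichmentScore(sample_id, set_name, 0.0, alpha)
    order = np.argsort(-expression.to_numpy(), kind="stable")
    in_ranked = in_set[order]
    rank_weight = np.arange(n, 0, -1, dtype=float) ** alpha
    in_weights = np.where(in_ranked, rank_weight, 0.0)
    total_in = in_weights.sum()
    cum_in = np.cumsum(in_weights) / total_in
    cum_out = np.cumsum(np.where(in_ranked, 0.0, 1.0 / (n - n_in)))
    es = float(np.sum(cum_in - cum_out))
    return EnrichmentScore(sample_id, set_name, es, alpha)


# ---------------------------------------------------------------------------
# Contamination
# ---------------------------------------------------------------------------

def estimate_contamination(
    met: pd.Series,
    liver: pd.Series,
    colon: pd.Series | None = None,
    liver_markers: list[str] | None = None,
    method: str = "marker_ratio",
    min_markers: int = 20,
    expression_floor: float = 1.0,
    sample_id: str = "",
) -> ContaminationEstimate:
    """Estimate the liver fraction f of a metastasis expression profile.

    marker_ratio (default): median over liver-marker genes of met/liver,
    requiring liver expression above ``expression_floor``. least_squares:
    closed-form minimiser of ||met - f*liver - (1-f)*colon||^2 over all shared
    genes (requires ``colon``). Both are clipped to [0, 1].
    """
    met, liver = met.align(liver, join="inner")
    diagnostics: dict = {}

    if liver_markers is not None:
        markers = [g for g in liver_markers if g in met.index]
        lm = liver.loc[markers]
        usable = lm.index[lm > expression_floor]
        if len(usable) < min_markers:
            raise InsufficientDataError(
                f"only {len(usable)} liver markers above floor (need >= {min_markers})"
            )
        ratios = (met.loc[usable] / liver.loc[usable]).to_numpy()
        f_marker = float(np.clip(np.median(ratios), 0.0, 1.0))
        diagnostics["marker_ratio"] = f_marker
        diagnostics["n_markers"] = int(len(usable))
    elif method == "marker_ratio":
        raise InsufficientDataError("marker_ratio requires liver_markers")

    if colon is not None:
        shared = met.index.intersection(colon.index)
        m = met.loc[shared].to_numpy(dtype=float)
        l = liver.loc[shared].to_numpy(dtype=float)
        c = colon.loc[shared].to_numpy(dtype=float)
        d = l - c
        denom = float(d @ d)
        if denom > 0:
            f_ls = float(np.clip((m - c) @ d / denom, 0.0, 1.0))
            resid = float(np.sum((m - f_ls * l - (1 - f_ls) * c) ** 2))
            diagnostics["least_squares"] = f_ls
            diagnostics["residual"] = resid
    if method == "least_squares" and "least_squares" not in diagnostics:
        raise InsufficientDataError(
            "least_squares requires a colon baseline with liver != colon genes"
        )

    fraction = diagnostics[method]
    return ContaminationEstimate(sample_id, fraction, method, diagnostics)


def estimate_contamination_variant_ratio(
    dna_vaf: np.ndarray | pd.Series,
    rna_vaf: np.ndarray | pd.Series,
    rna_depth: np.ndarray | None = None,
    min_variants: int = 10,
    min_rna_depth: int = 10,
    sample_id: str = "",
) -> ContaminationEstimate:
    """f = clip(1 - median(rna_vaf / dna_vaf), 0, 1) over shared somatic
    variants in non-differentially-expressed genes.

    Assumes the variant-bearing genes are expressed equally in tumor and
    liver, so liver admixture dilutes the RNA VAF by (1 - f). Variants with
    zero DNA VAF are excluded; with RNA depth below ``min_rna_depth`` too.
    """
    dna = np.asarray(dna_vaf, dtype=float)
    rna = np.asarray(rna_vaf, dtype=float)
    if dna.shape != rna.shape:
        raise ValueError("dna_vaf and rna_vaf must have matching shapes")
    keep = dna > 0
    if rna_depth is not None:
        keep &= np.asarray(rna_depth) >= min_rna_depth
    if keep.sum() < min_variants:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable variants (need >= {min_variants})"
        )
    ratios = rna[keep] / dna[keep]
    f = float(np.clip(1.0 - np.median(ratios), 0.0, 1.0))
    return ContaminationEstimate(
        sample_id, f, "variant_ratio", {"n_variants": int(keep.sum())}
    )


# ---------------------------------------------------------------------------
# Decontamination
# ---------------------------------------------------------------------------

def decontaminate_counts(
    met: pd.Series,
    liver: pd.Series,
    f: float,
    rescale: bool = True,
    return_clipped: bool = False,
):
    """Remove the liver component: cleaned = max(0, met - f*liver), divided by
    (1 - f) when ``rescale`` (the default) so the result is on the tumor scale.

    f = 0 is the identity; f = 1 with rescaling is an error (no tumor signal).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f={f} outside [0, 1]")
    if rescale and f >= 1.0:
        raise FullContaminationError("f = 1: sample is entirely liver signal")
    met_a, liver_a = met.align(liver, join="inner")
    if len(met_a) != len(met) or len(liver_a) != len(liver):
        raise ValueError("met and liver feature ids do not match")
    residual = met_a - f * liver_a
    clipped = residual < 0
    cleaned = residual.clip(lower=0.0)
    if rescale and f > 0:
        cleaned = cleaned / (1.0 - f)
    n_clip = int(clipped.sum())
    if n_clip:
        logger.debug("decontamination clipped %d negative genes to 0", n_clip)
    if return_clipped:
        return cleaned, clipped
    return cleaned


def decontaminate_matrix(
    met_matrix: pd.DataFrame,
    liver_matrix: pd.DataFrame,
    fractions: dict[str, float],
    pairing: dict[str, str],
    rescale: bool = True,
) -> pd.DataFrame:
    """Decontaminate each metastasis column against its paired liver column.

    ``pairing`` maps metastasis sample id -> liver sample id; ``fractions``
    maps metastasis sample id -> estimated f.
    """
    out = {}
    for met_id in met_matrix.columns:
        liv_id = pairing[met_id]
        out[met_id] = decontaminate_counts(
            met_matrix[met_id], liver_matrix[liv_id], fractions[met_id], rescale=rescale
        )
    return pd.DataFrame(out, index=met_matrix.index)
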
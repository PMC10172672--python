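"""Gene-level copy-number calls, cohort recurrence, and length statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_formats import GeneAnnotation, SegmentRecord, ValidationError, norm_chrom


@dataclass(frozen=True)
class GeneCnvCall:
    gene_id: str
    sample_id: str
    call: str  # gain | loss | neutral
    copy_number: int
    covered_fraction: float


@dataclass
class LengthStats:
    """Segment-length summary for one class (duplication or deletion).

    The density mode comes from a Gaussian KDE (Silverman bandwidth) on log10
    lengths, reported back on the base scale — the planted length scales span
    several orders of magnitude, so the log scale is where the density is
    unimodal.
    """

    cnv_class: str
    n: int
    median: float
    mode: float
    min: float
    max: float


def _check_no_overlap(segments: list[SegmentRecord]) -> None:
    by_sample: dict[tuple[str, str], list[SegmentRecord]] = {}
    for s in segments:
        by_sample.setdefault((s.sample_id, norm_chrom(s.chrom)), []).append(s)
    offenders = []
    for (_sid, _chrom), segs in by_sample.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                offenders.append((prev, cur))
    if offenders:
        desc = "; ".join(
            f"{a.sample_id} {a.chrom}:{a.start}-{a.end} overlaps {b.start}-{b.end}"
            for a, b in offenders[:5]
        )
        raise ValidationError(f"overlapping same-sample segments: {desc}")


def gene_level_calls(
    segments: list[SegmentRecord],
    annotation: dict[str, GeneAnnotation],
    ploidy: int = 2,
    min_cover: float = 0.5,
) -> list[GeneCnvCall]:
    """Call gain/loss/neutral per gene per sample from covering segments.

    Each gene takes the copy-number state covering the largest fraction of its
    span, provided that fraction reaches ``min_cover``; ties go to the state
    farther from ploidy (direction-faithful tie-break). Genes with no
    qualifying coverage are neutral. Same-sample overlapping segments are a
    validation error.
    """
    _check_no_overlap(segments)
    samples = sorted({s.sample_id for s in segments})
    by_key: dict[tuple[str, str], list[SegmentRecord]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, norm_chrom(s.chrom)), []).append(s)
    calls: list[GeneCnvCall] = []
    for sid in samples:
        for gene in annotation.values():
            span = gene.end - gene.start + 1
            cover: dict[int, float] = {}
            for seg in by_key.get((sid, norm_chrom(gene.chrom)), []):
                ov = min(seg.end, gene.end) - max(seg.start, gene.start) + 1
                if ov > 0:
                    cover[seg.copy_number] = cover.get(seg.copy_number, 0.0) + ov / span
            best_cn, best_frac = ploidy, 0.0
            if cover:
                # dominant state; |CN - ploidy| breaks ties toward the aberration
                best_cn = max(cover, key=lambda cn: (cover[cn], abs(cn - ploidy)))
                best_frac = cover[best_cn]
            if best_frac >= min_cover and best_cn != ploidy:
                call = "gain" if best_cn > ploidy else "loss"
            else:
                call = "neutral"
                if best_frac < min_cover:
                    best_cn = ploidy
            calls.append(GeneCnvCall(gene.gene_id, sid, call, best_cn,
                                     min(best_frac, 1.0)))
    return calls


def calls_to_frame(calls: list[GeneCnvCall]) -> pd.DataFrame:
    """Gene x sample matrix of call labels."""
    df = pd.DataFrame(
        [(c.gene_id, c.sample_id, c.call) for c in calls],
        columns=["gene_id", "sample_id", "call"],
    )
    return df.pivot(index="gene_id", columns="sample_id", values="call")


def recurrent_genes(
    calls: list[GeneCnvCall],
    min_fraction: float = 0.5,
    merge_directions: bool = False,
) -> tuple[set[str], set[str]]:
    """Genes gained (resp. lost) in at least ``min_fraction`` of samples.

    Directions are counted separately by default; ``merge_directions`` counts
    any aberration toward a single recurrence test (the gene then lands in the
    set of its majority direction).
    """
    samples = {c.sample_id for c in calls}
    if len(samples) < 2:
        raise ValueError("recurrence needs at least 2 samples")
    n = len(samples)
    gain_counts: dict[str, int] = {}
    loss_counts: dict[str, int] = {}
    for c in calls:
        if c.call == "gain":
            gain_counts[c.gene_id] = gain_counts.get(c.gene_id, 0) + 1
        elif c.call == "loss":
            loss_counts[c.gene_id] = loss_counts.get(c.gene_id, 0) + 1
    gains: set[str] = set()
    losses: set[str] = set()
    if merge_directions:
        for g in set(gain_counts) | set(loss_counts):
            total = gain_counts.get(g, 0) + loss_counts.get(g, 0)
            if total / n >= min_fraction:
                (gains if gain_counts.get(g, 0) >= loss_counts.get(g, 0) else losses).add(g)
    else:
        gains = {g for g, k in gain_counts.items() if k / n >= min_fraction}
        losses = {g for g, k in loss_counts.items() if k / n >= min_fraction}
    return gains, losses


def segment_length_stats(
    segments: list[SegmentRecord], ploidy: int = 2
) -> dict[str, LengthStats | None]:
    """Median / KDE-mode / range of duplication and deletion lengths.

    Classes with no segments are reported as None.
    """
    lengths = {"duplication": [], "deletion": []}
    for s in segments:
        if s.copy_number > ploidy:
            lengths["duplication"].append(s.length)
        elif s.copy_number < ploidy:
            lengths["deletion"].append(s.length)
    out: dict[str, LengthStats | None] = {}
    for cls, vals in lengths.items():
        if not vals:
            out[cls] = None
            continue
        arr = np.asarray(sorted(vals), dtype=float)
        if arr.size == 1 or np.allclose(arr, arr[0]):
            mode = float(arr[0])
        else:
            log_l = np.log10(arr)
            kde = gaussian_kde(log_l, bw_method="silverman")
            grid = np.linspace(log_l.min(), log_l.max(), 512)
            mode = float(10 ** grid[np.argmax(kde(grid))])
        out[cls] = LengthStats(
            cnv_class=cls,
            n=arr.size,
            median=float(np.median(arr)),
            mode=mode,
            min=float(arr.min()),
            max=float(arr.max()),
        )
    return out
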
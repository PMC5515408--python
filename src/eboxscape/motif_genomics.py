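"""Motif scanning over genomes and peak/summit statistics.

Coordinates are 0-based half-open throughout.  A motif instance is "in" a
region only when the full hexamer is contained in the region interval; for
enrichment each instance is counted once even if covered by several regions,
while per-region statistics (co-occurrence, coverage) count regions.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .errors import InvalidArgumentError, SchemaError

HIT_COLUMNS = ["motif", "chrom", "start", "end", "strand"]
SUMMIT_COLUMNS = ["chrom", "start", "end", "apex", "height", "pvalue", "condition", "id"]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _find_all(seq: str, pat: str) -> list[int]:
    """All (overlapping) exact match starts of pat in seq."""
    out = []
    i = seq.find(pat)
    while i != -1:
        out.append(i)
        i = seq.find(pat, i + 1)
    return out


def scan_motifs(genome: Mapping[str, str], motifs: Sequence[str]) -> pd.DataFrame:
    """Exact occurrences of each motif on both strands of every chromosome.

    Motif names in the output are canonical; palindromes yield one hit per
    position with strand '+'.  Windows containing N never match.  Hits are
    sorted by (chrom, start).
    """
    canon = []
    for m in motifs:
        _seq._validate_motif(m)
        c = _seq.canonical(m)
        if c not in canon:
            canon.append(c)
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for m in canon:
            for i in _find_all(seq, m):
                rows.append((m, chrom, i, i + 6, "+"))
            rc = _seq.revcomp(m)
            if rc != m:
                for i in _find_all(seq, rc):
                    rows.append((m, chrom, i, i + 6, "-"))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["chrom", "start", "motif"], kind="stable").reset_index(drop=True)


def genome_motif_counts(genome: Mapping[str, str], motifs: Sequence[str]) -> dict[str, int]:
    """Genome-wide occurrence count per canonical motif."""
    hits = scan_motifs(genome, motifs)
    counts = hits.groupby("motif").size().to_dict()
    return {_seq.canonical(m): int(counts.get(_seq.canonical(m), 0)) for m in motifs}


# ---------------------------------------------------------------------------
# peak handling
# ---------------------------------------------------------------------------

def make_summits(
    peaks: pd.DataFrame,
    radius: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One [apex-radius, apex+radius) region per peak, clamped to the chromosome."""
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    out = peaks.copy()
    start = out["apex"].to_numpy(int) - radius
    end = out["apex"].to_numpy(int) + radius
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limit = out["chrom"].map(chrom_sizes).to_numpy(int)
        end = np.minimum(end, limit)
    out["start"] = start
    out["end"] = end
    cols = [c for c in SUMMIT_COLUMNS if c in out.columns]
    return out[cols].reset_index(drop=True)


def top_fraction_peaks(
    peaks: pd.DataFrame, fraction: float = 0.33, key: str = "pvalue"
) -> pd.DataFrame:
    """The ceil(fraction*N) most significant peaks (smallest key values)."""
    if not 0 < fraction <= 1:
        raise InvalidArgumentError("fraction must lie in (0, 1]")
    n = math.ceil(fraction * len(peaks))
    ordered = peaks.sort_values(
        [key, "height", "id"], ascending=[True, False, True], kind="stable"
    )
    return ordered.head(n).reset_index(drop=True)


def stratify_by_fold(peaks: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Tertile split by fold enrichment: Low / Medium / High (sizes differ <=1).

    Ties in height are broken by peak id; with N not divisible by 3 the lower
    strata take the extra peaks.
    """
    if "height" not in peaks.columns:
        raise SchemaError("peaks must carry a height column")
    ordered = peaks.sort_values(["height", "id"], ascending=True, kind="stable")
    parts = np.array_split(np.arange(len(ordered)), 3)
    labels = ("Low", "Medium", "High")
    return {
        lab: ordered.iloc[idx].reset_index(drop=True) for lab, idx in zip(labels, parts)
    }


# ---------------------------------------------------------------------------
# containment machinery
# ---------------------------------------------------------------------------

def _merged_intervals(regions: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome merged (start, end) arrays for containment queries."""
    merged: dict[str, np.ndarray] = {}
    for chrom, sub in regions.groupby("chrom"):
        iv = sub[["start", "end"]].to_numpy(int)
        iv = iv[np.argsort(iv[:, 0], kind="stable")]
        out = []
        for s, e in iv:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=int)
    return merged


def _contained_mask(hits: pd.DataFrame, merged: Mapping[str, np.ndarray]) -> np.ndarray:
    """Boolean mask: hit fully contained in some merged region interval."""
    hits = hits.reset_index(drop=True)
    mask = np.zeros(len(hits), dtype=bool)
    for chrom, idx in hits.groupby("chrom").groups.items():
        iv = merged.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        starts = hits.loc[idx, "start"].to_numpy(int)
        ends = hits.loc[idx, "end"].to_numpy(int)
        j = np.searchsorted(iv[:, 0], starts, side="right") - 1
        ok = j >= 0
        ok[ok] &= ends[ok] <= iv[j[ok], 1]
        mask[hits.index.get_indexer(idx)] = ok
    return mask


def region_contains_motif(regions: pd.DataFrame, hits: pd.DataFrame) -> np.ndarray:
    """Per-region boolean: region fully contains >=1 hit."""
    out = np.zeros(len(regions), dtype=bool)
    by_chrom = {c: sub.sort_values("start") for c, sub in hits.groupby("chrom")}
    for i, (chrom, rs, re_) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        lo = np.searchsorted(starts, rs, side="left")
        hi = np.searchsorted(starts, re_ - 6, side="right")
        out[i] = bool(np.any(ends[lo:hi] <= re_))
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def normalized_frequency(
    regions: pd.DataFrame,
    hits: pd.DataFrame,
    genome_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Motif instances fully contained in the region set / genome-wide count.

    Each instance is counted once even when covered by overlapping regions.
    Motifs with a zero genome count are omitted with a warning.
    """
    merged = _merged_intervals(regions) if len(regions) else {}
    mask = _contained_mask(hits, merged) if len(hits) else np.zeros(0, dtype=bool)
    in_regions = hits.loc[mask].groupby("motif").size() if len(hits) else pd.Series(dtype=int)
    rows = []
    for motif, g in genome_counts.items():
        if g <= 0:
            warnings.warn(f"motif {motif} absent from genome; row omitted")
            continue
        k = int(in_regions.get(motif, 0))
        rows.append((motif, k, int(g), k / g))
    return pd.DataFrame(
        rows, columns=["motif", "hits_in_regions", "hits_genome", "normalized_frequency"]
    )


def cooccurrence_partition(
    regions: pd.DataFrame, hits_a: pd.DataFrame, hits_b: pd.DataFrame
) -> dict[str, int]:
    """Per-region Venn cells for two motifs: A_only / B_only / both / neither."""
    has_a = region_contains_motif(regions, hits_a)
    has_b = region_contains_motif(regions, hits_b)
    return {
        "A_only": int(np.sum(has_a & ~has_b)),
        "B_only": int(np.sum(~has_a & has_b)),
        "both": int(np.sum(has_a & has_b)),
        "neither": int(np.sum(~has_a & ~has_b)),
    }


def annotate_regions(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Assign each region to promoter / intragenic / intergenic by its apex.

    Precedence is promoter (apex within +/- promoter_window of a TSS) over
    intragenic (apex inside a gene span) over intergenic.  The nearest TSS
    gene is recorded with a signed distance (positive downstream of the TSS
    in the gene's orientation).
    """
    rows = []
    gene_list = list(genes.itertuples(index=False)) if len(genes) else []
    for reg in regions.itertuples(index=False):
        apex = int(reg.apex)
        category = "intergenic"
        nearest = None
        nearest_dist = None
        for g in gene_list:
            if g.chrom != reg.chrom:
                continue
            d = apex - int(g.tss)
            signed = d if g.strand == "+" else -d
            if nearest_dist is None or abs(signed) < abs(nearest_dist):
                nearest, nearest_dist = g.name, signed
            if abs(d) <= promoter_window:
                category = "promoter"
            elif category != "promoter" and g.start <= apex < g.end:
                category = "intragenic"
        rows.append((reg.id, category, nearest, nearest_dist))
    return pd.DataFrame(
        rows, columns=["region_id", "category", "nearest_gene", "tss_distance"]
    )


def condition_fold_change(
    summits_high: pd.DataFrame,
    summits_low: pd.DataFrame,
    hits_by_motif: Mapping[str, pd.DataFrame],
    mode: str = "count",
) -> pd.DataFrame:
    """High/low fold change in motif-containing summits (count or mean height)."""
    if mode not in ("count", "mean_height"):
        raise InvalidArgumentError("mode must be 'count' or 'mean_height'")
    rows = []
    for motif, hits in hits_by_motif.items():
        stat = {}
        for label, summits in (("high", summits_high), ("low", summits_low)):
            mask = region_contains_motif(summits, hits)
            if mode == "count":
                stat[label] = float(mask.sum())
            else:
                stat[label] = (
                    float(summits.loc[mask, "height"].mean()) if mask.any() else 0.0
                )
        if stat["low"] == 0:
            warnings.warn(f"motif {motif}: zero denominator in {mode} fold change")
            fc = math.inf
        else:
            fc = stat["high"] / stat["low"]
        rows.append((motif, mode, stat["high"], stat["low"], fc))
    return pd.DataFrame(rows, columns=["motif", "mode", "high", "low", "fold_change"])


def spatial_distribution(
    summits: pd.DataFrame,
    hits: pd.DataFrame,
    bin_size: int = 10,
    window: int = 100,
) -> pd.DataFrame:
    """Histogram of motif-midpoint offsets from the summit apex.

    Bins of ``bin_size`` bp cover [-window, window); counts are normalized by
    the number of summits.  A hit is binned once per summit whose window
    contains its midpoint.
    """
    if len(summits) == 0:
        raise InvalidArgumentError("summit set is empty")
    edges = np.arange(-window, window + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=float)
    by_chrom = {c: sub.sort_values("start") for c, sub in hits.groupby("chrom")}
    for s in summits.itertuples(index=False):
        sub = by_chrom.get(s.chrom)
        if sub is None:
            continue
        mids = sub["start"].to_numpy(int) + 3
        offs = mids - int(s.apex)
        sel = (offs >= -window) & (offs < window)
        if sel.any():
            counts += np.histogram(offs[sel], bins=edges)[0]
    return pd.DataFrame(
        {
            "offset_lo": edges[:-1],
            "offset_hi": edges[1:],
            "count": counts,
            "per_summit": counts / len(summits),
        }
    )


def topk_coverage(summits: pd.DataFrame, hits: pd.DataFrame, motif_list: Sequence[str]) -> float:
    """Fraction of summits containing >=1 hit of any motif in the list."""
    if len(summits) == 0:
        raise InvalidArgumentError("summit set is empty")
    canon = {_seq.canonical(m) for m in motif_list}
    if not canon:
        return 0.0
    sub = hits[hits["motif"].isin(canon)]
    return float(region_contains_motif(summits, sub).mean())
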
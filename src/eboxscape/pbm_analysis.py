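"""Probe-library design and array score analysis.

The designed library enumerates every central hexamer in the fixed register
``tgaNNNNNNgta`` (4096 probes), all 64 trinucleotide substitutions of each
flank of the top palindromic core (``nnnCACGTGgta`` and ``tgaCACGTGnnn``),
a configurable number of 3-6 point mutants of ``tgaCACGTGgta`` and a set of
fully random 12-mers that define the empirical null for thresholding.

Scores are log2 of median-of-triplicate intensities normalized to the array
median; motif lists are derived from the canonical core-register hexamer of
probes scoring above an empirical random-probe quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .errors import (
    CapacityError,
    InsufficientDataError,
    InvalidArgumentError,
    MissingNullError,
    SchemaError,
)

LINKER = "CGTCGATATAGTAATCTTAGCTATTAA"
CAP = "GCCGG"
CME_VAR12 = "TGACACGTGGTA"

LIBRARY_COLUMNS = ["id", "category", "var12", "core_hex", "full_seq"]
SCORE_COLUMNS = ["probe_id", "category", "var12", "dimer", "score"]


def _probe_row(pid: str, category: str, var12: str) -> tuple[str, str, str, str, str]:
    v = var12.upper()
    return (pid, category, v, v[3:9], LINKER + v + CAP)


def build_probe_library(
    n_cme_mut: int = 518, n_random: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Enumerate the designed probe library.

    Returns a frame with columns (id, category, var12, core_hex, full_seq);
    4096 core-register probes, 64 + 64 flank probes, ``n_cme_mut`` distinct
    3-6-point mutants of the reference 12-mer and ``n_random`` iid 12-mers.
    Deterministic for a fixed seed.
    """
    n_mutants_available = sum(
        math.comb(12, d) * 3 ** d for d in range(3, 7)
    )
    if n_cme_mut > n_mutants_available:
        raise CapacityError(
            f"only {n_mutants_available} distinct 3-6-point mutants exist"
        )
    if n_cme_mut < 0 or n_random < 0:
        raise InvalidArgumentError("probe counts must be non-negative")

    rows = []
    for i, hexamer in enumerate(_seq.all_kmers(6)):
        rows.append(_probe_row(f"core6_{i + 1:04d}", "core6", f"TGA{hexamer}GTA"))
    for i, tri in enumerate(_seq.all_kmers(3)):
        rows.append(_probe_row(f"flank_left_{i + 1:02d}", "flank_left", f"{tri}CACGTGGTA"))
    for i, tri in enumerate(_seq.all_kmers(3)):
        rows.append(_probe_row(f"flank_right_{i + 1:02d}", "flank_right", f"TGACACGTG{tri}"))

    rng = np.random.default_rng(seed)
    bases = np.array(list(_seq.DNA_ALPHABET))
    seen: set[str] = set()
    while len(seen) < n_cme_mut:
        d = int(rng.integers(3, 7))
        pos = rng.choice(12, size=d, replace=False)
        var = list(CME_VAR12)
        for p in pos:
            alt = [b for b in _seq.DNA_ALPHABET if b != var[p]]
            var[p] = alt[int(rng.integers(0, 3))]
        seen.add("".join(var))
    for i, var12 in enumerate(sorted(seen)):
        rows.append(_probe_row(f"cme_mut_{i + 1:03d}", "cme_mut", var12))

    for i in range(n_random):
        var12 = "".join(rng.choice(bases, size=12))
        rows.append(_probe_row(f"random_{i + 1:03d}", "random", var12))

    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def normalize_array(raw: pd.DataFrame) -> pd.DataFrame:
    """log2(median of triplicates / per-channel array median) per probe/dimer.

    The raw table needs columns (probe_id, dimer, rep, intensity); category
    and var12 are carried through when present.  Non-positive intensities are
    floored to the smallest positive intensity with a warning.
    """
    required = {"probe_id", "dimer", "rep", "intensity"}
    if not required.issubset(raw.columns):
        raise SchemaError(f"raw table must have columns {sorted(required)}")
    counts = raw.groupby(["probe_id", "dimer"], sort=False)["rep"].count()
    if (counts != 3).any():
        bad = counts[counts != 3].index[0]
        raise SchemaError(f"probe/dimer {bad} does not have exactly 3 replicates")

    raw = raw.copy()
    vals = raw["intensity"].to_numpy(float)
    if (vals <= 0).any():
        pos = vals[vals > 0]
        if pos.size == 0:
            raise SchemaError("all intensities are non-positive")
        floor = pos.min()
        warnings.warn(
            f"{int((vals <= 0).sum())} non-positive intensities floored to {floor}"
        )
        raw["intensity"] = np.where(vals <= 0, floor, vals)

    keys = ["probe_id", "dimer"]
    carry = [c for c in ("category", "var12") if c in raw.columns]
    med = raw.groupby(keys + carry, sort=False)["intensity"].median().reset_index()
    med = med.rename(columns={"intensity": "probe_median"})
    array_median = raw.groupby("dimer")["intensity"].median().rename("array_median")
    med = med.merge(array_median, on="dimer")
    med["score"] = np.log2(med["probe_median"] / med["array_median"])
    cols = ["probe_id", *carry, "dimer", "score"]
    return med[cols].sort_values(["dimer", "probe_id"], kind="stable").reset_index(drop=True)


class NullThreshold(NamedTuple):
    """Empirical-null threshold with the mean+2sd companion diagnostic."""

    value: float
    mean_plus_2sd: float
    q: float
    n_random: int


def null_threshold(scores: pd.DataFrame, dimer: str, q: float = 0.95) -> NullThreshold:
    """q-quantile (linear interpolation) of random-probe scores for a dimer."""
    if not 0 <= q <= 1:
        raise InvalidArgumentError("q must lie in [0, 1]")
    if "category" not in scores.columns:
        raise SchemaError("scores must carry a category column")
    null = scores[(scores["dimer"] == dimer) & (scores["category"] == "random")]["score"]
    if len(null) < 2:
        raise MissingNullError("need >= 2 random-category probes for a null")
    x = null.to_numpy(float)
    return NullThreshold(
        value=float(np.quantile(x, q)),
        mean_plus_2sd=float(x.mean() + 2 * x.std(ddof=1)),
        q=q,
        n_random=len(x),
    )


def bound_probes(
    scores: pd.DataFrame,
    dimer: str,
    threshold: float,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Probes with score strictly above the threshold, sorted descending.

    Ties are broken by probe id for a stable ordering.
    """
    thr = threshold.value if isinstance(threshold, NullThreshold) else float(threshold)
    sub = scores[scores["dimer"] == dimer]
    if categories is not None:
        sub = sub[sub["category"].isin(categories)]
    sub = sub[sub["score"] > thr]
    return sub.sort_values(
        ["score", "probe_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif lists
# ---------------------------------------------------------------------------

def motif_of_probe(var12: str) -> str:
    """Canonical core-register hexamer of a probe (var12 positions 4-9)."""
    v = var12.upper()
    if len(v) != 12:
        raise InvalidArgumentError("var12 must be 12 bases")
    return _seq.canonical(v[3:9])


MOTIF_CATEGORIES = ("core6", "flank_left", "flank_right", "cme_mut")


def rank_motifs(bound: pd.DataFrame) -> pd.DataFrame:
    """Rank canonical motifs of bound designed probes by best probe score.

    Random probes are excluded (they define the null, not a motif).  Ties in
    best score are broken by probe support (more probes first), then
    lexicographically by motif.
    """
    if bound.empty:
        raise InvalidArgumentError("bound set is empty")
    sub = bound[bound["category"].isin(MOTIF_CATEGORIES)].copy()
    sub["motif"] = [motif_of_probe(v) for v in sub["var12"]]
    agg = (
        sub.groupby("motif")
        .agg(best_score=("score", "max"), n_probes_above_threshold=("score", "size"))
        .reset_index()
    )
    agg = agg.sort_values(
        ["best_score", "n_probes_above_threshold", "motif"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    agg["class"] = [_seq.classify_hexamer(m) for m in agg["motif"]]
    return agg[["rank", "motif", "best_score", "n_probes_above_threshold", "class"]]


def common_motifs(list_a, list_b) -> set[str]:
    """Intersection of two motif collections (frames or iterables)."""

    def as_set(x) -> set[str]:
        if isinstance(x, pd.DataFrame):
            return set(x["motif"])
        return set(x)

    return as_set(list_a) & as_set(list_b)


def high_confidence_motifs(
    scores: pd.DataFrame,
    q_low: float = 0.80,
    q_high: float = 0.95,
    dimers: Sequence[str] = ("MYCMAX", "MAXMAX"),
) -> set[str]:
    """Motifs bound by both dimers above the relaxed null threshold.

    A motif qualifies when its best designed probe exceeds the ``q_low``
    random-probe quantile for *both* dimers and it appears in the union of the
    two ``q_high`` ranked lists.  ``q_low >= 1`` means "above 100% of the
    null", which is unsatisfiable by convention and yields the empty set.
    """
    if q_low >= 1.0:
        return set()
    ranked_union: set[str] = set()
    best: dict[str, dict[str, float]] = {}
    passes_low: dict[str, set[str]] = {}
    for dimer in dimers:
        thr_high = null_threshold(scores, dimer, q_high)
        bnd = bound_probes(scores, dimer, thr_high, categories=MOTIF_CATEGORIES)
        if not bnd.empty:
            ranked_union |= set(rank_motifs(bnd)["motif"])
        thr_low = null_threshold(scores, dimer, q_low)
        sub = scores[
            (scores["dimer"] == dimer) & (scores["category"].isin(MOTIF_CATEGORIES))
        ].copy()
        sub["motif"] = [motif_of_probe(v) for v in sub["var12"]]
        per_motif = sub.groupby("motif")["score"].max()
        passes_low[dimer] = set(per_motif[per_motif > thr_low.value].index)
    both_low = set.intersection(*passes_low.values()) if passes_low else set()
    return ranked_union & both_low


def score_correlation(scores: pd.DataFrame, dimers: Sequence[str] = ("MYCMAX", "MAXMAX")) -> float:
    """Squared Pearson correlation between the two dimers' paired scores."""
    wide = scores.pivot_table(index="probe_id", columns="dimer", values="score")
    wide = wide.dropna(subset=list(dimers))
    if len(wide) < 3:
        raise InsufficientDataError("need >= 3 paired probes")
    r = np.corrcoef(wide[dimers[0]], wide[dimers[1]])[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Base frequencies (rows A,C,G,T) and per-column information content."""

    freqs: np.ndarray  # shape (4, width)
    ic: np.ndarray  # bits per column
    n_sequences: int

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.freqs, axis=0))


_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _pwm_from_seqs(seqs: Sequence[str], pseudocount: float) -> PWM:
    width = len(seqs[0])
    counts = np.full((4, width), pseudocount, dtype=float)
    for s in seqs:
        for j, b in enumerate(s):
            counts[_BASE_INDEX[b], j] += 1.0
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return PWM(freqs=freqs, ic=np.clip(ic, 0.0, 2.0), n_sequences=len(seqs))


def build_pwm(
    bound: pd.DataFrame,
    rank_slice: tuple[int, int],
    pseudocount: float = 0.25,
) -> PWM:
    """PWM over the 8-mer window aNNNNNNg of rank-sliced core-register probes.

    ``rank_slice`` is 1-based inclusive over the descending score order of the
    bound set.  Each 8-mer (var12 positions 3-10) is flipped to the canonical
    orientation of its central hexamer before counting.
    """
    lo, hi = rank_slice
    if lo < 1 or hi < lo:
        raise InvalidArgumentError("rank_slice must be 1-based and non-empty")
    core = bound[bound["category"] == "core6"].reset_index(drop=True)
    if hi > len(core):
        raise InvalidArgumentError(
            f"rank_slice {rank_slice} exceeds the {len(core)} bound core probes"
        )
    seqs = []
    for var12 in core["var12"].iloc[lo - 1:hi]:
        window = var12[2:10].upper()
        hexamer = window[1:7]
        if _seq.canonical(hexamer) != hexamer:
            window = _seq.revcomp(window)
        seqs.append(window)
    return _pwm_from_seqs(seqs, pseudocount)


FLANK_QUARTILE_LABELS = ("0-25%", "25-50%", "50-75%", "75-100%")


def flank_quartile_pwms(
    scores: pd.DataFrame,
    side: str,
    dimer: str,
    pseudocount: float = 0.25,
) -> dict[str, PWM]:
    """Quartile PWMs over the 3 variable flank positions of one flank set.

    The 64 flank probes for the chosen side are ranked by descending score
    (ties by probe id) and split into four groups of 16, best first.
    """
    if side not in ("left", "right"):
        raise InvalidArgumentError("side must be 'left' or 'right'")
    category = f"flank_{side}"
    sub = scores[(scores["dimer"] == dimer) & (scores["category"] == category)]
    if len(sub) != 64:
        raise SchemaError(f"expected 64 {category} probes, found {len(sub)}")
    sub = sub.sort_values(
        ["score", "probe_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    sl = slice(0, 3) if side == "left" else slice(9, 12)
    out = {}
    for i, label in enumerate(FLANK_QUARTILE_LABELS):
        block = sub.iloc[i * 16:(i + 1) * 16]
        seqs = [v[sl].upper() for v in block["var12"]]
        out[label] = _pwm_from_seqs(seqs, pseudocount)
    return out


def relative_pbm_affinities(
    scores: pd.DataFrame, motifs: Sequence[str], reference: str, dimer: str
) -> dict[str, float]:
    """Linear-scale best-probe score per motif relative to a reference motif.

    Companion to the gel-shift affinity table: scores are log2, so ratios are
    ``2 ** (best(m) - best(ref))``.
    """
    sub = scores[
        (scores["dimer"] == dimer) & (scores["category"].isin(MOTIF_CATEGORIES))
    ].copy()
    sub["motif"] = [motif_of_probe(v) for v in sub["var12"]]
    best = sub.groupby("motif")["score"].max()
    ref = _seq.canonical(reference)
    if ref not in best:
        raise InvalidArgumentError(f"reference motif {reference!r} has no probes")
    return {
        m: float(2.0 ** (best[_seq.canonical(m)] - best[ref]))
        for m in motifs
        if _seq.canonical(m) in best
    }


def top_motifs_excluding_gcrich(ranked: pd.DataFrame, n: int = 21) -> list[str]:
    """Top-n ranked motifs after dropping the low-complexity G/C-rich class."""
    kept = ranked[ranked["class"] != "GC-rich"]
    return list(kept["motif"].iloc[:n])
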
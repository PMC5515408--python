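"""Synthetic input generators with known ground truth.

Everything the analysis pipeline consumes can be generated here: a random
genome with planted hexamer sites of tiered affinities, gene models,
dose-dependent peak calls driven by a mass-action occupancy model, triplicate
array intensities driven by a hexamer affinity table, and competition curves
with replicate noise.  All generators are pure functions of their arguments
(including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .errors import CapacityError, InvalidArgumentError, SchemaError

PROBE_CATEGORIES = ("core6", "flank_left", "flank_right", "cme_mut", "random")
DIMERS = ("MYCMAX", "MAXMAX")

TRUTH_COLUMNS = ["chrom", "start", "motif", "strand", "kd"]
PEAK_COLUMNS = ["chrom", "start", "end", "apex", "height", "pvalue", "condition", "id"]
GENE_COLUMNS = ["chrom", "start", "end", "name", "strand", "tss"]
ARRAY_COLUMNS = ["probe_id", "category", "var12", "dimer", "rep", "intensity"]


# ---------------------------------------------------------------------------
# affinity ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityTable:
    """Relative affinity a(m) per canonical hexamer, with tier labels.

    ``kd`` is defined as ``1 / a(m)`` so high-affinity motifs have low
    dissociation scales in the peak model.
    """

    entries: Mapping[str, float]
    tiers: Mapping[str, str]
    default_affinity: float = 0.05

    def __post_init__(self) -> None:
        if self.default_affinity <= 0:
            raise InvalidArgumentError("default_affinity must be > 0")
        canon_entries = {_seq.canonical(m): a for m, a in self.entries.items()}
        canon_tiers = {_seq.canonical(m): t for m, t in self.tiers.items()}
        object.__setattr__(self, "entries", canon_entries)
        object.__setattr__(self, "tiers", canon_tiers)
        if any(a <= 0 for a in canon_entries.values()):
            raise InvalidArgumentError("all affinities must be > 0")
        low = [a for m, a in canon_entries.items() if canon_tiers.get(m) == "low"]
        if low and self.default_affinity > min(low):
            raise InvalidArgumentError("default_affinity must not exceed the low tier")
        if canon_entries and max(canon_entries, key=canon_entries.get) != "CACGTG":
            raise InvalidArgumentError("CACGTG must be the maximum-affinity entry")

    def affinity(self, hexamer: str) -> float:
        return self.entries.get(_seq.canonical(hexamer), self.default_affinity)

    def kd(self, hexamer: str) -> float:
        return 1.0 / self.affinity(hexamer)

    def tier(self, hexamer: str) -> str:
        return self.tiers.get(_seq.canonical(hexamer), "none")


def default_affinity_table() -> AffinityTable:
    """Default tiers: top palindrome 25x, medium 5x, low 1x, background 0.05."""
    entries = {"CACGTG": 25.0}
    tiers = {"CACGTG": "high"}
    for m in ("CACGCG", "CATGTG", "CACGTT", "CATGCG", "CACGAG"):
        entries[m] = 5.0
        tiers[m] = "medium"
    for m in ("AACGTT", "CATATG", "CGCGTT"):
        entries[m] = 1.0
        tiers[m] = "low"
    return AffinityTable(entries=entries, tiers=tiers, default_affinity=0.05)


# ---------------------------------------------------------------------------
# genome / sites / genes
# ---------------------------------------------------------------------------

def gen_genome(n_chrom: int, length: int, gc: float, seed: int) -> dict[str, str]:
    """iid random genome with the requested GC fraction.

    Returns ``{chrom_name: sequence}`` with names ``chr1..chrN``.
    """
    if length <= 0:
        raise InvalidArgumentError("length must be positive")
    if not 0 < gc < 1:
        raise InvalidArgumentError("gc must lie in (0, 1)")
    if n_chrom <= 0:
        raise InvalidArgumentError("n_chrom must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {}
    for i in range(n_chrom):
        draw = rng.choice(bases, size=length, p=p)
        genome[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return genome


def plant_sites(
    genome: Mapping[str, str],
    plan: Sequence[tuple[str, int]],
    min_gap: int = 50,
    seed: int = 0,
    affinity: AffinityTable | None = None,
    max_tries_per_site: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant non-overlapping hexamer sites into a genome.

    Each planted site is written on a random strand; the returned truth table
    records (chrom, start, motif, strand, kd) with ``kd`` from the affinity
    table (default :func:`default_affinity_table`).
    """
    if affinity is None:
        affinity = default_affinity_table()
    for motif, count in plan:
        _seq._validate_motif(motif)
        if count < 0:
            raise InvalidArgumentError("counts must be non-negative")
    total = sum(c for _, c in plan)
    span = sum(len(s) for s in genome.values())
    if total * (6 + max(min_gap, 0)) > span:
        raise CapacityError("planting plan does not fit the genome")

    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    seqs = {c: bytearray(genome[c], "ascii") for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for motif, count in plan:
        m = motif.upper()
        for _ in range(count):
            for _attempt in range(max_tries_per_site):
                ci = rng.choice(len(chroms), p=weights)
                chrom = chroms[ci]
                L = len(genome[chrom])
                if L < 6:
                    continue
                start = int(rng.integers(0, L - 5))
                lo, hi = start - min_gap, start + 6 + min_gap
                if any(s < hi and lo < e for s, e in occupied[chrom]):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                written = m if strand == "+" else _seq.revcomp(m)
                seqs[chrom][start:start + 6] = written.encode("ascii")
                occupied[chrom].append((start, start + 6))
                rows.append((chrom, start, m, strand, affinity.kd(m)))
                break
            else:
                raise CapacityError(
                    f"could not place {motif} after {max_tries_per_site} tries"
                )
    out = {c: seqs[c].decode("ascii") for c in chroms}
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return out, truth


def gen_gene_models(
    genome: Mapping[str, str],
    n_genes: int,
    seed: int = 0,
    length_range: tuple[int, int] = (2000, 10000),
    max_tries_per_gene: int = 1000,
) -> pd.DataFrame:
    """Disjoint gene spans with strand-aware TSS (span start on +, end-1 on -)."""
    if n_genes < 0:
        raise InvalidArgumentError("n_genes must be non-negative")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    if n_genes and n_genes * length_range[0] > lengths.sum():
        raise CapacityError("genes do not fit the genome")
    weights = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for i in range(n_genes):
        for _attempt in range(max_tries_per_gene):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            L = len(genome[chrom])
            glen = int(rng.integers(length_range[0], length_range[1] + 1))
            if glen >= L:
                continue
            start = int(rng.integers(0, L - glen))
            end = start + glen
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            occupied[chrom].append((start, end))
            rows.append((chrom, start, end, f"gene{i + 1}", strand, tss))
            break
        else:
            raise CapacityError(f"could not place gene {i + 1}")
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


# ---------------------------------------------------------------------------
# dose-dependent peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPeakModel:
    """Mass-action occupancy model for peak emission.

    A site with dissociation scale ``kd`` has occupancy
    ``theta = c / (c + kd)`` at protein dose ``c``; the site emits a peak iff
    ``theta * exp(N(0, sigma_h^2)) > theta_det``; the emitted height is
    ``h0 * theta * exp(N(0, sigma_h^2))`` (same noise draw).
    """

    concentrations: Mapping[str, float]
    theta_det: float = 0.2
    h0: float = 10.0
    sigma_h: float = 0.0
    jitter: int = 20
    width_mean: float = 500.0
    width_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta_det < 1:
            raise InvalidArgumentError("theta_det must lie in (0, 1)")
        if self.h0 <= 0 or self.sigma_h < 0:
            raise InvalidArgumentError("h0 must be > 0 and sigma_h >= 0")
        if any(c <= 0 for c in self.concentrations.values()):
            raise InvalidArgumentError("concentrations must be > 0")


def occupancy(c: float, kd) -> np.ndarray:
    """Fractional occupancy c / (c + kd); vectorized over kd."""
    kd = np.asarray(kd, dtype=float)
    return c / (c + kd)


def gen_peaks(
    truth: pd.DataFrame, model: SyntheticPeakModel, condition: str
) -> pd.DataFrame:
    """Emit peaks from planted sites under the occupancy model for one dose."""
    if condition not in model.concentrations:
        raise InvalidArgumentError(f"no concentration configured for {condition!r}")
    if truth.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    rng = np.random.default_rng([model.seed, *condition.encode("ascii")])
    c = model.concentrations[condition]
    theta = occupancy(c, truth["kd"].to_numpy())
    noise = np.exp(rng.normal(0.0, model.sigma_h, size=len(truth)))
    signal = theta * noise
    jit = rng.integers(-model.jitter, model.jitter + 1, size=len(truth))
    widths = np.maximum(
        np.rint(rng.normal(model.width_mean, model.width_sd, size=len(truth))), 2 * model.jitter + 10
    ).astype(int)

    rows = []
    k = 0
    for i, (sig, row) in enumerate(zip(signal, truth.itertuples(index=False))):
        if sig <= model.theta_det:
            continue
        mid = row.start + 3
        apex = mid + int(jit[i])
        w = int(widths[i])
        start = max(0, mid - w // 2)
        end = start + w
        apex = min(max(apex, start), end - 1)
        height = model.h0 * sig
        # emitted peaks already pass the caller's significance filter;
        # surrogate p-value is monotone decreasing in height
        pvalue = 10.0 ** (-8.0 - height)
        k += 1
        rows.append(
            (row.chrom, start, end, apex, height, pvalue, condition, f"{condition}_peak{k}")
        )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


# ---------------------------------------------------------------------------
# PBM intensities
# ---------------------------------------------------------------------------

# Disfavored flanking context of the top palindrome: CACGTG followed by A
# (equivalently, preceded by T on the other strand).  Keys are 7-mers matched
# against the 12-mer on either strand; values multiply that window's affinity.
DEFAULT_FLANK_PENALTY: dict[str, float] = {"CACGTGA": 0.3}


def probe_specific_affinity(
    var12: str,
    affinity: AffinityTable,
    flank_penalty: Mapping[str, float] | None = None,
) -> float:
    """Best hexamer affinity over all windows of a 12-mer (both strands).

    ``flank_penalty`` maps disfavored extended contexts (7-mers: hexamer plus
    one adjacent base, either strand) to multipliers applied to the matching
    window before the maximum is taken.
    """
    v = var12.upper()
    penalties = {} if flank_penalty is None else flank_penalty
    best = 0.0
    for i in range(len(v) - 5):
        a = affinity.affinity(v[i:i + 6])
        for context, mult in penalties.items():
            c = context.upper()
            rc = _seq.revcomp(c)
            right = v[i:i + 7]
            left = v[max(i - 1, 0):i + 6] if i >= 1 else ""
            if right in (c, rc) or left in (c, rc):
                a *= mult
        best = max(best, a)
    return best


def gen_pbm_intensities(
    library: pd.DataFrame,
    affinity: AffinityTable,
    flank_penalty: Mapping[str, float] | None = None,
    noise_cv: float = 0.2,
    seed: int = 0,
    background: float = 100.0,
    scale: float = 1000.0,
    dimers: Sequence[str] = DIMERS,
) -> pd.DataFrame:
    """Triplicate spot intensities for every probe and dimer channel.

    ``intensity = background + scale * a*(probe) * exp(N(0, log(1+noise_cv)^2))``
    where ``a*`` is the best hexamer-window affinity of the probe's 12-mer
    after applying the disfavored-context multipliers of ``flank_penalty``
    (default: the CACGTGa / tCACGTG context at 0.3).
    """
    if noise_cv < 0:
        raise InvalidArgumentError("noise_cv must be >= 0")
    unknown = set(library["category"]) - set(PROBE_CATEGORIES)
    if unknown:
        raise SchemaError(f"unknown probe categories: {sorted(unknown)}")
    if flank_penalty is None:
        flank_penalty = DEFAULT_FLANK_PENALTY

    astar = np.array(
        [probe_specific_affinity(v, affinity, flank_penalty) for v in library["var12"]]
    )

    rng = np.random.default_rng(seed)
    sigma = np.log1p(noise_cv)
    frames = []
    for dimer in dimers:
        for rep in (1, 2, 3):
            noise = np.exp(rng.normal(0.0, sigma, size=len(library)))
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": library["id"].to_numpy(),
                        "category": library["category"].to_numpy(),
                        "var12": library["var12"].to_numpy(),
                        "dimer": dimer,
                        "rep": rep,
                        "intensity": background + scale * astar * noise,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["dimer", "probe_id", "rep"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# EMSA competition curves
# ---------------------------------------------------------------------------

def gen_competition_curves(
    assay,
    true_kl: float,
    true_kc: float,
    noise_sd: float = 0.0,
    n_rep: int = 3,
    seed: int = 0,
    competitor: str = "competitor",
) -> pd.DataFrame:
    """Replicate competition readouts from the equilibrium forward model.

    Returns long-format rows (competitor, amount_pmol, rep, bound_pct); noise
    is additive Gaussian on the percent scale, truncated to [0, 100].
    """
    from . import emsa_model  # local import to avoid a cycle at import time

    amounts = list(assay.c_tot)
    if not amounts:
        raise InvalidArgumentError("assay must define competitor amounts")
    if any(a < 0 for a in amounts):
        raise InvalidArgumentError("competitor amounts must be non-negative")
    if 0 not in amounts and 0.0 not in amounts:
        raise InvalidArgumentError("assay must include a zero-competitor point")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")

    a = assay.with_constants(k_l=true_kl, k_c=true_kc)
    clean = np.array([emsa_model.predict_fraction_bound(a, c) for c in amounts])
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        noisy = clean + rng.normal(0.0, noise_sd, size=len(amounts)) if noise_sd else clean
        noisy = np.clip(noisy, 0.0, 100.0)
        for amt, b in zip(amounts, noisy):
            rows.append((competitor, float(amt), rep, float(b)))
    return pd.DataFrame(rows, columns=["competitor", "amount_pmol", "rep", "bound_pct"])
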
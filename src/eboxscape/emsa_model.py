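"""Equilibrium competition modelling of gel-shift assays.

A labeled probe L and an unlabeled competitor C compete for a protein P under
full mass balance (no trace-probe approximation, since probe and protein are
both at pmol scale in a 10 ul reaction):

    [PL] = [P][L] / K_L,   [PC] = [P][C] / K_C
    P_tot = [P] (1 + [L]/K_L + [C]/K_C)
    L_tot = [L] (1 + [P]/K_L),   C_tot = [C] (1 + [P]/K_C)

The readout is the bound labeled fraction relative to the no-competitor lane,
``100 * [PL](C_tot) / [PL](0)``.  Fitting estimates K_C per competitor by
least squares against this forward model and reports affinities normalized to
a reference competitor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NumericalError,
)

DEFAULT_AMOUNTS = (0.0, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)


@dataclass(frozen=True)
class CompetitionAssay:
    """Design constants of one competition experiment.

    Amounts are pmol in a ``volume_ul`` reaction; concentrations used by the
    model are pmol/ul (i.e. uM).  ``k_l``/``k_c`` are dissociation constants in
    the same concentration units; ``k_c = inf`` encodes a non-binding
    competitor.
    """

    volume_ul: float = 10.0
    l_tot: float = 0.5
    p_tot: float = 1.0
    k_l: float | None = None
    k_c: float | None = None
    c_tot: Sequence[float] = DEFAULT_AMOUNTS

    def __post_init__(self) -> None:
        if self.volume_ul <= 0 or self.l_tot <= 0 or self.p_tot <= 0:
            raise InvalidArgumentError("volume, probe and protein amounts must be > 0")
        if self.k_l is not None and self.k_l <= 0:
            raise InvalidArgumentError("k_l must be > 0")
        if self.k_c is not None and self.k_c <= 0:
            raise InvalidArgumentError("k_c must be > 0")

    def with_constants(self, k_l: float | None = None, k_c: float | None = None):
        return replace(
            self,
            k_l=self.k_l if k_l is None else k_l,
            k_c=self.k_c if k_c is None else k_c,
        )


def _free_protein(p0: float, l0: float, kl: float, c0: float, kc: float) -> float:
    """Solve the scalar mass balance for free [P] by bracketed root finding."""

    def g(p: float) -> float:
        bound_c = p * c0 / (kc + p) if math.isfinite(kc) else 0.0
        return p + p * l0 / (kl + p) + bound_c - p0

    if g(p0) < 0:  # numerically degenerate; g(p0) >= 0 analytically
        return p0
    try:
        return optimize.brentq(g, 0.0, p0, xtol=1e-18, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise NumericalError(f"free-protein solve failed: {exc}") from exc


def _bound_labeled(assay: CompetitionAssay, c_tot: float) -> float:
    v = assay.volume_ul
    p0, l0, c0 = assay.p_tot / v, assay.l_tot / v, c_tot / v
    kl, kc = assay.k_l, assay.k_c if assay.k_c is not None else math.inf
    p = _free_protein(p0, l0, kl, c0, kc)
    return l0 * p / (kl + p)


def predict_fraction_bound(assay: CompetitionAssay, c_tot: float) -> float:
    """Bound labeled probe (%) relative to the no-competitor reaction."""
    if assay.k_l is None:
        raise InvalidArgumentError("assay.k_l must be set to predict")
    if c_tot < 0:
        raise InvalidArgumentError("competitor amount must be >= 0")
    ref = _bound_labeled(assay, 0.0)
    if ref <= 0:  # pragma: no cover - requires degenerate constants
        raise NumericalError("no labeled complex forms at C=0")
    return 100.0 * _bound_labeled(assay, c_tot) / ref


@dataclass(frozen=True)
class AffinityFit:
    """Fitted dissociation constant and derived relative affinity."""

    competitor: str
    k_c: float
    stderr: float
    rel_affinity: float  # K_C(reference) / K_C(this); reference == 1
    nonbinding: bool = False
    n_points: int = 0
    sse: float = float("nan")


def _fit_single_kc(
    assay: CompetitionAssay,
    amounts: np.ndarray,
    bound: np.ndarray,
    log10_bounds: tuple[float, float],
) -> tuple[float, float, float]:
    """Least-squares K_C for one curve; returns (k_c, stderr, sse)."""

    def resid(log10_kc: np.ndarray) -> np.ndarray:
        a = assay.with_constants(k_c=10.0 ** float(log10_kc[0]))
        pred = np.array([predict_fraction_bound(a, c) for c in amounts])
        return pred - bound

    grid = np.linspace(log10_bounds[0], log10_bounds[1], 49)
    sses = [float(np.sum(resid(np.array([g])) ** 2)) for g in grid]
    x0 = grid[int(np.argmin(sses))]
    sol = optimize.least_squares(
        resid, x0=[x0], bounds=([log10_bounds[0]], [log10_bounds[1]]), xtol=1e-14, ftol=1e-14
    )
    kc = 10.0 ** float(sol.x[0])
    sse = float(np.sum(sol.fun ** 2))
    dof = max(len(amounts) - 1, 1)
    jtj = float(np.asarray(sol.jac.T @ sol.jac).reshape(()))
    if jtj > 0:
        var_log10 = sse / dof / jtj
        stderr = kc * math.log(10) * math.sqrt(var_log10)  # delta method
    else:
        stderr = float("inf")
    return kc, stderr, sse


def fit_relative_affinity(
    curves: pd.DataFrame,
    assay: CompetitionAssay,
    reference: str,
    k_l: float | None = None,
    self_label: str | None = None,
    nonbinding_factor: float = 1e3,
    min_competition_pct: float = 10.0,
    log10_span: float = 6.0,
) -> dict[str, AffinityFit]:
    """Fit K_C per competitor and normalize affinities to ``reference`` = 1.

    ``curves`` is long format (competitor, amount_pmol, rep, bound_pct).  K_L
    is either supplied or anchored by fitting the self-competition curve
    (``self_label``, the labeled probe's own sequence) for which K_C == K_L.
    A competitor is reported non-binding when its fitted K_C exceeds
    ``nonbinding_factor`` times the reference K_C, when the fit does not
    improve on the flat 100% model, or when the fitted curve never predicts
    more than ``min_competition_pct`` points of competition over the measured
    amounts (no detectable competition signal).
    """
    required = {"competitor", "amount_pmol", "bound_pct"}
    if not required.issubset(curves.columns):
        raise InvalidArgumentError(f"curves must have columns {sorted(required)}")

    if k_l is None:
        if self_label is None or self_label not in set(curves["competitor"]):
            raise InvalidArgumentError(
                "supply k_l or a self-competition curve label to anchor K_L"
            )
        sub = curves[curves["competitor"] == self_label]
        amounts = sub["amount_pmol"].to_numpy(float)
        bound = sub["bound_pct"].to_numpy(float)
        if len(np.unique(amounts)) < 3:
            raise InsufficientDataError("self-competition curve needs >= 3 amounts")

        def resid_self(log10_k: np.ndarray) -> np.ndarray:
            k = 10.0 ** float(log10_k[0])
            a = assay.with_constants(k_l=k, k_c=k)
            pred = np.array([predict_fraction_bound(a, c) for c in amounts])
            return pred - bound

        scale = math.log10(assay.l_tot / assay.volume_ul)
        grid = np.linspace(scale - log10_span, scale + log10_span, 49)
        sses = [float(np.sum(resid_self(np.array([g])) ** 2)) for g in grid]
        sol = optimize.least_squares(
            resid_self,
            x0=[grid[int(np.argmin(sses))]],
            bounds=([grid[0]], [grid[-1]]),
            xtol=1e-14,
            ftol=1e-14,
        )
        k_l = 10.0 ** float(sol.x[0])

    anchored = assay.with_constants(k_l=k_l)
    center = math.log10(k_l)
    bounds = (center - log10_span, center + log10_span)

    raw: dict[str, tuple[float, float, float, int, float, float]] = {}
    for label, sub in curves.groupby("competitor", sort=True):
        amounts = sub["amount_pmol"].to_numpy(float)
        bound = sub["bound_pct"].to_numpy(float)
        if len(np.unique(amounts)) < 3:
            raise InsufficientDataError(f"{label}: need >= 3 competitor amounts")
        kc, stderr, sse = _fit_single_kc(anchored, amounts, bound, bounds)
        sse_flat = float(np.sum((bound - 100.0) ** 2))
        fit_assay = anchored.with_constants(k_c=kc)
        depth = 100.0 - min(
            predict_fraction_bound(fit_assay, c) for c in np.unique(amounts)
        )
        raw[label] = (kc, stderr, sse, len(amounts), sse_flat, depth)

    if reference not in raw:
        raise InvalidArgumentError(f"reference {reference!r} has no fitted curve")
    k_ref = raw[reference][0]

    fits: dict[str, AffinityFit] = {}
    for label, (kc, stderr, sse, n, sse_flat, depth) in raw.items():
        nonbinding = (
            kc > nonbinding_factor * k_ref
            or sse >= sse_flat * (1 - 1e-9)
            or depth < min_competition_pct
        )
        if nonbinding and label != reference:
            warnings.warn(f"{label}: no detectable competition; reported non-binding")
        fits[label] = AffinityFit(
            competitor=label,
            k_c=kc,
            stderr=stderr,
            rel_affinity=float("nan") if nonbinding else k_ref / kc,
            nonbinding=nonbinding,
            n_points=n,
            sse=sse,
        )
    return fits


DEFAULT_CLASS_CUTOFFS = {"high": 10.0, "medium": 2.0, "low": 0.5}


def classify_affinity(rel_affinity: float, cutoffs: Mapping[str, float] | None = None) -> str:
    """Affinity class label from a reference-normalized affinity."""
    if cutoffs is None:
        cutoffs = DEFAULT_CLASS_CUTOFFS
    if not np.isfinite(rel_affinity):
        return "-"
    if rel_affinity > cutoffs["high"]:
        return "High"
    if rel_affinity >= cutoffs["medium"]:
        return "Medium"
    if rel_affinity >= cutoffs["low"]:
        return "Low"
    return "-"


def summarize_affinity_table(
    fits_by_dimer: Mapping[str, Mapping[str, AffinityFit]],
    pbm_relative: Mapping[str, Mapping[str, float]] | None = None,
    motifs: Sequence[str] | None = None,
    cutoffs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Summary table of relative affinities per motif and dimer.

    Motifs without a fitted curve get ``n.a.``; non-binding competitors get
    ``-``.  When PBM-derived relative scores are supplied they appear in a
    bracketed companion column.
    """
    if motifs is None:
        seen: list[str] = []
        for fits in fits_by_dimer.values():
            for m in fits:
                if m not in seen:
                    seen.append(m)
        motifs = seen
    rows = []
    for motif in motifs:
        row: dict[str, object] = {"motif": motif}
        for dimer, fits in fits_by_dimer.items():
            fit = fits.get(motif)
            if fit is None:
                row[f"affinity_{dimer}"] = "n.a."
                row[f"class_{dimer}"] = "n.a."
            elif fit.nonbinding:
                row[f"affinity_{dimer}"] = "-"
                row[f"class_{dimer}"] = "-"
            else:
                row[f"affinity_{dimer}"] = round(fit.rel_affinity, 3)
                row[f"class_{dimer}"] = classify_affinity(fit.rel_affinity, cutoffs)
            if pbm_relative is not None:
                val = pbm_relative.get(dimer, {}).get(motif)
                row[f"pbm_{dimer}"] = "n.a." if val is None else round(val, 3)
        rows.append(row)
    return pd.DataFrame(rows)
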
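"""Editing-outcome statistics.

Implements the ratio statistics used to evaluate guide performance —
off-target specificity index, FACS cleavage efficiency, expression
fold change (with a 2^-ΔΔCt helper for qPCR Ct inputs) — and a
log-linear decay fit for guide RNA half-life from a transcription-
shutoff (actinomycin D) time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QuantifyError

# -- specificity --------------------------------------------------------


def specificity_index(table: pd.DataFrame, condition: str | None = None,
                      per_site: bool = False):
    """On-target read fraction: Σ on / (Σ on + Σ off).

    ``table`` needs columns ``site``, ``kind`` (``on_target`` /
    ``off_target``) and ``reads`` (plus ``condition`` when several guide
    conditions share the table).  ``per_site`` returns a per-site Series
    instead of the aggregate.
    """
    t = _subset(table, condition)
    _check_reads(t)
    if per_site:
        out = {}
        for site, grp in t.groupby("site", sort=True):
            out[site] = _si(grp)
        return pd.Series(out)
    return _si(t)


def _subset(table: pd.DataFrame, condition):
    for col in ("site", "kind", "reads"):
        if col not in table.columns:
            raise QuantifyError(f"read table is missing column {col!r}")
    if condition is not None:
        if "condition" not in table.columns:
            raise QuantifyError("read table has no 'condition' column")
        t = table[table["condition"] == condition]
        if t.empty:
            raise QuantifyError(f"no rows for condition {condition!r}")
        return t
    return table


def _check_reads(t: pd.DataFrame) -> None:
    if (t["reads"] < 0).any():
        raise QuantifyError("read counts must be non-negative")
    bad = set(t["kind"]) - {"on_target", "off_target"}
    if bad:
        raise QuantifyError(f"unknown site kind(s): {sorted(bad)}")


def _si(t: pd.DataFrame) -> float:
    on = float(t.loc[t["kind"] == "on_target", "reads"].sum())
    off = float(t.loc[t["kind"] == "off_target", "reads"].sum())
    if on + off == 0:
        raise QuantifyError("zero total reads")
    return on / (on + off)


# -- FACS cleavage ------------------------------------------------------


def cleavage_efficiency(mneon_neg_mcherry_pos: float, mcherry_pos: float,
                        total: float | None = None) -> float:
    """FACS cleavage efficiency: mNeonGreen− mCherry+ / mCherry+ cells."""
    if mcherry_pos <= 0:
        raise QuantifyError("no transfected (mCherry+) events")
    if not (0 <= mneon_neg_mcherry_pos <= mcherry_pos):
        raise QuantifyError(
            "mNeonGreen−∩mCherry+ events must lie within [0, mCherry+]"
        )
    if total is not None and mcherry_pos > total:
        raise QuantifyError("mCherry+ events exceed total events")
    return mneon_neg_mcherry_pos / mcherry_pos


def cleavage_efficiency_table(table: pd.DataFrame) -> pd.Series:
    """Per-sample efficiency from a FACS count table.

    Columns: ``sample``, ``total``, ``mcherry_pos``,
    ``mneon_neg_mcherry_pos``.
    """
    for col in ("sample", "total", "mcherry_pos", "mneon_neg_mcherry_pos"):
        if col not in table.columns:
            raise QuantifyError(f"FACS table is missing column {col!r}")
    out = {}
    for _, row in table.iterrows():
        out[row["sample"]] = cleavage_efficiency(
            row["mneon_neg_mcherry_pos"], row["mcherry_pos"], row["total"]
        )
    return pd.Series(out)


# -- fold change --------------------------------------------------------


def fold_change(test, control) -> float:
    """Ratio of mean expression in test vs control samples."""
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    if test.size == 0 or control.size == 0:
        raise QuantifyError("empty expression vector")
    c = control.mean()
    if c <= 0:
        raise QuantifyError("control mean must be positive")
    return float(test.mean() / c)


def ddct_fold_change(ct_target_test, ct_ref_test,
                     ct_target_control, ct_ref_control) -> float:
    """2^-ΔΔCt fold change from qPCR cycle thresholds.

    ΔCt = Ct(target) − Ct(reference) per condition; ΔΔCt is test minus
    control; the fold change is 2^-ΔΔCt.
    """
    d_test = np.mean(ct_target_test) - np.mean(ct_ref_test)
    d_ctrl = np.mean(ct_target_control) - np.mean(ct_ref_control)
    return float(2.0 ** -(d_test - d_ctrl))


# -- decay half-life ----------------------------------------------------


@dataclass(frozen=True)
class DecayFit:
    """Result of a log-linear RNA decay fit."""

    k: float              # first-order decay rate, 1/h
    t_half: float         # ln(2)/k, hours; inf for stable species
    stable: bool          # k <= 0 within the fit
    r_squared: float
    n_points: int


def decay_half_life(timepoints, abundance, normalize_to_first: bool = False) -> DecayFit:
    """Half-life from a transcription-shutoff time course.

    Ordinary least squares on ln(abundance) vs time; ``k = -slope`` and
    ``t_half = ln 2 / k``.  A non-positive estimated rate yields
    ``t_half = inf`` with the ``stable`` flag set.  ``normalize_to_first``
    divides the series by its first value (time-zero normalisation);
    this shifts the intercept only and leaves the rate untouched.
    """
    t = np.asarray(timepoints, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if t.size != a.size:
        raise QuantifyError("timepoints and abundance differ in length")
    if t.size < 3:
        raise QuantifyError("need at least 3 timepoints for a decay fit")
    if np.any(np.diff(t) <= 0):
        raise QuantifyError("timepoints must be strictly increasing")
    if np.any(a <= 0):
        raise QuantifyError("abundances must be positive for a log fit")
    if normalize_to_first:
        a = a / a[0]
    res = stats.linregress(t, np.log(a))
    k = -res.slope
    if k <= 0:
        return DecayFit(k=float(k), t_half=math.inf, stable=True,
                        r_squared=float(res.rvalue**2), n_points=int(t.size))
    return DecayFit(k=float(k), t_half=float(math.log(2) / k), stable=False,
                    r_squared=float(res.rvalue**2), n_points=int(t.size))
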
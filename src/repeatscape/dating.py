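"""Insertion dating of LTR retroelements from 5'/3' LTR divergence.

The two LTRs of an element are identical at insertion and diverge by
neutral substitution afterwards, so their distance clocks the
insertion.  The 5' and 3' LTRs are globally aligned, transitions (P)
and transversions (Q) are counted over gap-free columns, the Kimura
two-parameter distance

    k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

is computed, and the insertion age follows as T = k / (2 r) with
r = 1.3e-8 substitutions per site per year by default.  Pairs outside
the logarithms' domain are flagged saturated and excluded from
summaries rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import nt_aligner

DEFAULT_RATE = 1.3e-8  # substitutions / site / year

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturatedDivergenceError(ValueError):
    """LTR pair too diverged for the K2P distance to be defined."""


@dataclass
class DivergenceEstimate:
    P: float  # transition proportion
    Q: float  # transversion proportion
    k: float | None  # None when saturated
    aligned_sites: int
    saturated: bool = False


@dataclass
class InsertionAge:
    k: float
    r: float
    T: float  # years


def align_ltrs(ltr5: str, ltr3: str):
    """Optimal global alignment of the two LTRs (+1/-1, gap -4/-1)."""
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    return nt_aligner("global").align(ltr5, ltr3)[0]


def count_substitutions(alignment) -> tuple[float, float, int]:
    """(P, Q, aligned_sites) from an LTR alignment.

    Gap columns and columns containing ambiguous bases are excluded.
    Transitions are A<->G and C<->T; every other mismatch is a
    transversion.
    """
    a, b = str(alignment[0]).upper(), str(alignment[1]).upper()
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no aligned (gap-free) sites")
    return ts / sites, tv / sites, sites


def kimura2p(P: float, Q: float) -> float:
    """Kimura two-parameter distance; raises on domain violation."""
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be >= 0")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergenceError(f"saturated: P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def insertion_time(k: float, r: float = DEFAULT_RATE) -> float:
    """T = k / (2 r), in years."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k / (2.0 * r)


def date_ltr_pair(ltr5: str, ltr3: str, r: float = DEFAULT_RATE) -> tuple[DivergenceEstimate, InsertionAge | None]:
    """Estimate divergence and insertion age for one LTR pair."""
    alignment = align_ltrs(ltr5, ltr3)
    P, Q, sites = count_substitutions(alignment)
    try:
        k = kimura2p(P, Q)
    except SaturatedDivergenceError:
        return DivergenceEstimate(P, Q, None, sites, saturated=True), None
    return (DivergenceEstimate(P, Q, k, sites),
            InsertionAge(k=k, r=r, T=insertion_time(k, r)))


def date_elements(contigs: dict[str, str], elements, r: float = DEFAULT_RATE,
                  labels=None) -> pd.DataFrame:
    """Per-element dating table for annotated/classified candidates.

    ``elements`` is a list of AnnotatedElement; ``labels`` an optional
    parallel list of LineageLabel.  Saturated pairs get NaN k and T.
    """
    rows = []
    for idx, element in enumerate(elements):
        cand = element.candidate
        contig = contigs[cand.contig]
        ltr5 = contig[cand.ltr5[0] : cand.ltr5[1]]
        ltr3 = contig[cand.ltr3[0] : cand.ltr3[1]]
        est, age = date_ltr_pair(ltr5, ltr3, r)
        label = labels[idx] if labels is not None else None
        rows.append({
            "element_id": f"{cand.contig}:{cand.start}-{cand.end}",
            "contig": cand.contig, "start": cand.start, "end": cand.end,
            "P": est.P, "Q": est.Q,
            "k": est.k if est.k is not None else np.nan,
            "aligned_sites": est.aligned_sites,
            "saturated": est.saturated,
            "T": age.T if age is not None else np.nan,
            "superfamily": label.superfamily if label else "unknown",
            "lineage": label.lineage if label else "unknown",
        })
    return pd.DataFrame(rows)


def age_summary(ages: pd.DataFrame, bins=None, group: str | None = "superfamily") -> pd.DataFrame:
    """Grouped summary of insertion ages (years).

    Saturated (NaN) elements are excluded.  Reports mean, standard
    error, median, quartiles, and the fraction in each age bin.
    """
    if ages.empty:
        raise ValueError("no dated elements")
    data = ages.dropna(subset=["T"])
    if bins is None:
        bins = [0, 5e5, 1e6, 2e6, 5e6, np.inf]
    groups = data.groupby(group) if group else [("all", data)]
    rows = []
    for name, sub in groups:
        t = sub["T"].to_numpy()
        row = {
            "group": name, "n": len(t), "mean": t.mean(),
            "se": t.std(ddof=1) / math.sqrt(len(t)) if len(t) > 1 else 0.0,
            "median": float(np.median(t)),
            "q25": float(np.percentile(t, 25)), "q75": float(np.percentile(t, 75)),
        }
        for lo, hi in zip(bins[:-1], bins[1:]):
            frac = float(np.mean((t >= lo) & (t < hi)))
            row[f"frac_{lo:g}_{hi:g}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
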
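"""Compositional enrichment/depletion profiling of a query vs a background.

For each residue *aa* the statistic is the fractional difference

    (X_aa - Y_aa) / Y_aa

where X_aa and Y_aa are the pooled residue fractions of the query and
background samples (all residues of all sequences counted together).  A
positive value means relative enrichment of the residue in the query, a
negative value depletion; +1.0 means the residue is twice as frequent in
the query as in the background.

Significance comes from a seeded two-sided bootstrap: sequences are
resampled with replacement within each sample, the statistic recomputed,
and the null spread taken from the bootstrap distribution recentred at
zero.  Residues with p <= alpha are called enriched or depleted by the
sign of the observed statistic.  Grouped summaries aggregate the calls
over the conventional biochemistry classes (charged, polar, hydrophobic,
aromatic); group membership overlaps (H, F, W, Y belong to two groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, N_RESIDUES, residue_indices
from .errors import HspClassError
from .sequence_io import ProteinRecord

#: conventional residue classes (overlapping membership is deliberate)
RESIDUE_GROUPS: dict[str, tuple[str, ...]] = {
    "positively_charged": ("K", "R", "H"),
    "negatively_charged": ("D", "E"),
    "polar_uncharged": ("S", "T", "N", "Q", "C", "Y"),
    "hydrophobic": ("A", "V", "L", "I", "M", "F", "W", "G", "P"),
    "aromatic": ("F", "W", "Y", "H"),
}

CALLS = ("enriched", "depleted", "not-significant")


def _count_matrix(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Per-sequence residue count matrix, shape (n_records, 20)."""
    counts = np.zeros((len(records), N_RESIDUES), dtype=float)
    for i, rec in enumerate(records):
        counts[i] = np.bincount(residue_indices(rec.residues), minlength=N_RESIDUES)
    return counts


def pooled_fraction(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Residue fractions of the pooled sample (all sequences concatenated)."""
    if len(records) == 0:
        raise HspClassError("cannot compute fractions of an empty collection")
    totals = _count_matrix(records).sum(axis=0)
    n = totals.sum()
    if n < 1:
        raise HspClassError("collection contains no residues")
    return totals / n


def fractional_difference(query_fraction: float, background_fraction: float) -> float:
    """(X - Y) / Y; NaN with a warning when the background fraction is zero."""
    if background_fraction == 0:
        warnings.warn("residue absent from background: fractional difference undefined")
        return float("nan")
    return (query_fraction - background_fraction) / background_fraction


@dataclass
class EnrichmentResult:
    """Per-residue enrichment statistics and significance calls."""

    query_fraction: np.ndarray  # X_aa, shape (20,)
    background_fraction: np.ndarray  # Y_aa, shape (20,)
    difference: np.ndarray  # (X - Y) / Y, NaN where Y_aa == 0
    p_value: np.ndarray  # two-sided bootstrap p, shape (20,)
    call: list[str]  # per-residue: enriched / depleted / not-significant
    alpha: float
    iterations: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": list(AMINO_ACIDS),
                "query_fraction": self.query_fraction,
                "background_fraction": self.background_fraction,
                "fractional_difference": self.difference,
                "p_value": self.p_value,
                "call": self.call,
            }
        )

    def to_tsv(self, sink: str | Path | IO[str]) -> None:
        self.to_dataframe().to_csv(sink, sep="\t", index=False)


def _bootstrap_fractions(
    counts: np.ndarray, iterations: int, rng: np.random.Generator, chunk: int = 1000
) -> np.ndarray:
    """Pooled residue fractions of ``iterations`` with-replacement resamples.

    Resampling n sequences with replacement is equivalent to weighting
    sequences by a Multinomial(n, 1/n) draw, which turns the bootstrap into
    a matrix product.
    """
    n = counts.shape[0]
    p = np.full(n, 1.0 / n)
    out = np.empty((iterations, N_RESIDUES))
    for start in range(0, iterations, chunk):
        b = min(chunk, iterations - start)
        weights = rng.multinomial(n, p, size=b).astype(float)
        pooled = weights @ counts
        out[start : start + b] = pooled / pooled.sum(axis=1, keepdims=True)
    return out


def enrichment_test(
    query: Sequence[ProteinRecord],
    background: Sequence[ProteinRecord],
    iterations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> EnrichmentResult:
    """Per-residue fractional difference with bootstrap significance.

    Both samples are resampled with replacement ``iterations`` times; the
    bootstrap differences, recentred on their mean, form the null spread,
    and the two-sided p-value is the (add-one smoothed) fraction of null
    draws at least as extreme as the observed statistic.  Deterministic
    given the seed.
    """
    if len(query) == 0 or len(background) == 0:
        raise HspClassError("both query and background must be non-empty")
    if iterations < 100:
        raise HspClassError(f"need at least 100 bootstrap iterations, got {iterations}")
    if not 0 < alpha < 1:
        raise HspClassError("alpha must be in (0, 1)")

    q_counts = _count_matrix(query)
    b_counts = _count_matrix(background)
    x = q_counts.sum(axis=0)
    y = b_counts.sum(axis=0)
    x_frac = x / x.sum()
    y_frac = y / y.sum()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        observed = np.where(y_frac > 0, (x_frac - y_frac) / y_frac, np.nan)
    absent = y_frac == 0
    if absent.any():
        warnings.warn(
            "residues absent from background have undefined fractional "
            f"difference: {', '.join(np.array(list(AMINO_ACIDS))[absent])}"
        )

    rng = np.random.default_rng(seed)
    qf = _bootstrap_fractions(q_counts, iterations, rng)
    bf = _bootstrap_fractions(b_counts, iterations, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot = np.where(y_frac > 0, (qf - bf) / y_frac, np.nan)
        null = boot - np.nanmean(boot, axis=0)
        exceed = np.abs(null) >= np.abs(observed)
        p = (np.sum(exceed, axis=0) + 1.0) / (iterations + 1.0)
    p = np.where(absent | np.isnan(observed), np.nan, p)

    calls: list[str] = []
    for i in range(N_RESIDUES):
        if np.isnan(observed[i]) or np.isnan(p[i]) or p[i] > alpha or observed[i] == 0:
            calls.append("not-significant")
        elif observed[i] > 0:
            calls.append("enriched")
        else:
            calls.append("depleted")
    return EnrichmentResult(
        query_fraction=x_frac,
        background_fraction=y_frac,
        difference=observed,
        p_value=p,
        call=calls,
        alpha=alpha,
        iterations=iterations,
        seed=seed,
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing correction)."""
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    pv = p[valid]
    m = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    restored = np.empty(m)
    restored[order] = np.minimum(adjusted, 1.0)
    out[valid] = restored
    return out


def grouped_summary(
    result: EnrichmentResult,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Net direction per residue class.

    For each group the member calls are tallied; the direction is the
    majority among significant members ("no signal" when none are
    significant, "mixed" on a tie).
    """
    groups = groups or RESIDUE_GROUPS
    call_of = dict(zip(AMINO_ACIDS, result.call))
    rows = []
    for name, members in groups.items():
        calls = {aa: call_of[aa] for aa in members}
        n_enriched = sum(1 for c in calls.values() if c == "enriched")
        n_depleted = sum(1 for c in calls.values() if c == "depleted")
        if n_enriched == n_depleted == 0:
            direction = "no signal"
        elif n_enriched > n_depleted:
            direction = "enriched"
        elif n_depleted > n_enriched:
            direction = "depleted"
        else:
            direction = "mixed"
        rows.append(
            {
                "group": name,
                "members": "".join(members),
                "n_enriched": n_enriched,
                "n_depleted": n_depleted,
                "n_not_significant": len(members) - n_enriched - n_depleted,
                "direction": direction,
                "member_calls": ";".join(f"{aa}:{c}" for aa, c in calls.items()),
            }
        )
    return pd.DataFrame(rows)
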
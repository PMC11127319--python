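"""Evaluation harness: rank-FDR curves, sensitivity/FDR tables, BH adjustment.

Methods are compared on the ranking they induce, because Bayesian lfsr and
frequentist BH-adjusted p-values are not on a common scale: variants are
sorted ascending by each method's own ``raw`` column (lfsr or p) with ties
broken by |estimate| descending, and truth labels from simulation (or the
synonymous proxy on real data) score the ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CUTOFFS = (0.001, 0.01, 0.05, 0.10)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, clipped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ranked(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(
        ["raw", "estimate"],
        key=lambda s: -s.abs() if s.name == "estimate" else s,
        kind="stable",
    ).reset_index(drop=True)


def _neutral_mask(table: pd.DataFrame, truth: pd.DataFrame | None) -> np.ndarray:
    """True-neutral indicator aligned with ``table`` rows.

    With simulation truth, neutral means ``beta == 0`` (or variant_group in
    {neutral, control}).  Without truth, synonymous variants proxy for
    neutrals, as in real screens.
    """
    if truth is not None:
        merged = table.merge(truth, on="variant_id", how="left", validate="one_to_one")
        if "beta" in merged.columns:
            return (merged["beta"] == 0).to_numpy()
        if "variant_group" in merged.columns:
            return merged["variant_group"].isin(["neutral", "control"]).to_numpy()
        raise ValueError("truth table needs a 'beta' or 'variant_group' column")
    if not (table["mutation_type"] == "synonymous").any():
        raise ValueError("no truth labels and no synonymous variants to proxy them")
    return (table["mutation_type"] == "synonymous").to_numpy()


def rank_fdr_curve(table: pd.DataFrame, truth: pd.DataFrame | None = None) -> np.ndarray:
    """Fraction of true-neutral variants among the top-k ranked, for k = 1..V."""
    ranked = _ranked(table)
    neutral = _neutral_mask(ranked, truth)
    k = np.arange(1, len(ranked) + 1)
    return np.cumsum(neutral) / k


def sensitivity_at_cutoffs(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    cutoffs: tuple = DEFAULT_CUTOFFS,
    selection_sign: str | None = None,
) -> pd.DataFrame:
    """Sensitivity and observed FDR at each significance cutoff.

    A variant is called when ``raw < cutoff``; calls whose estimated sign
    opposes the direction of selection are excluded.  Observed FDR is NaN
    when nothing is called (no power at that cutoff).
    """
    neutral = _neutral_mask(table, truth)
    effect = ~neutral
    raw = table["raw"].to_numpy(dtype=float)
    est = table["estimate"].to_numpy(dtype=float)
    keep_sign = np.ones(len(table), dtype=bool)
    if selection_sign is not None:
        direction = 1.0 if selection_sign == "positive" else -1.0
        keep_sign = np.sign(est) == direction
    rows = []
    for cut in cutoffs:
        called = (raw < cut) & keep_sign
        n_called = int(called.sum())
        sens = float((called & effect).sum() / effect.sum()) if effect.any() else np.nan
        fdr = float((called & neutral).sum() / n_called) if n_called else np.nan
        rows.append({"cutoff": cut, "n_called": n_called, "sensitivity": sens,
                     "observed_fdr": fdr})
    return pd.DataFrame(rows)


def sensitivity_at_fdr(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    fdr_level: float,
    selection_sign: str | None = None,
) -> float:
    """Sensitivity at the largest rank cutoff whose observed FDR <= level.

    Enables power comparison between methods at a matched observed FDR even
    when their significance scales differ.
    """
    ranked = _ranked(table)
    if selection_sign is not None:
        direction = 1.0 if selection_sign == "positive" else -1.0
        ranked = ranked.loc[np.sign(ranked["estimate"].to_numpy()) == direction]
        ranked = ranked.reset_index(drop=True)
    if len(ranked) == 0:
        return 0.0
    neutral = _neutral_mask(ranked, truth)
    effect_total = int((~_neutral_mask(_ranked(table), truth)).sum())
    if effect_total == 0:
        return float("nan")
    fdr_k = np.cumsum(neutral) / np.arange(1, len(ranked) + 1)
    ok = np.nonzero(fdr_k <= fdr_level)[0]
    if ok.size == 0:
        return 0.0
    k = ok[-1] + 1
    return float((~neutral[:k]).sum() / effect_total)
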
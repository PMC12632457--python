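"""Fluctuation-assay arithmetic: plating counts -> rates, fold changes, ln fold.

The "rate" here is the per-cell frequency of resistant colony formation
observed in a parallel-culture plating experiment: both colony counts are
rescaled to the undiluted culture before taking the ratio,

    rate = (colonies_selective / dilution_selective)
         / (colonies_permissive / dilution_permissive).

This is deliberately the raw frequency, not a Luria-Delbrueck style mutation
rate estimate. Fold change divides each sample's rate by the mean rate of the
wild-type group; plots and downstream hypothesis tests use the natural log of
the fold change. This module only produces the tidy per-sample tables —
significance testing is left to standard external tools.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["rate_from_plating", "rates_table", "fold_change_ln"]


def rate_from_plating(
    colonies_selective: int,
    colonies_permissive: int,
    dilution_selective: float,
    dilution_permissive: float,
) -> tuple[float, bool]:
    """Per-cell event rate from one culture's plating counts.

    Returns ``(rate, censored)``; ``censored`` is True when no selective
    colonies were observed, in which case the rate is reported as 0 (censored
    at fewer than one event) rather than smoothed with a pseudo-count.
    """
    if colonies_permissive <= 0:
        raise ValueError("cannot estimate culture size: zero permissive colonies")
    if colonies_selective < 0:
        raise ValueError("colony counts must be non-negative")
    for d in (dilution_selective, dilution_permissive):
        if not (0 < d <= 1):
            raise ValueError("dilutions must lie in (0, 1]")
    rate = (colonies_selective / dilution_selective) / (
        colonies_permissive / dilution_permissive
    )
    return float(rate), colonies_selective == 0


def rates_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`rate_from_plating` to every row of a count table."""
    rates = []
    censored = []
    for _, row in counts.iterrows():
        r, c = rate_from_plating(
            int(row["colonies_selective"]),
            int(row["colonies_permissive"]),
            float(row["dilution_selective"]),
            float(row["dilution_permissive"]),
        )
        rates.append(r)
        censored.append(c)
    out = counts.copy()
    out["rate"] = rates
    out["censored"] = censored
    return out


def fold_change_ln(rates: pd.DataFrame, wt_label: str = "WT") -> pd.DataFrame:
    """Fold change vs the wild-type mean rate, and its natural log, per sample.

    fold_change_i = rate_i / mean(rate over the WT group); ln_fold = ln of
    that, applied to every sample including the WT samples themselves.
    Samples with rate 0 keep their fold change but get ln_fold = NaN (flagged
    with ``ln_defined = False``) since the log is undefined.
    """
    if "rate" not in rates.columns or "genotype" not in rates.columns:
        raise ValueError("rates table needs 'rate' and 'genotype' columns")
    wt = rates.loc[rates["genotype"] == wt_label, "rate"]
    if wt.empty:
        raise ValueError(f"no samples with wild-type genotype {wt_label!r}")
    wt_mean = float(wt.mean())
    if wt_mean <= 0:
        raise ValueError("wild-type mean rate is zero; fold change undefined")
    out = rates.copy()
    out["fold_change"] = out["rate"] / wt_mean
    defined = out["fold_change"] > 0
    if (~defined).any():
        logger.warning(
            "%d sample(s) with rate 0: ln fold change undefined, flagged",
            int((~defined).sum()),
        )
    out["ln_fold"] = np.where(defined, np.log(out["fold_change"].where(defined, 1.0)), np.nan)
    out["ln_defined"] = defined
    return out
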
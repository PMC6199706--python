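"""Phage lifestyle confidence calls and temperate-enrichment statistics.

Replicate classifier scores (probability "temperate" per replicate tree, as a
random-forest lifestyle classifier emits) are collapsed into a confident call
only when the mean minus the standard deviation clears 0.5; otherwise no
assignment is made.  Enrichment of a phenotype (e.g. DGR carriage) among
temperate vs lytic phages is tested with a Pearson goodness-of-fit
chi-square against the database's background composition.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .model import LifestyleScores


def confident_call(
    scores: LifestyleScores, threshold: float = 0.5, ddof: int = 1
) -> str:
    """Collapse replicate temperate-probabilities into a lifestyle call.

    With m, s the mean and standard deviation (sample, ddof=1 by default) of
    the replicate scores: temperate if m - s > threshold; lytic if
    (1 - m) - s > threshold; otherwise 'NA'.  The boundary is strict:
    m - s exactly at the threshold yields NA.
    """
    if scores.n_replicates < 2:
        raise ValueError(
            f"{scores.phage_id}: need >= 2 replicates for a confident call"
        )
    arr = np.asarray(scores.replicate_scores, dtype=float)
    m = float(arr.mean())
    s = float(arr.std(ddof=ddof))
    if m - s > threshold:
        return "temperate"
    if (1.0 - m) - s > threshold:
        return "lytic"
    return "NA"


def chi_square_enrichment(
    observed: Sequence[float], background: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of observed class counts against expectations
    proportional to background class counts.

    Returns (chi2, df, pvalue) with df = n_classes - 1 and the p-value from
    the chi-square upper tail.  Expected cells below 1 trigger a warning (the
    asymptotic approximation degrades).
    """
    obs = np.asarray(observed, dtype=float)
    bg = np.asarray(background, dtype=float)
    if obs.shape != bg.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and background must be equal-length vectors of >= 2 classes")
    if np.any(bg <= 0):
        raise ValueError("background counts must all be positive")
    total = obs.sum()
    if total == 0:
        raise ValueError("total observed count is zero")
    expected = total * bg / bg.sum()
    if np.any(expected < 1):
        warnings.warn(
            "expected cell count < 1: chi-square approximation unreliable",
            stacklevel=2,
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    pvalue = float(chi2_dist.sf(stat, df))
    return stat, df, pvalue
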
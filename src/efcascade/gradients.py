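"""Rostrocaudal expression-gradient calls.

A gene's regional profile is a vector of non-negative intensities over
ordered rostrocaudal bins (bin 0 = rostral pole) within a stated zone
context (e.g. VZ/SVZ).  The call is based on the Spearman rank correlation
of intensity against bin index, with a permutation p-value over bin
shuffles: a significant positive correlation is ``high_caudal``, a
significant negative one ``high_rostral``, anything else ``none``.  Both
|rho| >= rho_threshold and p < alpha are required.

When the number of bins is small enough that all orderings fit in the
permutation budget (n! <= n_perm) the p-value is computed by exhaustive
enumeration; otherwise by seeded Monte Carlo with the add-one estimator
(1 + #{|rho*| >= |rho|}) / (n_perm + 1).  Constant profiles get statistic 0
and direction ``none`` without error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-12


@dataclass(frozen=True)
class GradientCall:
    gene_id: str
    zone_context: str
    direction: str  # high_rostral | high_caudal | none
    statistic: float  # Spearman rho vs bin index
    p_value: float
    n_bins: int


def _spearman_rho(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    denom = math.sqrt(float((rx**2).sum()) * float((ry**2).sum()))
    if denom == 0:
        return 0.0
    return float((rx * ry).sum()) / denom


def classify_gradient(
    intensities: Sequence[float],
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    gene_id: str = "",
    zone_context: str = "",
) -> GradientCall:
    """Call the rostrocaudal gradient direction for one profile."""
    values = np.asarray(intensities, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("a gradient call needs at least 3 rostrocaudal bins")
    if np.any(values < 0):
        raise ValueError("intensities must be non-negative")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < rho_threshold <= 1:
        raise ValueError("rho_threshold must be in (0, 1]")

    bin_ranks = np.arange(n, dtype=float)

    def done(direction: str, rho: float, p: float) -> GradientCall:
        return GradientCall(
            gene_id=gene_id,
            zone_context=zone_context,
            direction=direction,
            statistic=rho,
            p_value=p,
            n_bins=n,
        )

    if np.all(values == values[0]):
        return done("none", 0.0, 1.0)

    ranks = stats.rankdata(values, method="average")
    rho = _spearman_rho(ranks, bin_ranks)

    if math.factorial(n) <= n_perm:
        hits = sum(
            abs(_spearman_rho(np.asarray(perm), bin_ranks)) >= abs(rho) - _EPS
            for perm in itertools.permutations(ranks)
        )
        p = hits / math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        perms = np.tile(ranks, (n_perm, 1))
        perms = rng.permuted(perms, axis=1)
        centered = perms - perms.mean(axis=1, keepdims=True)
        by = bin_ranks - bin_ranks.mean()
        denom = np.sqrt((centered**2).sum(axis=1) * float((by**2).sum()))
        rho_perm = np.where(denom > 0, centered @ by / np.where(denom > 0, denom, 1.0), 0.0)
        hits = int(np.sum(np.abs(rho_perm) >= abs(rho) - _EPS))
        p = (1 + hits) / (n_perm + 1)

    if p < alpha and abs(rho) >= rho_threshold - _EPS:
        direction = "high_caudal" if rho > 0 else "high_rostral"
    else:
        direction = "none"
    return done(direction, rho, p)


def classify_gradient_table(
    profiles: pd.DataFrame,
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Call gradients for a table of profiles.

    ``profiles`` has columns gene_id, zone_context, bin_0..bin_{k-1};
    one call per (gene, zone_context) row.
    """
    bin_cols = [c for c in profiles.columns if c.startswith("bin_")]
    bin_cols.sort(key=lambda c: int(c.split("_")[1]))
    if len(bin_cols) < 3:
        raise ValueError("profiles must have at least 3 bin_<i> columns")
    rows = []
    for r in profiles.itertuples(index=False):
        call = classify_gradient(
            [getattr(r, c) for c in bin_cols],
            rho_threshold=rho_threshold,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
            gene_id=str(r.gene_id),
            zone_context=str(getattr(r, "zone_context", "")),
        )
        rows.append(
            {
                "gene_id": call.gene_id,
                "zone_context": call.zone_context,
                "direction": call.direction,
                "statistic": call.statistic,
                "p_value": call.p_value,
                "n_bins": call.n_bins,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "zone_context", "direction", "statistic", "p_value", "n_bins"],
    )
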
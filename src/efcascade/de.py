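"""Differential expression on log2 microarray intensities.

Contrasts are two-group comparisons of probe-level log2 intensities:
mutant vs control within one experiment, or GFP+ vs GFP- lineage-sorted
fractions.  log2FC is mean(group_a) - mean(group_b).  The default statistic
is a Welch two-sample t-test; when either group has fewer than 3 samples
the test falls back to the pooled-variance Student's t (logged).  Gene-level
summaries take the minimum-p probe and flag *conflicted* genes: two or more
significant probes with opposite log2FC signs, which disqualify a gene from
cell-type assignment.

Significance is a strict raw-p threshold (p < alpha, default 0.05); a
Benjamini-Hochberg adjusted column is emitted for reference but is not used
for calls.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def _select_samples(
    sample_sheet: pd.DataFrame,
    group: str,
    group_col: str,
    experiment_id: str | None,
) -> list[str]:
    mask = sample_sheet[group_col].astype(str) == group
    if experiment_id is not None:
        mask &= sample_sheet["experiment"].astype(str) == experiment_id
    return sample_sheet.loc[mask, "sample_id"].astype(str).tolist()


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, pooled: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided two-sample t-test over matrix rows.

    Degenerate rows where both groups have zero variance get p=1 when the
    means agree and p=0 otherwise (perfect separation), so that noise-free
    planted effects remain decidable.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1) if n1 > 1 else np.zeros(a.shape[0])
    v2 = b.var(axis=1, ddof=1) if n2 > 1 else np.zeros(b.shape[0])
    diff = m1 - m2
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full(a.shape[0], float(n1 + n2 - 2))
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if np.any(degenerate):
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
        t_degen = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
        t = np.where(degenerate, t_degen, t)
    return t, p


def probe_de(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    experiment_id: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
    group_col: str = "genotype",
) -> pd.DataFrame:
    """Per-probe differential expression for group_a vs group_b.

    ``matrix`` holds log2 intensities (rows = probes, columns = sample ids).
    ``method`` is "welch", "pooled", or "auto" (Welch, falling back to
    pooled-variance Student's t when either group has < 3 samples).
    Returns columns probe_id, log2fc, p_value, p_bh, significant, method.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ids_a = _select_samples(sample_sheet, group_a, group_col, experiment_id)
    ids_b = _select_samples(sample_sheet, group_b, group_col, experiment_id)
    if not ids_a or not ids_b:
        raise ValueError(
            f"empty group in contrast {group_a!r} vs {group_b!r}"
            + (f" ({experiment_id})" if experiment_id else "")
        )
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")

    if method not in ("auto", "welch", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    used = method
    if method == "auto":
        used = "welch"
        if min(len(ids_a), len(ids_b)) < 3:
            used = "pooled"
            log.info(
                "contrast %s vs %s%s: group sizes (%d, %d) < 3, using "
                "pooled-variance Student's t",
                group_a,
                group_b,
                f" ({experiment_id})" if experiment_id else "",
                len(ids_a),
                len(ids_b),
            )
    if used == "pooled" and len(ids_a) + len(ids_b) < 3:
        raise ValueError("need at least 3 samples in total for a pooled t-test")

    a = matrix[ids_a].to_numpy(dtype=float)
    b = matrix[ids_b].to_numpy(dtype=float)
    t, p = _two_sample_t(a, b, pooled=(used == "pooled"))
    out = pd.DataFrame(
        {
            "probe_id": matrix.index.astype(str),
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
            "p_bh": multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1],
            "significant": p < alpha,
            "method": used,
        }
    ).reset_index(drop=True)
    return out


def gene_de(
    probe_results: pd.DataFrame,
    probe_map: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Aggregate probe-level results to genes.

    The minimum-p probe represents the gene (best_log2fc / best_p); the
    direction is the sign of the best probe's log2FC when significant, else
    "none".  ``conflicted`` is True when >= 2 probes are significant with
    opposite signs; conflicted genes get direction "none" for downstream
    classification.  Probes missing from the map are dropped with a warning.
    """
    probe_map = probe_map.astype({"probe_id": str, "gene_id": str})
    merged = probe_results.merge(probe_map, on="probe_id", how="left")
    unmapped = merged["gene_id"].isna()
    if unmapped.any():
        log.warning(
            "%d probes without a gene mapping were excluded (e.g. %s)",
            int(unmapped.sum()),
            merged.loc[unmapped, "probe_id"].iloc[0],
        )
        merged = merged[~unmapped]
    merged = merged.sort_values(["gene_id", "p_value", "probe_id"], kind="stable")

    rows = []
    for gene_id, grp in merged.groupby("gene_id", sort=True):
        best = grp.iloc[0]
        sig = grp[grp["p_value"] < alpha]
        conflicted = bool((sig["log2fc"] > 0).any() and (sig["log2fc"] < 0).any())
        significant = bool(best["p_value"] < alpha)
        if conflicted or not significant:
            direction = "none"
        else:
            direction = "up" if best["log2fc"] > 0 else "down"
        rows.append(
            {
                "gene_id": gene_id,
                "best_probe": best["probe_id"],
                "best_log2fc": float(best["log2fc"]),
                "best_p": float(best["p_value"]),
                "significant": significant,
                "direction": direction,
                "conflicted": conflicted,
                "n_probes": len(grp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "best_probe",
            "best_log2fc",
            "best_p",
            "significant",
            "direction",
            "conflicted",
            "n_probes",
        ],
    )


def lineage_enrichment(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    probe_map: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    positive: str = "GFP_pos",
    negative: str = "GFP_neg",
) -> pd.DataFrame:
    """Gene-level GFP+ vs GFP- lineage enrichment.

    Convention: log2FC > 0 means enriched in the GFP+ (Tbr2-lineage)
    fraction, log2FC < 0 enriched in GFP- cells.
    """
    fractions = set(sample_sheet["lineage_fraction"].astype(str))
    for frac in (positive, negative):
        if frac not in fractions:
            raise ValueError(f"lineage fraction {frac!r} missing from sample sheet")
    probes = probe_de(
        matrix,
        sample_sheet,
        group_a=positive,
        group_b=negative,
        alpha=alpha,
        group_col="lineage_fraction",
    )
    return gene_de(probes, probe_map, alpha=alpha)
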
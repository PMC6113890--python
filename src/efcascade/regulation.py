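"""Direct-target calling: TF binding intersected with mutant expression.

A gene is a *direct target* of a TF when it is both bound (peak in the gene
body or within 50 kb) and differentially expressed (p < alpha) in that TF's
mutant cortex on **any** covering experiment (the either-MA rule).  Sign
semantics follow loss-of-function logic on mutant-vs-control contrasts:
a gene UP in the mutant was repressed by the TF, a gene DOWN was activated.

Synergistic regulation by a TF pair (here Tbr1/Tbr2) requires binding sites
for both TFs and significant differential expression in the double mutant
only -- not in either single mutant on any experiment.  The direction comes
from the double-mutant sign (down in dKO => synergistic activation).

Some mutant designs make a gene's own expression change uninterpretable
(e.g. the conditionally deleted TF transcript in its own cKO); such
(tf, gene) pairs go on an exclusion list and are reported as bound_no_de
with a note rather than as regulation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from efcascade.peaks import binding_lookup

log = logging.getLogger(__name__)

MODES = (
    "activates",
    "represses",
    "synergistic_activates",
    "synergistic_represses",
    "bound_no_de",
    "not_bound",
)


def pair_label(tf1: str, tf2: str) -> str:
    return f"{tf1}+{tf2}"


def _summary_lookup(summary: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """gene_id -> (best_log2fc, best_p) from a gene_de-style table."""
    for col in ("gene_id", "best_log2fc", "best_p"):
        if col not in summary.columns:
            raise ValueError(f"gene summary table missing column {col!r}")
    return {
        str(r.gene_id): (float(r.best_log2fc), float(r.best_p))
        for r in summary.itertuples(index=False)
    }


def call_regulation(
    binding: pd.DataFrame,
    summaries: Mapping[str, Mapping[str, pd.DataFrame]],
    exclusions: Iterable[tuple[str, str]] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call activation/repression per (tf, gene).

    ``binding`` is a call_binding table; ``summaries`` maps
    tf -> experiment_id -> gene-level summary of the TF-mutant-vs-control
    contrast (mutant first: positive log2FC = up in mutant).  Exactly one
    mode is emitted per (tf, gene) pair present in ``binding`` for TFs with
    summaries.  When several experiments are significant with conflicting
    signs, the smaller p wins and ``sign_conflict`` is flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    excluded = {(str(tf), str(g)) for tf, g in exclusions}
    bound = binding_lookup(binding)
    rows = []
    for tf in sorted(summaries):
        per_exp = {
            exp: _summary_lookup(df) for exp, df in sorted(summaries[tf].items())
        }
        if not per_exp:
            raise ValueError(f"no experiments provided for TF {tf!r}")
        genes = sorted({g for (g, t) in bound if t == tf})
        for gene in genes:
            rows.append(
                _call_one(tf, gene, bound[(gene, tf)], per_exp, excluded, alpha)
            )
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


_CALL_COLUMNS = [
    "tf",
    "gene_id",
    "mode",
    "log2fc",
    "p_value",
    "experiment",
    "experiments_used",
    "n_significant",
    "sign_conflict",
    "note",
]


def _call_one(
    tf: str,
    gene: str,
    is_bound: bool,
    per_exp: Mapping[str, dict[str, tuple[float, float]]],
    excluded: set[tuple[str, str]],
    alpha: float,
) -> dict:
    row = {
        "tf": tf,
        "gene_id": gene,
        "mode": "not_bound",
        "log2fc": float("nan"),
        "p_value": float("nan"),
        "experiment": "",
        "experiments_used": ",".join(sorted(per_exp)),
        "n_significant": 0,
        "sign_conflict": False,
        "note": "",
    }
    evidence = [
        (exp, *per_exp[exp][gene]) for exp in sorted(per_exp) if gene in per_exp[exp]
    ]
    sig = [(exp, lfc, p) for exp, lfc, p in evidence if p < alpha]
    row["n_significant"] = len(sig)
    if not is_bound:
        return row
    if (tf, gene) in excluded:
        row["mode"] = "bound_no_de"
        row["note"] = "excluded: expression change is an artifact of the mutant design"
        return row
    if not sig:
        row["mode"] = "bound_no_de"
        return row
    best_exp, best_lfc, best_p = min(sig, key=lambda t: (t[2], t[0]))
    signs = {lfc > 0 for _, lfc, _ in sig}
    row.update(
        {
            "mode": "represses" if best_lfc > 0 else "activates",
            "log2fc": best_lfc,
            "p_value": best_p,
            "experiment": best_exp,
            "sign_conflict": len(signs) > 1,
        }
    )
    if row["sign_conflict"]:
        log.warning(
            "%s -> %s: significant with conflicting signs across experiments; "
            "mode set by the smaller p",
            tf,
            gene,
        )
    return row


def call_synergy(
    binding: pd.DataFrame,
    single_summaries: Mapping[str, Mapping[str, pd.DataFrame]],
    double_summaries: Mapping[str, pd.DataFrame],
    tf_pair: tuple[str, str] = ("Tbr1", "Tbr2"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call synergistic regulation for a TF pair.

    ``double_summaries`` maps experiment_id -> gene summary of the
    double-mutant-vs-control contrast.  A gene qualifies when bound by both
    TFs, significant in the double mutant on a covering experiment, and not
    significant in either single mutant on any experiment.  Genes bound by
    both but explained by a single mutant (or silent in the dKO) come back
    as bound_no_de with a note; genes not bound by both as not_bound.
    """
    if not double_summaries:
        raise ValueError("double-mutant contrast is required for a synergy call")
    tf1, tf2 = tf_pair
    for tf in tf_pair:
        if tf not in single_summaries:
            raise ValueError(f"missing single-mutant summaries for {tf!r}")
    bound = binding_lookup(binding)
    double = {exp: _summary_lookup(df) for exp, df in sorted(double_summaries.items())}
    singles = {
        tf: {exp: _summary_lookup(df) for exp, df in sorted(single_summaries[tf].items())}
        for tf in tf_pair
    }
    label = pair_label(tf1, tf2)
    genes = sorted({g for (g, _) in bound})
    rows = []
    for gene in genes:
        row = {
            "tf": label,
            "gene_id": gene,
            "mode": "not_bound",
            "log2fc": float("nan"),
            "p_value": float("nan"),
            "experiment": "",
            "experiments_used": ",".join(sorted(double)),
            "n_significant": 0,
            "sign_conflict": False,
            "note": "",
        }
        if not (bound.get((gene, tf1), False) and bound.get((gene, tf2), False)):
            rows.append(row)
            continue
        dbl_sig = [
            (exp, *double[exp][gene])
            for exp in sorted(double)
            if gene in double[exp] and double[exp][gene][1] < alpha
        ]
        row["n_significant"] = len(dbl_sig)
        single_hit = any(
            gene in singles[tf][exp] and singles[tf][exp][gene][1] < alpha
            for tf in tf_pair
            for exp in singles[tf]
        )
        if not dbl_sig:
            row["mode"] = "bound_no_de"
            rows.append(row)
            continue
        if single_hit:
            row["mode"] = "bound_no_de"
            row["note"] = "significant in a single mutant; assigned to single-TF calls"
            rows.append(row)
            continue
        best_exp, best_lfc, best_p = min(dbl_sig, key=lambda t: (t[2], t[0]))
        row.update(
            {
                "mode": (
                    "synergistic_represses" if best_lfc > 0 else "synergistic_activates"
                ),
                "log2fc": best_lfc,
                "p_value": best_p,
                "experiment": best_exp,
                "sign_conflict": len({lfc > 0 for _, lfc, _ in dbl_sig}) > 1,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)


def read_exclusions(path) -> set[tuple[str, str]]:
    """Read (tf, gene_id) exclusion pairs from a 2-column TSV with header."""
    df = pd.read_csv(path, sep="\t")
    for col in ("tf", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"exclusion list missing column {col!r}")
    return {(str(r.tf), str(r.gene_id)) for r in df.itertuples(index=False)}
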
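"""Curated worked examples for the Pax6/Tbr2/Tbr1 system.

Two small datasets assembled from published gene-level measurements in
E14.5 mouse neocortex:

* :func:`cascade_example` -- the TF trio itself.  ChIP-seq binding plus
  mutant log2FC/p values reproduce the cascade's wiring: feedforward
  activation Pax6 -> Tbr2 -> Tbr1, feedback repression Tbr2 -| Pax6, and
  Pax6 autorepression, with no Tbr1-sourced regulation of the trio.
* :func:`ef_example` -- seven EF genes with reported qualitative calls
  (Hdac9 repressed by Tbr2; Rybp and Auts2 activated by Tbr1; Chd3
  synergistically activated by Tbr1/Tbr2; Kdm5a lineage-conflicted; Bcl7c
  RGP-specific; Rcor2 aIP+bIP bilaminar).

Where a direction was reported without a printed magnitude (e.g. Tbr1
downregulation in Tbr2-cKO cortex), the value here is a synthetic
representative of the stated sign and significance, and is marked as such.
"""

from __future__ import annotations

import pandas as pd

from efcascade.peaks import GeneModel, Peak, call_binding

CASCADE_TF_ORDER = ("Pax6", "Tbr2", "Tbr1")


def _summary(rows: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Gene-level summary table in gene_de layout from (gene, log2fc, p)."""
    return pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows],
            "best_probe": [f"{r[0]}_pr1" for r in rows],
            "best_log2fc": [r[1] for r in rows],
            "best_p": [r[2] for r in rows],
            "significant": [r[2] < 0.05 for r in rows],
            "direction": [
                "none" if r[2] >= 0.05 else ("up" if r[1] > 0 else "down")
                for r in rows
            ],
            "conflicted": [False] * len(rows),
            "n_probes": [1] * len(rows),
        }
    )


def cascade_gene_models() -> list[GeneModel]:
    """Three well-separated loci on one synthetic chromosome."""
    return [
        GeneModel("Pax6", "Pax6", "chr1", 1_000_000, 1_030_000, "+"),
        GeneModel("Tbr2", "Eomes", "chr1", 2_000_000, 2_010_000, "+"),
        GeneModel("Tbr1", "Tbr1", "chr1", 3_000_000, 3_010_000, "+"),
    ]


def cascade_peaks() -> list[Peak]:
    """Peaks realizing the reported binding: Pax6 at Pax6+Tbr2; Tbr2 at
    Pax6+Tbr1+Tbr2; Tbr1 at Tbr2 only (40 kb away, inside the window)."""
    return [
        Peak("Pax6_at_Pax6", "Pax6", "chr1", 990_000, 990_400),
        Peak("Pax6_at_Tbr2", "Pax6", "chr1", 2_002_000, 2_002_400),  # in gene body
        Peak("Tbr2_at_Pax6", "Tbr2", "chr1", 1_045_000, 1_045_400),  # 15 kb downstream
        Peak("Tbr2_at_Tbr1", "Tbr2", "chr1", 2_995_000, 2_995_400),  # 4.6 kb upstream
        Peak("Tbr2_at_Tbr2", "Tbr2", "chr1", 2_001_000, 2_001_300),  # own locus
        Peak("Tbr1_at_Tbr2", "Tbr1", "chr1", 2_050_400, 2_050_800),  # 40 kb downstream
    ]


def cascade_example() -> dict:
    """Binding calls, DE summaries, and exclusions for the TF trio.

    Expression evidence (mutant vs control log2FC, p):

    * Pax6-null: Pax6 +1.20 (1e-6; non-functional transcript derepressed),
      Tbr2 -1.07 (1e-6) -- single-array Pax6 dataset.
    * Tbr2-cKO: Pax6 +0.36 (1e-3, MA1) and +0.49 (1e-3, MA2); Tbr1 down on
      both arrays (representative values); Tbr2 itself excluded (its
      transcript is disrupted by the conditional allele).
    * Tbr1-null: Tbr2 unchanged on either array.
    """
    genes = cascade_gene_models()
    peaks = cascade_peaks()
    binding = call_binding(peaks, genes, window_bp=50_000)
    single = {
        "Pax6": {
            "Holm": _summary(
                [("Pax6", +1.20, 1e-6), ("Tbr2", -1.07, 1e-6), ("Tbr1", 0.02, 0.86)]
            ),
        },
        "Tbr2": {
            "MA1": _summary(
                [
                    ("Pax6", +0.36, 1e-3),
                    ("Tbr1", -0.62, 0.012),  # synthetic representative: down, p<0.05
                    ("Tbr2", -1.50, 1e-4),  # uninterpretable: cKO disrupts the transcript
                ]
            ),
            "MA2": _summary(
                [
                    ("Pax6", +0.49, 1e-3),
                    ("Tbr1", -0.48, 0.03),  # synthetic representative
                    ("Tbr2", -1.40, 1e-4),
                ]
            ),
        },
        "Tbr1": {
            "MA1": _summary([("Tbr2", -0.05, 0.62), ("Pax6", 0.03, 0.71)]),
            "MA2": _summary([("Tbr2", +0.04, 0.55), ("Pax6", -0.02, 0.80)]),
        },
    }
    return {
        "gene_models": genes,
        "peaks": peaks,
        "binding": binding,
        "summaries": single,
        "exclusions": {("Tbr2", "Tbr2")},
        "tf_order": CASCADE_TF_ORDER,
    }


def ef_example() -> dict:
    """Seven EF genes with reported regulation and expression calls.

    Expected qualitative outcomes:

    * Tbr2 represses Hdac9 (+0.55, p=2e-4 on MA1; +0.68, p=0.008 on MA2)
    * Tbr1 activates Rybp and Auts2 (down in Tbr1-null; representative values)
    * Tbr1/Tbr2 synergistically activate Chd3 (dKO-only significance)
    * Kdm5a: probes enriched in opposite lineage fractions -> conflicted
    * Bcl7c: GFP- enrichment (-1.07) + VZ expression -> RGP
    * Rcor2: GFP+ enrichment (+1.94) + VZ/SVZ bilaminar -> aIP+bIP
    """
    genes = [
        GeneModel("Hdac9", "Hdac9", "chr2", 1_000_000, 1_050_000, "+"),
        GeneModel("Rybp", "Rybp", "chr2", 2_000_000, 2_020_000, "+"),
        GeneModel("Auts2", "Auts2", "chr2", 3_000_000, 3_100_000, "+"),
        GeneModel("Chd3", "Chd3", "chr2", 4_000_000, 4_020_000, "-"),
        GeneModel("Kdm5a", "Kdm5a", "chr2", 5_000_000, 5_030_000, "+"),
        GeneModel("Bcl7c", "Bcl7c", "chr2", 6_000_000, 6_010_000, "+"),
        GeneModel("Rcor2", "Rcor2", "chr2", 7_000_000, 7_010_000, "+"),
    ]
    peaks = [
        Peak("Tbr2_at_Hdac9", "Tbr2", "chr2", 995_000, 995_400),
        Peak("Tbr1_at_Rybp", "Tbr1", "chr2", 1_990_000, 1_990_400),
        Peak("Tbr1_at_Auts2", "Tbr1", "chr2", 3_010_000, 3_010_400),
        Peak("Tbr1_at_Chd3", "Tbr1", "chr2", 3_995_000, 3_995_400),
        Peak("Tbr2_at_Chd3", "Tbr2", "chr2", 4_025_000, 4_025_400),
    ]
    binding = call_binding(peaks, genes, window_bp=50_000)
    ns = [("Hdac9", 0.02, 0.8), ("Rybp", -0.03, 0.7), ("Auts2", 0.01, 0.9),
          ("Chd3", -0.05, 0.6)]

    def merge(base, extra):
        have = {g for g, _, _ in extra}
        return extra + [row for row in base if row[0] not in have]

    single = {
        "Tbr2": {
            "MA1": _summary(merge(ns, [("Hdac9", +0.55, 2e-4)])),
            "MA2": _summary(merge(ns, [("Hdac9", +0.68, 0.008)])),
        },
        "Tbr1": {
            # representative magnitudes for reported activation (down in KO)
            "MA1": _summary(merge(ns, [("Rybp", -0.52, 0.01), ("Auts2", -0.41, 0.02)])),
            "MA2": _summary(merge(ns, [("Rybp", -0.45, 0.02), ("Auts2", -0.38, 0.04)])),
        },
    }
    double = {"MA2": _summary(merge(ns, [("Chd3", -0.80, 0.01)]))}

    # probe-level lineage results (gene_de input) for the classifier genes
    lineage_probes = pd.DataFrame(
        {
            "probe_id": [
                "Kdm5a_pr1", "Kdm5a_pr2", "Bcl7c_pr1", "Rcor2_pr1",
            ],
            "log2fc": [+0.90, -0.70, -1.07, +1.94],
            "p_value": [0.01, 0.02, 1e-4, 1e-5],
            "p_bh": [0.02, 0.03, 4e-4, 4e-5],
            "significant": [True, True, True, True],
            "method": ["welch"] * 4,
        }
    )
    probe_map = pd.DataFrame(
        {
            "probe_id": ["Kdm5a_pr1", "Kdm5a_pr2", "Bcl7c_pr1", "Rcor2_pr1"],
            "gene_id": ["Kdm5a", "Kdm5a", "Bcl7c", "Rcor2"],
        }
    )
    zonal = pd.DataFrame(
        {
            "gene_id": ["Kdm5a", "Bcl7c", "Rcor2"],
            "VZ": [0.9, 1.0, 0.9],
            "SVZ": [0.8, 0.1, 0.8],
            "IZ": [0.0, 0.0, 0.1],
            "CP": [0.0, 0.05, 0.0],
        }
    )
    return {
        "gene_models": genes,
        "peaks": peaks,
        "binding": binding,
        "summaries": single,
        "double_summaries": double,
        "lineage_probes": lineage_probes,
        "probe_map": probe_map,
        "zonal_profiles": zonal,
        "expected_regulation": {
            ("Tbr2", "Hdac9"): "represses",
            ("Tbr1", "Rybp"): "activates",
            ("Tbr1", "Auts2"): "activates",
        },
        "expected_synergy": {"Chd3": "synergistic_activates"},
        "expected_celltype": {
            "Kdm5a": "conflicted",
            "Bcl7c": "RGP",
            "Rcor2": "aIP+bIP",
        },
    }
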
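"""Cell-type classification from lineage enrichment plus zonal expression.

Cortical cell types occupy characteristic histological zones at E14.5:
radial glial progenitors (RGP) in VZ; apical intermediate progenitors (aIP)
in VZ; basal intermediate progenitors (bIP) in SVZ; postmitotic projection
neurons in SVZ/IZ/CP.  A gene is assigned a label from (a) the sign and
significance of its GFP+ vs GFP- lineage enrichment and (b) its *primary
zones* -- detected zones whose intensity reaches a dominance fraction of the
maximum ("expressed mainly in" quantified as a dominance rule).

Decision table (first match wins):

* conflicted enrichment            -> ``conflicted`` (never cell-type-specific)
* not significant, or no zones     -> ``none``
* GFP- enriched, zones == {VZ}     -> ``RGP``
* GFP+ enriched, zones == {VZ}     -> ``aIP``
* GFP+ enriched, zones == {SVZ}    -> ``bIP``
* GFP+ enriched, zones == {VZ,SVZ} -> ``aIP+bIP`` (bilaminar)
* GFP+ enriched, zones touch IZ/CP -> neuron class named by the earliest
  (most apical) primary zone, ``N-vz`` .. ``N-cp``; prefixed ``PN-`` when the
  gene is annotated cortex-specific and the initial zone is IZ or CP
* anything else detected           -> ``mixed``

Cortex specificity (projection-neuron PN labels vs general neuron N labels)
is an input annotation, not inferred: it derives from expression outside the
cortex, which is beyond this data model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

ZONES = ("VZ", "SVZ", "IZ", "CP")  # apical -> pial

LABELS = (
    "RGP",
    "aIP",
    "bIP",
    "aIP+bIP",
    "N-vz",
    "N-svz",
    "N-iz",
    "N-cp",
    "PN-iz",
    "PN-cp",
    "mixed",
    "none",
    "conflicted",
)


@dataclass(frozen=True)
class CellTypeCall:
    gene_id: str
    label: str
    enrichment_log2fc: float
    enrichment_significant: bool
    conflicted: bool
    zones: tuple[str, ...]


def primary_zones(
    intensities: Mapping[str, float] | Sequence[float],
    detect_floor: float,
    dominance_frac: float = 0.5,
) -> set[str]:
    """Zones where a gene is mainly expressed.

    A zone is primary when its intensity is detected (>= ``detect_floor``)
    and reaches ``dominance_frac`` of the maximum zone intensity.  Returns
    the empty set when nothing is detected.
    """
    if not 0 < dominance_frac <= 1:
        raise ValueError("dominance_frac must be in (0, 1]")
    if isinstance(intensities, Mapping):
        values = [float(intensities[z]) for z in ZONES]
    else:
        values = [float(v) for v in intensities]
        if len(values) != len(ZONES):
            raise ValueError(f"expected {len(ZONES)} zone intensities")
    if any(v < 0 for v in values):
        raise ValueError("zone intensities must be non-negative")
    peak = max(values)
    if peak < detect_floor:
        return set()
    return {
        z
        for z, v in zip(ZONES, values)
        if v >= detect_floor and v >= dominance_frac * peak
    }


def classify_cell_type(
    gene_id: str,
    enrichment_log2fc: float,
    significant: bool,
    conflicted: bool,
    zones: Iterable[str],
    cortex_specific: bool = False,
) -> CellTypeCall:
    """Assign one cell-type label; total over the whole input lattice."""
    zones = set(zones)
    unknown = zones - set(ZONES)
    if unknown:
        raise ValueError(f"unknown zones: {sorted(unknown)}")

    def call(label: str) -> CellTypeCall:
        return CellTypeCall(
            gene_id=gene_id,
            label=label,
            enrichment_log2fc=enrichment_log2fc,
            enrichment_significant=significant,
            conflicted=conflicted,
            zones=tuple(z for z in ZONES if z in zones),
        )

    if conflicted:
        return call("conflicted")
    if not significant or not zones:
        return call("none")
    gfp_pos = enrichment_log2fc > 0
    if not gfp_pos:
        return call("RGP") if zones == {"VZ"} else call("mixed")
    if zones == {"VZ"}:
        return call("aIP")
    if zones == {"SVZ"}:
        return call("bIP")
    if zones == {"VZ", "SVZ"}:
        return call("aIP+bIP")
    if "IZ" in zones or "CP" in zones:
        initial = next(z for z in ZONES if z in zones)
        if cortex_specific and initial in ("IZ", "CP"):
            return call(f"PN-{initial.lower()}")
        return call(f"N-{initial.lower()}")
    return call("mixed")


def classify_table(
    lineage_summary: pd.DataFrame,
    zonal_profiles: pd.DataFrame,
    detect_floor: float,
    dominance_frac: float = 0.5,
    cortex_specific: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Classify every gene present in the lineage summary.

    ``lineage_summary`` is a gene_de/lineage_enrichment table;
    ``zonal_profiles`` has columns gene_id, VZ, SVZ, IZ, CP.  Genes without
    a zonal profile are treated as undetected (empty zone set).
    """
    cortex_specific = cortex_specific or {}
    zonal = zonal_profiles.set_index("gene_id")
    rows = []
    for r in lineage_summary.itertuples(index=False):
        gene_id = str(r.gene_id)
        if gene_id in zonal.index:
            zones = primary_zones(
                {z: zonal.loc[gene_id, z] for z in ZONES},
                detect_floor=detect_floor,
                dominance_frac=dominance_frac,
            )
        else:
            zones = set()
        res = classify_cell_type(
            gene_id=gene_id,
            enrichment_log2fc=float(r.best_log2fc),
            significant=bool(r.significant),
            conflicted=bool(r.conflicted),
            zones=zones,
            cortex_specific=bool(cortex_specific.get(gene_id, False)),
        )
        rows.append(
            {
                "gene_id": res.gene_id,
                "label": res.label,
                "enrichment_log2fc": res.enrichment_log2fc,
                "enrichment_significant": res.enrichment_significant,
                "conflicted": res.conflicted,
                "zones": "+".join(res.zones),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "label",
            "enrichment_log2fc",
            "enrichment_significant",
            "conflicted",
            "zones",
        ],
    )
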
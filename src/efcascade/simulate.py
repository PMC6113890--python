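"""Synthetic study generator with planted ground truth.

Emulates every input the pipeline consumes, at the statistical structure of
the real study design, so each downstream stage is testable offline:

* gene models on a small multi-chromosome genome (non-overlapping loci)
* per-TF ChIP-seq peak sets: planted peaks within the 50 kb binding window
  of their target genes, plus decoy peaks farther than the window from all
  genes
* a probe-level log2 expression matrix with a sample sheet covering the
  mutant genotypes (default replicate counts 3 control / 4 Tbr1-KO /
  2 Tbr2-cKO / 3 Tbr1/2-dKO on the newer array, MA2) and GFP-sorted lineage
  fractions, with planted log2FC effects plus i.i.d. Gaussian noise
* zonal (VZ/SVZ/IZ/CP) and rostrocaudal profiles realizing each planted
  label's canonical pattern

Loss-of-function sign convention: a gene repressed by a TF gains +effect in
that TF's mutant (derepression); an activated gene loses the effect.
Synergistic targets shift only in the double mutant.  Lineage-sorted
samples encode the planted cell-type's enrichment sign; *conflicted* genes
get probes with opposite-sign lineage effects.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` children, so identical seeds and configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from efcascade.celltypes import LABELS, ZONES
from efcascade.peaks import (
    DEFAULT_WINDOW_BP,
    GeneModel,
    Peak,
    gene_index,
    write_gene_models,
    write_peaks,
)
from efcascade.regulation import pair_label

TFS = ("Pax6", "Tbr2", "Tbr1")
SYNERGY_PAIR = ("Tbr1", "Tbr2")

# which TF functions each genotype has lost
GENOTYPE_LESIONS: dict[str, frozenset[str]] = {
    "control": frozenset(),
    "pax6_null": frozenset({"Pax6"}),
    "tbr1_ko": frozenset({"Tbr1"}),
    "tbr2_cko": frozenset({"Tbr2"}),
    "tbr1_tbr2_dko": frozenset({"Tbr1", "Tbr2"}),
}

TF_GENOTYPE = {
    "Pax6": "pax6_null",
    "Tbr1": "tbr1_ko",
    "Tbr2": "tbr2_cko",
    pair_label(*SYNERGY_PAIR): "tbr1_tbr2_dko",
}

# canonical zone-intensity templates per planted cell-type label
ZONE_TEMPLATES: dict[str, tuple[str, ...]] = {
    "RGP": ("VZ",),
    "aIP": ("VZ",),
    "bIP": ("SVZ",),
    "aIP+bIP": ("VZ", "SVZ"),
    "N-vz": ("VZ", "SVZ", "IZ", "CP"),
    "N-svz": ("SVZ", "IZ", "CP"),
    "N-iz": ("IZ", "CP"),
    "N-cp": ("CP",),
    "PN-iz": ("IZ", "CP"),
    "PN-cp": ("CP",),
    "mixed": ("VZ", "SVZ"),  # paired with GFP- enrichment => mixed sink
    "none": (),
    "conflicted": ("VZ", "SVZ"),
}

# lineage-enrichment sign planted per label (+1 = GFP+, -1 = GFP-, 0 = flat)
LABEL_LINEAGE_SIGN: dict[str, int] = {
    "RGP": -1,
    "aIP": +1,
    "bIP": +1,
    "aIP+bIP": +1,
    "N-vz": +1,
    "N-svz": +1,
    "N-iz": +1,
    "N-cp": +1,
    "PN-iz": +1,
    "PN-cp": +1,
    "mixed": -1,
    "none": 0,
    "conflicted": 0,  # realized as opposite-sign probe effects
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Microarray study design: experiments, genotypes, replicate counts.

    ``replicates`` maps experiment id -> genotype -> replicate count; the
    lineage-sort experiment maps fraction labels (GFP_pos / GFP_neg) to
    replicate counts and carries the control genotype.
    """

    replicates: Mapping[str, Mapping[str, int]]
    lineage_replicates: Mapping[str, int]
    control: str = "control"
    sort_experiment: str = "sort"
    seed: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for exp, genos in self.replicates.items():
            if exp in seen:
                raise ValueError(f"duplicate experiment id {exp!r}")
            seen.add(exp)
            for geno, n in genos.items():
                if geno not in GENOTYPE_LESIONS:
                    raise ValueError(f"unknown genotype label {geno!r} in {exp}")
                if n < 2:
                    raise ValueError(
                        f"genotype {geno} in {exp} needs >= 2 replicates, got {n}"
                    )
        for frac, n in self.lineage_replicates.items():
            if n < 2:
                raise ValueError(f"lineage fraction {frac} needs >= 2 replicates")

    @property
    def experiments(self) -> list[str]:
        return list(self.replicates)

    def experiments_covering(self, genotype: str) -> list[str]:
        return [
            exp
            for exp, genos in self.replicates.items()
            if genotype in genos and self.control in genos
        ]


def default_design(seed: int = 0) -> ExperimentDesign:
    """The study's default two-array design plus the GFP-sort experiment.

    MA2 carries the 3/4/2/3 control / Tbr1-KO / Tbr2-cKO / dKO replicate
    counts; MA1 is the earlier array round covering the single mutants and
    the Pax6-null dataset (the dKO was profiled only on MA2, and Pax6 only
    on one array, so the either-array rule degenerates for Pax6).
    """
    return ExperimentDesign(
        replicates={
            "MA1": {"control": 3, "tbr1_ko": 3, "tbr2_cko": 3, "pax6_null": 3},
            "MA2": {"control": 3, "tbr1_ko": 4, "tbr2_cko": 2, "tbr1_tbr2_dko": 3},
        },
        lineage_replicates={"GFP_pos": 4, "GFP_neg": 4},
        seed=seed,
    )


@dataclass
class PlantedTruth:
    """Ground-truth labels and edges planted into a synthetic study."""

    cell_type: dict[str, str]
    gradient: dict[str, str]
    regulation: pd.DataFrame  # tf, gene_id, mode, effect_log2fc
    binding: pd.DataFrame  # tf, gene_id, bound

    def __post_init__(self) -> None:
        bound = {
            (str(r.tf), str(r.gene_id))
            for r in self.binding.itertuples(index=False)
            if r.bound
        }
        for r in self.regulation.itertuples(index=False):
            if r.mode.startswith("synergistic"):
                for tf in str(r.tf).split("+"):
                    if (tf, str(r.gene_id)) not in bound:
                        raise ValueError(
                            f"synergistic target {r.gene_id} must be bound by {tf}"
                        )
            elif r.mode != "none":
                if (str(r.tf), str(r.gene_id)) not in bound:
                    raise ValueError(
                        f"regulated gene {r.gene_id} must be bound by {r.tf}"
                    )
        bad = set(self.cell_type.values()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown cell-type labels: {sorted(bad)}")
        bad = set(self.gradient.values()) - {"high_rostral", "high_caudal", "none"}
        if bad:
            raise ValueError(f"unknown gradient labels: {sorted(bad)}")


def plant_truth(
    gene_ids: Sequence[str],
    seed: int = 0,
    n_single_edges: int = 40,
    n_synergy: int = 4,
    n_bound_only_per_tf: int = 4,
    effect_log2fc: float = 0.75,
    frac_specific: float = 0.30,
    frac_conflicted: float = 0.05,
    frac_mixed: float = 0.025,
    frac_graded: float = 0.10,
) -> PlantedTruth:
    """Randomly assign labels, gradients, binding, and regulation edges.

    Single-TF edges are spread round-robin over Pax6/Tbr2/Tbr1 with
    alternating activation/repression; synergy targets are bound by both
    Tbr1 and Tbr2 and shift only in the dKO; ``n_bound_only_per_tf`` extra
    genes per TF are bound without regulation (binding alone is not
    regulation).  Label and edge assignments are independent draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    gene_ids = [str(g) for g in gene_ids]
    n = len(gene_ids)
    needed = n_single_edges + n_synergy + n_bound_only_per_tf * len(TFS)
    if needed > n:
        raise ValueError(f"need >= {needed} genes for the requested truth, got {n}")

    shuffled = list(rng.permutation(gene_ids))
    reg_rows = []
    bind_rows = []
    singles = [shuffled.pop() for _ in range(n_single_edges)]
    for i, gene in enumerate(singles):
        tf = TFS[i % len(TFS)]
        mode = "activates" if (i // len(TFS)) % 2 == 0 else "represses"
        reg_rows.append(
            {"tf": tf, "gene_id": gene, "mode": mode, "effect_log2fc": effect_log2fc}
        )
        bind_rows.append({"tf": tf, "gene_id": gene, "bound": True})
    for i in range(n_synergy):
        gene = shuffled.pop()
        mode = "synergistic_activates" if i % 2 == 0 else "synergistic_represses"
        reg_rows.append(
            {
                "tf": pair_label(*SYNERGY_PAIR),
                "gene_id": gene,
                "mode": mode,
                "effect_log2fc": effect_log2fc,
            }
        )
        for tf in SYNERGY_PAIR:
            bind_rows.append({"tf": tf, "gene_id": gene, "bound": True})
    for tf in TFS:
        for _ in range(n_bound_only_per_tf):
            gene = shuffled.pop()
            bind_rows.append({"tf": tf, "gene_id": gene, "bound": True})

    specific_labels = [
        "RGP", "aIP", "bIP", "aIP+bIP",
        "N-vz", "N-svz", "N-iz", "N-cp", "PN-iz", "PN-cp",
    ]
    cell_type = {}
    for gene in gene_ids:
        u = rng.random()
        if u < frac_specific:
            cell_type[gene] = specific_labels[
                int(rng.integers(len(specific_labels)))
            ]
        elif u < frac_specific + frac_conflicted:
            cell_type[gene] = "conflicted"
        elif u < frac_specific + frac_conflicted + frac_mixed:
            cell_type[gene] = "mixed"
        else:
            cell_type[gene] = "none"

    gradient = {}
    for gene in gene_ids:
        u = rng.random()
        if u < frac_graded / 2:
            gradient[gene] = "high_rostral"
        elif u < frac_graded:
            gradient[gene] = "high_caudal"
        else:
            gradient[gene] = "none"

    return PlantedTruth(
        cell_type=cell_type,
        gradient=gradient,
        regulation=pd.DataFrame(
            reg_rows, columns=["tf", "gene_id", "mode", "effect_log2fc"]
        ),
        binding=pd.DataFrame(bind_rows, columns=["tf", "gene_id", "bound"]),
    )


def generate_gene_models(
    n_genes: int,
    n_chroms: int = 5,
    min_gap_bp: int = 150_000,
    seed: int = 0,
    chrom_length_bp: int = 50_000_000,
    min_len_bp: int = 1_000,
    max_len_bp: int = 100_000,
) -> list[GeneModel]:
    """Place non-overlapping genes on a small synthetic genome.

    Genes are spread round-robin over chromosomes and placed left to right
    with at least ``min_gap_bp`` between neighbours; leftover space is
    distributed as random extra gaps.  Lengths are uniform in
    [min_len_bp, max_len_bp].
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min_gap_bp < 0:
        raise ValueError("min_gap_bp must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    genes: list[GeneModel] = []
    idx = 0
    for c, k in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        if k == 0:
            continue
        lengths = rng.integers(min_len_bp, max_len_bp + 1, size=k)
        slack = chrom_length_bp - int(lengths.sum()) - (k - 1) * min_gap_bp
        if slack < 0:
            raise ValueError(
                f"cannot place {k} genes on {chrom}: need "
                f"{int(lengths.sum()) + (k - 1) * min_gap_bp} bp, have "
                f"{chrom_length_bp}"
            )
        weights = rng.random(k + 1)
        extra = np.floor(weights / weights.sum() * slack).astype(int)
        cursor = int(extra[0])
        for j in range(k):
            idx += 1
            start, end = cursor, cursor + int(lengths[j])
            genes.append(
                GeneModel(
                    gene_id=f"g{idx:04d}",
                    symbol=f"Gene{idx}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            cursor = end + min_gap_bp + int(extra[j + 1])
    return genes


def generate_peaks(
    gene_models: Sequence[GeneModel],
    truth_binding: pd.DataFrame,
    decoy_per_tf: int = 10,
    window_bp: int = DEFAULT_WINDOW_BP,
    seed: int = 0,
    peak_len_bp: tuple[int, int] = (200, 1_000),
    chrom_length_bp: int = 50_000_000,
    max_tries: int = 1_000,
) -> list[Peak]:
    """Place planted peaks inside the binding window and decoys beyond it.

    Each (tf, gene, bound=True) row gets one peak overlapping the gene body
    or within ``window_bp`` of an edge, re-sampled until no *other* gene
    falls inside its window, so gene-level binding calls round-trip the
    truth exactly.  Decoys are re-sampled until farther than ``window_bp``
    from every gene.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    by_id = {g.gene_id: g for g in gene_models}
    index = gene_index(list(gene_models))
    chroms = sorted({g.chrom for g in gene_models})
    peaks: list[Peak] = []
    counter: dict[str, int] = {}

    def next_id(tf: str) -> str:
        counter[tf] = counter.get(tf, 0) + 1
        return f"{tf}_p{counter[tf]:04d}"

    for r in truth_binding.itertuples(index=False):
        if not r.bound:
            continue
        gene = by_id.get(str(r.gene_id))
        if gene is None:
            raise ValueError(f"truth references unknown gene {r.gene_id!r}")
        placed = False
        for _ in range(max_tries):
            length = int(rng.integers(peak_len_bp[0], peak_len_bp[1] + 1))
            u = rng.random()
            if u < 0.5:  # inside the gene body
                start = int(rng.integers(gene.start, max(gene.start + 1, gene.end - length)))
            else:  # flanking, edge gap uniform in [0, window_bp]
                gap = int(rng.integers(0, window_bp + 1))
                if rng.random() < 0.5:
                    start = gene.start - gap - length
                else:
                    start = gene.end + gap
            if start < 0:
                continue
            end = start + length
            hits = {
                g.gene_id
                for g in index.within(gene.chrom, start, end, window_bp)
            }
            if hits == {gene.gene_id}:
                peaks.append(
                    Peak(next_id(str(r.tf)), str(r.tf), gene.chrom, start, end)
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place a peak for ({r.tf}, {r.gene_id}) without "
                f"hitting another gene's window; genome too dense"
            )

    tfs = sorted(set(truth_binding["tf"].astype(str))) or list(TFS)
    for tf in tfs:
        for _ in range(decoy_per_tf):
            placed = False
            for _ in range(max_tries):
                length = int(rng.integers(peak_len_bp[0], peak_len_bp[1] + 1))
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, chrom_length_bp - length))
                if not index.within(chrom, start, start + length, window_bp):
                    peaks.append(Peak(next_id(tf), tf, chrom, start, start + length))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place a decoy peak for {tf} beyond {window_bp} bp "
                    f"of all genes; genome too dense"
                )
    return peaks


def generate_expression(
    design: ExperimentDesign,
    truth: PlantedTruth,
    probes_per_gene: int = 2,
    noise_sd: float = 0.25,
    baseline: float = 8.0,
    lineage_effect_log2fc: float = 0.75,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the probe-level matrix, sample sheet, and probe map.

    log2 intensity = baseline + gene offset + probe offset + planted effect
    + N(0, noise_sd).  Regulation effects follow the loss-of-function sign
    convention and apply in every genotype whose lesions cover the edge's
    TF(s); lineage effects apply to GFP+ samples with the planted label's
    sign, and conflicted genes get alternating probe signs.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if probes_per_gene < 2 and "conflicted" in truth.cell_type.values():
        raise ValueError("conflicted genes need probes_per_gene >= 2")
    for r in truth.regulation.itertuples(index=False):
        genotype = TF_GENOTYPE.get(str(r.tf))
        if genotype is None:
            raise ValueError(f"no mutant genotype known for TF {r.tf!r}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    genes = sorted(truth.cell_type)
    gene_pos = {g: i for i, g in enumerate(genes)}

    sheet_rows = []
    for exp, genos in design.replicates.items():
        for geno, n in genos.items():
            for i in range(1, n + 1):
                sheet_rows.append(
                    {
                        "sample_id": f"{exp}.{geno}.r{i}",
                        "genotype": geno,
                        "experiment": exp,
                        "lineage_fraction": "bulk",
                        "replicate": i,
                    }
                )
    for frac, n in design.lineage_replicates.items():
        for i in range(1, n + 1):
            sheet_rows.append(
                {
                    "sample_id": f"{design.sort_experiment}.{frac}.r{i}",
                    "genotype": design.control,
                    "experiment": design.sort_experiment,
                    "lineage_fraction": frac,
                    "replicate": i,
                }
            )
    sample_sheet = pd.DataFrame(sheet_rows)
    samples = sample_sheet["sample_id"].tolist()
    genotype_of = dict(zip(samples, sample_sheet["genotype"]))
    fraction_of = dict(zip(samples, sample_sheet["lineage_fraction"]))

    probe_rows = [
        {"probe_id": f"{g}_pr{p + 1}", "gene_id": g}
        for g in genes
        for p in range(probes_per_gene)
    ]
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])
    n_probes, n_samples = len(probe_rows), len(samples)

    gene_offset = rng.normal(0.0, 1.0, size=len(genes))
    probe_offset = rng.normal(0.0, 0.25, size=n_probes)

    effect = np.zeros((n_probes, n_samples))
    sample_lesions = [GENOTYPE_LESIONS[genotype_of[s]] for s in samples]
    for r in truth.regulation.itertuples(index=False):
        lost = frozenset(str(r.tf).split("+"))
        delta = float(r.effect_log2fc)
        if r.mode in ("activates", "synergistic_activates"):
            delta = -delta
        cols = [
            j
            for j, lesions in enumerate(sample_lesions)
            if lost <= lesions and fraction_of[samples[j]] == "bulk"
        ]
        g = gene_pos[str(r.gene_id)]
        for p in range(probes_per_gene):
            effect[g * probes_per_gene + p, cols] += delta

    gfp_pos_cols = [j for j, s in enumerate(samples) if fraction_of[s] == "GFP_pos"]
    for g_id, label in truth.cell_type.items():
        g = gene_pos[g_id]
        if label == "conflicted":
            for p in range(probes_per_gene):
                sign = 1.0 if p % 2 == 0 else -1.0
                effect[g * probes_per_gene + p, gfp_pos_cols] += (
                    sign * lineage_effect_log2fc
                )
        else:
            sign = LABEL_LINEAGE_SIGN[label]
            if sign:
                for p in range(probes_per_gene):
                    effect[g * probes_per_gene + p, gfp_pos_cols] += (
                        sign * lineage_effect_log2fc
                    )

    values = (
        baseline
        + np.repeat(gene_offset, probes_per_gene)[:, None]
        + probe_offset[:, None]
        + effect
        + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    )
    matrix = pd.DataFrame(
        values, index=[r["probe_id"] for r in probe_rows], columns=samples
    )
    matrix.index.name = "probe_id"
    return matrix, sample_sheet, probe_map


def generate_zonal_profiles(
    truth: PlantedTruth,
    detect_floor: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
    on_intensity: float = 1.0,
) -> pd.DataFrame:
    """Zone-intensity profiles realizing each label's canonical template."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    rows = []
    for gene in sorted(truth.cell_type):
        label = truth.cell_type[gene]
        if label not in ZONE_TEMPLATES:
            raise ValueError(f"unknown cell-type label {label!r}")
        on = ZONE_TEMPLATES[label]
        row = {"gene_id": gene}
        for z in ZONES:
            value = (on_intensity if z in on else 0.0) + rng.normal(0.0, noise_sd)
            row[z] = max(0.0, value)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", *ZONES])


def generate_gradient_profiles(
    truth: PlantedTruth,
    n_bins: int = 8,
    slope: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    base_intensity: float = 2.0,
    zone_context: str = "VZ/SVZ",
) -> pd.DataFrame:
    """Rostrocaudal profiles: monotone trends for graded genes, flat else.

    ``slope`` is the total log-intensity change from bin 0 (rostral) to the
    last (caudal) bin; high_rostral genes decrease, high_caudal increase.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3 (trend undefined below that)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    ramp = np.linspace(0.0, slope, n_bins)
    rows = []
    for gene in sorted(truth.gradient):
        direction = truth.gradient[gene]
        if direction == "high_caudal":
            trend = ramp
        elif direction == "high_rostral":
            trend = ramp[::-1]
        else:
            trend = np.zeros(n_bins)
        values = np.maximum(
            0.0, base_intensity + trend + rng.normal(0.0, noise_sd, size=n_bins)
        )
        row = {"gene_id": gene, "zone_context": zone_context}
        row.update({f"bin_{i}": values[i] for i in range(n_bins)})
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["gene_id", "zone_context", *[f"bin_{i}" for i in range(n_bins)]]
    )


@dataclass
class SimulatedStudy:
    """All generated inputs plus the planted truth and the config used."""

    design: ExperimentDesign
    truth: PlantedTruth
    gene_models: list[GeneModel]
    peaks: list[Peak]
    matrix: pd.DataFrame
    sample_sheet: pd.DataFrame
    probe_map: pd.DataFrame
    zonal_profiles: pd.DataFrame
    gradient_profiles: pd.DataFrame
    config: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models(self.gene_models, outdir / "gene_models.bed")
        for tf in sorted({p.tf for p in self.peaks}):
            write_peaks(
                [p for p in self.peaks if p.tf == tf], outdir / f"peaks_{tf}.bed"
            )
        self.matrix.to_csv(outdir / "expression.tsv", sep="\t")
        self.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        self.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
        self.zonal_profiles.to_csv(outdir / "zonal_profiles.tsv", sep="\t", index=False)
        self.gradient_profiles.to_csv(
            outdir / "gradient_profiles.tsv", sep="\t", index=False
        )
        self.truth.regulation.to_csv(
            outdir / "truth_regulation.tsv", sep="\t", index=False
        )
        self.truth.binding.to_csv(outdir / "truth_binding.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "gene_id": sorted(self.truth.cell_type),
                "cell_type": [
                    self.truth.cell_type[g] for g in sorted(self.truth.cell_type)
                ],
                "gradient": [
                    self.truth.gradient[g] for g in sorted(self.truth.cell_type)
                ],
            }
        ).to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)
        return outdir


def simulate_study(
    n_genes: int = 400,
    seed: int = 0,
    design: ExperimentDesign | None = None,
    n_single_edges: int = 40,
    n_synergy: int = 4,
    n_bound_only_per_tf: int = 4,
    effect_log2fc: float = 0.75,
    noise_sd: float = 0.25,
    probes_per_gene: int = 2,
    decoy_per_tf: int = 10,
    window_bp: int = DEFAULT_WINDOW_BP,
    zonal_noise_sd: float = 0.1,
    gradient_noise_sd: float = 0.25,
    gradient_slope: float = 2.0,
    n_gradient_bins: int = 8,
    n_chroms: int = 5,
    chrom_length_bp: int = 50_000_000,
) -> SimulatedStudy:
    """Generate a full synthetic study with internally consistent truth."""
    design = design or default_design(seed=seed)
    genes = generate_gene_models(
        n_genes, n_chroms=n_chroms, seed=seed, chrom_length_bp=chrom_length_bp
    )
    truth = plant_truth(
        [g.gene_id for g in genes],
        seed=seed,
        n_single_edges=n_single_edges,
        n_synergy=n_synergy,
        n_bound_only_per_tf=n_bound_only_per_tf,
        effect_log2fc=effect_log2fc,
    )
    peaks = generate_peaks(
        genes,
        truth.binding,
        decoy_per_tf=decoy_per_tf,
        window_bp=window_bp,
        seed=seed,
        chrom_length_bp=chrom_length_bp,
    )
    matrix, sample_sheet, probe_map = generate_expression(
        design,
        truth,
        probes_per_gene=probes_per_gene,
        noise_sd=noise_sd,
        lineage_effect_log2fc=effect_log2fc,
        seed=seed,
    )
    zonal = generate_zonal_profiles(truth, noise_sd=zonal_noise_sd, seed=seed)
    gradients = generate_gradient_profiles(
        truth,
        n_bins=n_gradient_bins,
        slope=gradient_slope,
        noise_sd=gradient_noise_sd,
        seed=seed,
    )
    config = {
        "n_genes": n_genes,
        "seed": seed,
        "n_single_edges": n_single_edges,
        "n_synergy": n_synergy,
        "n_bound_only_per_tf": n_bound_only_per_tf,
        "effect_log2fc": effect_log2fc,
        "noise_sd": noise_sd,
        "probes_per_gene": probes_per_gene,
        "decoy_per_tf": decoy_per_tf,
        "window_bp": window_bp,
        "zonal_noise_sd": zonal_noise_sd,
        "gradient_noise_sd": gradient_noise_sd,
        "gradient_slope": gradient_slope,
        "n_gradient_bins": n_gradient_bins,
        "n_chroms": n_chroms,
        "chrom_length_bp": chrom_length_bp,
        "replicates": {k: dict(v) for k, v in design.replicates.items()},
        "lineage_replicates": dict(design.lineage_replicates),
    }
    return SimulatedStudy(
        design=design,
        truth=truth,
        gene_models=genes,
        peaks=peaks,
        matrix=matrix,
        sample_sheet=sample_sheet,
        probe_map=probe_map,
        zonal_profiles=zonal,
        gradient_profiles=gradients,
        config=config,
    )
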
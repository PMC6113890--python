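"""End-to-end orchestration: simulate -> annotate -> DE -> classify ->
gradients -> targets -> network -> report.

`run_all` is a pure function of its config: rerunning with the same config
(and seed) writes byte-identical artifacts.  A manifest records the package
version, the config and its hash, and per-stage row counts; it carries no
timestamps so determinism is checkable by file comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from efcascade import __version__
from efcascade.celltypes import ZONES, classify_table
from efcascade.de import gene_de, lineage_enrichment, probe_de
from efcascade.gradients import classify_gradient_table
from efcascade.network import (
    build_network,
    export_network,
    find_motifs,
    render_report,
    summarize,
)
from efcascade.peaks import call_binding
from efcascade.regulation import call_regulation, call_synergy, pair_label
from efcascade.simulate import SYNERGY_PAIR, TF_GENOTYPE, TFS, simulate_study

log = logging.getLogger(__name__)

DEFAULT_TF_ORDER = ("Pax6", "Tbr2", "Tbr1")


@dataclass
class RunConfig:
    """Configuration for a simulation-backed end-to-end run."""

    seed: int = 0
    n_genes: int = 400
    alpha: float = 0.05
    window_bp: int = 50_000
    detect_floor: float = 0.2
    dominance_frac: float = 0.5
    rho_threshold: float = 0.8
    n_perm: int = 2_000
    tf_order: tuple[str, ...] = DEFAULT_TF_ORDER
    exclusions: tuple[tuple[str, str], ...] = ()
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if not 0 < self.dominance_frac <= 1:
            raise ValueError("dominance_frac must be in (0, 1]")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tf_order" in raw:
            raw["tf_order"] = tuple(raw["tf_order"])
        if "exclusions" in raw:
            raw["exclusions"] = tuple(tuple(x) for x in raw["exclusions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tf_order"] = list(self.tf_order)
        d["exclusions"] = [list(x) for x in self.exclusions]
        return d


def mutant_summaries(
    study, alpha: float
) -> tuple[dict[str, dict[str, pd.DataFrame]], dict[str, pd.DataFrame]]:
    """Gene-level mutant-vs-control summaries per TF and for the dKO.

    Returns (single, double): single maps tf -> experiment -> summary for
    every experiment that carries both the TF's mutant genotype and the
    control; double maps experiment -> dKO summary.
    """
    single: dict[str, dict[str, pd.DataFrame]] = {}
    for tf in TFS:
        genotype = TF_GENOTYPE[tf]
        per_exp = {}
        for exp in study.design.experiments_covering(genotype):
            probes = probe_de(
                study.matrix,
                study.sample_sheet,
                group_a=genotype,
                group_b=study.design.control,
                experiment_id=exp,
                alpha=alpha,
            )
            per_exp[exp] = gene_de(probes, study.probe_map, alpha=alpha)
        if per_exp:
            single[tf] = per_exp
    double: dict[str, pd.DataFrame] = {}
    dko = TF_GENOTYPE[pair_label(*SYNERGY_PAIR)]
    for exp in study.design.experiments_covering(dko):
        probes = probe_de(
            study.matrix,
            study.sample_sheet,
            group_a=dko,
            group_b=study.design.control,
            experiment_id=exp,
            alpha=alpha,
        )
        double[exp] = gene_de(probes, study.probe_map, alpha=alpha)
    return single, double


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full pipeline on a simulated study; returns the artifact dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    log.info("stage simulate: %d genes, seed %d", config.n_genes, config.seed)
    study = simulate_study(
        n_genes=config.n_genes,
        seed=config.seed,
        window_bp=config.window_bp,
        **config.sim_overrides,
    )
    inputs = study.write(outdir / "inputs")
    counts["genes"] = len(study.gene_models)
    counts["peaks"] = len(study.peaks)
    counts["probes"] = len(study.matrix)
    counts["samples"] = len(study.sample_sheet)

    log.info("stage annotate")
    binding = call_binding(study.peaks, study.gene_models, window_bp=config.window_bp)
    binding.to_csv(outdir / "binding_calls.tsv", sep="\t", index=False)
    counts["binding_calls"] = len(binding)

    log.info("stage de")
    single, double = mutant_summaries(study, alpha=config.alpha)
    for tf, per_exp in single.items():
        for exp, df in per_exp.items():
            df.to_csv(outdir / f"gene_de_{tf}_{exp}.tsv", sep="\t", index=False)
    for exp, df in double.items():
        df.to_csv(outdir / f"gene_de_dKO_{exp}.tsv", sep="\t", index=False)
    lineage = lineage_enrichment(
        study.matrix, study.sample_sheet, study.probe_map, alpha=config.alpha
    )
    lineage.to_csv(outdir / "lineage_enrichment.tsv", sep="\t", index=False)
    counts["lineage_genes"] = len(lineage)

    log.info("stage classify")
    celltypes = classify_table(
        lineage,
        study.zonal_profiles,
        detect_floor=config.detect_floor,
        dominance_frac=config.dominance_frac,
        cortex_specific={
            g: lbl.startswith("PN-") for g, lbl in study.truth.cell_type.items()
        },
    )
    celltypes.to_csv(outdir / "celltype_calls.tsv", sep="\t", index=False)
    counts["celltype_calls"] = len(celltypes)

    log.info("stage gradients")
    gradients = classify_gradient_table(
        study.gradient_profiles,
        rho_threshold=config.rho_threshold,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    gradients.to_csv(outdir / "gradient_calls.tsv", sep="\t", index=False)
    counts["gradient_calls"] = len(gradients)

    log.info("stage targets")
    calls = call_regulation(
        binding, single, exclusions=config.exclusions, alpha=config.alpha
    )
    synergy = call_synergy(
        binding, single, double, tf_pair=SYNERGY_PAIR, alpha=config.alpha
    )
    regulation = pd.concat([calls, synergy], ignore_index=True)
    regulation.to_csv(outdir / "regulation_calls.tsv", sep="\t", index=False)
    counts["regulation_calls"] = len(regulation)

    log.info("stage network")
    graph = build_network(regulation)
    export_network(graph, outdir / "network.tsv", "tsv")
    export_network(graph, outdir / "network.sif", "sif")
    export_network(graph, outdir / "network.graphml", "graphml")
    counts["network_edges"] = graph.number_of_edges()

    log.info("stage report")
    motifs = find_motifs(graph, config.tf_order)
    summary = summarize(graph, celltypes, gradients)
    summary["motifs"] = {
        "feedforward_chains": [list(p) for p in motifs.feedforward_chains],
        "feedback_edges": [list(e) for e in motifs.feedback_edges],
        "autoregulation": [list(e) for e in motifs.autoregulation],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "report.md").write_text(render_report(summary))

    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "tool": "efcascade",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %s", outdir)
    return outdir


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

_EXPECTED = {
    "gene_models.bed": None,
    "expression.tsv": None,
    "sample_sheet.tsv": ["sample_id", "genotype", "experiment", "lineage_fraction", "replicate"],
    "probe_map.tsv": ["probe_id", "gene_id"],
    "zonal_profiles.tsv": ["gene_id", *ZONES],
    "gradient_profiles.tsv": ["gene_id", "zone_context"],
}


def validate_inputs(input_dir: str | Path) -> list[str]:
    """Check a pipeline input directory; returns a list of violations.

    Checks file existence, required columns, probe->gene cross-consistency
    with the gene models, and zone/bin column ordering.  An empty list
    means the inputs are clean.
    """
    input_dir = Path(input_dir)
    problems: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in _EXPECTED.items():
        path = input_dir / name
        if not path.exists():
            problems.append(f"{name}: file missing")
            continue
        if name.endswith(".tsv"):
            df = pd.read_csv(path, sep="\t")
            tables[name] = df
            for col in cols or []:
                if col not in df.columns:
                    problems.append(f"{name}: missing column {col!r}")

    gene_ids: set[str] = set()
    gene_path = input_dir / "gene_models.bed"
    if gene_path.exists():
        try:
            from efcascade.peaks import read_gene_models

            gene_ids = {g.gene_id for g in read_gene_models(gene_path)}
        except ValueError as exc:
            problems.append(str(exc))

    pm = tables.get("probe_map.tsv")
    if pm is not None and gene_ids and "gene_id" in pm.columns:
        unknown = sorted(set(pm["gene_id"].astype(str)) - gene_ids)
        if unknown:
            problems.append(
                f"probe_map.tsv: {len(unknown)} probes reference unknown genes "
                f"(e.g. {unknown[0]})"
            )
        if "probe_id" in pm.columns and pm["probe_id"].duplicated().any():
            problems.append("probe_map.tsv: duplicate probe_id values")

    expr = tables.get("expression.tsv")
    sheet = tables.get("sample_sheet.tsv")
    if expr is not None and sheet is not None and "sample_id" in sheet.columns:
        sample_cols = [c for c in expr.columns if c != "probe_id"]
        missing = sorted(set(sample_cols) - set(sheet["sample_id"].astype(str)))
        if missing:
            problems.append(
                f"expression.tsv: {len(missing)} sample columns absent from "
                f"sample sheet (e.g. {missing[0]})"
            )

    zonal = tables.get("zonal_profiles.tsv")
    if zonal is not None:
        present = [c for c in zonal.columns if c in ZONES]
        if present != [z for z in ZONES if z in present]:
            problems.append("zonal_profiles.tsv: zone columns out of VZ->CP order")

    grad = tables.get("gradient_profiles.tsv")
    if grad is not None:
        bins = [c for c in grad.columns if c.startswith("bin_")]
        order = sorted(bins, key=lambda c: int(c.split("_")[1]))
        if bins != order:
            problems.append("gradient_profiles.tsv: bin columns out of order")
        if 0 < len(bins) < 3:
            problems.append("gradient_profiles.tsv: fewer than 3 bins")
    return problems
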
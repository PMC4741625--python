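"""End-to-end pipeline: DEG filter -> promoters -> scan -> gene sets ->
enrichment -> composite-module GA -> master-regulator search.

The configuration carries either paths to the four real inputs (expression
signals/calls/groups, genome + annotation, matrix library, network edge list)
or a ``simulate`` block, in which case the synthetic generators produce all
inputs with planted ground truth.  All randomness flows from the single global
seed; a rerun with the same config writes a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import expression as xp
from . import modules as cm
from . import pwm as pw
from . import regulators as mr
from . import simulate as sim

logger = logging.getLogger(__name__)

STAGES = ("deg", "promoters", "scan", "gene_sets", "enrichment", "cma", "mr")


class ConfigError(ValueError):
    pass


@dataclass
class SimulateProfile:
    """Scale of the synthetic study; defaults are the fast desk-scale run."""

    n_genes: int = 300
    n_per_group: int = 10
    effect_log2fc: float = float(np.log2(3))
    frac_deg: float = 0.1
    frac_down: float = 0.0
    call_error_rate: float = 0.02
    n_promoter_background: int = 100
    n_matrices: int = 12
    module_partners: int = 2
    module_distance: int = 100
    plant_floor: float = 0.9
    network_nodes: int = 300
    network_mean_out_degree: float = 2.0
    wired_fraction: float = 2 / 3


@dataclass
class PipelineConfig:
    outdir: str = "mycnet_out"
    seed: int = 0
    deg_preset: str = "tumor"  # tumor | transgenic
    group_a: str = "control"
    group_b: str = "case"
    core_cutoff: float = pw.DEFAULT_CORE_CUTOFF
    matrix_cutoff: float = pw.DEFAULT_MATRIX_CUTOFF
    ga_preset: str = "fast"  # fast | full
    ga_mutation_rate: float = 0.25
    mr_params: mr.MRParams = field(default_factory=mr.MRParams)
    simulate: SimulateProfile | None = field(default_factory=SimulateProfile)
    # external-input paths (used when simulate is None)
    signals_path: str | None = None
    calls_path: str | None = None
    groups_path: str | None = None
    genome_path: str | None = None
    annotation_path: str | None = None
    pwm_path: str | None = None
    network_path: str | None = None

    def __post_init__(self) -> None:
        if self.deg_preset not in {"tumor", "transgenic"}:
            raise ConfigError(f"unknown DEG preset {self.deg_preset!r}")
        if self.ga_preset not in {"fast", "full"}:
            raise ConfigError(f"unknown GA preset {self.ga_preset!r}")

    @property
    def deg_criteria(self) -> xp.DEGCriteria:
        return xp.TUMOR_CRITERIA if self.deg_preset == "tumor" else xp.TRANSGENIC_CRITERIA

    def ga_config(self, seed: int) -> cm.GAConfig:
        factory = cm.GAConfig.fast if self.ga_preset == "fast" else cm.GAConfig.full
        return factory(mutation_rate=self.ga_mutation_rate, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "deg_criteria" in raw:
            raise ConfigError("set deg_preset, not deg_criteria")
        if "mr_params" in raw:
            raw["mr_params"] = mr.MRParams(**raw["mr_params"])
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulateProfile(**raw["simulate"])
        return cls(**raw)


def _seed_stream(seed: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the global one."""
    ss = np.random.SeedSequence(seed)
    names = ("expression", "pwms", "promoters", "network", "ga", "mr")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage in order; write stage outputs and a summary JSON."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(config.seed)
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}

    try:
        inputs = _prepare_inputs(config, out, seeds)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    stage_fns = {
        "deg": _stage_deg,
        "promoters": _stage_promoters,
        "scan": _stage_scan,
        "gene_sets": _stage_gene_sets,
        "enrichment": _stage_enrichment,
        "cma": _stage_cma,
        "mr": _stage_mr,
    }
    state: dict[str, Any] = {"inputs": inputs, "config": config, "out": out, "seeds": seeds}
    for name in STAGES:
        logger.info("stage %s (seed=%d)", name, config.seed)
        try:
            summary["stages"][name] = stage_fns[name](state)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _prepare_inputs(config: PipelineConfig, out: Path, seeds: dict[str, int]) -> dict[str, Any]:
    if config.simulate is None:
        required = ("signals_path", "calls_path", "groups_path", "genome_path",
                    "annotation_path", "pwm_path", "network_path")
        missing = [k for k in required if getattr(config, k) is None]
        if missing:
            raise ConfigError(f"missing input paths: {missing}")
        expr = xp.load_expression(config.signals_path, config.calls_path, config.groups_path)
        pwms = pw.load_pwms(config.pwm_path, core_cutoff=config.core_cutoff,
                            matrix_cutoff=config.matrix_cutoff)
        return {
            "expr": expr,
            "pwms": pwms,
            "genome_path": config.genome_path,
            "annotation_path": config.annotation_path,
            "network_path": config.network_path,
            "truth": None,
        }

    prof = config.simulate
    expr, expr_truth = sim.simulate_expression(
        n_genes=prof.n_genes,
        n_per_group=prof.n_per_group,
        effect_log2fc=prof.effect_log2fc,
        frac_deg=prof.frac_deg,
        frac_down=prof.frac_down,
        call_error_rate=prof.call_error_rate,
        seed=seeds["expression"],
    )
    pwm_path = out / "pwms.jaspar"
    pwms = sim.simulate_pwm_library(prof.n_matrices, seed=seeds["pwms"], path=pwm_path)
    # calibrated per-matrix cutoffs (stringent-profile style); the config
    # cutoffs act as floors
    for p in pwms:
        p.core_cutoff = config.core_cutoff
        p.matrix_cutoff = max(
            config.matrix_cutoff, pw.calibrate_matrix_cutoff(p, seed=seeds["pwms"])
        )

    yes_genes = sorted(expr_truth.planted_deg)
    background = [f"bg{i:05d}" for i in range(prof.n_promoter_background)]
    module_pwms = [pwms[0]] + list(pwms[1 : 1 + prof.module_partners])
    planting = {
        p.id: sim.PlantingSpec(
            genes=tuple(yes_genes),
            probability=1.0,
            score_floor=max(prof.plant_floor, p.matrix_cutoff),
        )
        for p in module_pwms
    }
    fasta = out / "promoters.fa"
    ann = out / "promoters.tsv"
    for stale in (fasta.with_suffix(".fa.fai"), Path(str(fasta) + ".fai")):
        stale.unlink(missing_ok=True)
    _, prom_truth = sim.simulate_promoters(
        genes=yes_genes + background,
        pwm_library=pwms,
        planting=planting,
        max_span=prof.module_distance,
        seed=seeds["promoters"],
        fasta_path=fasta,
        annotation_path=ann,
    )
    net_df, net_truth = sim.simulate_network(
        n_nodes=prof.network_nodes,
        mean_out_degree=prof.network_mean_out_degree,
        input_genes=yes_genes,
        wired_fraction=prof.wired_fraction,
        wiring_distance=1,
        seed=seeds["network"],
        path=out / "network.tsv",
    )
    truth = sim.SyntheticTruth(
        seed=config.seed,
        planted_deg=expr_truth.planted_deg,
        planted_motifs=prom_truth.planted_motifs,
        planted_module={
            "pwm_ids": [p.id for p in module_pwms],
            "max_pair_distance": prof.module_distance,
        },
        planted_regulator=net_truth.planted_regulator,
    )
    truth.to_json(out / "truth.json")
    return {
        "expr": expr,
        "pwms": pwms,
        "genome_path": str(fasta),
        "annotation_path": str(ann),
        "network_path": str(out / "network.tsv"),
        "truth": truth,
    }


def _stage_deg(state: dict) -> dict:
    config, inputs, out = state["config"], state["inputs"], state["out"]
    records = xp.compute_deg(inputs["expr"], config.group_a, config.group_b, config.deg_criteria)
    state["degs"] = records
    xp.deg_table(records).to_csv(out / "deg.tsv", sep="\t", index=False)
    block = {"n_deg": len(records), "n_up": sum(r.direction == "up" for r in records),
             "n_down": sum(r.direction == "down" for r in records)}
    truth = inputs["truth"]
    if truth is not None:
        venn = xp.compare_deg_sets({r.gene_id for r in records}, set(truth.planted_deg))
        block["venn_vs_planted"] = dataclasses.asdict(venn)
        (out / "venn.json").write_text(json.dumps(dataclasses.asdict(venn), sort_keys=True) + "\n")
    return block


def _stage_promoters(state: dict) -> dict:
    inputs = state["inputs"]
    proms = pw.extract_promoters(inputs["genome_path"], inputs["annotation_path"])
    state["promoters"] = proms
    return {"n_promoters": len(proms), "window": len(proms[0].seq) if proms else 0}


def _stage_scan(state: dict) -> dict:
    inputs, out = state["inputs"], state["out"]
    hits = pw.scan_promoters(inputs["pwms"], state["promoters"])
    state["hits"] = hits
    pw.hits_table(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    # permissive rescan feeding the GA, whose per-component cutoffs start at 0.5
    ga_pwms = [dataclasses.replace(p, core_cutoff=0.5, matrix_cutoff=0.5) for p in inputs["pwms"]]
    state["ga_hits"] = cm.index_hits(pw.scan_promoters(ga_pwms, state["promoters"]))
    return {"n_hits": len(hits), "n_genes_with_hits": len(pw.genes_with_hits(hits))}


def _stage_gene_sets(state: dict) -> dict:
    inputs = state["inputs"]
    all_genes = [p.gene_id for p in state["promoters"]]
    yes = {r.gene_id for r in state["degs"]} & set(all_genes)
    if not yes and inputs["truth"] is not None:
        # fall back to the planted foreground if the filter found nothing
        yes = set(inputs["truth"].planted_deg) & set(all_genes)
    myc_ids = [inputs["pwms"][0].id]
    sets = pw.build_gene_sets(all_genes, yes, background_regulated=set(), myc_pwm_ids=myc_ids,
                              hits=state["hits"])
    state["gene_sets"] = sets
    state["myc_ids"] = myc_ids
    return {"n_yes": len(sets.yes_set), "n_no": len(sets.no_set)}


def _stage_enrichment(state: dict) -> dict:
    inputs, out = state["inputs"], state["out"]
    sets = state["gene_sets"]
    table = pw.matrix_enrichment(inputs["pwms"], state["hits"], sets.yes_set, sets.no_set)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {"n_enriched": int(table["enriched"].sum()),
            "enriched_pwms": sorted(table.loc[table["enriched"], "pwm_id"])}


def _stage_cma(state: dict) -> dict:
    config, inputs, out, seeds = state["config"], state["inputs"], state["out"], state["seeds"]
    sets = state["gene_sets"]
    ga_hits = state["ga_hits"]
    empty: dict = {}
    yes_hits = {g: ga_hits.get(g, empty) for g in sets.yes_set}
    no_hits = {g: ga_hits.get(g, empty) for g in sets.no_set}
    ga_conf = config.ga_config(seeds["ga"])
    best, history = cm.run_ga(ga_conf, [p.id for p in inputs["pwms"]], yes_hits, no_hits,
                              myc_ids=state["myc_ids"])
    state["module"] = best
    cm.save_module(best, out / "module.json")
    (out / "ga_history.tsv").write_text(
        "iteration\tbest_fitness\n" + "".join(f"{i}\t{v:.6f}\n" for i, v in enumerate(history))
    )
    n_fit, pct = cm.module_coverage(best, yes_hits)
    block = {"components": sorted(best.pwm_ids), "max_pair_distance": best.max_pair_distance,
             "fitness": round(best.fitness, 6), "coverage_n": n_fit, "coverage_pct": pct}
    truth = inputs["truth"]
    if truth is not None and truth.planted_module:
        block["planted_recovered"] = sorted(best.pwm_ids) == sorted(truth.planted_module["pwm_ids"])
    return block


def _stage_mr(state: dict) -> dict:
    config, inputs, out, seeds = state["config"], state["inputs"], state["out"], state["seeds"]
    net = mr.load_network(inputs["network_path"])
    input_genes = sorted(set(g for g in (r.gene_id for r in state["degs"]) if g in net))
    if not input_genes and inputs["truth"] is not None:
        input_genes = sorted(set(inputs["truth"].planted_deg) & set(net.nodes))
    n_perm = max(config.mr_params.n_permutations,
                 mr.recommended_permutations(net.number_of_nodes(), config.mr_params.fdr_cutoff))
    params = dataclasses.replace(config.mr_params, seed=seeds["mr"], n_permutations=n_perm)
    results = mr.rank_master_regulators(net, input_genes, params)
    mr.results_table(results).to_csv(out / "master_regulators.tsv", sep="\t", index=False)
    top = results[0]
    block = {"n_candidates": len(results), "n_passing": sum(r.passes for r in results),
             "top": {"node": top.node, "score": round(top.score, 6),
                     "z": round(top.z_score, 3), "pct_of_inputs": top.network_fraction,
                     "passes": top.passes}}
    truth = inputs["truth"]
    if truth is not None and truth.planted_regulator:
        block["planted_recovered"] = top.node == truth.planted_regulator["hub"]
    return block


def make_report(outdir: str | Path,
                breakdown: xp.CategoryBreakdown | None = None,
                venn: xp.VennCounts | None = None,
                coverage_rows: list[tuple[str, int, int]] | None = None,
                mr_results: list[mr.MasterRegulatorResult] | None = None) -> dict[str, str]:
    """Emit the report bundle; sections with missing inputs are marked absent."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if breakdown is not None:
        path = out / "category_breakdown.tsv"
        breakdown.to_frame().to_csv(path, sep="\t", index=False, float_format="%.1f")
        written["breakdown"] = str(path)
    else:
        written["breakdown"] = "absent"
    if venn is not None:
        path = out / "venn.json"
        path.write_text(json.dumps(dataclasses.asdict(venn), sort_keys=True) + "\n")
        written["venn"] = str(path)
    else:
        written["venn"] = "absent"
    if coverage_rows is not None:
        path = out / "module_coverage.tsv"
        lines = ["label\tn_fit\tn_total\tpct"]
        for label, n_fit, n_total in coverage_rows:
            lines.append(f"{label}\t{n_fit}\t{n_total}\t{cm.coverage_percentage(n_fit, n_total)}%")
        path.write_text("\n".join(lines) + "\n")
        written["coverage"] = str(path)
    else:
        written["coverage"] = "absent"
    if mr_results is not None:
        path = out / "master_regulators.tsv"
        mr.results_table(mr_results).to_csv(path, sep="\t", index=False)
        written["mr"] = str(path)
    else:
        written["mr"] = "absent"
    return written
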
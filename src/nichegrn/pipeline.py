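"""End-to-end orchestration: discretize -> contextualize -> SCC -> pairs.

One seeded configuration drives the whole comparative analysis of the two
sites; every stage consumes only prior-stage outputs, intermediates are
written as TSV/SIF, and the consolidated report is machine-readable JSON.
Rerunning with the same config and seed reproduces all outputs
byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boolean import GAParams, booleanize, consistency_score, contextualize
from .discretize import (differential_qe, distribution_stats, quartile_profile,
                         summarize_to_gene)
from .errors import FormatError
from .io import (BaselineReference, read_baseline, read_expression,
                 read_network, read_probe_map, read_sample_sheet, write_network,
                 write_table)
from .pairs import filter_candidates, evaluate_pairs
from .synthetic import SynthConfig, generate_dataset
from .topology import compare_sccs, find_sccs, out_degree_interface

logger = logging.getLogger("nichegrn.pipeline")


@dataclass
class RunConfig:
    """Everything one analysis run needs; defaults follow the method."""

    outdir: str
    seed: int
    synth: SynthConfig | None = None
    # file-based inputs (used when synth is None)
    expr_a: str | None = None
    expr_b: str | None = None
    sheet: str | None = None
    probemap: str | None = None
    network: str | None = None
    baseline: str | None = None
    tf_file: str | None = None
    # stage parameters
    k: int = 4
    qde_threshold: int = 2
    on_threshold: int = 3
    ga_population: int = 200
    ga_generations: int = 500
    removal_penalty: float = 0.1
    alpha: float = 0.05
    trim_fraction: float = 0.025
    top_k: int = 3
    write_inputs: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        synth = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synth = SynthConfig(**synth)
        return cfg


def _derive_seeds(seed: int, n: int):
    """Child seeds below 2^31, deterministic in the master seed."""
    return [int(s) % (2 ** 31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _load_inputs(config: RunConfig):
    if config.synth is not None:
        ds = generate_dataset(config.synth)
        tf_list = ds.truth.tf_list
        return ds.expr_a, ds.expr_b, ds.sheet, ds.probemap, ds.baseline, \
            ds.prior, tf_list, ds.truth
    needed = ["expr_a", "expr_b", "sheet", "probemap", "network", "baseline"]
    missing = [k for k in needed if getattr(config, k) is None]
    if missing:
        raise FormatError(f"run config missing inputs: {missing}")
    expr_a = read_expression(config.expr_a, platform_tag="microarray")
    expr_b = read_expression(config.expr_b, platform_tag="rnaseq-fpkm")
    sheet = read_sample_sheet(config.sheet)
    probemap = read_probe_map(config.probemap)
    prior = read_network(config.network)
    baseline = read_baseline(config.baseline)
    tf_list = None
    if config.tf_file:
        tf_list = [line.strip() for line in open(config.tf_file) if line.strip()]
    return expr_a, expr_b, sheet, probemap, baseline, prior, tf_list, None


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write intermediates under ``outdir``, return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr_a, expr_b, sheet, probemap, baseline, prior, tf_list, truth = \
        _load_inputs(config)

    # --- discretization
    summary_a = summarize_to_gene(expr_a, probemap, sheet)
    summary_b = summarize_to_gene(expr_b, probemap, sheet)
    qe_a = quartile_profile(summary_a, k=config.k)
    qe_b = quartile_profile(summary_b, k=config.k)
    stats_a = distribution_stats(expr_a, sheet)
    stats_b = distribution_stats(expr_b, sheet)
    if baseline.quartiles is None:
        from .discretize import quartile_expression
        baseline = BaselineReference(
            baseline.values,
            quartile_expression(pd.Series(baseline.values), k=config.k).to_dict(),
        )

    diff_cross = differential_qe(qe_a.region("stemA"), qe_b.region("stemB"),
                                 "stemA", "stemB", threshold=config.qde_threshold)
    diff_site_a = differential_qe(qe_a.region("diffA"), qe_a.region("stemA"),
                                  "diffA", "stemA", threshold=config.qde_threshold)
    diff_site_b = differential_qe(qe_b.region("diffB"), qe_b.region("stemB"),
                                  "diffB", "stemB", threshold=config.qde_threshold)
    for name, d in (("differential_stemA_vs_stemB", diff_cross),
                    ("differential_diffA_vs_stemA", diff_site_a),
                    ("differential_diffB_vs_stemB", diff_site_b)):
        write_table(d.table, out / f"{name}.tsv")
    write_table(qe_a.qe.reset_index(names="gene_id"), out / "qe_siteA.tsv")
    write_table(qe_b.qe.reset_index(names="gene_id"), out / "qe_siteB.tsv")
    write_table(pd.concat([stats_a.table, stats_b.table]), out / "distribution_stats.tsv")

    # --- Booleanization and contextualization, one network per site
    seeds = _derive_seeds(config.seed, 2)
    nets, reports, sccs, states_stem = {}, {}, {}, {}
    for site, qe, stem, diff, seed in (
        ("site_a", qe_a, "stemA", "diffA", seeds[0]),
        ("site_b", qe_b, "stemB", "diffB", seeds[1]),
    ):
        states = [
            booleanize(qe.region(stem), genes=sorted(prior.nodes),
                       on_threshold=config.on_threshold, label=stem),
            booleanize(qe.region(diff), genes=sorted(prior.nodes),
                       on_threshold=config.on_threshold, label=diff),
        ]
        params = GAParams(seed=seed, population=config.ga_population,
                          generations=config.ga_generations,
                          removal_penalty=config.removal_penalty)
        net, report = contextualize(prior, states, params)
        nets[site], reports[site] = net, report
        states_stem[site] = states[0]
        write_network(net, out / f"contextualized_{site}.sif")
        sccs[site] = find_sccs(net, label=site)

    overlap = None
    rankings = {}
    for site in nets:
        if sccs[site].components:
            rankings[site] = out_degree_interface(
                sccs[site].designated(), nets[site], top_k=config.top_k)
            write_table(rankings[site].entries, out / f"ranking_{site}.tsv")
    if all(s.components for s in sccs.values()):
        overlap = compare_sccs(
            sccs["site_a"], states_stem["site_a"],
            sccs["site_b"], states_stem["site_b"],
            diff_a=diff_cross, diff_b=diff_cross,
        )
        write_table(overlap.shared, out / "scc_overlap_shared.tsv")

    # --- fate pairs (site A lineage: stem vs differentiated)
    pairs_block = None
    if tf_list:
        results = evaluate_pairs(summary_a.log2(), tf_list, "stemA", "diffA",
                             trim_fraction=config.trim_fraction, alpha=config.alpha)
        write_table(results, out / "pair_tests.tsv")
        candidates = filter_candidates(
            results, qe_a.region("stemA"), qe_a.region("diffA"), baseline,
            sccs["site_a"].designated() if sccs["site_a"].components else frozenset(),
            prior, alpha=config.alpha, qde_threshold=config.qde_threshold,
        )
        write_table(candidates, out / "candidate_pairs.tsv")
        pairs_block = {
            "n_pairs": int(len(results)),
            "n_significant": int(results["significant"].sum()),
            "n_candidates": int(len(candidates)),
            "candidates": [
                {"gene1": r.gene1, "gene2": r.gene2, "d": round(float(r.d), 6),
                 "p_adj": float(r.p_adj)}
                for r in candidates.itertuples(index=False)
            ],
        }

    report = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "params": {
            "k": config.k, "qde_threshold": config.qde_threshold,
            "on_threshold": config.on_threshold,
            "ga": {"population": config.ga_population,
                   "generations": config.ga_generations,
                   "removal_penalty": config.removal_penalty},
            "alpha": config.alpha, "trim_fraction": config.trim_fraction,
        },
        "distribution_stats": {
            row["region"]: {"skewness": round(float(row["skewness"]), 4),
                            "kurtosis": round(float(row["kurtosis"]), 4)}
            for _, row in pd.concat([stats_a.table, stats_b.table]).iterrows()
        },
        "differential": {
            "stemA_vs_stemB": {
                "n_significant": diff_cross.n_significant,
                "up_in_stemA": diff_cross.n_up_in_x,
                "up_in_stemB": diff_cross.n_up_in_y,
            },
        },
        "contextualization": {
            site: {
                "overall_consistency": round(rep.overall, 6),
                "per_state": {k: round(v, 6) for k, v in rep.per_state.items()},
                "edges_removed": len(rep.edges_removed),
                "signs_assigned": len(rep.signs_assigned),
                "seed": rep.seed,
            }
            for site, rep in reports.items()
        },
        "scc": {
            site: {
                "sizes": [len(c) for c in sccs[site].components],
                "masters": rankings[site].masters if site in rankings else [],
            }
            for site in sccs
        },
        "scc_overlap": None if overlap is None else {
            "n_shared": int(len(overlap.shared)),
            "n_shared_agreeing": overlap.n_shared_agreeing,
            "unique_to_a": len(overlap.unique_to_a),
            "unique_to_b": len(overlap.unique_to_b),
        },
        "pairs": pairs_block,
    }
    if truth is not None:
        planted_sig = set(truth.de_genes)
        indexed = diff_cross.table.set_index("gene_id")
        found = set(indexed.index[indexed["significant"]])
        recovered = sum(
            1 for g, shift in truth.de_genes.items()
            if g in found and np.sign(indexed.at[g, "qde"]) == np.sign(shift)
        )
        report["ground_truth"] = {
            "n_planted_de": len(planted_sig),
            "de_recovery_sensitivity": round(recovered / max(len(planted_sig), 1), 4),
            "planted_pairs": [[u, p] for u, p, _ in truth.planted_pairs],
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
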
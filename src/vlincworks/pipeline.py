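"""End-to-end orchestration: simulate -> quantify -> annotate -> build genes
-> neighbour correlation -> class metrics -> regulators -> GO, with a
manifest of every output.

The pipeline is driven by a single config mapping (YAML on disk) whose one
mandatory key is ``seed``; any :class:`~vlincworks.simulate.SimulationConfig`
field can be overridden at the top level, and stage-level knobs sit under
``pipeline:``.  All randomness fans out from the root seed through named
substreams, so config + seed fully determine every output file.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import LTR, annotate_vlincs
from .classmetrics import (
    CANCER,
    SampleTable,
    class_fraction_tests,
    label_permutation_test,
    mass_fractions,
    max_location_counts,
    rmecn,
    timecourse_trend,
    top_n_class_enrichment,
)
from .genes import designate_all
from .go import build_profiles, make_synthetic_ontology, subset_enrichment
from .intervals import GenomicInterval
from .neighbors import correlation_table, nearest_neighbor_sets
from .quantify import build_expression_matrix, effective_length
from .regulators import (
    flank_peak_enrichment,
    mirna_surrogate_expression,
    mirna_target_profile,
    tf_group_correlations,
    vlinc_tf_groups,
)
from .simulate import SimulationConfig, SimulatedWorld, simulate_world


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: dict[str, tuple[str, int]]) -> None:
        for path, rows in outputs.values():
            if not os.path.exists(path) or os.path.getsize(path) == 0:
                raise RuntimeError(f"stage {name}: declared output missing: {path}")
        self.stages.append(
            {
                "name": name,
                "outputs": {
                    key: {"path": path, "rows": rows}
                    for key, (path, rows) in outputs.items()
                },
            }
        )


def _simulation_config(cfg: dict) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    kwargs = {k: v for k, v in cfg.items() if k in known}
    return SimulationConfig(**kwargs)


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: str, **kw) -> tuple[str, int]:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)
    return path, len(df)


def run_pipeline(cfg: dict, outdir: str | os.PathLike) -> RunManifest:
    """Run every stage on a simulated world and write all summary tables.

    Raises at the failing stage; on success the manifest lists each stage's
    outputs with row counts.
    """
    if "seed" not in cfg:
        raise KeyError("config missing required key 'seed'")
    os.makedirs(outdir, exist_ok=True)
    out = os.fspath(outdir)
    pipe = cfg.get("pipeline", {}) or {}
    manifest = RunManifest(_hash_config(cfg), int(cfg["seed"]), __version__)

    # --- simulate ---------------------------------------------------------
    sim_cfg = _simulation_config(cfg)
    world = simulate_world(sim_cfg)
    from .io import write_annotation_bundle

    write_annotation_bundle(world.bundle, os.path.join(out, "annotation"))
    world.samples.write_tsv(os.path.join(out, "samples.tsv"))
    manifest.add(
        "simulate",
        {
            "samples": (os.path.join(out, "samples.tsv"), len(world.samples.table)),
            "vlincs": (
                os.path.join(out, "annotation", "vlincs.bed"),
                len(world.bundle.vlincs),
            ),
        },
    )

    # --- quantify ---------------------------------------------------------
    expr = build_expression_matrix(world.tagsets, world.bundle, mode="internal")
    manifest.add(
        "quantify",
        {"expression": _write(expr.values, os.path.join(out, "expression.tsv"))},
    )

    # --- annotate ---------------------------------------------------------
    anns = annotate_vlincs(world.bundle)
    ann_df = pd.DataFrame(
        [
            {
                "vlinc_id": a.vlinc_id,
                "category": a.promoter_category,
                "promoters": ",".join(a.assigned_promoters),
                "distal": a.distal,
                **{f"tf_{f}": flag for f, flag in sorted(a.tf_status.items())},
            }
            for a in anns.values()
        ]
    ).set_index("vlinc_id")
    manifest.add(
        "annotate",
        {"annotation": _write(ann_df, os.path.join(out, "vlinc_annotation.tsv"))},
    )

    # --- build genes ------------------------------------------------------
    calls, vgenes = designate_all(
        world.bundle.vlincs, world.bundle.genes, world.bundle.insulators
    )
    calls_df = pd.DataFrame(
        [{"vlinc_id": c.vlinc_id, "standalone": c.standalone, "reason": c.reason}
         for c in calls]
    ).set_index("vlinc_id")
    genes_df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "strand": g.interval.strand,
                "members": ",".join(g.member_vlinc_ids),
            }
            for g in vgenes
        ]
    ).set_index("gene_id")
    manifest.add(
        "build_genes",
        {
            "standalone": _write(calls_df, os.path.join(out, "standalone_calls.tsv")),
            "vlinc_genes": _write(genes_df, os.path.join(out, "vlinc_genes.tsv")),
        },
    )

    # --- neighbour correlation -------------------------------------------
    vg_pairs = nearest_neighbor_sets(
        world.bundle.vlincs, world.bundle.genes, "vlinc-gene",
        world.bundle.insulators,
    )
    gg_pairs = nearest_neighbor_sets(
        world.bundle.genes, world.bundle.genes, "gene-gene",
        world.bundle.insulators,
        horizon=pipe.get("gene_pair_horizon", 50_000),
    )
    table = correlation_table(
        expr, vg_pairs + gg_pairs, min_features=pipe.get("min_features", 1)
    )
    manifest.add(
        "neighbors",
        {
            "correlation_table": _write(
                table, os.path.join(out, "correlation_table.tsv"), index=False
            )
        },
    )

    # --- class metrics ----------------------------------------------------
    results, medians, n_undef = rmecn(expr, world.samples, anns)
    rmecn_df = pd.DataFrame(
        [
            {
                "vlinc_id": r.vlinc_id,
                "max_cancer": r.max_cancer,
                "max_normal": r.max_normal,
                "rmecn": r.rmecn,
                "category": r.category,
            }
            for r in results
        ]
    ).set_index("vlinc_id")
    observed, perm_p, _ = label_permutation_test(
        expr, world.samples, anns,
        n_perm=pipe.get("n_perm", 500), seed=sim_cfg.seed + 11,
    )
    tbl, fisher_p = max_location_counts(expr, world.samples, anns)

    frag_of = {
        v.id: effective_length(v, world.bundle)[0] for v in world.bundle.vlincs
    }
    distal_ltr = [
        frag_of[a.vlinc_id] for a in anns.values()
        if a.distal and a.promoter_category == LTR and frag_of[a.vlinc_id]
    ]
    distal_non = [
        frag_of[a.vlinc_id] for a in anns.values()
        if a.distal and a.promoter_category == "nonLTR" and frag_of[a.vlinc_id]
    ]
    fracs = mass_fractions(
        world.tagsets,
        {"distal_LTR": distal_ltr, "distal_nonLTR": distal_non},
        list(frag_of.values()),
    )
    top = top_n_class_enrichment(
        fracs["distal_LTR_of_informative"], world.samples,
        n=pipe.get("top_n", 20), klass=CANCER,
    )
    pmat, class_medians = class_fraction_tests(
        fracs["distal_LTR_of_informative"], world.samples
    )
    tc_ids = world.truth.timecourse_sample_ids
    trend = timecourse_trend(
        fracs.loc[tc_ids, "distal_LTR_of_informative"].to_numpy()
    )
    summary = pd.DataFrame(
        [
            {"metric": "median_rmecn_LTR", "value": medians[LTR]},
            {"metric": "median_rmecn_nonLTR", "value": medians["nonLTR"]},
            {"metric": "rmecn_undefined", "value": n_undef},
            {"metric": "perm_observed_ratio", "value": observed},
            {"metric": "perm_p", "value": perm_p},
            {"metric": "max_in_cancer_fisher_p", "value": fisher_p},
            {"metric": "top_n_cancer_p", "value": top["p"]},
            {"metric": "top_n_cancer_observed", "value": top["observed"]},
            {"metric": "top_n_cancer_expected", "value": top["expected"]},
            {"metric": "timecourse_trend_slope", "value": trend.slope},
            {"metric": "timecourse_trend_p",
             "value": trend.p if trend.p is not None else float("nan")},
        ]
    )
    manifest.add(
        "class_metrics",
        {
            "rmecn": _write(rmecn_df, os.path.join(out, "rmecn.tsv")),
            "fractions": _write(fracs, os.path.join(out, "mass_fractions.tsv")),
            "class_tests": _write(pmat, os.path.join(out, "class_mww.tsv")),
            "summary": _write(
                summary, os.path.join(out, "class_summary.tsv"), index=False
            ),
        },
    )

    # --- regulators: miRNA targets and TF coupling ------------------------
    mir_expr = mirna_surrogate_expression(world.tagsets, world.mirna_records)
    summaries, ks_p, n_dropped = mirna_target_profile(
        expr, mir_expr, world.mirna_records, seed=sim_cfg.seed + 13
    )
    mir_df = pd.DataFrame(
        [
            {
                "mirna_id": s.id,
                "median_rho_real": s.median_rho_real,
                "median_rho_random": s.median_rho_random,
                "n_targets": s.n_targets_used,
            }
            for s in summaries
        ]
    )
    tc_expr = expr.values[tc_ids]
    groups = {
        f: vlinc_tf_groups(anns, f) for f in world.truth.tf_feature_ids
    }
    _, tf_contrasts = tf_group_correlations(
        tc_expr, world.truth.tf_feature_ids, groups
    )
    flanks = [
        GenomicInterval(v.chrom, max(0, v.body.five_prime() - 5_000),
                        v.body.five_prime() + 5_000)
        for v in world.bundle.vlincs
        if v.strand != "."
    ]
    enrich = flank_peak_enrichment(
        flanks, world.bundle.tf_peaks, world.bundle.chrom_sizes,
        n_perm=pipe.get("flank_n_perm", 200), seed=sim_cfg.seed + 17,
    )
    enrich_df = pd.DataFrame(
        [{"factor": f, **vals} for f, vals in enrich.items()]
    )
    manifest.add(
        "regulators",
        {
            "mirna": _write(mir_df, os.path.join(out, "mirna_targets.tsv"), index=False),
            "tf_contrasts": _write(
                tf_contrasts, os.path.join(out, "tf_contrasts.tsv"), index=False
            ),
            "flank_enrichment": _write(
                enrich_df, os.path.join(out, "flank_enrichment.tsv"), index=False
            ),
        },
    )

    # --- GO enrichment ----------------------------------------------------
    gene_ids = [g.id for g in world.bundle.genes]
    _, gene_go = make_synthetic_ontology(sim_cfg.seed + 19, gene_ids)
    member_anns = {g.gene_id: g.member_vlinc_ids for g in vgenes}
    vg_expr = pd.DataFrame(
        {
            gid: expr.values.reindex(list(members)).mean(axis=0)
            for gid, members in member_anns.items()
        }
    ).T
    profiles = build_profiles(expr, vg_expr, gene_go)
    pluri = [
        gid for gid, members in member_anns.items()
        if any(
            anns[m].promoter_category == LTR and anns[m].any_tf for m in members
        )
    ]
    go_df = (
        subset_enrichment(profiles, pluri, "pos")
        if pluri
        else pd.DataFrame(columns=["term", "p_raw", "ExpCount", "Count", "Size", "p_adj"])
    )
    prof_df = pd.DataFrame(
        [
            {
                "vlinc_gene_id": p.vlinc_gene_id,
                "n_pos_terms": len(p.pos_terms),
                "n_neg_terms": len(p.neg_terms),
            }
            for p in profiles
        ]
    )
    manifest.add(
        "go_enrichment",
        {
            "profiles": _write(
                prof_df, os.path.join(out, "go_profiles.tsv"), index=False
            ),
            "enrichment": _write(
                go_df, os.path.join(out, "go_enrichment.tsv"), index=False
            ),
        },
    )

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest


def report(outdir: str | os.PathLike) -> str:
    """Render the run's main tables into one readable text summary."""
    out = os.fspath(outdir)
    with open(os.path.join(out, "manifest.json")) as fh:
        manifest = json.load(fh)
    lines = [
        f"vlincworks run (seed={manifest['seed']}, config {manifest['config_hash']})",
        "",
    ]
    for fname, title in [
        ("class_summary.tsv", "Class metrics"),
        ("correlation_table.tsv", "Neighbour correlation (two-stage medians)"),
        ("mirna_targets.tsv", "miRNA target coupling"),
        ("flank_enrichment.tsv", "TF peak flank enrichment"),
        ("go_enrichment.tsv", "GO enrichment (pluripotency-associated set)"),
    ]:
        path = os.path.join(out, fname)
        lines.append(f"== {title} ==")
        if not os.path.exists(path):
            lines.append("(no data)\n")
            continue
        df = pd.read_csv(path, sep="\t")
        if fname == "correlation_table.tsv":
            df = df[(df["stratum"] == "all") & df["median_rho"].notna()]
        lines.append(df.to_string(index=False) if len(df) else "(no data)")
        lines.append("")
    return "\n".join(lines)
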
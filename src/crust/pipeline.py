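"""End-to-end orchestration with a reproducible run manifest.

Stages execute in dependency order (coverage -> islands -> annotate on the
recruitment branch; qc, taxonomy, hosts, amgs on the curation branch;
tpm on the abundance branch).  Every stage records its parameters, input
and output checksums and basic record counts in the manifest, and a rerun
with an identical config produces byte-identical outputs and manifest.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Any

import pandas as pd
import yaml

from . import abundance as ab
from . import annotate as an
from . import hosts as ho
from . import io as cio
from . import islands as isl
from . import taxonomy as tx
from . import viral_qc as vq
from .errors import DependencyError

__all__ = ["STAGE_ORDER", "run_pipeline", "load_config", "write_simulation"]

logger = logging.getLogger("crust.pipeline")

STAGE_ORDER = (
    "coverage",
    "islands",
    "annotate",
    "qc",
    "taxonomy",
    "hosts",
    "amgs",
    "tpm",
)

# stage -> upstream stage whose outputs it consumes
_DEPENDS = {"islands": "coverage", "annotate": "islands"}


def load_config(path: str) -> dict[str, Any]:
    with open(path) as handle:
        return yaml.safe_load(handle)


def _float_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the enabled stages and return (and write) the manifest.

    ``config`` keys: ``output_dir``, ``seed`` (recorded), ``stages`` (a
    mapping stage -> bool), ``inputs`` (stage input paths) and ``params``
    (per-stage parameter overrides).  A stage whose upstream stage is
    disabled raises :class:`DependencyError` naming the missing stage.
    """
    outdir = config["output_dir"]
    os.makedirs(outdir, exist_ok=True)
    stages: dict[str, bool] = {
        s: bool(config.get("stages", {}).get(s, True)) for s in STAGE_ORDER
    }
    inputs: dict[str, Any] = config.get("inputs", {})
    params: dict[str, Any] = config.get("params", {})

    manifest: dict[str, Any] = {
        "seed": config.get("seed"),
        "output_dir": outdir,
        "stages": [],
    }
    produced: dict[str, dict[str, str]] = {}  # stage -> outputs

    def record(stage: str, stage_inputs: dict, outputs: dict, p: dict, counts: dict):
        entry = {
            "stage": stage,
            "parameters": p,
            "inputs": {k: cio.sha256_file(v) for k, v in stage_inputs.items()},
            "outputs": {k: cio.sha256_file(v) for k, v in outputs.items()},
            "counts": counts,
        }
        manifest["stages"].append(entry)
        produced[stage] = outputs
        logger.info("stage %s: %s", stage, counts)

    def need(stage: str) -> dict[str, str]:
        upstream = _DEPENDS[stage]
        if upstream not in produced:
            raise DependencyError(
                f"stage '{stage}' requires output of stage '{upstream}', "
                "which did not run"
            )
        return produced[upstream]

    # ------------------------------------------------------------- coverage
    if stages["coverage"]:
        p = {"max_mismatches": int(params.get("coverage", {}).get("max_mismatches", 1))}
        aln_path = inputs["alignments"]
        genomes_path = inputs["genomes"]
        if aln_path.endswith((".sam", ".bam")):
            records = cio.read_alignments_sam(aln_path)
        else:
            records = cio.read_alignments_tsv(aln_path)
        genomes = cio.read_genomes_tsv(genomes_path)
        from .coverage import compute_coverage, filter_alignments, genome_mean_coverage

        retained = filter_alignments(records, p["max_mismatches"])
        by_contig: dict[str, list] = {}
        for rec in retained:
            by_contig.setdefault(rec.contig_id, []).append(rec)
        all_tracks = []
        mean_rows = []
        for genome in genomes:
            recs = [r for cid, _ in genome.contigs for r in by_contig.get(cid, [])]
            tracks = compute_coverage(recs, genome)
            all_tracks.extend(tracks)
            mean_rows.append(
                {
                    "genome_id": genome.genome_id,
                    "mean_coverage": genome_mean_coverage(tracks, genome),
                }
            )
        bg_path = os.path.join(outdir, "coverage.bedgraph")
        means_path = os.path.join(outdir, "genome_means.tsv")
        cio.write_bedgraph(all_tracks, bg_path)
        _float_tsv(pd.DataFrame(mean_rows), means_path)
        record(
            "coverage",
            {"alignments": aln_path, "genomes": genomes_path},
            {"bedgraph": bg_path, "genome_means": means_path},
            p,
            {"alignments_in": len(records), "alignments_retained": len(retained)},
        )

    # -------------------------------------------------------------- islands
    if stages["islands"]:
        cov_out = need("islands")
        p_raw = params.get("islands", {})
        ip = isl.IslandParams(
            drop_fraction=float(p_raw.get("drop_fraction", 0.25)),
            min_len_drop=int(p_raw.get("min_len_drop", 100)),
            min_len_zero=int(p_raw.get("min_len_zero", 200)),
            high_cov_threshold=float(p_raw.get("high_cov_threshold", 5.0)),
            low_cov_threshold=float(p_raw.get("low_cov_threshold", 2.0)),
            gap_merge=int(p_raw.get("gap_merge", 0)),
        )
        genomes = cio.read_genomes_tsv(inputs["genomes"])
        contig_lengths = {
            cid: length for g in genomes for cid, length in g.contigs
        }
        tracks = cio.read_bedgraph(cov_out["bedgraph"], contig_lengths)
        track_by_id = {t.contig_id: t for t in tracks}
        means = pd.read_csv(cov_out["genome_means"], sep="\t").set_index("genome_id")[
            "mean_coverage"
        ]
        all_islands = []
        for genome in genomes:
            gtracks = [track_by_id[cid] for cid, _ in genome.contigs]
            all_islands.extend(
                isl.detect_islands(
                    gtracks, float(means[genome.genome_id]), ip, genome.genome_id
                )
            )
        bed_path = os.path.join(outdir, "islands.bed")
        summary_path = os.path.join(outdir, "island_summary.tsv")
        cio.write_islands_bed(all_islands, bed_path)
        _float_tsv(isl.island_summary(all_islands, genomes), summary_path)
        record(
            "islands",
            dict(cov_out),
            {"islands_bed": bed_path, "summary": summary_path},
            ip.__dict__,
            {"islands_called": len(all_islands)},
        )

    # ------------------------------------------------------------- annotate
    if stages["annotate"]:
        isl_out = need("annotate")
        p = {
            "others_threshold": float(
                params.get("annotate", {}).get("others_threshold", 2.0)
            ),
            "exclude_S": bool(params.get("annotate", {}).get("exclude_S", False)),
            "top_n": int(params.get("annotate", {}).get("top_n", 20)),
        }
        means = pd.read_csv(
            produced["coverage"]["genome_means"], sep="\t"
        ).set_index("genome_id")["mean_coverage"]
        islands_list = cio.read_islands_bed(isl_out["islands_bed"], dict(means))
        if str(inputs["cds"]).endswith((".gff3", ".gff")):
            features = cio.read_gff3_cds(inputs["cds"])
        else:
            cds_df = pd.read_csv(inputs["cds"], sep="\t")
            features = [
                an.CdsFeature(
                    contig_id=str(r.contig_id),
                    start=int(r.start),
                    end=int(r.end),
                    strand=str(r.strand),
                    protein_id=str(r.protein_id),
                )
                for r in cds_df.itertuples(index=False)
            ]
        emapper = cio.read_emapper_tsv(inputs["emapper"])
        features = cio.annotate_features(features, emapper)
        pairs = an.overlap_islands_with_cds(islands_list, features)
        profile = an.summarize_categories(
            pairs, others_threshold=p["others_threshold"], exclude_S=p["exclude_S"]
        )
        cogs = an.top_cogs(pairs, n=p["top_n"])
        pairs_path = os.path.join(outdir, "island_gene_pairs.tsv")
        profile_path = os.path.join(outdir, "category_profile.tsv")
        cogs_path = os.path.join(outdir, "top_cogs.tsv")
        pd.DataFrame(
            [
                {
                    "contig_id": i.contig_id,
                    "island_start": i.start,
                    "island_end": i.end,
                    "protein_id": f.protein_id,
                    "cds_start": f.start,
                    "cds_end": f.end,
                }
                for i, f in pairs
            ],
            columns=["contig_id", "island_start", "island_end", "protein_id",
                     "cds_start", "cds_end"],
        ).to_csv(pairs_path, sep="\t", index=False)
        _float_tsv(profile.to_frame(), profile_path)
        _float_tsv(cogs, cogs_path)
        record(
            "annotate",
            {**isl_out, "cds": inputs["cds"], "emapper": inputs["emapper"]},
            {"pairs": pairs_path, "profile": profile_path, "top_cogs": cogs_path},
            p,
            {"pairs": len(pairs), "profiled_hits": profile.total_hits},
        )

    # ------------------------------------------------------------------- qc
    if stages["qc"]:
        p = {"min_length": int(params.get("qc", {}).get("min_length", 5000))}
        cands = cio.read_candidate_records_tsv(inputs["qc_candidates"])
        votus = cio.read_votu_qc_tsv(inputs["qc_votus"])
        mags = cio.read_mag_quality_tsv(inputs["qc_mags"])
        life = cio.read_lifestyle_tsv(inputs["qc_lifestyle"])
        screened = vq.screen_candidates(cands, p["min_length"])
        retained = vq.retain_votus(votus, p["min_length"])
        tiers = vq.tier_mags(mags)
        calls = vq.call_lifestyle(life)
        paths = {
            "screened": os.path.join(outdir, "screened_candidates.tsv"),
            "retained": os.path.join(outdir, "retained_votus.tsv"),
            "tiers": os.path.join(outdir, "mag_tiers.tsv"),
            "lifestyle": os.path.join(outdir, "lifestyle_calls.tsv"),
        }
        pd.DataFrame({"contig_id": screened}).to_csv(paths["screened"], sep="\t", index=False)
        pd.DataFrame({"votu_id": retained}).to_csv(paths["retained"], sep="\t", index=False)
        tiers.to_csv(paths["tiers"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "votu_id": c.votu_id,
                    "virulent_score": c.virulent_score,
                    "temperate_score": c.temperate_score,
                    "call": c.call,
                }
                for c in calls
            ]
        ).to_csv(paths["lifestyle"], sep="\t", index=False)
        record(
            "qc",
            {k: inputs[k] for k in ("qc_candidates", "qc_votus", "qc_mags", "qc_lifestyle")},
            paths,
            p,
            {
                "candidates_passed": len(screened),
                "votus_retained": len(retained),
                "lifestyle_assigned": sum(1 for c in calls if c.call != "unassigned"),
            },
        )

    # ------------------------------------------------------------- taxonomy
    if stages["taxonomy"]:
        call_paths = inputs["taxonomy_calls"]  # mapping classifier -> path
        calls = []
        for classifier, path in sorted(call_paths.items()):
            calls.extend(cio.read_lineage_calls_tsv(path, classifier=classifier))
        filtered = tx.filter_calls(calls)
        consensuses = tx.consensus_all(filtered)
        rates = tx.classification_rates(consensuses)
        cons_path = os.path.join(outdir, "consensus_taxonomy.tsv")
        rates_path = os.path.join(outdir, "classification_rates.tsv")
        pd.DataFrame(
            [{"votu_id": c.votu_id, **c.ranks} for c in consensuses]
        ).to_csv(cons_path, sep="\t", index=False)
        _float_tsv(rates, rates_path)
        record(
            "taxonomy",
            {c: p for c, p in sorted(call_paths.items())},
            {"consensus": cons_path, "rates": rates_path},
            {},
            {"calls_in": len(calls), "calls_filtered": len(filtered),
             "votus": len(consensuses)},
        )

    # ---------------------------------------------------------------- hosts
    if stages["hosts"]:
        associations = cio.read_host_predictions_tsv(inputs["host_predictions"])
        stage_inputs = {"host_predictions": inputs["host_predictions"]}
        if inputs.get("matches"):
            matches = cio.read_match_records_tsv(inputs["matches"])
            kept = ho.filter_matches(matches)
            stage_inputs["matches"] = inputs["matches"]
        else:
            kept = []
        spectrum = ho.association_spectrum(associations)
        assoc_path = os.path.join(outdir, "associations.tsv")
        spec_path = os.path.join(outdir, "association_spectrum.tsv")
        pd.DataFrame(
            [
                {
                    "votu_id": a.votu_id,
                    "mag_id": a.mag_id,
                    "family": a.mag_lineage.get("family", ""),
                    "class": a.mag_lineage.get("class", ""),
                    "source": a.source,
                }
                for a in associations
            ]
        ).to_csv(assoc_path, sep="\t", index=False)
        _float_tsv(spectrum, spec_path)
        record(
            "hosts",
            stage_inputs,
            {"associations": assoc_path, "spectrum": spec_path},
            {},
            {"associations": len(associations), "matches_kept": len(kept)},
        )

    # ----------------------------------------------------------------- amgs
    if stages["amgs"]:
        p = {
            "edge_mode": str(params.get("amgs", {}).get("edge_mode", "first_last_gene")),
            "combine": str(params.get("amgs", {}).get("combine", "union")),
        }
        calls_a = cio.read_amg_calls_tsv(inputs["amg_caller_a"], "caller_a")
        calls_b = cio.read_amg_calls_tsv(inputs["amg_caller_b"], "caller_b")
        curated = ho.curate_amgs(
            calls_a + calls_b, edge_mode=p["edge_mode"], combine=p["combine"]
        )
        amg_path = os.path.join(outdir, "curated_amgs.tsv")
        pd.DataFrame(
            [
                {
                    "votu_id": c.votu_id,
                    "gene_index": c.gene_index,
                    "total_genes": c.total_genes,
                    "cog_id": c.cog_id,
                    "categories": c.categories,
                    "callers": ",".join(sorted(c.callers)),
                }
                for c in curated
            ],
            columns=["votu_id", "gene_index", "total_genes", "cog_id",
                     "categories", "callers"],
        ).to_csv(amg_path, sep="\t", index=False)
        record(
            "amgs",
            {"amg_caller_a": inputs["amg_caller_a"], "amg_caller_b": inputs["amg_caller_b"]},
            {"curated": amg_path},
            p,
            {"calls_in": len(calls_a) + len(calls_b), "curated": len(curated)},
        )

    # ------------------------------------------------------------------ tpm
    if stages["tpm"]:
        counts, lengths = cio.read_counts_tsv(inputs["counts"])
        tpm_matrix = ab.tpm(counts, lengths)
        log_matrix = ab.log_transform(tpm_matrix)
        tpm_path = os.path.join(outdir, "tpm.tsv")
        log_path = os.path.join(outdir, "tpm_log10.tsv")
        tpm_matrix.to_csv(tpm_path, sep="\t", float_format="%.6g")
        log_matrix.to_csv(log_path, sep="\t", float_format="%.6g")
        record(
            "tpm",
            {"counts": inputs["counts"]},
            {"tpm": tpm_path, "tpm_log10": log_path},
            {},
            {"rows": int(tpm_matrix.shape[0]), "samples": int(tpm_matrix.shape[1])},
        )

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def write_simulation(sim_config, outdir: str) -> dict[str, Any]:
    """Generate a full synthetic input set plus a ready pipeline config.

    Runs the read and table simulators, writes every input dialect the
    pipeline consumes (alignments TSV, genome table, GFF3 + emapper TSV,
    QC/classifier/host/AMG/count TSVs, truth BED/JSON) into ``outdir`` and
    returns the pipeline config dict, also saved as ``pipeline.yaml``.
    """
    from .simulate import simulate_recruitment, simulate_tables

    os.makedirs(outdir, exist_ok=True)
    genomes, records, truth = simulate_recruitment(sim_config)
    tables = simulate_tables(sim_config, truth, genomes=genomes)

    paths = {name: os.path.join(outdir, f"{name}.tsv") for name in tables}
    cio.write_alignments_tsv(records, os.path.join(outdir, "alignments.tsv"))
    cio.write_genomes_tsv(genomes, os.path.join(outdir, "genomes.tsv"))
    for name, df in tables.items():
        if name == "cds":
            paths[name] = os.path.join(outdir, "cds.gff3")
            cio.write_gff3_cds(df, paths[name])
        else:
            df.to_csv(paths[name], sep="\t", index=False)

    with open(os.path.join(outdir, "truth_islands.bed"), "w") as handle:
        for isl_ in truth.islands:
            handle.write(
                f"{isl_.contig_id}\t{isl_.start}\t{isl_.end}\t"
                f"{isl_.genome_id}\t{isl_.depth_fraction:.4g}\t.\n"
            )
    truth_json = {
        "baselines": truth.baselines,
        "lineages": truth.lineages,
        "hosts": {k: sorted(v) for k, v in truth.hosts.items()},
        "amgs": [list(t) for t in truth.amgs],
        "lifestyles": truth.lifestyles,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as handle:
        json.dump(truth_json, handle, indent=2, sort_keys=True)
        handle.write("\n")

    pipeline_config = {
        "seed": sim_config.seed,
        "output_dir": os.path.join(outdir, "results"),
        "stages": {s: True for s in STAGE_ORDER},
        "inputs": {
            "alignments": os.path.join(outdir, "alignments.tsv"),
            "genomes": os.path.join(outdir, "genomes.tsv"),
            "cds": paths["cds"],
            "emapper": paths["emapper"],
            "qc_candidates": paths["qc_candidates"],
            "qc_votus": paths["qc_votus"],
            "qc_mags": paths["qc_mags"],
            "qc_lifestyle": paths["qc_lifestyle"],
            "taxonomy_calls": {
                c: paths[f"taxonomy_{c}"]
                for c in ("aln_protein", "aln_gene", "profile_search",
                          "composite_scorer")
            },
            "host_predictions": paths["host_predictions"],
            "amg_caller_a": paths["amg_caller_a"],
            "amg_caller_b": paths["amg_caller_b"],
            "counts": paths["counts"],
        },
        "params": {},
    }
    with open(os.path.join(outdir, "pipeline.yaml"), "w") as handle:
        yaml.safe_dump(pipeline_config, handle, sort_keys=True)
    return pipeline_config
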
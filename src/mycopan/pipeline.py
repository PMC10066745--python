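"""End-to-end orchestration of the comparative multi-omic analysis.

Stage order: synthetic data (optional) -> orthology -> secretome ->
TE proximity -> symbiosis expression -> carbon transfer.  Every stage writes
tidy TSV/JSON outputs into the results directory and the run closes with a
manifest (seed, configuration, input hashes) that fully determines the
outputs: re-running with the same manifest reproduces them byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mycopan import expression, orthology, secretome, te_proximity, transfer
from mycopan.annotation_io import write_functional_annotations, write_gff3
from mycopan.config import AnalysisConfig
from mycopan.synthetic import (
    SimulationConfig,
    simulate_counts,
    simulate_functional_annotations,
    simulate_genome_layout,
    simulate_isotopes,
    simulate_pangenome,
)

log = logging.getLogger("mycopan.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    sim_config: SimulationConfig | None = None,
    simulate: bool = True,
) -> Path:
    """Run every stage on simulated inputs and write a results directory.

    With ``simulate=True`` (the only built-in input source; real data enters
    through the per-stage library functions and loaders) the synthetic module
    generates proteomes, genome layouts, functional flags, count matrices and
    isotope triplets, and each analysis stage consumes exactly the files the
    corresponding reader understands.
    """
    if not simulate:
        raise ValueError(
            "run_pipeline currently orchestrates simulated inputs; for real "
            "data call the stage functions with your own files"
        )
    config = config or AnalysisConfig()
    sim = sim_config or SimulationConfig(seed=config.seed)
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": config.seed,
        "analysis_config": config.__dict__,
        "simulation_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in sim.__dict__.items()
        },
        "inputs": {},
        "stages": [],
    }

    # ------------------------------------------------------------------ simulate
    stage = "simulate"
    try:
        proteins, og_truth = simulate_pangenome(sim)
        lengths = {
            sp: {gid: len(seq) for gid, seq in genes.items()}
            for sp, genes in proteins.items()
        }
        annotations_fn = simulate_functional_annotations(sim, lengths)
        class_map: dict[str, str] = {}
        for sp in sorted(proteins):
            class_map.update(
                secretome.classify_genes(
                    annotations_fn[sp], lengths[sp], config.ssp_max_len
                )
            )
        genes_by_species = {
            sp: [
                # genomic span ~ 3 bp per codon (intron-less desk-scale model)
                (gid, 3 * lengths[sp][gid], class_map[gid])
                for gid in sorted(proteins[sp])
            ]
            for sp in proteins
        }
        layouts, layout_truth = simulate_genome_layout(sim, genes_by_species)

        for sp in sorted(proteins):
            with open(out / "inputs" / f"{sp}_proteins.fasta", "w") as fh:
                for gid in sorted(proteins[sp]):
                    fh.write(f">{gid}\n{proteins[sp][gid]}\n")
            write_gff3(out / "inputs" / f"{sp}_genes.gff3", layouts[sp].genes)
            write_gff3(out / "inputs" / f"{sp}_repeats.gff3", layouts[sp].repeats)
            write_functional_annotations(
                out / "inputs" / f"{sp}_function.tsv", annotations_fn[sp].values()
            )
        _write_tsv(og_truth, out / "inputs" / "truth_orthogroups.tsv")
        _write_tsv(layout_truth, out / "inputs" / "truth_layout.tsv")

        partition_truth = og_truth.set_index("gene_id")["partition"]
        expr_species = sorted(proteins)[: sim.n_expression_species]
        counts_by_species: dict[str, pd.DataFrame] = {}
        samples_by_species: dict[str, pd.DataFrame] = {}
        for sp in expr_species:
            counts, samples, de_truth = simulate_counts(
                sim, partition_truth[partition_truth.index.str.startswith(sp)]
            )
            counts_by_species[sp] = counts
            samples_by_species[sp] = samples
            counts.to_csv(out / "inputs" / f"{sp}_counts.tsv", sep="\t")
            _write_tsv(samples, out / "inputs" / f"{sp}_samples.tsv")
            _write_tsv(de_truth, out / "inputs" / f"truth_de_{sp}.tsv")

        triplets = simulate_isotopes(
            sim.isotope_n,
            sim.isotope_fraction,
            sim.isotope_noise_sd,
            seed=sim.seed,
            delta_leaf=sim.delta_leaf,
            delta_flm=sim.delta_flm,
        )
        _write_tsv(triplets, out / "inputs" / "isotopes.tsv")
        log.info(
            "stage=simulate species=%d genes=%d",
            len(proteins),
            sum(len(v) for v in proteins.values()),
        )
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ orthology
    stage = "orthology"
    try:
        graph = orthology.build_similarity_graph(
            proteins, config.min_identity, config.min_coverage
        )
        orthogroups, converged = orthology.mcl_cluster(
            graph, inflation=config.mcl_inflation
        )
        og_frame = orthology.orthogroups_to_frame(orthogroups)
        partition = orthology.partition_pangenome(orthogroups, sorted(proteins))
        _write_tsv(og_frame, out / "orthogroups.tsv")
        _write_tsv(
            pd.DataFrame(
                sorted(partition.labels.items()), columns=["og_id", "partition"]
            ),
            out / "partition.tsv",
        )
        summary = {
            "n_orthogroups": partition.n_orthogroups,
            "counts": partition.counts,
            "percentages": {
                k: round(v) for k, v in partition.percentages.items()
            },
            "single_copy": len(
                orthology.single_copy_orthogroups(orthogroups, sorted(proteins))
            ),
            "mcl_converged": converged,
        }
        with open(out / "pangenome_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        inferred_partition_by_gene = (
            og_frame.assign(partition=og_frame.og_id.map(partition.labels))
            .set_index("gene_id")["partition"]
        )
        log.info(
            "stage=orthology orthogroups=%d core=%d accessory=%d specific=%d",
            partition.n_orthogroups,
            partition.counts["core"],
            partition.counts["accessory"],
            partition.counts["specific"],
        )
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ secretome
    stage = "secretome"
    try:
        secretome.write_classes_tsv(out / "classes.tsv", class_map)
        summary_df = secretome.secretome_summary(
            annotations_fn, lengths, config.ssp_max_len
        )
        _write_tsv(summary_df, out / "secretome_summary.tsv")
        length_frames = []
        for sp in sorted(layouts):
            frame = secretome.gene_length_by_class(
                layouts[sp], class_map, lengths[sp]
            )
            length_frames.append(frame.assign(species_id=sp))
        _write_tsv(pd.concat(length_frames), out / "gene_length_by_class.tsv")
        log.info("stage=secretome species=%d", len(layouts))
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ proximity
    stage = "te_proximity"
    try:
        prox_cfg = te_proximity.ProximityConfig(
            close_proximity_threshold=config.close_proximity,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=config.seed,
        )
        prox_frames = []
        coverage_rows = []
        for sp in sorted(layouts):
            results = te_proximity.permutation_test(layouts[sp], class_map, prox_cfg)
            prox_frames.append(
                te_proximity.results_to_frame(results).assign(species_id=sp)
            )
            coverage_rows.append(
                {"species_id": sp, "te_coverage": te_proximity.te_coverage(layouts[sp])}
            )
        _write_tsv(pd.concat(prox_frames), out / "te_proximity.tsv")
        _write_tsv(pd.DataFrame(coverage_rows), out / "te_coverage.tsv")
        log.info("stage=te_proximity species=%d", len(layouts))
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ expression
    stage = "symbiosis_expression"
    try:
        de_cfg = expression.DEConfig(
            lfc_threshold=config.lfc_threshold, fdr_threshold=config.fdr_threshold
        )
        de_by_species: dict[str, pd.DataFrame] = {}
        table1_rows = []
        table23 = {"expressed": [], "up": [], "down": []}
        for sp in expr_species:
            counts = counts_by_species[sp]
            samples = samples_by_species[sp]
            cond = samples.set_index("sample_id")["condition"]
            de = expression.test_de(counts, cond, de_cfg)
            de_by_species[sp] = de
            _write_tsv(de, out / f"de_{sp}.tsv")
            part_sp = inferred_partition_by_gene[
                inferred_partition_by_gene.index.str.startswith(sp)
            ]
            summary = expression.summarize_by_partition(
                de, part_sp.to_dict(), genome_total_genes=len(part_sp)
            )
            table1_rows.append(summary.assign(species_id=sp))
            _, normalized = expression.normalize_counts(counts)
            ssp_table = expression.ssp_regulation_table(
                de,
                class_map,
                part_sp.to_dict(),
                normalized,
                cond,
                config.expression_floor,
            )
            for _, row in ssp_table.iterrows():
                table23[row.category].append({**row.to_dict(), "species_id": sp})
        _write_tsv(pd.concat(table1_rows), out / "table1.tsv")
        _write_tsv(pd.DataFrame(table23["expressed"]), out / "table2.tsv")
        _write_tsv(
            pd.DataFrame(table23["up"] + table23["down"]), out / "table3.tsv"
        )
        regulation = expression.orthogroup_regulation(de_by_species, og_frame)
        upset_rows = []
        for direction in ("up", "down"):
            sets = {sp: regulation[sp][direction] for sp in regulation}
            for subset, count in sorted(
                expression.upset_counts(sets).items(), key=lambda kv: sorted(kv[0])
            ):
                upset_rows.append(
                    {
                        "direction": direction,
                        "species_subset": ",".join(sorted(subset)),
                        "count": count,
                    }
                )
        _write_tsv(pd.DataFrame(upset_rows), out / "upset_counts.tsv")
        n_degs = {sp: int((de.call != "ns").sum()) for sp, de in de_by_species.items()}
        log.info("stage=symbiosis_expression degs=%s", n_degs)
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ transfer
    stage = "transfer_stats"
    try:
        percents = []
        leaf_mean = triplets["delta_leaf"].mean()
        for _, row in triplets.iterrows():
            ct = transfer.percent_c_acquired(
                transfer.IsotopeTriplet(
                    delta_leaf=leaf_mean,
                    delta_erm=row.delta_erm,
                    delta_flm=row.delta_flm,
                    replicate=row.replicate,
                )
            )
            percents.append(
                {
                    "replicate": row.replicate,
                    "percent_c_acquired": ct.percent,
                    "within_range": ct.within_range,
                }
            )
        recovery = transfer.recover_fraction(triplets)
        _write_tsv(pd.DataFrame(percents), out / "carbon_transfer.tsv")
        with open(out / "carbon_transfer_summary.json", "w") as fh:
            json.dump(
                {
                    "mean_percent": recovery.mean_percent,
                    "ci_low": recovery.ci_low,
                    "ci_high": recovery.ci_high,
                    "ci_defined": recovery.ci_defined,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        log.info("stage=transfer_stats mean_percent=%.2f", recovery.mean_percent)
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    for f in sorted((out / "inputs").iterdir()):
        manifest["inputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
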
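"""End-to-end orchestration: simulate -> overlap -> classify -> methylation -> GO.

One global seed is expanded into independent per-stage streams through
``numpy.random.SeedSequence`` spawn keys, so adding or re-ordering stages
never perturbs another stage's draws. Every report embeds the seed, rep
count and thresholds it was produced with, and the run manifest records the
config snapshot, input digests and per-stage outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_core import RunConfig, logger, write_cgmap, write_de_table, write_fasta, \
    write_orthogroups
from .methylation import (cg_enrichment_test, context_census, filter_coverage,
                          methylation_context_composition,
                          methylation_expression_correlation, subset_mean_ztest,
                          transcript_mC, transcript_table)
from .overlap import overlap_report, stratified_overlap
from .go_tools import fisher_enrichment, propagate, rollup_level
from .synthetic import (MethylomeSimParams, OntologySimParams, OrthoSimParams,
                        OverlapSimParams, simulate_de_pair, simulate_methylome,
                        simulate_ontology, simulate_orthogroup_matrix)
from .txr import category_proportions, classify_matrix, exclude_unassigned

STAGES = ("simulate", "overlap", "classify", "methylation", "go")

# fixed spawn keys: stage seeds never depend on which stages run
_STAGE_KEY = {name: i for i, name in enumerate(STAGES)}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the global seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEY[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class MissingInputError(FileNotFoundError):
    """A requested stage lacks its input; names the producer stage."""


def run_pipeline(config: RunConfig, outdir: str | Path,
                 stages: "tuple[str, ...] | list[str]" = STAGES) -> RunManifest:
    """Run the requested stages in dependency order under one output dir.

    With the ``simulate`` stage enabled the pipeline is self-contained;
    without it, downstream stages expect the simulate outputs (or
    user-supplied files of the same names) to exist in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    ordered = [s for s in STAGES if s in stages]
    manifest = RunManifest(config={**asdict(config)}, seed=config.seed,
                           version=__version__)
    logger.info("pipeline run: seed=%d stages=%s", config.seed, ",".join(ordered))

    if "simulate" in ordered:
        _stage_simulate(config, outdir, manifest)
    if "overlap" in ordered:
        _stage_overlap(config, outdir, manifest)
    if "classify" in ordered:
        _stage_classify(config, outdir, manifest)
    if "methylation" in ordered:
        _stage_methylation(config, outdir, manifest)
    if "go" in ordered:
        _stage_go(config, outdir, manifest)

    manifest.write(outdir / "manifest.json")
    return manifest


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"missing input {path.name}: run the '{producer}' stage first or "
            f"supply the file")
    return path


def _stage_simulate(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    seed = stage_seed(config.seed, "simulate")
    fasta, cgmap, truth = simulate_methylome(MethylomeSimParams(seed=seed))
    write_fasta(fasta, outdir / "transcriptome.fa")
    write_cgmap(cgmap, outdir / "nurse.cgmap")
    truth.to_csv(outdir / "methylome_truth.tsv", sep="\t")

    ta, tb, universes, de_truth = simulate_de_pair(OverlapSimParams(seed=seed))
    write_de_table(ta, outdir / "de_species_a.tsv")
    write_de_table(tb, outdir / "de_species_b.tsv")
    for name, terms in universes.items():
        (outdir / f"universe_{name}.txt").write_text("\n".join(terms) + "\n")
    de_truth.to_csv(outdir / "de_truth.tsv", sep="\t", index=False)

    matrix, labels = simulate_orthogroup_matrix(OrthoSimParams(seed=seed))
    write_orthogroups(matrix, outdir / "Orthogroups.tsv")
    pd.Series(labels, name="category").rename_axis("orthogroup").to_csv(
        outdir / "orthogroup_truth.tsv", sep="\t")

    manifest.outputs["simulate"] = [
        "transcriptome.fa", "nurse.cgmap", "methylome_truth.tsv",
        "de_species_a.tsv", "de_species_b.tsv", "de_truth.tsv", "Orthogroups.tsv",
        "orthogroup_truth.tsv"]
    for f in manifest.outputs["simulate"]:
        manifest.input_digests[f] = _digest(outdir / f)


def _stage_overlap(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    from .io_core import read_de_table
    seed = stage_seed(config.seed, "overlap")
    de_a = _require(outdir / "de_species_a.tsv", "simulate")
    de_b = _require(outdir / "de_species_b.tsv", "simulate")
    ua = _require(outdir / "universe_species_a.txt", "simulate")
    ub = _require(outdir / "universe_species_b.txt", "simulate")
    table_a = read_de_table(de_a, "species_a")
    table_b = read_de_table(de_b, "species_b")
    universe_a = ua.read_text().splitlines()
    universe_b = ub.read_text().splitlines()
    results = stratified_overlap(table_a, universe_a, table_b, universe_b,
                                 reps=config.resample_reps, seed=seed)
    (outdir / "overlap_report.tsv").write_text(
        overlap_report(results, alpha=config.alpha))
    shared = pd.DataFrame(
        [(s, t) for s, r in results.items() for t in r.curated_terms],
        columns=["stratum", "term"])
    shared.to_csv(outdir / "overlap_shared_terms.tsv", sep="\t", index=False)
    manifest.outputs["overlap"] = ["overlap_report.tsv", "overlap_shared_terms.tsv"]


def _stage_classify(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    from .io_core import read_orthogroups
    from .txr import DEFAULT_RULES, DEFAULT_CLADES, load_clades, load_rules
    path = _require(outdir / "Orthogroups.tsv", "simulate")
    matrix = read_orthogroups(path)
    rules = (load_rules(config.category_rules_path)
             if config.category_rules_path else DEFAULT_RULES)
    clades = (load_clades(config.clade_config_path)
              if config.clade_config_path else DEFAULT_CLADES)
    assignments = classify_matrix(matrix, rules, clades)
    pd.Series(assignments, name="category").rename_axis("orthogroup").to_csv(
        outdir / "orthogroup_categories.tsv", sep="\t")
    # focal ring: orthogroups of the simulated DE genes when available, else all
    focal = set(matrix.orthogroup_ids)
    report = category_proportions(matrix, assignments, focal)
    df = report.to_frame()
    df["seed"] = config.seed
    df.to_csv(outdir / "category_report.tsv", sep="\t", index=False)
    manifest.outputs["classify"] = ["orthogroup_categories.tsv", "category_report.tsv"]


def _stage_methylation(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    from .io_core import read_cgmap, read_fasta
    seed = stage_seed(config.seed, "methylation")
    cgmap_path = _require(outdir / "nurse.cgmap", "simulate")
    fasta_path = _require(outdir / "transcriptome.fa", "simulate")
    records = filter_coverage(read_cgmap(cgmap_path), config.min_coverage)
    fasta = read_fasta(fasta_path)
    census = context_census(fasta)
    composition = methylation_context_composition(records)
    enrich = cg_enrichment_test(records, census, reps=config.resample_reps, seed=seed)
    per_t = transcript_mC(records)
    table = transcript_table(per_t)
    table.to_csv(outdir / "transcript_methylation.tsv", sep="\t")

    report = {
        "census": {k: census[k] for k in ("CG", "CW", "CC")},
        "n_defined_sites": census["n_defined"],
        "composition_percent": {k: composition[k] for k in ("CG", "CW", "CC")},
        "n_methylated": composition["n_methylated"],
        "cg_enrichment": enrich,
        "transcriptome_mean_mC": float(table["mean_mC"].mean()),
        "min_coverage": config.min_coverage,
        "reps": config.resample_reps,
        "seed": seed,
    }
    truth_path = outdir / "methylome_truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="seq_id")
        counts = truth["norm_count"].to_dict()
        corr = methylation_expression_correlation(per_t, counts)
        report["spearman"] = {c: {"r_s": r.r_s, "p": r.p_value, "n": r.n}
                              for c, r in corr.items()}
        # set test: most highly expressed decile vs transcriptome
        table_ids = [sid for sid in table.index if sid in counts]
        ranked = sorted(table_ids, key=lambda s: counts[s], reverse=True)
        top = ranked[: max(len(ranked) // 10, 2)]
        res = subset_mean_ztest(table.loc[top, "mean_mC"].to_numpy(),
                                table["mean_mC"].to_numpy(), label="high_expression")
        report["high_expression_ztest"] = {
            "subset_mean": res.subset_mean, "global_mean": res.global_mean,
            "z": res.z, "p": res.p_value, "percent_difference": res.percent_difference,
            "ci": [res.ci_low, res.ci_high], "n": res.n_subset, "tail": res.tail,
        }
    with open(outdir / "methylation_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    manifest.outputs["methylation"] = ["transcript_methylation.tsv",
                                       "methylation_report.json"]


def _stage_go(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    seed = stage_seed(config.seed, "go")
    dag, annotations, study, truth = simulate_ontology(OntologySimParams(seed=seed))
    propagated = propagate(annotations, dag)
    results = fisher_enrichment(study, set(annotations), propagated,
                                alpha=config.alpha)
    rows = [{"term": r.term_id, "study_count": r.study_count,
             "study_size": r.study_size, "background_count": r.background_count,
             "background_size": r.background_size, "p_value": r.p_value,
             "significant": r.p_value < config.alpha, "seed": seed}
            for r in results]
    pd.DataFrame(rows).to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)
    logfc = {g: 1.0 for g in study}
    summary = rollup_level(logfc, propagated, dag, level=3)
    pd.DataFrame([{"term": t, "n_genes": n, "mean_logFC": m}
                  for t, (n, m) in summary.items()]).to_csv(
        outdir / "go_level3_rollup.tsv", sep="\t", index=False)
    manifest.outputs["go"] = ["go_enrichment.tsv", "go_level3_rollup.tsv"]
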
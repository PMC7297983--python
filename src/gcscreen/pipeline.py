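"""End-to-end screen pipeline: simulate, count, score, summarize.

`run_screens` ties the stages together for real or simulated FASTQ input;
`run_demo` generates a synthetic library with planted regulator genes, runs
two independent screens, and scores them — a one-command reproduction of the
whole analysis flow.  Every run writes a provenance JSON (tool version,
master seed, full configuration, output paths) from which the outputs are
re-derivable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__
from .errors import ConfigurationError
from .library import LibraryManifest, generate_library, write_manifest
from .quantify import (
    CountMatrix,
    count_reads,
    counts_from_array,
    median_abundance,
    to_percentages,
    write_abundance,
    write_counts,
)
from .score import (
    FilterPolicy,
    ScreenAbundance,
    gene_summary,
    rank_hits,
    score_screens,
)
from .simulate import (
    COMPARTMENTS,
    EffectTable,
    SimulationConfig,
    simulate_screen,
    write_effects,
)

log = logging.getLogger("gcscreen")

DEMO_DEPLETED_EFFECT = 0.05
DEMO_ENRICHED_EFFECT = 4.0


def screen_abundance_from_counts(
    name: str, gc_counts: CountMatrix, nongc_counts: CountMatrix,
    denominator: str = "matched",
) -> ScreenAbundance:
    """Counts for both compartments -> per-screen median abundance tables."""
    return ScreenAbundance(
        name=name,
        gc=median_abundance(to_percentages(gc_counts, denominator)),
        nongc=median_abundance(to_percentages(nongc_counts, denominator)),
    )


def demo_effects(manifest: LibraryManifest) -> EffectTable:
    """Planted ground truth for the demo: two strongly depleted genes
    (knockdowns of positive GC regulators) and one enriched gene."""
    effects = {gene: 1.0 for gene in manifest.genes}
    genes = manifest.genes
    if len(genes) >= 3:
        effects[genes[0]] = DEMO_DEPLETED_EFFECT
        effects[genes[1]] = DEMO_DEPLETED_EFFECT
        effects[genes[2]] = DEMO_ENRICHED_EFFECT
    return EffectTable(effects)


def run_screens(
    manifest: LibraryManifest,
    effects: EffectTable,
    config: SimulationConfig,
    out_dir,
    n_screens: int = 2,
    through_fastq: bool = True,
    policy: FilterPolicy | None = None,
    fc_cut: float = 2.0,
    consistency_quantile: float = 0.5,
    consistency_mode: str = "replicate_pairs",
) -> dict:
    """Simulate ``n_screens`` independent screens and score them.

    With ``through_fastq=True`` reads are written to FASTQ and counted back
    by exact matching; otherwise the simulator's read counts feed the
    abundance stage directly (identical up to sequencing errors).  Returns
    scores, gene summary, hit lists, per-screen truths, and written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    policy = policy or FilterPolicy(library_size=len(manifest))
    screens = []
    truths = {}
    for s in range(n_screens):
        name = f"screen{s + 1}"
        cfg = dataclasses.replace(config, seed=config.seed + s)
        result = simulate_screen(
            manifest, effects, cfg, out_dir, screen=name, write_reads=through_fastq
        )
        truths[name] = result["truth"]
        compartment_counts = {}
        for compartment in COMPARTMENTS:
            sample = f"{name}_{compartment}"
            if through_fastq:
                cm = count_reads(
                    result["outputs"]["fastq"][compartment], manifest, sample=sample
                )
            else:
                cm = counts_from_array(result["counts"][compartment], manifest, sample)
            write_counts(cm, out_dir / f"{sample}_counts.tsv")
            log.info(
                "%s: %d matched / %d ambiguous / %d unmatched reads",
                sample,
                cm.totals["matched"].sum(),
                cm.totals["ambiguous"].sum(),
                cm.totals["unmatched"].sum(),
            )
            compartment_counts[compartment] = cm
        screen_ab = screen_abundance_from_counts(
            name, compartment_counts["gc"], compartment_counts["nongc"]
        )
        write_abundance(screen_ab.gc, out_dir / f"{name}_gc_abundance.tsv")
        write_abundance(screen_ab.nongc, out_dir / f"{name}_nongc_abundance.tsv")
        screens.append(screen_ab)

    scores = score_screens(
        screens,
        policy,
        consistency_mode=consistency_mode,
        fc_cut=fc_cut,
        consistency_quantile=consistency_quantile,
    )
    scores_out = scores.reset_index()
    scores_out.to_csv(out_dir / "scores.tsv", sep="\t", index=False, lineterminator="\n")
    summary = gene_summary(scores)
    summary.reset_index().to_csv(
        out_dir / "gene_summary.tsv", sep="\t", index=False, lineterminator="\n"
    )
    depleted, enriched = rank_hits(scores, fc_cut, consistency_quantile)
    depleted.reset_index().to_csv(
        out_dir / "hits_depleted.tsv", sep="\t", index=False, lineterminator="\n"
    )
    enriched.reset_index().to_csv(
        out_dir / "hits_enriched.tsv", sep="\t", index=False, lineterminator="\n"
    )
    scatter = scores.loc[scores["consistent"], ["gene", "log2_fc", "inv_sd"]]
    scatter.reset_index().to_csv(
        out_dir / "scatter.tsv", sep="\t", index=False, lineterminator="\n"
    )
    log.info(
        "scored %d constructs; %d consistently recovered; %d depleted / %d enriched hits",
        len(scores), int(scores["consistent"].sum()), len(depleted), len(enriched),
    )
    return {
        "scores": scores,
        "gene_summary": summary,
        "depleted": depleted,
        "enriched": enriched,
        "screens": screens,
        "truths": truths,
    }


def run_demo(
    out_dir,
    seed: int = 0,
    n_genes: int = 78,
    k_per_gene: int = 5,
    n_screens: int = 2,
    config: SimulationConfig | None = None,
    through_fastq: bool = True,
) -> dict:
    """Full synthetic demonstration run.

    Generates a library (default 78 genes x 5 hairpins), plants two strongly
    depleted regulator genes and one enriched gene, simulates ``n_screens``
    independent screens, quantifies, filters, and ranks.  Deterministic for a
    fixed master seed.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and not out_dir.is_dir():
        raise ConfigurationError(f"{out_dir} exists and is not a directory")
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig(seed=seed)
    if config.seed != seed:
        config = dataclasses.replace(config, seed=seed)

    log.info("generating library: %d genes x %d constructs", n_genes, k_per_gene)
    manifest = generate_library(n_genes, k_per_gene, seed=seed)
    write_manifest(manifest, out_dir / "manifest.tsv")
    effects = demo_effects(manifest)
    write_effects(effects, out_dir / "effects.tsv")

    result = run_screens(
        manifest, effects, config, out_dir,
        n_screens=n_screens, through_fastq=through_fastq,
    )
    provenance = {
        "tool": "gcscreen",
        "version": __version__,
        "seed": seed,
        "n_genes": n_genes,
        "k_per_gene": k_per_gene,
        "n_screens": n_screens,
        "through_fastq": through_fastq,
        "config": dataclasses.asdict(config),
        "planted_effects": {
            g: e for g, e in effects.effects.items() if e != 1.0
        },
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    summary = result["gene_summary"].dropna(subset=["median_log2_fc"])
    ranked = summary.sort_values("median_log2_fc")
    run_summary = {
        "n_constructs": len(manifest),
        "n_consistent": int(result["scores"]["consistent"].sum()),
        "n_depleted_hits": len(result["depleted"]),
        "n_enriched_hits": len(result["enriched"]),
        "most_depleted_genes": list(ranked.index[:3]),
        "most_enriched_genes": list(ranked.index[::-1][:3]),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2)
    result["manifest"] = manifest
    result["effects"] = effects
    result["summary"] = run_summary
    return result
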
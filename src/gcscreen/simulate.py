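"""Synthetic in vivo screen generator.

Emulates the data-generating process the analysis assumes, stage by stage:

1. **Plasmid pool** — log-normal skew over constructs (cloning never yields a
   perfectly uniform pool); sigma 0 recovers the uniform pool.
2. **Founder bottleneck** — a fixed number of transduced cells (default
   4,000, about tenfold the library size) drawn multinomially from the pool.
3. **GC-fate selection** — each founder independently enters the germinal
   center with probability ``clamp(baseline_gc_prob * gc_effect(gene))``.
   ``gc_effect < 1`` models knockdown of a positive regulator of GC entry
   (depletion), ``> 1`` a negative regulator (enrichment).  GC founders
   expand clonally by a rounded log-normal burst; non-GC founders contribute
   one cell each.
4. **PCR replicates** — each compartment's cell pool is amplified five times
   in parallel; per replicate, per construct, read counts are Gamma-Poisson
   (negative-binomial) with mean proportional to cell counts, so that rare
   early-cycle jackpots produce the heavy-tailed replicate scatter the
   median-of-replicates estimator is designed to absorb.
5. **Reads** — each read embeds the construct's full cassette inside the
   fixed nested-PCR amplicon context, on a uniformly random strand, with
   independent substitution errors, written as Phred+33 FASTQ.

A ground-truth table (founder and compartment cell counts, expected log2
fold change from the realized pools) accompanies every simulated screen so
recovery can be tested against what actually happened.
"""

from __future__ import annotations

import gzip
import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .library import LibraryManifest, reverse_complement
from .score import default_pseudocount, fold_change

# Fixed amplicon context for synthetic reads: the second-round nested-PCR
# primer pair (forward primer, then reverse-complemented reverse primer)
# with short constant vector-derived spacers between primers and cassette,
# and a constant tail for padding reads past the amplicon end.
AMPLICON_5 = "GGACTATCATATGCTTACCGTAACTTGA" + "AAGGTATAT"
AMPLICON_3 = "CTGTGAAGC" + reverse_complement("TGGATGTGGAATGTGTGCGA")
PAD_TAIL = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

COMPARTMENTS = ("gc", "nongc")


def stage_rng(seed: int, *labels: str) -> np.random.Generator:
    """Named, reproducible substream of a master seed.

    Each pipeline stage draws from its own stream so that, e.g., changing the
    sequencing depth never perturbs the founder draw.
    """
    entropy = [int(seed)] + [zlib.crc32(label.encode()) for label in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable knobs of the generator (see module docstring for roles)."""

    n_founder_cells: int = 4000
    baseline_gc_prob: float = 0.5
    pool_lognormal_sigma: float = 1.0
    expansion_lognormal_mu: float = float(np.log(8.0) - 0.5**2 / 2)  # mean burst ~8
    expansion_lognormal_sigma: float = 0.5
    n_replicates: int = 5
    reads_per_replicate: int = 100_000
    pcr_dispersion: float = 4.0
    read_length: int = 150
    seq_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founder_cells < 1 or self.n_replicates < 1:
            raise ConfigurationError("cell and replicate counts must be positive")
        if self.reads_per_replicate < 0 or self.read_length < 1:
            raise ConfigurationError("read counts/length must be nonnegative/positive")
        for name in ("baseline_gc_prob", "seq_error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.pool_lognormal_sigma < 0 or self.expansion_lognormal_sigma < 0:
            raise ConfigurationError("log-normal sigmas must be >= 0")
        if not self.pcr_dispersion > 0:
            raise ConfigurationError("pcr_dispersion must be > 0")


def load_config(path) -> SimulationConfig:
    """Read a flat YAML mapping of :class:`SimulationConfig` fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a key: value mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


@dataclass
class EffectTable:
    """Per-gene multiplier on the baseline GC-entry probability."""

    effects: dict[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.effects.items():
            if value < 0:
                raise ConfigurationError(f"gc_effect for {gene} must be >= 0")

    @classmethod
    def neutral(cls, manifest: LibraryManifest) -> "EffectTable":
        return cls({gene: 1.0 for gene in manifest.genes})

    def for_manifest(self, manifest: LibraryManifest) -> np.ndarray:
        """Per-construct effect vector aligned to manifest order."""
        missing = [g for g in manifest.genes if g not in self.effects]
        if missing:
            raise ConfigurationError(f"gene(s) missing from effect table: {missing}")
        return np.array([self.effects[c.gene] for c in manifest], dtype=float)


def read_effects(path) -> EffectTable:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "gc_effect"} <= set(frame.columns):
        raise ConfigurationError(f"effect table {path} needs columns gene, gc_effect")
    return EffectTable(dict(zip(frame["gene"], frame["gc_effect"].astype(float))))


def write_effects(effects: EffectTable, path) -> None:
    pd.DataFrame(
        {"gene": list(effects.effects), "gc_effect": list(effects.effects.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class GroundTruth:
    """Realized per-construct state of one simulated screen."""

    table: pd.DataFrame  # construct_id, gene, founder_count, gc/nongc cells, expected_log2fc

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


def simulate_pool(
    manifest: LibraryManifest, sigma: float, seed_or_rng
) -> np.ndarray:
    """Plasmid-pool proportions per construct (positive, summing to 1)."""
    if len(manifest) == 0:
        raise ConfigurationError("manifest is empty")
    if sigma < 0:
        raise ConfigurationError("pool sigma must be >= 0")
    n = len(manifest)
    if sigma == 0:
        return np.full(n, 1.0 / n)
    rng = _as_rng(seed_or_rng)
    weights = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return weights / weights.sum()


def simulate_fates(
    manifest: LibraryManifest,
    pool: np.ndarray,
    effects: EffectTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Bottleneck, GC-fate assignment, and clonal expansion.

    Founders are drawn multinomially from the pool; each founder enters the
    GC with probability ``clamp(baseline_gc_prob * gc_effect, 0, 1)``.  GC
    founders each expand into a rounded log-normal burst of >= 1 cells;
    non-GC founders contribute one cell each.  The expected log2 fold change
    is computed from the realized cell pools with the scoring module's
    pseudocount rule.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    pool = np.asarray(pool, dtype=float)
    if pool.shape != (len(manifest),):
        raise ConfigurationError("pool does not align with the manifest")
    effect_vec = effects.for_manifest(manifest)
    founders = rng.multinomial(config.n_founder_cells, pool)
    p_gc = np.clip(config.baseline_gc_prob * effect_vec, 0.0, 1.0)
    gc_founders = rng.binomial(founders, p_gc)
    nongc_cells = founders - gc_founders

    gc_cells = np.zeros(len(manifest), dtype=np.int64)
    for i, k in enumerate(gc_founders):
        if k > 0:
            bursts = rng.lognormal(
                config.expansion_lognormal_mu, config.expansion_lognormal_sigma, size=k
            )
            gc_cells[i] = int(np.maximum(1, np.round(bursts)).sum())

    expected = np.full(len(manifest), np.nan)
    if gc_cells.sum() > 0 and nongc_cells.sum() > 0:
        pct_gc = 100.0 * gc_cells / gc_cells.sum()
        pct_ngc = 100.0 * nongc_cells / nongc_cells.sum()
        delta = default_pseudocount(pct_gc, pct_ngc)
        _, expected = fold_change(pct_gc, pct_ngc, pseudocount=delta)

    table = pd.DataFrame(
        {
            "construct_id": manifest.construct_ids,
            "gene": [c.gene for c in manifest],
            "founder_count": founders,
            "gc_cell_count": gc_cells,
            "nongc_cell_count": nongc_cells,
            "expected_log2fc": expected,
        }
    )
    return GroundTruth(table)


def simulate_replicates(
    cell_counts,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Parallel-PCR read counts: shape ``(n_replicates, n_constructs)``.

    Each replicate draws, per construct, ``Poisson(depth * p_i * G)`` with
    ``G ~ Gamma(shape=pcr_dispersion, mean=1)`` — i.e. negative-binomial
    counts whose overdispersion grows as ``pcr_dispersion`` shrinks (the
    PCR-jackpot regime).  Expected total depth per replicate is
    ``reads_per_replicate``; realized totals vary.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    cells = np.asarray(cell_counts, dtype=float)
    if (cells < 0).any():
        raise ConfigurationError("cell counts must be nonnegative")
    if cells.sum() == 0:
        warnings.warn("empty compartment: all cell counts zero; emitting zero reads")
        return np.zeros((config.n_replicates, cells.size), dtype=np.int64)
    proportions = cells / cells.sum()
    counts = np.empty((config.n_replicates, cells.size), dtype=np.int64)
    for r in range(config.n_replicates):
        gain = rng.gamma(config.pcr_dispersion, 1.0 / config.pcr_dispersion, cells.size)
        lam = config.reads_per_replicate * proportions * gain
        counts[r] = rng.poisson(lam)
    return counts


def emit_fastq(
    read_counts: np.ndarray,
    manifest: LibraryManifest,
    config: SimulationConfig,
    out_dir,
    sample: str,
    rng: np.random.Generator | None = None,
    strands: str = "random",
    gzip_output: bool = True,
) -> list[Path]:
    """Write one FASTQ file per replicate for one compartment sample.

    Each read embeds its construct's full cassette inside the fixed amplicon
    context, padded/truncated to ``read_length``; the strand is uniform
    (``strands`` may force ``"forward"``/``"reverse"`` for testing),
    substitution errors are independent per base at ``seq_error_rate``, and
    qualities are constant Phred+33.  Read order is shuffled and read ids
    (``sample:rep:serial``) encode nothing about the construct.
    """
    if strands not in ("random", "forward", "reverse"):
        raise ConfigurationError(f"unknown strands mode {strands!r}")
    rng = _as_rng(rng if rng is not None else config.seed)
    read_counts = np.asarray(read_counts)
    if read_counts.ndim != 2 or read_counts.shape[1] != len(manifest):
        raise ConfigurationError("read_counts must be (n_replicates, n_constructs)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    templates_fwd, templates_rev = [], []
    min_flank = 4
    for construct in manifest:
        amplicon = AMPLICON_5 + construct.oligo + AMPLICON_3
        if config.read_length < len(construct.oligo) + min_flank:
            raise ConfigurationError(
                f"read_length {config.read_length} too short for the "
                f"{len(construct.oligo)} nt cassette plus flanks"
            )
        fwd = (amplicon + PAD_TAIL * 3)[: config.read_length]
        rev = (reverse_complement(amplicon) + PAD_TAIL * 3)[: config.read_length]
        templates_fwd.append(fwd)
        templates_rev.append(rev)

    qual = "I" * config.read_length
    paths = []
    for rep in range(read_counts.shape[0]):
        counts = read_counts[rep]
        total = int(counts.sum())
        construct_of_read = np.repeat(np.arange(len(manifest)), counts)
        construct_of_read = rng.permutation(construct_of_read)
        if strands == "random":
            reverse_flags = rng.integers(0, 2, size=total).astype(bool)
        else:
            reverse_flags = np.full(total, strands == "reverse")
        n_errors = (
            rng.binomial(config.read_length, config.seq_error_rate, size=total)
            if config.seq_error_rate > 0
            else np.zeros(total, dtype=int)
        )
        name = f"{sample}_rep{rep + 1}.fastq" + (".gz" if gzip_output else "")
        path = out_dir / name
        opener = gzip.open if gzip_output else open
        with opener(path, "wt", **({"compresslevel": 2} if gzip_output else {})) as fh:
            for i in range(total):
                c = construct_of_read[i]
                seq = templates_rev[c] if reverse_flags[i] else templates_fwd[c]
                k = n_errors[i]
                if k:
                    seq = _mutate(seq, k, rng)
                fh.write(f"@{sample}:rep{rep + 1}:{i + 1:07d}\n{seq}\n+\n{qual}\n")
        paths.append(path)
    return paths


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _mutate(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_errors, replace=False)
    for pos in positions:
        base = chars[pos]
        alternatives = _OTHER_BASES.get(base, list("ACGT"))
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def simulate_screen(
    manifest: LibraryManifest,
    effects: EffectTable,
    config: SimulationConfig,
    out_dir,
    screen: str = "screen1",
    write_reads: bool = True,
    gzip_output: bool = True,
) -> dict:
    """End-to-end simulation of one screen (both compartments).

    Writes ``{screen}_{compartment}_rep{i}.fastq.gz`` files (5 each for GC
    and non-GC by default), a ground-truth TSV, and a JSON manifest of
    outputs.  Deterministic for a fixed ``config.seed``; stages draw from
    named substreams so each is individually reproducible.

    Returns a dict with the ground truth, per-compartment read-count arrays,
    and output paths.  ``write_reads=False`` skips FASTQ emission (the count
    arrays are the exact read counts the FASTQ files would contain).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = simulate_pool(
        manifest, config.pool_lognormal_sigma, stage_rng(config.seed, screen, "pool")
    )
    truth = simulate_fates(
        manifest, pool, effects, config, stage_rng(config.seed, screen, "fates")
    )
    counts = {}
    fastq_paths: dict[str, list[str]] = {}
    for compartment in COMPARTMENTS:
        column = "gc_cell_count" if compartment == "gc" else "nongc_cell_count"
        cells = truth.table[column].to_numpy()
        counts[compartment] = simulate_replicates(
            cells, config, stage_rng(config.seed, screen, "pcr", compartment)
        )
        if write_reads:
            paths = emit_fastq(
                counts[compartment],
                manifest,
                config,
                out_dir,
                sample=f"{screen}_{compartment}",
                rng=stage_rng(config.seed, screen, "reads", compartment),
                gzip_output=gzip_output,
            )
            fastq_paths[compartment] = [str(p) for p in paths]
    truth_path = out_dir / f"{screen}_truth.tsv"
    truth.write(truth_path)
    outputs = {
        "screen": screen,
        "seed": config.seed,
        "truth": str(truth_path),
        "fastq": fastq_paths,
    }
    with open(out_dir / f"{screen}_outputs.json", "w") as fh:
        json.dump(outputs, fh, indent=2)
    return {"truth": truth, "counts": counts, "outputs": outputs, "pool": pool}


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
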
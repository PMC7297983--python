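# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `gcscreen`, and what the synthetic screens do and do not establish
about real data.

## Hairpin cassette grammar

A cloned shRNA cassette is treated purely as a string:

```
leader + sense + loop + antisense + terminator + trailer
GATCC  + (19-22 nt) + TTCAAGAGA + revcomp(sense) + TTTTTT + GATATCG
```

The default constants are exactly those shared by the four published
pSIREN-style hairpin oligos bundled as fixtures (Bcl6, Zdhhc2-2, Zdhhc2-4,
scramble; 21- and 22-nt stems); they are configurable because other vectors
use other loops. No restriction-site semantics are asserted for the
leader/trailer — the cassette is parsed and assembled as a string only.

**Parsing.** The loop motif is located by scanning every occurrence between
leader and terminator; an occurrence is accepted only if the flanking stems
are equal-length, inside the length range, and exactly reverse-
complementary. An off-centre occurrence shifts one stem longer and the
other shorter, so for an equal-stem grammar at most one occurrence can
validate; a hypothetical tie still raises a dedicated ambiguity error.

**Library generation.** Stems are drawn uniformly over A/C/G/T and accepted
if they avoid the loop motif and runs of ≥6 T on either strand (which would
mimic the Pol III terminator) and differ from every accepted stem at ≥3
positions (default), so a single sequencing error cannot convert one
construct's read into another's under exact matching. Genes are named
`G001…`; effect annotations live outside the manifest so libraries stay
phenotype-agnostic.

## Screen simulator

The generator reproduces the data-generating process the analysis assumes,
with one stage per biological step. Stage randomness comes from named
substreams of one master seed, so changing one stage's parameters never
perturbs another's draws.

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `n_founder_cells` | 4000 | transduced cells seeding the response; ~10× the 390-construct library |
| `baseline_gc_prob` | 0.5 | GC-entry probability of a neutral founder by day 10 (see below) |
| `pool_lognormal_sigma` | 1.0 | plasmid-pool skew; puts ~96 % of constructs above the 0.025 % threshold, matching the reported completeness of such pools (~95 %) |
| `expansion_lognormal_mu/sigma` | ln 8 − 0.125 / 0.5 | GC clonal burst: mean ~8 cells (≈3 divisions), moderate spread; creates realistic dominance of few clones |
| `n_replicates` | 5 | parallel PCR amplifications per compartment |
| `reads_per_replicate` | 100 000 | expected sequencing depth per replicate |
| `pcr_dispersion` | 4.0 | Gamma shape of the per-construct replicate gain; CV = 50 %, far above Poisson, still absorbable by a median of five |
| `read_length` / `seq_error_rate` | 150 / 0.001 | single-end reads, uniform substitutions |

Stages: (1) pool proportions are normalized log-normals (σ = 0 gives the
uniform pool); (2) founders are one multinomial draw; each founder enters
the GC with probability `clamp(baseline_gc_prob × gc_effect(gene), 0, 1)`,
GC founders expand by a rounded log-normal burst (≥1), non-GC founders
contribute one cell each; (3) each replicate's counts are
Poisson(depth × proportion × Gamma(shape = `pcr_dispersion`, mean = 1)) —
negative-binomial "jackpot" noise, the reason the estimator is a median of
five; (4) reads embed the full cassette inside a fixed amplicon context
built from the second-round nested-PCR primer pair plus constant synthetic
spacers and padding, on a uniformly random strand, with independent
substitution errors, written as Phred+33 FASTQ whose read ids carry no
truth information.

**Choice of `baseline_gc_prob`.** The flow-cytometry observation that only
a small percentage of GC B cells carry the reporter reflects dilution by
the enormous endogenous GC response, not the GC-entry rate of transduced
founders; antigen-specific transferred B cells enter GCs efficiently around
the day-10 peak. We therefore model a neutral founder's GC-entry
probability as 0.5. This also makes the neutral screen statistically
well-posed at the 4,000-founder bottleneck: expected GC founders per
construct ≈ 5, so neutral constructs are rarely absent from GC by chance
(Poisson dropout < 1 %), and the neutral-null calibration below holds. At,
say, 0.05 the GC compartment would hold ~0.5 founders per construct and
~60 % of neutral constructs would vanish from GC by sampling alone,
swamping any biological signal at this library size.

## Quantification

Reads are assigned by **exact substring matching** of the construct's
cassette key (`sense+loop+antisense`, 51–53 nt) against the read and its
reverse complement. The counter anchors candidate windows on occurrences of
the invariant loop motif and looks them up in a key dictionary — provably
equivalent to scanning every key against every read (the key contains the
loop at a fixed offset) and verified in the tests against a brute-force
all-pairs scan. Reads matching two or more constructs (chimeras) are
tallied as ambiguous and counted for no construct; a read matching one
construct on both strands counts once. A `sense`-only match mode exists for
short reads. No mismatch tolerance is applied: with error rate *e* and key
length *L* the matched fraction is ≈ (1−e)^L (≈95 % at defaults), and the
loss is uniform across constructs and compartments, thinning coverage
without biasing the GC/non-GC ratio.

Percentages are computed per replicate over **matched** reads (configurable
to total reads) — vector-only or primer-dimer reads would otherwise distort
abundances — and reduced to the exact sample median across replicates;
a replicate with zero matched reads is treated as missing.

## Scoring

* **Scarcity filter**: threshold = `100/(library_size × 10)` percent
  (0.025 % at 400 constructs); *strictly* exceeding it in either compartment
  passes a screen; the consistent-recovery set passes every screen.
* **Fold change**: `(a_GC + δ)/(a_nonGC + δ)` with one δ per screen — half
  the smallest nonzero median across both compartments' tables. A
  sample-level δ keeps GC-absent constructs (the strongest candidate
  positive regulators) finite *and* ordered by their non-GC abundance; a
  per-construct δ would collapse them all to log2 FC = −1.58. The
  construct's log2 FC is the mean of its per-screen values; swapping
  compartments negates it exactly.
* **Consistency**: SD (n−1) of per-replicate fold-change estimates —
  replicate *i* of GC against replicate *i* of non-GC within each screen
  (5 × n_screens estimates; the across-screen pairing is arbitrary but
  fixed). The reciprocal 1/SD is capped at 100 so identical estimates don't
  produce infinities; identical estimates return SD exactly 0. A
  `screen_medians` mode (SD across per-screen median fold changes, ≥2
  screens) implements the stricter per-screen reading.
* **Hit calling**: depleted candidates have log2 FC ≤ −2 (boundary
  inclusive) and 1/SD at or above the median of the consistent set;
  enriched mirror this. The cut-offs are explicit parameters
  (`fc_cut = 2`, `consistency_quantile = 0.5`) — conventions of this
  package, since hit identification on the fold-change-vs-1/SD scatter is
  ultimately a judgement call. Ties break by 1/SD, then construct id. No
  multiple-testing control is applied: the procedure is a ranking, not a
  test.
* **Gene summary**: per gene, constructs recovered in all screens / in some
  but not all / in none (a partition), and the median log2 FC over the
  fully recovered ones. Gene-level reasoning is essential at this scale —
  see below.

## Calibration and what the synthetic screens show

With all effects neutral at the default study scale (390 constructs, 4,000
founders, two screens, 5 × 100k reads per compartment), the pipeline's
construct log2 fold changes pooled over ten simulations have mean ≈ −0.07
(|mean| < 0.1; the small negative offset is the Jensen effect of the larger
clone-size variance on the GC side), and no gene has all its constructs
recovered yet beyond |log2 FC| = 2. With one gene planted at GC-effect 0.05
and one at 4.0, the planted genes top the depleted and enriched gene
rankings in 20/20 seeded two-screen runs.

Individual *constructs*, however, are noisy at this bottleneck: ~5 founders
per construct per compartment give a per-screen log2 FC standard deviation
near 1, so a handful of neutral constructs per run exceed |log2 FC| = 2
even after the consistency gate. This is a property of the experimental
scale, not of the estimator — and it is exactly why the analysis aggregates
five hairpins per gene and demands recovery in every screen before calling
candidates. Expect construct-level hit lists to carry false positives;
trust gene-level concordance.

The simulator emulates pool skew, bottleneck dropout, selection, clonal
expansion, and PCR jackpots. It does **not** model in vivo engraftment
loss, dark-zone/light-zone cycling, hairpin-specific knockdown efficacy,
PCR chimeras, quality-score degradation, or per-mouse structure (recipients
are pooled before sorting). Passing tests therefore establish the
correctness and calibration of the *analysis* under the assumed noise
model, not the biology of any particular screen; real screens with heavier
unmodelled losses will show more construct dropout than the neutral
simulation (which is why the recovery classes in the gene summary matter).

## Numerical and scale choices

Acceptance-level simulations (`scripts/acceptance.py`, `tests/`) run the
null and planted-recovery studies at full study scale but feed the
simulator's replicate counts directly to the abundance stage; the FASTQ
emission + exact-counting round trip is validated separately — it is exact
by construction at zero error rate (verified), so re-running it for every
simulated screen would only re-test I/O. The oracle-equivalence check uses
60 constructs × >1,000 reads with an elevated 2 % error rate to exercise
near-miss windows. Degenerate inputs are defined errors, not silent
results: all-zero sample pairs (no pseudocount derivable), fewer than two
fold-change estimates, empty consistent sets (warning + empty lists),
all-missing replicates, and read lengths too short for the cassette all
raise typed exceptions.
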
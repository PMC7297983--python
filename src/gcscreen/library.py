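"""shRNA hairpin cassettes and library manifests.

A cloned shRNA cassette is a single DNA string with a fixed grammar::

    leader + sense + loop + antisense + terminator + trailer

where ``antisense`` is the reverse complement of ``sense``.  The stem pair
(read out by exact matching in sequencing data) identifies the construct and
hence the targeted gene.  This module models that grammar: parsing a cassette
back into its stems, assembling a cassette from a stem, generating whole
synthetic libraries under design constraints, and reading/writing the
tab-separated library manifest used by every downstream stage.

The default grammar (leader ``GATCC``, loop ``TTCAAGAGA``, terminator
``TTTTTT``, trailer ``GATATCG``, stems 19-22 nt) is shared by all hairpins of
the pSIREN-style cloning scheme this package targets; it is configurable
because other vectors use other loops.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousHairpinError,
    DesignConstraintError,
    GenerationError,
    GrammarMismatchError,
    HairpinInvalidError,
    InvalidAlphabetError,
    ManifestError,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_RE = re.compile(r"^[ACGT]*$")

MANIFEST_COLUMNS = ("construct_id", "gene", "sense", "oligo")


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of an A/C/G/T string.

    Applying the function twice returns the input.  Raises
    :class:`InvalidAlphabetError` on any character outside A/C/G/T
    (case-sensitive; sequences are handled uppercase throughout).
    """
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise InvalidAlphabetError(f"non-ACGT character(s) {bad} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CassetteGrammar:
    """Constant elements of the hairpin cassette.

    Parameters
    ----------
    leader, loop, terminator, trailer
        Fixed DNA elements surrounding the stems.  The terminator is the
        poly-T Pol III stop; leader/trailer are the cloning-site remnants.
    stem_min, stem_max
        Inclusive bounds on stem length (both stems are equal length).
    """

    leader: str = "GATCC"
    loop: str = "TTCAAGAGA"
    terminator: str = "TTTTTT"
    trailer: str = "GATATCG"
    stem_min: int = 19
    stem_max: int = 22

    def __post_init__(self) -> None:
        for name in ("leader", "loop", "terminator", "trailer"):
            value = getattr(self, name)
            if not value or not _DNA_RE.match(value):
                raise DesignConstraintError(
                    f"grammar element {name!r} must be a nonempty ACGT string"
                )
        if not (1 <= self.stem_min <= self.stem_max):
            raise DesignConstraintError(
                f"degenerate stem length range [{self.stem_min}, {self.stem_max}]"
            )

    @property
    def suffix(self) -> str:
        return self.terminator + self.trailer


DEFAULT_GRAMMAR = CassetteGrammar()


def validate_stem(sense: str, grammar: CassetteGrammar = DEFAULT_GRAMMAR) -> None:
    """Check a sense stem against the library design rules.

    Rules: ACGT alphabet, length within the grammar's range, and neither the
    stem nor its reverse complement may contain the loop motif or a run of
    six or more consecutive T (which would mimic the terminator and truncate
    transcription).  Raises :class:`DesignConstraintError` naming the violated
    rule.
    """
    if not _DNA_RE.match(sense):
        raise DesignConstraintError(f"stem contains non-ACGT characters: {sense!r}")
    if not grammar.stem_min <= len(sense) <= grammar.stem_max:
        raise DesignConstraintError(
            f"stem length {len(sense)} outside [{grammar.stem_min}, {grammar.stem_max}]"
        )
    antisense = sense.translate(_COMPLEMENT)[::-1]
    for label, stem in (("sense", sense), ("antisense", antisense)):
        if grammar.loop in stem:
            raise DesignConstraintError(f"{label} stem contains the loop motif")
        if "T" * 6 in stem:
            raise DesignConstraintError(f"{label} stem contains a run of >=6 T")


@dataclass(frozen=True)
class ShRNAConstruct:
    """One library member: identity plus its hairpin decomposition."""

    construct_id: str
    gene: str
    sense: str
    loop: str
    antisense: str
    oligo: str

    def validate(self, grammar: CassetteGrammar = DEFAULT_GRAMMAR) -> None:
        validate_stem(self.sense, grammar)
        if self.antisense != reverse_complement(self.sense):
            raise HairpinInvalidError(
                f"{self.construct_id}: antisense is not the reverse complement of sense"
            )
        if self.loop != grammar.loop:
            raise HairpinInvalidError(
                f"{self.construct_id}: loop {self.loop!r} differs from grammar loop"
            )
        expected = (
            grammar.leader + self.sense + self.loop + self.antisense + grammar.suffix
        )
        if self.oligo != expected:
            raise HairpinInvalidError(
                f"{self.construct_id}: oligo does not reconstruct from its parts"
            )

    @property
    def cassette_key(self) -> str:
        """The stem-loop-stem region used for exact read matching."""
        return self.sense + self.loop + self.antisense


def parse_hairpin(
    oligo: str,
    grammar: CassetteGrammar = DEFAULT_GRAMMAR,
    construct_id: str = "",
    gene: str = "",
) -> ShRNAConstruct:
    """Decompose a full cassette oligo into sense / loop / antisense.

    The loop motif is located by scanning for every occurrence inside the
    region between leader and terminator; an occurrence is accepted only if
    the flanking stems are equal-length, within the grammar's length range,
    and exactly reverse-complementary.  Because an off-centre occurrence
    forces unequal stem lengths, at most one occurrence can validate for an
    equal-stem grammar; a hypothetical tie still raises
    :class:`AmbiguousHairpinError`.
    """
    if not _DNA_RE.match(oligo):
        raise InvalidAlphabetError("oligo contains non-ACGT characters")
    if not oligo.startswith(grammar.leader):
        raise GrammarMismatchError(f"missing leader {grammar.leader!r} at 5' end")
    if not oligo.endswith(grammar.suffix):
        if oligo.endswith(grammar.trailer):
            raise GrammarMismatchError(f"missing terminator {grammar.terminator!r}")
        raise GrammarMismatchError(f"missing trailer {grammar.trailer!r} at 3' end")
    core = oligo[len(grammar.leader) : len(oligo) - len(grammar.suffix)]
    if grammar.loop not in core:
        raise GrammarMismatchError(f"missing loop motif {grammar.loop!r}")

    candidates = []
    start = core.find(grammar.loop)
    while start != -1:
        sense = core[:start]
        antisense = core[start + len(grammar.loop) :]
        if (
            len(sense) == len(antisense)
            and grammar.stem_min <= len(sense) <= grammar.stem_max
            and antisense == sense.translate(_COMPLEMENT)[::-1]
        ):
            candidates.append((sense, antisense))
        start = core.find(grammar.loop, start + 1)
    if not candidates:
        raise HairpinInvalidError(
            "no loop placement yields equal-length reverse-complementary stems"
        )
    if len(candidates) > 1:
        raise AmbiguousHairpinError(
            f"{len(candidates)} loop placements yield valid hairpins"
        )
    sense, antisense = candidates[0]
    return ShRNAConstruct(
        construct_id=construct_id,
        gene=gene,
        sense=sense,
        loop=grammar.loop,
        antisense=antisense,
        oligo=oligo,
    )


def assemble_hairpin(sense: str, grammar: CassetteGrammar = DEFAULT_GRAMMAR) -> str:
    """Build the full cassette oligo for a sense stem (inverse of parsing).

    The stem is validated first (:func:`validate_stem`), so
    ``parse_hairpin(assemble_hairpin(s)) `` recovers ``s`` exactly.
    """
    validate_stem(sense, grammar)
    antisense = reverse_complement(sense)
    return grammar.leader + sense + grammar.loop + antisense + grammar.suffix


@dataclass
class LibraryManifest:
    """Ordered collection of constructs sharing one cassette grammar."""

    constructs: list[ShRNAConstruct]
    grammar: CassetteGrammar = field(default_factory=CassetteGrammar)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.construct_id for c in self.constructs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate construct_id(s): {dup}")
        senses = [c.sense for c in self.constructs]
        if len(set(senses)) != len(senses):
            dup = sorted({s for s in senses if senses.count(s) > 1})
            raise ManifestError(f"duplicate sense sequence(s): {dup}")
        for construct in self.constructs:
            construct.validate(self.grammar)

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LibraryManifest)
            and self.grammar == other.grammar
            and self.constructs == other.constructs
        )

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    @property
    def genes(self) -> list[str]:
        """Gene names in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.constructs:
            seen.setdefault(c.gene, None)
        return list(seen)

    @property
    def k_per_gene(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.constructs:
            counts[c.gene] = counts.get(c.gene, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "construct_id": [c.construct_id for c in self.constructs],
                "gene": [c.gene for c in self.constructs],
                "sense": [c.sense for c in self.constructs],
                "oligo": [c.oligo for c in self.constructs],
            }
        )


def generate_library(
    n_genes: int,
    k_per_gene: int,
    grammar: CassetteGrammar = DEFAULT_GRAMMAR,
    min_pairwise_mismatches: int = 3,
    seed: int = 0,
    stem_length: int = 21,
    max_attempts_per_stem: int = 2000,
) -> LibraryManifest:
    """Generate a synthetic library by constrained rejection sampling.

    Stems of ``stem_length`` nt are drawn uniformly and accepted if they pass
    :func:`validate_stem` and differ from every previously accepted stem at
    >= ``min_pairwise_mismatches`` positions (so a single sequencing error
    cannot convert one construct's read into another's).  Genes are named
    ``G001`` ... and constructs ``G001-1`` ... ``G001-k``; the manifest carries
    no effect annotation, which lives in the simulator's effect table.

    Deterministic for a fixed ``seed``.  Raises :class:`GenerationError` if a
    stem cannot be placed within ``max_attempts_per_stem`` draws.
    """
    if n_genes < 1 or k_per_gene < 1:
        raise GenerationError("n_genes and k_per_gene must be positive")
    if not grammar.stem_min <= stem_length <= grammar.stem_max:
        raise GenerationError(
            f"stem_length {stem_length} outside grammar range "
            f"[{grammar.stem_min}, {grammar.stem_max}]"
        )
    n_total = n_genes * k_per_gene
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    accepted = np.empty((n_total, stem_length), dtype=np.uint8)
    n_accepted = 0
    attempts = 0
    while n_accepted < n_total:
        if attempts >= max_attempts_per_stem:
            raise GenerationError(
                f"could not place stem {n_accepted + 1}/{n_total} after "
                f"{attempts} attempts; relax length/distance constraints"
            )
        candidate = bases[rng.integers(0, 4, size=stem_length)]
        attempts += 1
        sense = candidate.tobytes().decode()
        try:
            validate_stem(sense, grammar)
        except DesignConstraintError:
            continue
        if n_accepted:
            dists = (accepted[:n_accepted] != candidate).sum(axis=1)
            if int(dists.min()) < min_pairwise_mismatches:
                continue
        accepted[n_accepted] = candidate
        n_accepted += 1
        attempts = 0

    width = max(3, len(str(n_genes)))
    constructs = []
    for g in range(n_genes):
        gene = f"G{g + 1:0{width}d}"
        for k in range(k_per_gene):
            sense = accepted[g * k_per_gene + k].tobytes().decode()
            oligo = assemble_hairpin(sense, grammar)
            constructs.append(
                parse_hairpin(oligo, grammar, construct_id=f"{gene}-{k + 1}", gene=gene)
            )
    return LibraryManifest(constructs=constructs, grammar=grammar)


def read_manifest(
    path, grammar: CassetteGrammar = DEFAULT_GRAMMAR
) -> LibraryManifest:
    """Read a tab-separated manifest (construct_id, gene, sense[, oligo]).

    The ``oligo`` column is optional on input; missing oligos are assembled
    from the sense stem.  Every row is re-validated (grammar parse, hairpin
    invariant); errors report the offending 1-based data row.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"construct_id", "gene", "sense"} - set(frame.columns)
    if missing:
        raise ManifestError(f"manifest {path} missing column(s): {sorted(missing)}")
    constructs = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        oligo = getattr(row, "oligo", "") if "oligo" in frame.columns else ""
        try:
            if not oligo:
                oligo = assemble_hairpin(row.sense, grammar)
            construct = parse_hairpin(
                oligo, grammar, construct_id=row.construct_id, gene=row.gene
            )
            if construct.sense != row.sense:
                raise ManifestError(
                    f"oligo stems disagree with the sense column ({row.sense!r})"
                )
        except (ManifestError, DesignConstraintError, GrammarMismatchError,
                HairpinInvalidError, InvalidAlphabetError, AmbiguousHairpinError) as exc:
            raise ManifestError(
                f"manifest {path} row {row_no} ({row.construct_id!r}): {exc}"
            ) from exc
        constructs.append(construct)
    return LibraryManifest(constructs=constructs, grammar=grammar)


def write_manifest(manifest: LibraryManifest, path) -> None:
    """Write a manifest as UTF-8 TSV with Unix newlines, preserving order."""
    manifest.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
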
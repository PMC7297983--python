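"""Shared fixtures: published hairpin oligos, small libraries, read factories."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gcscreen.library import (
    DEFAULT_GRAMMAR,
    LibraryManifest,
    generate_library,
    parse_hairpin,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The four published hairpin cassette oligos cloned into the pSIREN-RetroQ
# vectors (two Zdhhc2 hairpins, the Bcl6 hairpin, and a scramble control).
PUBLISHED_OLIGOS = {
    "Bcl6-1": (
        "Bcl6",
        "GATCCGCTGTCAAAGAGAAGGCTTTATTCAAGAGATAAAGCCTTCTCTTTGACAGCTTTTTTGATATCG",
    ),
    "Zdhhc2-2": (
        "Zdhhc2",
        "GATCCGTGACAGATGCCAACTTATAATTCAAGAGATTATAAGTTGGCATCTGTCACTTTTTTGATATCG",
    ),
    "Zdhhc2-4": (
        "Zdhhc2",
        "GATCCGCTACTCCTGCGGGACTAAATTTTCAAGAGAAATTTAGTCCCGCAGGAGTAGCTTTTTTGATATCG",
    ),
    "scramble-1": (
        "scramble",
        "GATCCGTGCGTTGCTAGTACCAACCTATTCAAGAGATAGGTTGGTACTAGCAACGCACTTTTTTGATATCG",
    ),
}


@pytest.fixture(scope="session")
def grammar():
    return DEFAULT_GRAMMAR


@pytest.fixture(scope="session")
def published_manifest():
    """Manifest built from the four published cassette oligos."""
    constructs = [
        parse_hairpin(oligo, DEFAULT_GRAMMAR, construct_id=cid, gene=gene)
        for cid, (gene, oligo) in PUBLISHED_OLIGOS.items()
    ]
    return LibraryManifest(constructs=constructs)


@pytest.fixture(scope="session")
def small_manifest():
    """Synthetic 6-gene x 5-hairpin library (30 constructs)."""
    return generate_library(6, 5, seed=11)


@pytest.fixture(scope="session")
def medium_manifest():
    """Synthetic 12-gene x 5-hairpin library (60 constructs)."""
    return generate_library(12, 5, seed=23)


def naive_count(reads, manifest):
    """Independent counting oracle: all-pairs, both-strand substring scan.

    For every read, every construct's cassette key (sense+loop+antisense) is
    tested with ``in`` against the read and against the read's reverse
    complement.  Returns (per-construct counts dict, matched, ambiguous,
    unmatched).  Deliberately brute force and separate from the package's
    anchored matcher.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    keys = {c.construct_id: c.sense + manifest.grammar.loop + c.antisense
            for c in manifest}
    counts = {cid: 0 for cid in keys}
    matched = ambiguous = unmatched = 0
    for read in reads:
        read = read.upper()
        rc = read.translate(comp)[::-1]
        hits = {cid for cid, key in keys.items() if key in read or key in rc}
        if len(hits) == 1:
            counts[hits.pop()] += 1
            matched += 1
        elif hits:
            ambiguous += 1
        else:
            unmatched += 1
    return counts, matched, ambiguous, unmatched


def write_fastq(path, reads, qual_char="I"):
    """Write plain (uncompressed) 4-line FASTQ records for the given reads."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i + 1}\n{seq}\n+\n{qual_char * len(seq)}\n")
    return path


def random_reads(rng, n, length=150):
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, length)]) for _ in range(n)]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
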
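"""Exact-match read counting and median-of-replicates abundance.

A read is assigned to a construct when the construct's match key occurs as
an exact substring of the read or of its reverse complement.  The default
key is the full hairpin ``sense + loop + antisense`` (51-53 nt) — maximally
specific because the stem pair is unique per construct; ``match_mode="sense"``
matches on the 19-22 nt sense stem alone for short-read data.  Reads hitting
two or more constructs' keys (chimeras) are tallied as ambiguous and counted
for no construct; a read matching one construct on both strands counts once.

Counting is exact (no mismatch tolerance): a sequencing error anywhere in
the key loses the read, uniformly across constructs and compartments, so the
loss thins coverage without biasing the GC / non-GC ratio.  With error rate
``e`` and key length ``L`` the expected matched fraction is ``(1 - e)**L``.

Percentages are computed within each replicate over *matched* reads by
default (configurable to total reads), and the five parallel replicates are
reduced to one abundance per construct by the exact sample median — robust
to a single PCR-jackpot replicate.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, EmptySampleError, FastqParseError
from .library import CassetteGrammar, LibraryManifest

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

TOTALS_ROWS = ("matched", "ambiguous", "unmatched")


class CassetteMatcher:
    """Keyed exact-substring matcher for hairpin cassettes.

    In cassette mode, candidate windows are anchored on occurrences of the
    invariant loop motif: for each loop hit at position ``p`` and each stem
    length ``L`` present in the library, the window ``seq[p-L : p+|loop|+L]``
    is looked up in a key dictionary.  This is equivalent to scanning every
    key against the read (the key contains the loop at a fixed offset) but
    costs one ``str.find`` chain plus a handful of dict lookups per read.
    Sense mode slides a window of each stem length across the read.
    """

    def __init__(
        self,
        manifest: LibraryManifest,
        grammar: CassetteGrammar | None = None,
        match_mode: str = "cassette",
    ) -> None:
        if len(manifest) == 0:
            raise ConfigurationError("manifest is empty")
        if match_mode not in ("cassette", "sense"):
            raise ConfigurationError(f"unknown match_mode {match_mode!r}")
        grammar = grammar or manifest.grammar
        self.match_mode = match_mode
        self.loop = grammar.loop
        if match_mode == "cassette":
            self.key_to_id = {c.cassette_key: c.construct_id for c in manifest}
            self.stem_lengths = sorted({len(c.sense) for c in manifest})
        else:
            self.key_to_id = {c.sense: c.construct_id for c in manifest}
            self.stem_lengths = sorted({len(c.sense) for c in manifest})

    def match(self, seq: str) -> set[str]:
        """Construct ids whose key occurs in ``seq`` or its reverse complement."""
        seq = seq.upper()
        hits = self._scan(seq)
        hits |= self._scan(seq.translate(_RC_TABLE)[::-1])
        return hits

    def _scan(self, seq: str) -> set[str]:
        hits: set[str] = set()
        lookup = self.key_to_id.get
        if self.match_mode == "cassette":
            loop_len = len(self.loop)
            pos = seq.find(self.loop)
            while pos != -1:
                for L in self.stem_lengths:
                    if pos >= L:
                        cid = lookup(seq[pos - L : pos + loop_len + L])
                        if cid is not None:
                            hits.add(cid)
                pos = seq.find(self.loop, pos + 1)
        else:
            for L in self.stem_lengths:
                for i in range(len(seq) - L + 1):
                    cid = lookup(seq[i : i + L])
                    if cid is not None:
                        hits.add(cid)
        return hits


@dataclass
class CountMatrix:
    """Per-replicate construct counts and read-fate totals for one sample.

    ``counts``: DataFrame indexed by construct_id with a ``gene`` column and
    one integer column per replicate.  ``totals``: DataFrame indexed by
    replicate with matched / ambiguous / unmatched columns; per replicate,
    the three fates partition the reads and the construct counts sum to
    ``matched``.
    """

    sample: str
    counts: pd.DataFrame
    totals: pd.DataFrame

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.counts.columns if c != "gene"]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_reads(
    fastq_paths,
    manifest: LibraryManifest,
    grammar: CassetteGrammar | None = None,
    match_mode: str = "cassette",
    sample: str = "sample",
) -> CountMatrix:
    """Count cassette occurrences in one or more FASTQ files (one per replicate).

    Each file becomes one replicate column (``rep1`` ...).  Gzipped input is
    detected by the ``.gz`` suffix.  Raises :class:`FastqParseError` with the
    file and approximate record index on malformed input.
    """
    if isinstance(fastq_paths, (str, bytes)) or hasattr(fastq_paths, "suffix"):
        paths = [fastq_paths]
    else:
        paths = list(fastq_paths)
    if not paths:
        raise ConfigurationError("no FASTQ files given")
    matcher = CassetteMatcher(manifest, grammar, match_mode)
    ids = manifest.construct_ids
    id_index = {cid: i for i, cid in enumerate(ids)}

    count_cols = {}
    totals_rows = []
    for rep_no, path in enumerate(paths, start=1):
        counts = np.zeros(len(ids), dtype=np.int64)
        matched = ambiguous = unmatched = 0
        record_no = 0
        try:
            with _open_text(path) as fh:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    record_no += 1
                    hits = matcher.match(seq)
                    if len(hits) == 1:
                        counts[id_index[next(iter(hits))]] += 1
                        matched += 1
                    elif len(hits) > 1:
                        ambiguous += 1
                    else:
                        unmatched += 1
        except ValueError as exc:
            raise FastqParseError(
                f"{path}: malformed FASTQ near record {record_no + 1}: {exc}"
            ) from exc
        count_cols[f"rep{rep_no}"] = counts
        totals_rows.append(
            {"replicate": f"rep{rep_no}", "matched": matched,
             "ambiguous": ambiguous, "unmatched": unmatched}
        )

    counts_frame = pd.DataFrame(count_cols, index=pd.Index(ids, name="construct_id"))
    counts_frame.insert(0, "gene", [c.gene for c in manifest])
    totals = pd.DataFrame(totals_rows).set_index("replicate")
    return CountMatrix(sample=sample, counts=counts_frame, totals=totals)


def counts_from_array(
    read_counts: np.ndarray, manifest: LibraryManifest, sample: str = "sample"
) -> CountMatrix:
    """Wrap a simulator ``(n_replicates, n_constructs)`` array as a CountMatrix.

    Used to run the abundance/scoring stages directly on simulated counts
    (exactly what error-free FASTQ emission plus exact counting would yield).
    """
    read_counts = np.asarray(read_counts)
    if read_counts.ndim != 2 or read_counts.shape[1] != len(manifest):
        raise ConfigurationError("read_counts must be (n_replicates, n_constructs)")
    cols = {f"rep{r + 1}": read_counts[r] for r in range(read_counts.shape[0])}
    counts = pd.DataFrame(cols, index=pd.Index(manifest.construct_ids, name="construct_id"))
    counts.insert(0, "gene", [c.gene for c in manifest])
    totals = pd.DataFrame(
        {
            "replicate": list(cols),
            "matched": [int(read_counts[r].sum()) for r in range(read_counts.shape[0])],
            "ambiguous": 0,
            "unmatched": 0,
        }
    ).set_index("replicate")
    return CountMatrix(sample=sample, counts=counts, totals=totals)


def to_percentages(
    count_matrix: CountMatrix, denominator: str = "matched"
) -> pd.DataFrame:
    """Per-replicate percentage of each construct.

    ``denominator="matched"`` (default) divides by the replicate's matched
    reads, so percentages sum to 100 within each replicate; ``"total"``
    divides by all reads including ambiguous and unmatched.  A replicate
    with zero matched reads yields NaN percentages (excluded from medians).
    """
    if denominator not in ("matched", "total"):
        raise ConfigurationError(f"unknown denominator mode {denominator!r}")
    out = pd.DataFrame(index=count_matrix.counts.index)
    out["gene"] = count_matrix.counts["gene"]
    for col in count_matrix.replicate_columns:
        matched = count_matrix.totals.loc[col, "matched"]
        if denominator == "total":
            denom = int(count_matrix.totals.loc[col].sum())
        else:
            denom = int(matched)
        if matched == 0:
            out[f"{col}_pct"] = np.nan
        else:
            out[f"{col}_pct"] = 100.0 * count_matrix.counts[col] / denom
    return out


def median_abundance(percentages: pd.DataFrame) -> pd.DataFrame:
    """Reduce replicate percentages to one median abundance per construct.

    The exact sample median (midpoint of the two central values for an even
    number of replicates) over the non-missing replicates; invariant under
    replicate permutation and robust to a single jackpot replicate.  Raises
    :class:`EmptySampleError` if every replicate is missing.
    """
    pct_cols = [c for c in percentages.columns if c.endswith("_pct")]
    if not pct_cols:
        raise ConfigurationError("no replicate percentage columns found")
    values = percentages[pct_cols].to_numpy(dtype=float)
    if np.isnan(values).all():
        raise EmptySampleError("all replicates missing; no median abundance defined")
    out = percentages.copy()
    with np.errstate(invalid="ignore"):
        out["median_pct"] = np.nanmedian(values, axis=1)
    return out


def write_counts(count_matrix: CountMatrix, path) -> None:
    """Counts TSV: construct rows, then matched/ambiguous/unmatched summary rows."""
    frame = count_matrix.counts.reset_index()
    reps = count_matrix.replicate_columns
    summary_rows = []
    for fate in TOTALS_ROWS:
        row = {"construct_id": fate, "gene": "-"}
        row.update({rep: int(count_matrix.totals.loc[rep, fate]) for rep in reps})
        summary_rows.append(row)
    frame = pd.concat([frame, pd.DataFrame(summary_rows)], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts_table(path, sample: str = "sample") -> CountMatrix:
    """Inverse of :func:`write_counts`."""
    frame = pd.read_csv(path, sep="\t", dtype={"construct_id": str, "gene": str})
    is_summary = frame["construct_id"].isin(TOTALS_ROWS)
    body = frame[~is_summary].set_index("construct_id")
    summary = frame[is_summary].set_index("construct_id")
    reps = [c for c in body.columns if c != "gene"]
    totals = pd.DataFrame(
        {fate: [int(summary.loc[fate, rep]) for rep in reps] for fate in TOTALS_ROWS},
        index=pd.Index(reps, name="replicate"),
    )
    body[reps] = body[reps].astype(np.int64)
    return CountMatrix(sample=sample, counts=body, totals=totals)


def write_abundance(abundance: pd.DataFrame, path) -> None:
    abundance.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_abundance(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"construct_id": str, "gene": str}).set_index(
        "construct_id"
    )
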
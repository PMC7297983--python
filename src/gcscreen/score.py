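"""Scarcity filtering, GC/non-GC fold change, consistency, and hit ranking.

The screen readout is simple by design: for each construct, its median
percentage abundance in the germinal-center (GC) compartment is divided by
its median percentage abundance in the non-GC compartment.  A construct whose
knockdown removes a positive regulator of GC differentiation is depleted from
GC (fold change < 1); a negative-regulator knockdown is enriched (> 1).

Constructs too scarce to quantify are removed first by the scarcity filter:
with a library of ``n`` constructs the uniform expectation is ``100/n`` %,
and a construct is kept only if its median abundance *exceeds* one tenth of
that (0.025 % for a 400-construct library) in either compartment, in every
screen ("consistently recovered").

Fold changes are reported as binary logarithms, paired with a consistency
measure: the reciprocal of the standard deviation of per-replicate fold-change
estimates.  Large |log2 FC| with large 1/SD marks a strong, reproducible
candidate.  A small 2^-ddCt utility for qPCR validation lives here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptySampleError,
    InsufficientReplicationError,
)

CATEGORY_DEPLETED = "positive_regulator_candidate"
CATEGORY_ENRICHED = "negative_regulator_candidate"
CATEGORY_NEUTRAL = "neutral"
CATEGORY_EXCLUDED = "excluded"


def filter_threshold(library_size: int, scarcity_factor: float = 10.0) -> float:
    """Scarcity cut-off in percent: ``100 / (library_size * scarcity_factor)``.

    For 400 constructs and the default factor 10 this is 0.025 %, i.e. ten
    times less than the uniform average abundance.
    """
    if library_size < 1:
        raise ConfigurationError(f"library_size must be >= 1, got {library_size}")
    if not scarcity_factor > 0:
        raise ConfigurationError(f"scarcity_factor must be > 0, got {scarcity_factor}")
    return 100.0 / (library_size * scarcity_factor)


@dataclass(frozen=True)
class FilterPolicy:
    """Scarcity-filter parameters.

    ``compartments_rule="either"``: a construct passes a screen if its median
    abundance exceeds the threshold in the GC *or* the non-GC compartment.
    ``screens_rule="all"``: the consistent-recovery set comprises constructs
    passing every screen.
    """

    library_size: int
    scarcity_factor: float = 10.0
    compartments_rule: str = "either"
    screens_rule: str = "all"

    def __post_init__(self) -> None:
        if self.compartments_rule != "either" or self.screens_rule != "all":
            raise ConfigurationError(
                "only compartments_rule='either' with screens_rule='all' is defined"
            )
        filter_threshold(self.library_size, self.scarcity_factor)

    @property
    def threshold(self) -> float:
        return filter_threshold(self.library_size, self.scarcity_factor)


@dataclass
class ScreenAbundance:
    """Median abundance tables of one screen's two compartments.

    ``gc`` and ``nongc`` are abundance frames as produced by
    :func:`gcscreen.quantify.median_abundance`: indexed by construct_id, with
    a ``gene`` column, per-replicate ``rep*_pct`` columns and ``median_pct``.
    """

    name: str
    gc: pd.DataFrame
    nongc: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.gc.index.equals(self.nongc.index):
            raise ConfigurationError(
                f"screen {self.name}: GC and non-GC tables cover different constructs"
            )

    @property
    def replicate_columns(self) -> list[str]:
        return [c for c in self.gc.columns if c.endswith("_pct") and c != "median_pct"]


def default_pseudocount(median_gc, median_nongc) -> float:
    """Half the smallest nonzero median across the GC/non-GC sample pair."""
    values = np.concatenate(
        [np.asarray(median_gc, dtype=float).ravel(),
         np.asarray(median_nongc, dtype=float).ravel()]
    )
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise EmptySampleError("all medians are zero; no pseudocount can be derived")
    return float(nonzero.min()) / 2.0


def fold_change(median_gc, median_nongc, pseudocount: float | None = None):
    """GC/non-GC abundance ratio with pseudocount flooring.

    ``FC = (median_gc + d) / (median_nongc + d)`` with ``d`` the pseudocount
    (default: half the smallest nonzero median in the sample pair, shared by
    all constructs of the pair so that fully GC-absent constructs remain
    finite and rankable).  Returns ``(fc, log2_fc)``; inputs may be scalars
    or aligned arrays.  Swapping the compartments maps ``log2_fc`` to its
    negative exactly.
    """
    gc = np.asarray(median_gc, dtype=float)
    ngc = np.asarray(median_nongc, dtype=float)
    if (gc < 0).any() or (ngc < 0).any():
        raise ConfigurationError("median abundances must be nonnegative")
    if pseudocount is None:
        pseudocount = default_pseudocount(gc, ngc)
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be nonnegative")
    if pseudocount == 0 and ((gc == 0) & (ngc == 0)).any():
        raise EmptySampleError(
            "fold change undefined: both medians zero with zero pseudocount"
        )
    fc = (gc + pseudocount) / (ngc + pseudocount)
    log2_fc = np.log2(fc)
    if np.isscalar(median_gc) and np.isscalar(median_nongc):
        return float(fc), float(log2_fc)
    return fc, log2_fc


def consistency(estimates, cap: float = 100.0):
    """Spread of a construct's fold-change estimates.

    Returns ``(fc_sd, inv_sd)`` where ``fc_sd`` is the sample standard
    deviation (n-1 denominator) of the log2 fold-change estimates and
    ``inv_sd = min(1/fc_sd, cap)``; identical estimates give SD 0 and the
    cap.  Requires at least two estimates.
    """
    values = np.asarray(estimates, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InsufficientReplicationError(
            f"need >=2 fold-change estimates, got {values.size}"
        )
    # identical estimates must give exactly 0, not accumulation noise
    sd = 0.0 if np.ptp(values) == 0 else float(np.std(values, ddof=1))
    inv = cap if sd == 0 else min(1.0 / sd, cap)
    return sd, float(inv)


def apply_filter(screens: list[ScreenAbundance], policy: FilterPolicy) -> pd.DataFrame:
    """Pass/fail per construct per screen plus the consistent-recovery flag.

    A construct passes a screen iff its median abundance strictly exceeds the
    policy threshold in either compartment; the ``consistent`` column marks
    constructs passing every screen.
    """
    if not screens:
        raise ConfigurationError("no screens provided")
    index = screens[0].gc.index
    for s in screens[1:]:
        if not s.gc.index.equals(index):
            raise ConfigurationError(
                f"screen {s.name} covers a different manifest than {screens[0].name}"
            )
    out = pd.DataFrame(index=index)
    out["gene"] = screens[0].gc["gene"]
    for i, s in enumerate(screens, start=1):
        out[f"pass_screen{i}"] = (
            (s.gc["median_pct"] > policy.threshold)
            | (s.nongc["median_pct"] > policy.threshold)
        )
    pass_cols = [c for c in out.columns if c.startswith("pass_screen")]
    out["consistent"] = out[pass_cols].all(axis=1)
    return out


def score_screens(
    screens: list[ScreenAbundance],
    policy: FilterPolicy,
    consistency_mode: str = "replicate_pairs",
    inv_sd_cap: float = 100.0,
    fc_cut: float = 2.0,
    consistency_quantile: float = 0.5,
) -> pd.DataFrame:
    """Full per-construct score table across one or more screens.

    Per screen, a shared pseudocount (half the smallest nonzero median in the
    GC/non-GC pair) floors the ratio; the construct's ``log2_fc`` is the mean
    of its per-screen log2 fold changes and ``fold_change = 2**log2_fc``.

    ``consistency_mode``:

    * ``"replicate_pairs"`` (default): the SD is taken over per-replicate
      estimates — replicate *i* of GC paired with replicate *i* of non-GC
      within each screen, giving ``n_replicates * n_screens`` estimates.
    * ``"screen_medians"``: the SD is taken over the per-screen median-based
      log2 fold changes (requires >= 2 screens).

    Categories: constructs failing consistent recovery are ``excluded``;
    among the rest, those with ``log2_fc <= -fc_cut`` (or ``>= +fc_cut``) and
    ``inv_sd`` at or above the stated quantile of the consistent set's
    ``inv_sd`` are depletion (enrichment) candidates; all others ``neutral``.
    """
    if consistency_mode not in ("replicate_pairs", "screen_medians"):
        raise ConfigurationError(f"unknown consistency_mode {consistency_mode!r}")
    if consistency_mode == "screen_medians" and len(screens) < 2:
        raise InsufficientReplicationError(
            "screen_medians consistency needs >= 2 screens"
        )
    flags = apply_filter(screens, policy)
    index = flags.index
    n = len(index)

    per_screen_l2 = np.empty((len(screens), n))
    estimates: list[np.ndarray] = []
    mean_gc = np.zeros(n)
    mean_ngc = np.zeros(n)
    for si, s in enumerate(screens):
        mg = s.gc["median_pct"].to_numpy(dtype=float)
        mn = s.nongc["median_pct"].to_numpy(dtype=float)
        delta = default_pseudocount(mg, mn)
        _, per_screen_l2[si] = fold_change(mg, mn, pseudocount=delta)
        mean_gc += mg
        mean_ngc += mn
        if consistency_mode == "replicate_pairs":
            for col in s.replicate_columns:
                g = s.gc[col].to_numpy(dtype=float)
                ng = s.nongc[col].to_numpy(dtype=float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    estimates.append(np.log2((g + delta) / (ng + delta)))
    if consistency_mode == "screen_medians":
        estimates = [per_screen_l2[si] for si in range(len(screens))]
    est = np.vstack(estimates)

    log2_fc = per_screen_l2.mean(axis=0)
    n_est = (~np.isnan(est)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        fc_sd = np.nanstd(est, axis=0, ddof=1)
    fc_sd[n_est < 2] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sd = np.where(fc_sd == 0, inv_sd_cap, np.minimum(1.0 / fc_sd, inv_sd_cap))

    scores = pd.DataFrame(index=index)
    scores["gene"] = flags["gene"]
    scores["median_gc_pct"] = mean_gc / len(screens)
    scores["median_nongc_pct"] = mean_ngc / len(screens)
    for col in flags.columns:
        if col.startswith("pass_screen"):
            scores[col] = flags[col]
    scores["consistent"] = flags["consistent"]
    scores["log2_fc"] = log2_fc
    scores["fold_change"] = np.exp2(log2_fc)
    scores["fc_sd"] = fc_sd
    scores["inv_sd"] = inv_sd

    category = np.full(n, CATEGORY_NEUTRAL, dtype=object)
    consistent = scores["consistent"].to_numpy()
    category[~consistent] = CATEGORY_EXCLUDED
    if consistent.any():
        inv_ok = _consistency_gate(inv_sd, consistent, consistency_quantile)
        category[consistent & (log2_fc <= -fc_cut) & inv_ok] = CATEGORY_DEPLETED
        category[consistent & (log2_fc >= fc_cut) & inv_ok] = CATEGORY_ENRICHED
    scores["category"] = category
    return scores


def _consistency_gate(inv_sd, consistent, quantile: float) -> np.ndarray:
    pool = inv_sd[consistent & ~np.isnan(inv_sd)]
    if pool.size == 0:
        return np.zeros_like(consistent, dtype=bool)
    cut = np.quantile(pool, quantile)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(inv_sd, nan=-np.inf) >= cut


def rank_hits(
    scores: pd.DataFrame,
    fc_cut: float = 2.0,
    consistency_quantile: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordered candidate lists from a score table.

    Depleted candidates: consistent constructs with ``log2_fc <= -fc_cut``
    (boundary inclusive) and ``inv_sd`` at or above the given quantile of
    the consistent set, sorted ascending by ``log2_fc``; enriched candidates
    mirror this with ``>= +fc_cut``, sorted descending.  Ties break by
    ``inv_sd`` (more consistent first), then ``construct_id``.
    """
    consistent = scores["consistent"].to_numpy(dtype=bool)
    if not consistent.any():
        import warnings

        warnings.warn("consistent-recovery set is empty; no hits can be ranked")
        empty = scores.iloc[0:0]
        return empty, empty
    inv_ok = _consistency_gate(
        scores["inv_sd"].to_numpy(dtype=float), consistent, consistency_quantile
    )
    base = scores[consistent & inv_ok]
    depleted = _sort_hits(base[base["log2_fc"] <= -fc_cut], ascending=True)
    enriched = _sort_hits(base[base["log2_fc"] >= fc_cut], ascending=False)
    return depleted, enriched


def _sort_hits(subset: pd.DataFrame, ascending: bool) -> pd.DataFrame:
    frame = subset.copy()
    frame["_id"] = frame.index.astype(str)
    frame = frame.sort_values(
        by=["log2_fc", "inv_sd", "_id"],
        ascending=[ascending, False, True],
        kind="mergesort",
    )
    return frame.drop(columns="_id")


def gene_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-gene construct recovery classes and median fold change.

    For each gene: number of constructs recovered in all screens, recovered
    in at least one but not all, and lost in all; the three counts partition
    the gene's constructs.  ``median_log2_fc`` is the median ``log2_fc`` over
    the all-screen-recovered constructs (NaN if none).
    """
    pass_cols = [c for c in scores.columns if c.startswith("pass_screen")]
    if not pass_cols:
        raise ConfigurationError("score table carries no pass_screen columns")
    passes = scores[pass_cols].to_numpy(dtype=bool)
    n_pass = passes.sum(axis=1)
    all_screens = n_pass == len(pass_cols)
    some = (n_pass > 0) & ~all_screens
    work = pd.DataFrame(
        {
            "gene": scores["gene"].to_numpy(),
            "all": all_screens,
            "some": some,
            "none": n_pass == 0,
            "log2_fc": scores["log2_fc"].to_numpy(),
        }
    )
    rows = []
    for gene, grp in work.groupby("gene", sort=False):
        recovered = grp.loc[grp["all"], "log2_fc"]
        rows.append(
            {
                "gene": gene,
                "n_constructs": len(grp),
                "n_recovered_all_screens": int(grp["all"].sum()),
                "n_recovered_one_screen": int(grp["some"].sum()),
                "n_lost_all_screens": int(grp["none"].sum()),
                "median_log2_fc": float(recovered.median()) if len(recovered) else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def plot_scatter(scores: pd.DataFrame, path, fc_cut: float = 2.0) -> None:
    """Write the log2 fold-change vs 1/SD scatter of the consistent set.

    Depletion/enrichment candidate regions beyond ``fc_cut`` are shaded.
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = scores.loc[scores["consistent"]]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    neutral = data["category"] == CATEGORY_NEUTRAL
    ax.scatter(data.loc[neutral, "log2_fc"], data.loc[neutral, "inv_sd"],
               s=12, c="0.6", label="recovered")
    for cat, color, label in (
        (CATEGORY_DEPLETED, "tab:blue", "depleted (positive regulator?)"),
        (CATEGORY_ENRICHED, "tab:red", "enriched (negative regulator?)"),
    ):
        sel = data["category"] == cat
        if sel.any():
            ax.scatter(data.loc[sel, "log2_fc"], data.loc[sel, "inv_sd"],
                       s=18, c=color, label=label)
    for x in (-fc_cut, fc_cut):
        ax.axvline(x, ls="--", lw=0.8, c="0.4")
    ax.set_xlabel("log2 fold change (GC / non-GC)")
    ax.set_ylabel("1 / SD of fold-change estimates")
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One relative-expression qPCR measurement (test vs control sample)."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    @property
    def fold_difference(self) -> float:
        return ddct_fold(
            self.ct_target_test,
            self.ct_reference_test,
            self.ct_target_control,
            self.ct_reference_control,
        )


def ddct_fold(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,control -
    Ct_ref,control)``; the fold difference of the test sample relative to the
    control is ``2 ** -ddCt``.
    """
    cts = (ct_target_test, ct_reference_test, ct_target_control, ct_reference_control)
    if not all(math.isfinite(c) for c in cts):
        raise ConfigurationError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_test - ct_reference_test) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0 ** -ddct)
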
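"""Statistical procedures for barcoded-screen count data.

Covers: counts-per-fixed-total normalization, log2 fold change with a
pseudocount, per-ORF barcode concordance, recombination-frequency
estimation with the homozygous-virion correction, an exact binomial rate
comparison, the GC-bias correlation diagnostic, and the subpool-distortion
diagnostic.

The homozygous-virion correction: recombination between the two identical
genomes of a homozygous virion is undetectable, so the measured chimera
frequency underestimates the true recombination frequency. With ``h`` the
homozygous-virion fraction (``sum(p_i**2)``; 1/11 = 9.09% for an equimolar
11-clone pool), the corrected estimate is

    f_true = f_measured * (1 + h)

i.e. the measured frequency plus the inferred frequency of undetected
events in homozygous virions. (Note this conventional correction is not the
exact inverse of the generative relation f_measured = p * (1 - h); see the
methods documentation for the ~0.2-point difference at the measured rates.)

No multiple-testing correction is applied anywhere: the procedures here
report single correlations and a single rate comparison. Users running many
tests should correct downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import CountMatrix, Library
from .packaging import homozygosity_fraction, ProvirusTable

__all__ = [
    "normalize_counts",
    "log2fc",
    "barcode_concordance",
    "RecombEstimate",
    "measured_recombination_frequency",
    "correct_recombination_frequency",
    "recombination_estimate",
    "compare_recombination",
    "GcBiasReport",
    "gc_bias_test",
    "SubpoolDistortion",
    "subpool_distortion",
]


def normalize_counts(cm: CountMatrix, total: float = 1e6) -> CountMatrix:
    """Scale each sample column to sum to ``total`` (reads-per-million default).

    Per-element proportions within a sample are unchanged. Rejects zero-sum
    columns.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    sums = cm.counts.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"zero-sum sample column(s): {[cm.samples[j] for j in zero]}")
    return replace(cm, counts=cm.counts * (total / sums), normalized=True)


def log2fc(ref, end, pseudocount: float = 1.0):
    """Per-element log2((end + pc) / (ref + pc)).

    Accepts aligned pandas Series (indexes must contain the same elements;
    ``end`` is reindexed to ``ref``'s order) or plain arrays of equal
    length. The pseudocount guards elements that dropped to zero counts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if isinstance(ref, pd.Series) and isinstance(end, pd.Series):
        if set(ref.index) != set(end.index):
            raise ValueError("element sets of ref and end differ")
        end = end.reindex(ref.index)
        return np.log2((end + pseudocount) / (ref + pseudocount))
    ref = np.asarray(ref, dtype=float)
    end = np.asarray(end, dtype=float)
    if ref.shape != end.shape:
        raise ValueError("ref and end must align")
    return np.log2((end + pseudocount) / (ref + pseudocount))


def barcode_concordance(log2fc_values, orf_of) -> pd.DataFrame:
    """Per-ORF agreement among the log2 fold changes of its barcodes.

    Multiple independent barcodes per ORF give internal replication: if
    barcodes stay coupled to their ORF they should shift together, whereas
    barcode--ORF uncoupling makes some barcodes report other ORFs'
    phenotypes and drives the signs apart. Sign agreement is
    ``max(#nonnegative, #negative) / n`` per ORF; single-barcode ORFs get
    NaN (no internal replicate).
    """
    values = pd.Series(np.asarray(log2fc_values, dtype=float))
    orfs = pd.Series(np.asarray(orf_of, dtype=object))
    if len(values) == 0:
        raise ValueError("empty input")
    if len(values) != len(orfs):
        raise ValueError("log2fc and orf labels must align")

    def _agree(x: pd.Series) -> float:
        if len(x) < 2:
            return float("nan")
        pos = int((x >= 0).sum())
        return max(pos, len(x) - pos) / len(x)

    g = values.groupby(orfs.values)
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean": g.mean(),
            "sd": g.std(ddof=1),
            "sign_agreement": g.apply(_agree),
        }
    )
    out.index.name = "orf_id"
    return out


@dataclass
class RecombEstimate:
    """Measured and homozygosity-corrected recombination frequencies."""

    n_analyzed: int
    n_recombined: int
    f_measured: float
    h: float = float("nan")
    f_true_est: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_analyzed": [self.n_analyzed],
                "n_recombined": [self.n_recombined],
                "f_measured_pct": [100.0 * self.f_measured],
                "homozygous_fraction_pct": [100.0 * self.h],
                "f_true_est_pct": [100.0 * self.f_true_est],
            }
        )


def _observed_pairs(observed) -> list[tuple[str, str]]:
    if isinstance(observed, ProvirusTable):
        observed = observed.to_frame()
    if isinstance(observed, pd.DataFrame):
        if not {"orf_id", "bc_id"} <= set(observed.columns):
            raise ValueError("observed frame needs orf_id and bc_id columns")
        return list(zip(observed["orf_id"].astype(str), observed["bc_id"].astype(str)))
    return [(str(o), str(b)) for o, b in observed]


def measured_recombination_frequency(observed, library: Library) -> RecombEstimate:
    """Count observed (orf, bc) pairs absent from the library pairing.

    Every observed id must exist in the library; unknown ids are rejected
    (they indicate a truth-table mismatch, not recombination).
    """
    pairs = _observed_pairs(observed)
    if not pairs:
        raise ValueError("no observed pairs")
    truth = library.pairing()
    orfs = set(library.orf_ids)
    bcs = set(library.bc_ids)
    for orf, bc in pairs:
        if orf not in orfs:
            raise ValueError(f"unknown orf_id {orf!r}")
        if bc not in bcs:
            raise ValueError(f"unknown bc_id {bc!r}")
    n_recombined = sum(1 for p in pairs if p not in truth)
    return RecombEstimate(
        n_analyzed=len(pairs),
        n_recombined=n_recombined,
        f_measured=n_recombined / len(pairs),
    )


def correct_recombination_frequency(f_measured: float, h: float) -> float:
    """Homozygous-virion correction: ``f_measured * (1 + h)``.

    Linear in the measured frequency, the identity at h = 0, and bounded by
    twice the measured frequency.
    """
    if not 0 <= f_measured <= 1:
        raise ValueError("f_measured must be in [0, 1]")
    if not 0 <= h <= 1:
        raise ValueError("h must be in [0, 1]")
    return f_measured * (1.0 + h)


def recombination_estimate(observed, library: Library) -> RecombEstimate:
    """Full estimate: measured frequency plus the homozygosity correction,
    with ``h`` computed from the library abundance vector."""
    est = measured_recombination_frequency(observed, library)
    h = homozygosity_fraction(library.abundance)
    return replace(est, h=h, f_true_est=correct_recombination_frequency(est.f_measured, h))


def compare_recombination(
    k1: int, n1: int, k2: int, n2: int, method: str = "binom", alternative: str = "two-sided"
) -> float:
    """Exact test that two observed recombination rates share an underlying rate.

    Default (``binom``): exact binomial test of ``k2`` successes in ``n2``
    trials at the rate ``k1/n1`` observed in the first sample (the first
    sample conditions the rate). ``fisher``: Fisher's exact test on the 2x2
    table, which conditions on both margins. Both are exposed because the
    construction is ambiguous for small counts; they agree on order of
    magnitude here.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("n must be > 0")
        if not 0 <= k <= n:
            raise ValueError("k must be in [0, n]")
    if method == "binom":
        if k1 == 0 and k2 == 0:
            return 1.0
        return float(stats.binomtest(k2, n2, p=k1 / n1, alternative=alternative).pvalue)
    if method == "fisher":
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(stats.fisher_exact(table, alternative=alternative)[1])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class GcBiasReport:
    """Pearson correlation of log2 fold change against GC, with binned summaries."""

    pearson_r: float
    p_value: float
    binned: pd.DataFrame
    n: int
    note: str | None = None

    @property
    def significant(self) -> bool:
        return bool(not math.isnan(self.p_value) and self.p_value < 0.01)


def _gc_bins(gc: np.ndarray, bins) -> pd.Series:
    if bins is None:
        strata = np.unique(gc)
        if strata.size <= 10:
            # discrete GC strata (e.g. the 40/45/50/55/60% mock ladder)
            return pd.Series(gc).map(lambda g: f"{100 * g:g}%")
        width = 0.025
        lo = math.floor(gc.min() / width) * width
        hi = math.ceil(gc.max() / width) * width
        bins = np.arange(lo, hi + width / 2, width)
    cut = pd.cut(gc, bins=bins, include_lowest=True)
    return pd.Series(cut.astype(str))


def gc_bias_test(log2fc_values, gc, bins=None) -> GcBiasReport:
    """Pearson product-moment correlation between GC content and log2 fold change.

    Returns the two-sided p-value from the t-distribution plus per-bin
    median and quartiles of the fold changes (equal-width 2.5-point bins by
    default, or the exact strata when GC takes few distinct values).
    Constant input makes r undefined; it is reported as NaN with a
    diagnostic note rather than an error.
    """
    y = np.asarray(log2fc_values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if y.shape != gc.shape:
        raise ValueError("log2fc and gc must align")
    if y.size < 3:
        raise ValueError("need at least 3 elements")
    labels = _gc_bins(gc, bins)
    grouped = pd.Series(y).groupby(labels.values)
    binned = pd.DataFrame(
        {
            "n": grouped.size(),
            "median": grouped.median(),
            "q1": grouped.quantile(0.25),
            "q3": grouped.quantile(0.75),
        }
    )
    binned.index.name = "gc_bin"
    if np.allclose(gc, gc[0]) or np.allclose(y, y[0]):
        return GcBiasReport(float("nan"), float("nan"), binned, y.size, note="constant input; r undefined")
    r, p = stats.pearsonr(gc, y)
    return GcBiasReport(float(r), float(p), binned, y.size)


@dataclass
class SubpoolDistortion:
    """Spread and titer-relation of per-subpool read abundance."""

    spread: float
    spearman_rho: float
    p_value: float
    per_subpool: pd.DataFrame


def subpool_distortion(reads, subpool_of, titers: dict[str, float]) -> SubpoolDistortion:
    """Max/min ratio of subpool mean reads and its rank correlation with titer.

    Plasmid carryover scales with the supernatant volume added, which is
    inversely proportional to titer, so contaminated reference samples show
    a negative rank correlation between subpool read abundance and titer
    (and a several-fold spread); uncontaminated samples show neither.
    """
    reads = np.asarray(reads, dtype=float)
    pools = np.asarray(subpool_of, dtype=object)
    if reads.shape != pools.shape:
        raise ValueError("reads and subpool labels must align")
    names = sorted(set(pools))
    if len(names) < 2:
        raise ValueError("need at least 2 subpools")
    missing = set(names) - set(titers)
    if missing:
        raise ValueError(f"missing titer for subpool(s) {sorted(missing)}")
    means = np.array([reads[pools == s].mean() for s in names])
    titer = np.array([titers[s] for s in names])
    if means.min() <= 0:
        spread = math.inf if means.max() > 0 else 1.0
    else:
        spread = float(means.max() / means.min())
    if np.allclose(means, means[0]):
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(means, titer)
    table = pd.DataFrame({"subpool_id": names, "mean_reads": means, "titer": titer})
    return SubpoolDistortion(spread, float(rho), float(p), table)
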
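"""Binned position PMFs, probability-ratio bias curves, and per-bin tests.

The central statistic is the per-bin probability ratio
p(x | positive) / p(x | negative) over normalized positions binned into
equal intervals of [0, 1] (5 by default). A flat curve at 1.0 means no
positional bias; values below 1 mean epitope under-representation in that
region. Uncertainty comes from resampling positives and negatives
independently with replacement at the peptide level (1000 resamples by
default) and summarizing the per-bin resample ratios with 25th/75th
percentiles and whiskers extending 1.0 interquartile ranges beyond the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PositionPMF:
    """Probability mass function over position bins."""

    bin_edges: np.ndarray  # n_bins + 1 edges, 0 .. 1
    probabilities: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not np.isclose(self.probabilities.sum(), 1.0, atol=1e-12):
            raise ValueError("PMF masses must sum to 1")


@dataclass
class BiasCurve:
    """Per-bin probability ratios with bootstrap summaries.

    ``defined`` marks bins whose full-data negative mass is non-zero; ratios
    in undefined bins are NaN but the bins are kept (never silently
    dropped). ``n_undefined_resamples`` counts bootstrap replicates whose
    resampled negative mass was zero in that bin; those replicates are
    excluded from the percentile summaries.
    """

    bin_edges: np.ndarray
    ratio: np.ndarray
    boot_p25: np.ndarray
    boot_p75: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    boot_sd: np.ndarray
    n_undefined_resamples: np.ndarray
    defined: np.ndarray
    n_boot: int
    seed: int | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


@dataclass
class BinTestResult:
    """Exact two-sided binomial test per position bin."""

    positives: np.ndarray
    negatives: np.ndarray
    expected_fraction: float
    p_values: np.ndarray
    defined: np.ndarray  # False where a bin had zero total count


def bin_positions(xs, n_bins: int = 5) -> PositionPMF:
    """Bin normalized positions into ``n_bins`` equal intervals of [0, 1].

    Bins are half-open [lo, hi) except the last, which is closed at 1.0, so
    x = 1.0 lands in the final bin.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ValueError("cannot build a PMF from zero positions")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.any((xs < 0) | (xs > 1)):
        raise ValueError("normalized positions must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(xs, bins=edges)  # np.histogram closes the last bin
    return PositionPMF(bin_edges=edges, probabilities=counts / xs.size, n=int(xs.size))


def _box_whiskers(sample: np.ndarray) -> tuple[float, float, float, float]:
    """25/75 percentiles and whiskers at 1.0 x IQR, clipped to the sample."""
    q25, q75 = np.percentile(sample, [25, 75])
    iqr = q75 - q25
    lo_bound, hi_bound = q25 - 1.0 * iqr, q75 + 1.0 * iqr
    within = sample[(sample >= lo_bound) & (sample <= hi_bound)]
    return q25, q75, float(within.min()), float(within.max())


def _bootstrap_ratio_summaries(
    counts_pos: np.ndarray,
    counts_neg: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
):
    """Bootstrap the per-bin ratio of two binned samples.

    Resampling n items with replacement and re-binning is distributionally
    identical to a multinomial draw over the empirical bin masses, so the
    resample ratios are generated directly from multinomial counts.
    """
    n_bins = counts_pos.size
    n_pos, n_neg = int(counts_pos.sum()), int(counts_neg.sum())
    boot_pos = rng.multinomial(n_pos, counts_pos / n_pos, size=n_boot)
    boot_neg = rng.multinomial(n_neg, counts_neg / n_neg, size=n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_ratio = (boot_pos / n_pos) / (boot_neg / n_neg)

    p25 = np.full(n_bins, np.nan)
    p75 = np.full(n_bins, np.nan)
    w_lo = np.full(n_bins, np.nan)
    w_hi = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n_undef = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        col = boot_ratio[:, b]
        finite = col[np.isfinite(col)]
        n_undef[b] = n_boot - finite.size
        if finite.size == 0:
            continue
        p25[b], p75[b], w_lo[b], w_hi[b] = _box_whiskers(finite)
        sd[b] = finite.std(ddof=1) if finite.size > 1 else 0.0
    return p25, p75, w_lo, w_hi, sd, n_undef


def ratio_curve(
    pos_xs,
    neg_xs,
    n_bins: int = 5,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BiasCurve:
    """Probability-ratio bias curve p(x|positive)/p(x|negative) per bin.

    Point ratios use the full data. Positives and negatives are
    bootstrapped independently at the peptide level; bins whose full-data
    negative mass is zero are flagged undefined rather than dropped.
    """
    pos = bin_positions(pos_xs, n_bins)
    neg = bin_positions(neg_xs, n_bins)
    counts_pos = np.round(pos.probabilities * pos.n).astype(int)
    counts_neg = np.round(neg.probabilities * neg.n).astype(int)
    defined = counts_neg > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(defined, pos.probabilities / neg.probabilities, np.nan)

    rng = np.random.default_rng(seed)
    p25, p75, w_lo, w_hi, sd, n_undef = _bootstrap_ratio_summaries(
        counts_pos, counts_neg, n_boot, rng
    )
    return BiasCurve(
        bin_edges=pos.bin_edges,
        ratio=ratio,
        boot_p25=p25,
        boot_p75=p75,
        whisker_lo=w_lo,
        whisker_hi=w_hi,
        boot_sd=sd,
        n_undefined_resamples=n_undef,
        defined=defined,
        n_boot=n_boot,
        seed=seed,
    )


def exact_binom_pvalue(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value under the min-likelihood convention.

    Sums the probabilities of every outcome whose point probability does
    not exceed that of the observed count (a tiny relative cushion absorbs
    floating-point ties).
    """
    if not 0 < p0 < 1:
        raise ValueError("expected fraction must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    support = np.arange(n + 1)
    pmf = stats.binom.pmf(support, n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()))


def expected_positive_fraction(n_positive: int, n_total: int) -> float:
    """Null fraction of positives: (all positives) / (all tested)."""
    if not 0 < n_positive < n_total:
        raise ValueError("need 0 < n_positive < n_total")
    return n_positive / n_total


def binomial_bin_tests(
    positives, negatives, expected_fraction_: float | None = None
) -> BinTestResult:
    """Per-bin exact binomial test of positive counts against a null fraction.

    With ``expected_fraction_`` omitted, the null fraction is computed from
    the table's own totals. Bins with zero total are flagged, p = NaN.
    """
    positives = np.asarray(positives, dtype=int)
    negatives = np.asarray(negatives, dtype=int)
    if positives.shape != negatives.shape:
        raise ValueError("positive/negative count vectors must align")
    if np.any(positives < 0) or np.any(negatives < 0):
        raise ValueError("counts must be non-negative")
    totals = positives + negatives
    if expected_fraction_ is None:
        expected_fraction_ = expected_positive_fraction(
            int(positives.sum()), int(totals.sum())
        )
    if not 0 < expected_fraction_ < 1:
        raise ValueError("expected fraction must be in (0, 1)")
    defined = totals > 0
    p_values = np.full(positives.shape, np.nan)
    for i in np.nonzero(defined)[0]:
        p_values[i] = exact_binom_pvalue(
            int(positives[i]), int(totals[i]), expected_fraction_
        )
    return BinTestResult(
        positives=positives,
        negatives=negatives,
        expected_fraction=float(expected_fraction_),
        p_values=p_values,
        defined=defined,
    )


def combine_curves_weighted(curves: list[BiasCurve], weights) -> BiasCurve:
    """Weighted arithmetic mean of bias curves sharing a binning.

    Weights are normalized to sum 1. A bin undefined in some contributing
    curves is combined over the defined subset with re-normalized weights
    (and stays flagged defined only if at least one contributor defines it).
    Bootstrap summary fields are combined with the same weights and should
    be read as descriptive, not as percentiles of a joint bootstrap.
    """
    if not curves:
        raise ValueError("need at least one curve")
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(curves) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative, aligned, and sum > 0")
    edges = curves[0].bin_edges
    for c in curves[1:]:
        if not np.allclose(c.bin_edges, edges):
            raise ValueError("curves must share bin edges")
    weights = weights / weights.sum()

    def _wmean(attr: str) -> np.ndarray:
        mat = np.vstack([getattr(c, attr) for c in curves])
        out = np.full(mat.shape[1], np.nan)
        for b in range(mat.shape[1]):
            ok = np.isfinite(mat[:, b])
            if ok.any():
                w = weights[ok] / weights[ok].sum()
                out[b] = float(w @ mat[ok, b])
        return out

    defined = np.vstack([c.defined for c in curves]).any(axis=0)
    return BiasCurve(
        bin_edges=edges.copy(),
        ratio=_wmean("ratio"),
        boot_p25=_wmean("boot_p25"),
        boot_p75=_wmean("boot_p75"),
        whisker_lo=_wmean("whisker_lo"),
        whisker_hi=_wmean("whisker_hi"),
        boot_sd=_wmean("boot_sd"),
        n_undefined_resamples=np.vstack(
            [c.n_undefined_resamples for c in curves]
        ).max(axis=0),
        defined=defined,
        n_boot=curves[0].n_boot,
        seed=curves[0].seed,
    )


def bins_consistent_with_unity(
    curve: BiasCurve, alpha: float = 0.05, family_size: int | None = None
) -> np.ndarray:
    """Per-bin check that the ratio is statistically consistent with 1.0.

    Uses a normal interval ratio +/- z * bootstrap-sd per bin, with the
    significance level Bonferroni-divided across ``family_size``
    simultaneous bins (default: the curve's defined bins) so that a jointly
    flat curve passes in all bins with family-wise probability ~ 1 - alpha.
    Undefined bins return False.
    """
    m = int(curve.defined.sum()) if family_size is None else int(family_size)
    if m <= 0:
        raise ValueError("no defined bins to test")
    z = stats.norm.ppf(1 - alpha / (2 * m))
    ok = np.zeros(curve.n_bins, dtype=bool)
    for b in range(curve.n_bins):
        if not curve.defined[b] or not np.isfinite(curve.boot_sd[b]):
            continue
        ok[b] = abs(curve.ratio[b] - 1.0) <= z * max(curve.boot_sd[b], 1e-12)
    return ok


def curves_overlap(a: BiasCurve, b: BiasCurve) -> np.ndarray:
    """Per-bin overlap of the two curves' whisker intervals."""
    if not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("curves must share bin edges")
    return (a.whisker_lo <= b.whisker_hi) & (b.whisker_lo <= a.whisker_hi)
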
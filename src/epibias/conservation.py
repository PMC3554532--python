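"""Conservation profiles and the conservation-only estimate of positional bias.

Per-residue conservation scores (higher = more conserved) are z-scored
within each protein, pooled by normalized residue position to give a
positional conservation profile with protein-level bootstrap CIs, and
related to immune recognition through a quantile-binned ratio function
p(score | positive) / p(score | negative). Composing the two — evaluating
the ratio function at each position bin's mean conservation — yields the
positional bias curve expected from conservation alone, which can then be
compared with the observed curve (Pearson correlation over bins, per-bin
CI overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bias import BiasCurve, _bootstrap_ratio_summaries, _box_whiskers
from .mapping import PeptideMapping


class ConstantProfileError(ValueError):
    """Profile has zero variance; z-scoring is undefined."""


@dataclass
class ConservationProfile:
    """Per-residue conservation scores for one antigen."""

    antigen_id: str
    scores: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-d array")


@dataclass
class PositionalConservation:
    """Mean conservation per normalized-position bin, protein bootstrapped.

    ``boot_means`` holds the (n_boot, n_bins) bin means of every
    protein-level bootstrap replicate so downstream estimators can
    propagate this uncertainty; ``degenerate`` is set when only one
    profile was available and the bootstrap collapses to the point
    estimate.
    """

    bin_edges: np.ndarray
    mean_score: np.ndarray
    boot_p25: np.ndarray
    boot_p75: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    boot_means: np.ndarray
    n_boot: int
    n_proteins: int
    seed: int | None = None
    degenerate: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ConservationRatioFunction:
    """p(score|positive)/p(score|negative) over quantile score bins.

    Bin edges are quantiles of the pooled scores so each bin holds roughly
    equal counts; ``midpoints`` are the medians of pooled scores per bin.
    ``collapsed`` flags that duplicate-heavy data collapsed some quantile
    edges, which were merged.
    """

    bin_edges: np.ndarray
    midpoints: np.ndarray
    ratio: np.ndarray
    boot_p25: np.ndarray
    boot_p75: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    boot_sd: np.ndarray
    defined: np.ndarray
    n_boot: int
    seed: int | None = None
    collapsed: bool = False

    def __call__(self, score) -> np.ndarray:
        """Piecewise-linear interpolation over midpoints, clamped outside."""
        good = self.defined & np.isfinite(self.ratio)
        if good.sum() < 2:
            raise ValueError("need >= 2 defined bins to interpolate")
        return np.interp(np.asarray(score, float), self.midpoints[good], self.ratio[good])


@dataclass
class WelchResult:
    """One-sided Welch test that positives are more conserved."""

    t: float
    df: float
    p: float
    mean_pos: float
    mean_neg: float
    n_pos: int
    n_neg: int
    degenerate: bool = False


def normalize_profile(profile: ConservationProfile) -> ConservationProfile:
    """Z-score a profile within its protein (sample sd, n-1)."""
    if profile.scores.size < 2:
        raise ValueError(f"profile {profile.antigen_id!r}: need >= 2 residues")
    sd = profile.scores.std(ddof=1)
    if sd == 0:
        raise ConstantProfileError(
            f"profile {profile.antigen_id!r} is constant; cannot normalize"
        )
    z = (profile.scores - profile.scores.mean()) / sd
    return ConservationProfile(profile.antigen_id, z, normalized=True)


def normalize_profiles(
    profiles: list[ConservationProfile],
) -> tuple[list[ConservationProfile], list[tuple[str, str]]]:
    """Normalize each profile; constant/short profiles go to the audit list."""
    out, excluded = [], []
    for p in profiles:
        try:
            out.append(normalize_profile(p))
        except ConstantProfileError:
            excluded.append((p.antigen_id, "constant-profile"))
        except ValueError:
            excluded.append((p.antigen_id, "too-short"))
    return out, excluded


def positional_conservation(
    profiles: list[ConservationProfile],
    n_bins: int = 5,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PositionalConservation:
    """Mean conservation per normalized-position bin with protein bootstrap.

    Residue i of a protein of length L sits at normalized position
    (i-1)/(L-1); single-residue proteins are excluded. Confidence
    intervals come from ``n_boot`` bootstrap resamples drawn over whole
    proteins, mirroring protein-level (not residue-level) exchangeability.
    """
    usable = [p for p in profiles if p.scores.size >= 2]
    if not usable:
        raise ValueError("no profiles with >= 2 residues")
    for p in usable:
        if not p.normalized:
            raise ValueError(f"profile {p.antigen_id!r} is not normalized")
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    # per-protein per-bin sums and counts; bootstrap = reweighting proteins
    sums = np.zeros((len(usable), n_bins))
    counts = np.zeros((len(usable), n_bins))
    for j, p in enumerate(usable):
        pos = np.arange(p.scores.size) / (p.scores.size - 1)
        bins = np.minimum((pos * n_bins).astype(int), n_bins - 1)
        np.add.at(sums[j], bins, p.scores)
        np.add.at(counts[j], bins, 1.0)

    mean_score = sums.sum(axis=0) / counts.sum(axis=0)
    n_prot = len(usable)
    rng = np.random.default_rng(seed)
    degenerate = n_prot == 1
    if degenerate:
        boot_means = np.tile(mean_score, (n_boot, 1))
    else:
        weights = rng.multinomial(n_prot, np.full(n_prot, 1 / n_prot), size=n_boot)
        with np.errstate(invalid="ignore"):
            boot_means = (weights @ sums) / (weights @ counts)

    p25 = np.empty(n_bins)
    p75 = np.empty(n_bins)
    w_lo = np.empty(n_bins)
    w_hi = np.empty(n_bins)
    for b in range(n_bins):
        col = boot_means[:, b]
        col = col[np.isfinite(col)]
        p25[b], p75[b], w_lo[b], w_hi[b] = _box_whiskers(col)
    return PositionalConservation(
        bin_edges=edges,
        mean_score=mean_score,
        boot_p25=p25,
        boot_p75=p75,
        whisker_lo=w_lo,
        whisker_hi=w_hi,
        boot_means=boot_means,
        n_boot=n_boot,
        n_proteins=n_prot,
        seed=seed,
        degenerate=degenerate,
    )


def peptide_conservation(
    mapping: PeptideMapping, profile: ConservationProfile
) -> float:
    """Mean normalized conservation over the peptide's footprint."""
    if not profile.normalized:
        raise ValueError("profile must be normalized")
    if profile.antigen_id != mapping.antigen_id:
        raise ValueError(
            f"profile is for {profile.antigen_id!r}, "
            f"mapping is in {mapping.antigen_id!r}"
        )
    k = len(mapping.peptide.sequence)
    start0 = mapping.peptide_start - 1
    if start0 + k > profile.scores.size:
        raise ValueError("peptide footprint exceeds profile length")
    return float(profile.scores[start0 : start0 + k].mean())


def conservation_ratio_function(
    pos_scores,
    neg_scores,
    n_bins: int = 5,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ConservationRatioFunction:
    """Ratio of positive to negative score masses over quantile bins.

    Bin edges are quantiles of the pooled scores (~equal counts per bin);
    collapsed edges from duplicate-heavy data are merged and flagged.
    Bootstrap follows the same independent two-sample scheme as the
    positional ratio curve.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score samples must be non-empty")
    pooled = np.concatenate([pos, neg])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    uniq = np.unique(edges)
    collapsed = uniq.size < edges.size
    edges = uniq
    if edges.size < 3:
        raise ValueError("scores too degenerate to form >= 2 quantile bins")
    nb = edges.size - 1

    # last bin closed (np.histogram convention), matching position binning
    counts_pos, _ = np.histogram(pos, bins=edges)
    counts_neg, _ = np.histogram(neg, bins=edges)
    bin_of = np.minimum(np.searchsorted(edges, pooled, side="right") - 1, nb - 1)
    midpoints = np.array([np.median(pooled[bin_of == b]) for b in range(nb)])

    defined = counts_neg > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            defined, (counts_pos / pos.size) / (counts_neg / neg.size), np.nan
        )
    rng = np.random.default_rng(seed)
    p25, p75, w_lo, w_hi, sd, _ = _bootstrap_ratio_summaries(
        counts_pos, np.maximum(counts_neg, 0), n_boot, rng
    )
    return ConservationRatioFunction(
        bin_edges=edges,
        midpoints=midpoints,
        ratio=ratio,
        boot_p25=p25,
        boot_p75=p75,
        whisker_lo=w_lo,
        whisker_hi=w_hi,
        boot_sd=sd,
        defined=defined,
        n_boot=n_boot,
        seed=seed,
        collapsed=collapsed,
    )


def estimate_bias_from_conservation(
    pos_cons: PositionalConservation, f: ConservationRatioFunction
) -> BiasCurve:
    """Positional bias curve expected from conservation alone.

    Evaluates the conservation-to-recognition ratio function at each
    position bin's mean conservation (piecewise-linear over the function's
    bin midpoints, clamped to the terminal ratios outside its range).
    Uncertainty is propagated by evaluating the point ratio function on
    every protein-level bootstrap replicate of the bin means.
    """
    point = f(pos_cons.mean_score)
    boot = f(pos_cons.boot_means)  # (n_boot, n_bins)
    n_bins = pos_cons.mean_score.size
    p25 = np.empty(n_bins)
    p75 = np.empty(n_bins)
    w_lo = np.empty(n_bins)
    w_hi = np.empty(n_bins)
    sd = np.empty(n_bins)
    for b in range(n_bins):
        col = boot[:, b]
        col = col[np.isfinite(col)]
        p25[b], p75[b], w_lo[b], w_hi[b] = _box_whiskers(col)
        sd[b] = col.std(ddof=1) if col.size > 1 else 0.0
    return BiasCurve(
        bin_edges=pos_cons.bin_edges.copy(),
        ratio=point,
        boot_p25=p25,
        boot_p75=p75,
        whisker_lo=w_lo,
        whisker_hi=w_hi,
        boot_sd=sd,
        n_undefined_resamples=np.zeros(n_bins, dtype=int),
        defined=np.ones(n_bins, dtype=bool),
        n_boot=pos_cons.n_boot,
        seed=pos_cons.seed,
    )


def curve_agreement(observed: BiasCurve, estimated: BiasCurve) -> float:
    """Pearson correlation of the two curves' defined per-bin ratios."""
    if not np.allclose(observed.bin_edges, estimated.bin_edges):
        raise ValueError("curves must share bin edges")
    common = (
        observed.defined
        & estimated.defined
        & np.isfinite(observed.ratio)
        & np.isfinite(estimated.ratio)
    )
    if common.sum() < 3:
        raise ValueError("need >= 3 common defined bins")
    a, b = observed.ratio[common], estimated.ratio[common]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant curve")
    return float(stats.pearsonr(a, b).statistic)


def welch_one_sided(pos_scores, neg_scores) -> WelchResult:
    """Welch's unequal-variance t-test, one-sided: mean(pos) > mean(neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 values per group")
    if pos.var(ddof=1) == 0 and neg.var(ddof=1) == 0:
        if pos.mean() == neg.mean():
            # no variance, no difference: evidence is vacuous either way
            return WelchResult(
                t=0.0, df=float(pos.size + neg.size - 2), p=0.5,
                mean_pos=float(pos.mean()), mean_neg=float(neg.mean()),
                n_pos=pos.size, n_neg=neg.size, degenerate=True,
            )
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(pos, neg, equal_var=False, alternative="greater")
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_pos=float(pos.mean()),
        mean_neg=float(neg.mean()),
        n_pos=pos.size,
        n_neg=neg.size,
    )
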
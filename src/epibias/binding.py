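"""Positional bias of predicted MHC-I binders per HLA supertype.

Every k-mer window of the proteome (9-mers by default) gets a predicted
IC50 per allele from an external table; windows are split into binders
(IC50 < 500 nM) and non-binders, alleles are grouped into supertypes, and
each supertype's binder vs. non-binder positional ratio curve is computed
with the same machinery as the epitope curve. Because binding predictions
depend only on peptide sequence, any systematic positional structure here
would indicate residue-composition bias along proteins rather than an
epitope-specific effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bias import BiasCurve, combine_curves_weighted, ratio_curve
from .mapping import Antigen

DEFAULT_BINDER_CUTOFF_NM = 500.0


def generate_kmers(antigens: list[Antigen], k: int = 9) -> pd.DataFrame:
    """Every window of length k from every antigen, with its 1-based start.

    Proteins shorter than k (or of length k, whose normalized position
    would be degenerate) contribute no windows. Columns: antigen_id,
    start_1based, peptide, x.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frames = []
    for antigen in antigens:
        L = len(antigen)
        if L <= k:
            continue
        starts = np.arange(1, L - k + 2)
        frames.append(
            pd.DataFrame(
                {
                    "antigen_id": antigen.id,
                    "start_1based": starts,
                    "peptide": [
                        antigen.sequence[s - 1 : s - 1 + k] for s in starts
                    ],
                    "x": (starts - 1) / (L - k),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["antigen_id", "start_1based", "peptide", "x"])
    return pd.concat(frames, ignore_index=True)


def classify_binders(
    predictions: pd.DataFrame, cutoff_nM: float = DEFAULT_BINDER_CUTOFF_NM
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split predictions into binders (IC50 < cutoff) and non-binders.

    A prediction exactly at the cutoff counts as a non-binder (the strict
    inequalities on either side leave the boundary unassigned; the
    conservative choice yields fewer binders). Rows with non-positive IC50
    are returned separately as an audit table.
    """
    if cutoff_nM <= 0:
        raise ValueError("cutoff must be > 0")
    bad = predictions[predictions["ic50_nM"] <= 0]
    good = predictions[predictions["ic50_nM"] > 0].copy()
    good["binder"] = good["ic50_nM"] < cutoff_nM
    return good, bad


def supertype_bias_curves(
    windows: pd.DataFrame,
    predictions: pd.DataFrame,
    supertype_map: pd.DataFrame,
    n_bins: int = 5,
    n_boot: int = 1000,
    seed: int | None = None,
    cutoff_nM: float = DEFAULT_BINDER_CUTOFF_NM,
) -> tuple[dict[str, BiasCurve], dict[str, str]]:
    """Binder vs. non-binder positional ratio curve per supertype.

    Windows are pooled across a supertype's member alleles; each window
    counts once per (allele, window) prediction. Returns the curves plus a
    dict of supertypes that could not be computed (zero binders or zero
    non-binders) with the reason.
    """
    missing = set(predictions["allele"]) - set(supertype_map["allele"])
    if missing:
        raise ValueError(f"alleles without a supertype: {sorted(missing)}")
    labelled, _ = classify_binders(predictions, cutoff_nM)
    merged = windows.merge(labelled, on="peptide", how="inner").merge(
        supertype_map, on="allele", how="left"
    )
    curves: dict[str, BiasCurve] = {}
    flagged: dict[str, str] = {}
    for supertype, grp in merged.groupby("supertype", sort=True):
        pos_xs = grp.loc[grp["binder"], "x"].to_numpy()
        neg_xs = grp.loc[~grp["binder"], "x"].to_numpy()
        if pos_xs.size == 0:
            flagged[supertype] = "no-binders"
            continue
        if neg_xs.size == 0:
            flagged[supertype] = "no-non-binders"
            continue
        curves[supertype] = ratio_curve(
            pos_xs, neg_xs, n_bins=n_bins, n_boot=n_boot, seed=seed
        )
    return curves, flagged


def combined_supertype_curve(
    curves: dict[str, BiasCurve], weights: dict[str, float] | None = None
) -> BiasCurve:
    """Restriction-frequency-weighted combination of supertype curves.

    Weights default to equal (a user-supplied restriction-frequency table
    is preferred when available).
    """
    names = sorted(curves)
    if weights is None:
        w = np.ones(len(names))
    else:
        w = np.array([weights[name] for name in names], dtype=float)
    return combine_curves_weighted([curves[name] for name in names], w)
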
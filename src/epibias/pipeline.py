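"""End-to-end analysis: map peptides, then bias, binding and conservation.

``run_pipeline`` ties the stages together from files on disk and returns a
single JSON-serializable report carrying every curve, test, audit count and
the full configuration (with a hash for provenance). Stages whose inputs
are not configured are skipped; a failure inside a stage aborts the run
with the stage named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import binding as binding_mod
from . import conservation as cons_mod
from . import io as io_mod
from .bias import BiasCurve, binomial_bin_tests, ratio_curve
from .conservation import ConservationProfile


@dataclass
class RunConfig:
    """Inputs and parameters of one analysis run.

    Defaults reproduce the reference analysis settings: 5 position bins,
    1000 bootstrap resamples, 500 nM binder cutoff, 9-mer windows, and the
    organism-immunogen slice of the assay table.
    """

    proteome_path: str
    assay_path: str
    conservation_path: str | None = None
    predictions_path: str | None = None
    supertype_path: str | None = None
    n_bins: int = 5
    n_boot: int = 1000
    binder_cutoff_nM: float = 500.0
    k: int = 9
    seed: int = 0
    immunogen: str = "organism"  # organism | peptide | all
    flip_conservation_sign: bool = False

    def __post_init__(self) -> None:
        if self.immunogen not in ("organism", "peptide", "all"):
            raise ValueError("immunogen filter must be organism/peptide/all")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _curve_dict(curve: BiasCurve) -> dict:
    return {
        col: io_mod.curve_frame(curve)[col].tolist()
        for col in io_mod.curve_frame(curve).columns
    }


def _profiles_from_table(table) -> list[ConservationProfile]:
    return [
        ConservationProfile(antigen_id=aid, scores=grp["score"].to_numpy())
        for aid, grp in table.groupby("antigen_id", sort=True)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report bundle."""
    params = dataclasses.asdict(config)
    report: dict = {
        "schema_version": 1,
        "config": params,
        "config_hash": io_mod.config_hash(params),
    }

    # --- stage: map --------------------------------------------------------
    try:
        proteome = io_mod.read_fasta(config.proteome_path)
        records = io_mod.read_assay_table(config.assay_path)
        if config.immunogen != "all":
            records = [r for r in records if r.immunogen == config.immunogen]
        from .mapping import map_peptides

        mappings, audit = map_peptides(records, proteome)
        report["mapping_audit"] = {
            "n_input": audit.n_input,
            "mapped": audit.mapped,
            "unmapped": audit.unmapped,
            "ties": audit.ties,
            "degenerate": audit.degenerate,
            "rejected": audit.rejected,
            "homology_filter": "n/a (single reference proteome)",
        }
    except Exception as err:
        raise StageError(f"stage 'map' failed: {err}") from err

    # --- stage: positional bias -------------------------------------------
    try:
        pos_xs = np.array([m.x for m in mappings if m.peptide.label == "positive"])
        neg_xs = np.array([m.x for m in mappings if m.peptide.label == "negative"])
        observed = ratio_curve(
            pos_xs, neg_xs, n_bins=config.n_bins, n_boot=config.n_boot,
            seed=config.seed,
        )
        edges = observed.bin_edges
        pos_counts, _ = np.histogram(pos_xs, bins=edges)
        neg_counts, _ = np.histogram(neg_xs, bins=edges)
        tests = binomial_bin_tests(pos_counts, neg_counts)
        report["positional_bias"] = {
            "observed_curve": _curve_dict(observed),
            "binomial_tests": {
                col: io_mod.bin_tests_frame(tests)[col].tolist()
                for col in io_mod.bin_tests_frame(tests).columns
            },
        }
    except Exception as err:
        raise StageError(f"stage 'posbias' failed: {err}") from err

    # --- stage: binder bias (optional) ------------------------------------
    if config.predictions_path and config.supertype_path:
        try:
            predictions = io_mod.read_predictions_table(config.predictions_path)
            supertypes = io_mod.read_supertype_table(config.supertype_path)
            windows = binding_mod.generate_kmers(proteome, k=config.k)
            curves, flagged = binding_mod.supertype_bias_curves(
                windows, predictions, supertypes,
                n_bins=config.n_bins, n_boot=config.n_boot, seed=config.seed,
                cutoff_nM=config.binder_cutoff_nM,
            )
            combined = binding_mod.combined_supertype_curve(curves)
            report["binder_bias"] = {
                "supertype_curves": {s: _curve_dict(c) for s, c in curves.items()},
                "flagged_supertypes": flagged,
                "combined_curve": _curve_dict(combined),
                "weights": "equal (no restriction-frequency table supplied)",
            }
        except Exception as err:
            raise StageError(f"stage 'bindbias' failed: {err}") from err

    # --- stage: conservation bias (optional) ------------------------------
    if config.conservation_path:
        try:
            table = io_mod.read_conservation_table(
                config.conservation_path, flip_sign=config.flip_conservation_sign
            )
            raw_profiles = _profiles_from_table(table)
            profiles, excluded = cons_mod.normalize_profiles(raw_profiles)
            by_id = {p.antigen_id: p for p in profiles}
            pos_cons = cons_mod.positional_conservation(
                profiles, n_bins=config.n_bins, n_boot=config.n_boot,
                seed=config.seed,
            )
            pep_scores: dict[str, list[float]] = {"positive": [], "negative": []}
            n_missing_profile = 0
            for m in mappings:
                profile = by_id.get(m.antigen_id)
                if profile is None:
                    n_missing_profile += 1
                    continue
                pep_scores[m.peptide.label].append(
                    cons_mod.peptide_conservation(m, profile)
                )
            f = cons_mod.conservation_ratio_function(
                pep_scores["positive"], pep_scores["negative"],
                n_bins=config.n_bins, n_boot=config.n_boot, seed=config.seed,
            )
            estimated = cons_mod.estimate_bias_from_conservation(pos_cons, f)
            welch = cons_mod.welch_one_sided(
                pep_scores["positive"], pep_scores["negative"]
            )
            agreement = cons_mod.curve_agreement(observed, estimated)
            report["conservation_bias"] = {
                "profiles_excluded": excluded,
                "peptides_without_profile": n_missing_profile,
                "positional_conservation": {
                    "bin_center": pos_cons.bin_centers.tolist(),
                    "mean_score": pos_cons.mean_score.tolist(),
                    "boot_p25": pos_cons.boot_p25.tolist(),
                    "boot_p75": pos_cons.boot_p75.tolist(),
                    "whisker_lo": pos_cons.whisker_lo.tolist(),
                    "whisker_hi": pos_cons.whisker_hi.tolist(),
                },
                "ratio_function": {
                    "midpoint": f.midpoints.tolist(),
                    "ratio": f.ratio.tolist(),
                    "collapsed": bool(f.collapsed),
                },
                "estimated_curve": _curve_dict(estimated),
                "welch_one_sided": {
                    "t": welch.t, "df": welch.df, "p": welch.p,
                    "mean_pos": welch.mean_pos, "mean_neg": welch.mean_neg,
                    "n_pos": welch.n_pos, "n_neg": welch.n_neg,
                },
                "pearson_r_observed_vs_estimated": agreement,
            }
        except Exception as err:
            raise StageError(f"stage 'consbias' failed: {err}") from err

    return report
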
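"""Synthetic proteomes, assay peptides, conservation fields, toy predictor.

Every downstream stage of the positional-bias analysis is exercised against
data with known ground truth generated here:

* proteomes of random sequences over the 20-residue alphabet;
* assay-labelled peptides whose positive placements follow a configurable
  positional density (uniform, central, N- or C-terminal), while negatives
  are placed uniformly — so the expected per-bin probability ratio is known
  in closed form;
* per-residue conservation fields with a configurable centre-minus-termini
  trend, and a configurable coupling by which a peptide's probability of a
  positive assay outcome increases with the conservation of its footprint;
* a toy position-specific-scoring-matrix binding predictor emitting
  IC50-scale values that are independent of a window's position in its
  protein by construction, so binder-bias curves over its output should be
  flat.

All draws come from generators seeded per operation from the scenario seed;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .mapping import AMINO_ACIDS, Antigen, PeptideMapping, PeptideRecord

_DENSITIES = ("uniform", "central", "n_terminal", "c_terminal")

#: The 12 functional HLA class I supertype labels used to group alleles.
SUPERTYPES = (
    "A01", "A02", "A03", "A24", "A26", "B07",
    "B08", "B27", "B39", "B44", "B58", "B62",
)

# independent RNG streams per operation, spawned from the scenario seed
_STREAM_PROTEOME = 0
_STREAM_PEPTIDES = 1
_STREAM_CONS_NOISE = 2
_STREAM_LABELS = 3


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Parameters
    ----------
    n_proteins, length_range
        Proteome size and inclusive protein length bounds (residues).
    n_peptides, peptide_length
        Number of assay records and their length (9-mers by default).
    positive_fraction
        Marginal probability of a positive assay outcome.
    positional_density, density_strength
        Placement density of positive peptides over normalized position x;
        negatives are always uniform. ``central`` uses the truncated
        quadratic weight w(x) = 1 + s (1 - 4 (x - 1/2)^2); the terminal
        densities are linear in x. Strength s >= 0; s = 0 is uniform.
    conservation_trend
        Centre-minus-termini amplitude of the conservation field, in sd
        units of the per-residue noise.
    conservation_coupling
        Logistic slope (per raw score unit) by which a peptide's positive
        probability increases with its mean footprint conservation; the
        intercept is calibrated so the marginal positive fraction is kept.
        Applies only to organism-immunogen records.
    peptide_immunogen_fraction
        Fraction of records whose immunogen context is an individual
        peptide rather than a whole organism; their labels never couple to
        conservation.
    seed
        Scenario seed; every generator is a pure function of it.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (200, 800)
    n_peptides: int = 10_000
    peptide_length: int = 9
    positive_fraction: float = 0.2
    positional_density: str = "uniform"
    density_strength: float = 0.0
    conservation_trend: float = 1.0
    conservation_coupling: float = 0.0
    peptide_immunogen_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be > 0")
        if self.n_peptides <= 0:
            raise ValueError("n_peptides must be > 0")
        if self.peptide_length <= 0:
            raise ValueError("peptide_length must be > 0")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range must be (min, max) with min <= max")
        if lo <= self.peptide_length:
            raise ValueError("length_range min must exceed peptide_length")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.positional_density not in _DENSITIES:
            raise ValueError(
                f"positional_density must be one of {_DENSITIES}, "
                f"got {self.positional_density!r}"
            )
        if self.density_strength < 0:
            raise ValueError("density_strength must be >= 0")
        if not 0 <= self.peptide_immunogen_fraction < 1:
            raise ValueError("peptide_immunogen_fraction must be in [0, 1)")


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_proteome(config: ScenarioConfig) -> list[Antigen]:
    """Random proteome: uniform residues, lengths uniform in length_range."""
    rng = _rng(config, _STREAM_PROTEOME)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    letters = np.array(list(AMINO_ACIDS))
    return [
        Antigen(id=f"SYN{i:04d}", sequence="".join(rng.choice(letters, size=L)))
        for i, L in enumerate(lengths)
    ]


# ---------------------------------------------------------------------------
# positional densities (positives); negatives are uniform

def density_weight(x: np.ndarray, density: str, s: float) -> np.ndarray:
    """Unnormalized placement weight w(x) of a positional density."""
    x = np.asarray(x, dtype=float)
    if density == "uniform" or s == 0:
        return np.ones_like(x)
    if density == "central":
        return 1 + s * (1 - 4 * (x - 0.5) ** 2)
    if density == "n_terminal":
        return 1 + s * (1 - x)
    if density == "c_terminal":
        return 1 + s * x
    raise ValueError(f"unknown density {density!r}")


def density_bin_masses(density: str, s: float, n_bins: int = 5) -> np.ndarray:
    """Closed-form bin masses of a positional density over equal bins.

    The expected bias curve of a scenario is these masses divided by the
    uniform mass 1/n_bins.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    a, b = edges[:-1], edges[1:]
    if density == "uniform" or s == 0:
        masses = b - a
    elif density == "central":
        # integral of 1 + s - 4 s (x - 1/2)^2
        masses = (1 + s) * (b - a) - (4 * s / 3) * ((b - 0.5) ** 3 - (a - 0.5) ** 3)
        masses /= 1 + 2 * s / 3
    elif density == "n_terminal":
        masses = (1 + s) * (b - a) - (s / 2) * (b**2 - a**2)
        masses /= 1 + s / 2
    elif density == "c_terminal":
        masses = (b - a) + (s / 2) * (b**2 - a**2)
        masses /= 1 + s / 2
    else:
        raise ValueError(f"unknown density {density!r}")
    return masses


def expected_ratio_curve(config: ScenarioConfig, n_bins: int = 5) -> np.ndarray:
    """Analytic per-bin probability ratio implied by the scenario density."""
    masses = density_bin_masses(
        config.positional_density, config.density_strength, n_bins
    )
    return masses * n_bins


def _sample_density_x(
    rng: np.random.Generator, n: int, density: str, s: float
) -> np.ndarray:
    """Draw n positions from the configured density by rejection sampling."""
    if density == "uniform" or s == 0:
        return rng.uniform(0, 1, size=n)
    out = np.empty(0)
    w_max = 1 + s  # all three families are bounded by 1 + s
    while out.size < n:
        m = max(2 * (n - out.size), 64)
        x = rng.uniform(0, 1, size=m)
        u = rng.uniform(0, w_max, size=m)
        out = np.concatenate([out, x[u <= density_weight(x, density, s)]])
    return out[:n]


# ---------------------------------------------------------------------------
# conservation field (shared latent structure)

def _residue_positions(L: int) -> np.ndarray:
    """Normalized residue positions (i-1)/(L-1) for a protein of length L."""
    if L < 2:
        raise ValueError("need at least two residues")
    return np.arange(L) / (L - 1)


def _conservation_fields(
    antigens: list[Antigen], config: ScenarioConfig
) -> dict[str, np.ndarray]:
    """Raw conservation scores per antigen: parabolic trend + unit noise.

    Deterministic in (antigens, seed); shared by generate_conservation and
    the label-coupling step of generate_assay_peptides so both see the same
    field.
    """
    rng = _rng(config, _STREAM_CONS_NOISE)
    fields = {}
    for antigen in antigens:
        pos = _residue_positions(len(antigen))
        trend = config.conservation_trend * (1 - 4 * (pos - 0.5) ** 2)
        fields[antigen.id] = trend + rng.standard_normal(len(antigen))
    return fields


def generate_conservation(
    antigens: list[Antigen], config: ScenarioConfig
) -> pd.DataFrame:
    """Raw (un-normalized) per-residue conservation table.

    Higher score = more conserved. Columns: antigen_id, position_1based,
    score. The positional trend is parabolic in normalized residue
    position with amplitude ``conservation_trend`` (sd units of the noise).
    """
    if not antigens:
        raise ValueError("antigens must be non-empty")
    fields = _conservation_fields(antigens, config)
    frames = [
        pd.DataFrame(
            {
                "antigen_id": a.id,
                "position_1based": np.arange(1, len(a) + 1),
                "score": fields[a.id],
            }
        )
        for a in antigens
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# assay peptides

def generate_assay_peptides(
    antigens: list[Antigen], config: ScenarioConfig
) -> tuple[list[PeptideRecord], list[PeptideMapping]]:
    """Assay-labelled peptides cut from the proteome, with ground truth.

    Returns the records together with their true placements (the generator
    knows where each peptide was cut). Placement: negatives uniform over
    windows; positives follow the configured positional density. When
    ``conservation_coupling`` is non-zero, labels of organism-context
    records are redrawn with probability logistic in the peptide's mean
    raw conservation, the intercept calibrated so the marginal positive
    fraction is preserved; peptide-immunization records never couple.
    """
    if not antigens:
        raise ValueError("antigens must be non-empty")
    k = config.peptide_length
    shortest = min(len(a) for a in antigens)
    if k >= shortest:
        raise ValueError(
            f"peptide_length={k} must be shorter than the shortest protein "
            f"({shortest} residues)"
        )
    rng = _rng(config, _STREAM_PEPTIDES)
    n = config.n_peptides

    n_windows = np.array([len(a) - k + 1 for a in antigens], dtype=float)
    which = rng.choice(len(antigens), size=n, p=n_windows / n_windows.sum())

    labels = rng.uniform(size=n) < config.positive_fraction
    immunogen_pep = rng.uniform(size=n) < config.peptide_immunogen_fraction

    # positions: uniform over the start lattice, except density-placed positives
    M_all = np.array([len(antigens[a]) - k for a in which])  # starts are 1 .. M + 1
    starts = rng.integers(0, M_all + 1) + 1
    dense = labels & (
        config.positional_density != "uniform" and config.density_strength > 0
    )
    if dense.any():
        xs = _sample_density_x(
            rng, int(dense.sum()), config.positional_density, config.density_strength
        )
        starts[dense] = np.rint(xs * M_all[dense]).astype(int) + 1

    if config.conservation_coupling != 0:
        fields = _conservation_fields(antigens, config)
        mean_cons = np.array(
            [
                fields[antigens[a_idx].id][s - 1 : s - 1 + k].mean()
                for a_idx, s in zip(which, starts)
            ]
        )
        beta = config.conservation_coupling
        organism = ~immunogen_pep
        m = mean_cons[organism]

        def _excess(alpha: float) -> float:
            return float(expit(alpha + beta * m).mean()) - config.positive_fraction

        alpha = brentq(_excess, -50, 50)
        rng_lab = _rng(config, _STREAM_LABELS)
        coupled = rng_lab.uniform(size=m.size) < expit(alpha + beta * m)
        labels = labels.copy()
        labels[organism] = coupled

    records: list[PeptideRecord] = []
    mappings: list[PeptideMapping] = []
    for i in range(n):
        antigen = antigens[which[i]]
        start = int(starts[i])
        rec = PeptideRecord(
            sequence=antigen.sequence[start - 1 : start - 1 + k],
            label="positive" if labels[i] else "negative",
            immunogen="peptide" if immunogen_pep[i] else "organism",
            organism_id="SYNVIRUS",
        )
        records.append(rec)
        mappings.append(
            PeptideMapping(
                peptide=rec,
                antigen_id=antigen.id,
                peptide_start=start,
                x=(start - 1) / (len(antigen) - k),
            )
        )
    return records, mappings


# ---------------------------------------------------------------------------
# toy binding predictor

def toy_binding_predictor(
    peptides, n_alleles: int = 24, seed: int = 0
) -> pd.DataFrame:
    """Matrix-based stand-in for an MHC-I binding predictor.

    Each pseudo-allele gets a fixed random position-specific score matrix;
    a k-mer's summed score is squashed through a logistic and mapped onto
    an IC50 scale in the open interval (1, 50000) nM. Scores depend only on
    a peptide's residues, never on where the window sits in its protein, so
    bias curves of predicted binders over uniform-composition proteomes are
    flat by construction.

    Returns a table with columns peptide, allele, ic50_nM covering the
    unique input peptides x all pseudo-alleles.
    """
    unique = sorted(set(peptides))
    if not unique:
        raise ValueError("need at least one peptide")
    lengths = {len(p) for p in unique}
    if len(lengths) != 1:
        raise ValueError(f"mixed peptide lengths {sorted(lengths)} rejected")
    k = lengths.pop()
    if n_alleles <= 0:
        raise ValueError("n_alleles must be > 0")

    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    try:
        encoded = np.array([[aa_index[aa] for aa in p] for p in unique])
    except KeyError as err:
        raise ValueError(f"peptide contains non-canonical residue {err}") from None

    rng = np.random.default_rng([int(seed), 4])
    rows = []
    for a in range(n_alleles):
        pssm = rng.standard_normal((k, len(AMINO_ACIDS)))
        score = pssm[np.arange(k), encoded].sum(axis=1) / np.sqrt(k)
        # offset keeps the binder (<500 nM) fraction realistically small
        ic50 = 50_000.0 ** expit(score + 2.0)
        rows.append(
            pd.DataFrame(
                {"peptide": unique, "allele": f"HLA-SIM-{a:03d}", "ic50_nM": ic50}
            )
        )
    return pd.concat(rows, ignore_index=True)


def default_supertype_map(n_alleles: int = 24) -> pd.DataFrame:
    """Round-robin assignment of pseudo-alleles to the 12 supertypes."""
    return pd.DataFrame(
        {
            "allele": [f"HLA-SIM-{a:03d}" for a in range(n_alleles)],
            "supertype": [SUPERTYPES[a % len(SUPERTYPES)] for a in range(n_alleles)],
        }
    )


# ---------------------------------------------------------------------------
# named scenarios used by the analysis drivers and acceptance checks

def scenario_null(seed: int = 0, n_peptides: int = 10_000) -> ScenarioConfig:
    """No positional bias, no conservation structure: calibration null."""
    return ScenarioConfig(
        n_peptides=n_peptides, conservation_trend=0.0, seed=seed
    )


def scenario_central_bias(seed: int = 0, n_peptides: int = 10_000) -> ScenarioConfig:
    """Positives enriched centrally by a direct placement density."""
    return ScenarioConfig(
        n_peptides=n_peptides,
        positional_density="central",
        density_strength=1.5,
        conservation_trend=0.0,
        seed=seed,
    )


def scenario_conservation_recovery(
    seed: int = 0, n_peptides: int = 20_000
) -> ScenarioConfig:
    """Asymmetry arises ONLY through conservation coupling.

    Placement is uniform for everyone; the conservation field has a strong
    central trend and labels couple strongly to footprint conservation, so
    the conservation-composed curve should recover the observed one.
    A fifth of the records are peptide-immunization context, whose labels
    never couple — the slice where the conservation-recognition link must
    vanish.
    """
    return ScenarioConfig(
        n_peptides=n_peptides,
        conservation_trend=1.0,
        conservation_coupling=2.0,
        peptide_immunogen_fraction=0.2,
        seed=seed,
    )


def scenario_dissociation(seed: int = 0, n_peptides: int = 10_000) -> ScenarioConfig:
    """Central placement bias with a flat, uncoupled conservation field.

    Negative control: the observed curve is centrally peaked while the
    conservation-derived curve must stay flat.
    """
    return ScenarioConfig(
        n_peptides=n_peptides,
        positional_density="central",
        density_strength=1.5,
        conservation_trend=0.0,
        conservation_coupling=0.0,
        seed=seed,
    )


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    """The same scenario under a different seed."""
    return replace(config, seed=seed)
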
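"""Peptide-to-proteome placement and normalized positions.

A tested peptide enters the analysis only if it occurs as an exact substring
at exactly one (antigen, start) site across the whole reference proteome;
ambiguous (tied) and absent peptides are excluded and accounted for in a
mapping audit. Each unique placement is reduced to a length-independent
normalized position ``x`` in [0, 1]:

    x = (peptide_start - 1) / (protein_length - peptide_length)

with ``peptide_start`` 1-based, so that a peptide containing the first
residue of its protein scores 0 and a peptide containing the last residue
scores 1. Uniformly placed peptides then yield a uniform distribution of
``x`` regardless of protein length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}


class DegenerateLengthError(ValueError):
    """Peptide length >= protein length: normalized position is undefined."""


@dataclass(frozen=True)
class Antigen:
    """A reference protein sequence.

    The alphabet is the 20 canonical residues plus ``X`` (unknown); ``X``
    never matches a peptide residue.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("antigen id must be non-empty")
        if not self.sequence:
            raise ValueError(f"antigen {self.id!r}: sequence must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"antigen {self.id!r}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideRecord:
    """A tested peptide with its assay outcome and immunogen context."""

    sequence: str
    label: str  # "positive" | "negative"
    immunogen: str = "organism"  # "organism" | "peptide"
    organism_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.immunogen not in ("organism", "peptide"):
            raise ValueError(
                f"immunogen must be organism/peptide, got {self.immunogen!r}"
            )


@dataclass(frozen=True)
class PeptideMapping:
    """A unique placement of a peptide in an antigen."""

    peptide: PeptideRecord
    antigen_id: str
    peptide_start: int  # 1-based
    x: float


@dataclass
class MappingAudit:
    """Attrition bookkeeping for one mapping run.

    mapped + unmapped + ties + degenerate + rejected == n_input.
    """

    n_input: int = 0
    mapped: int = 0
    unmapped: int = 0
    ties: int = 0
    degenerate: int = 0
    rejected: int = 0  # record-level problems (e.g. empty sequence)
    reasons: list = field(default_factory=list)  # (peptide, reason) pairs

    def conserved(self) -> bool:
        return (
            self.mapped + self.unmapped + self.ties + self.degenerate + self.rejected
            == self.n_input
        )


def normalized_position(
    peptide_start: int, protein_length: int, peptide_length: int
) -> float:
    """Normalized position of a peptide within its protein.

    Parameters
    ----------
    peptide_start
        1-based index of the peptide's first residue in the protein.
    protein_length, peptide_length
        Lengths in residues; the peptide must be strictly shorter than the
        protein and fit entirely within it.

    Returns
    -------
    float in [0, 1]; 0 iff the peptide contains the first residue of the
    protein, 1 iff it contains the last.
    """
    if peptide_length >= protein_length:
        raise DegenerateLengthError(
            f"peptide_length={peptide_length} >= protein_length={protein_length}"
        )
    if peptide_length < 1:
        raise ValueError("peptide_length must be >= 1")
    if not 1 <= peptide_start <= protein_length - peptide_length + 1:
        raise ValueError(
            f"peptide_start={peptide_start} out of range for "
            f"protein_length={protein_length}, peptide_length={peptide_length}"
        )
    return (peptide_start - 1) / (protein_length - peptide_length)


def _window_index(proteome: list[Antigen], lengths: set[int]) -> dict[str, list]:
    """Index every window of each needed length to its placement sites.

    Windows containing ``X`` are not indexed (X never matches). Sites are
    capped at 2 per window: the mapping rule only needs to distinguish
    "unique" from "tied".
    """
    index: dict[str, list] = {}
    for antigen in proteome:
        seq = antigen.sequence
        L = len(seq)
        for k in lengths:
            if k > L:
                continue
            for start0 in range(L - k + 1):
                window = seq[start0 : start0 + k]
                if "X" in window:
                    continue
                sites = index.setdefault(window, [])
                if len(sites) < 2:
                    sites.append((antigen.id, start0 + 1))
                else:  # already tied; keep the count honest but bounded
                    sites_flag = sites
                    if len(sites_flag) == 2:
                        sites_flag.append(None)
    return index


def map_peptides(
    peptides: list[PeptideRecord], proteome: list[Antigen]
) -> tuple[list[PeptideMapping], MappingAudit]:
    """Place peptides in the proteome under the unique-exact-match rule.

    A peptide maps iff its sequence occurs at exactly one (antigen, start)
    site across all antigens. Peptides absent from the proteome, peptides
    with >= 2 occurrences (ties), and peptides whose unique hit falls in a
    protein of equal length (degenerate normalized position) are excluded
    and counted in the audit.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    audit = MappingAudit(n_input=len(peptides))
    lengths = {len(p.sequence) for p in peptides if p.sequence}
    index = _window_index(proteome, lengths)
    protein_length = {a.id: len(a) for a in proteome}

    mappings: list[PeptideMapping] = []
    for rec in peptides:
        if not rec.sequence:
            audit.rejected += 1
            audit.reasons.append((rec, "empty-sequence"))
            continue
        sites = index.get(rec.sequence, [])
        if len(sites) == 0:
            audit.unmapped += 1
            audit.reasons.append((rec, "no-exact-match"))
            continue
        if len(sites) >= 2:
            audit.ties += 1
            audit.reasons.append((rec, "tie"))
            continue
        antigen_id, start = sites[0]
        try:
            x = normalized_position(
                start, protein_length[antigen_id], len(rec.sequence)
            )
        except DegenerateLengthError:
            audit.degenerate += 1
            audit.reasons.append((rec, "degenerate-length"))
            continue
        audit.mapped += 1
        mappings.append(
            PeptideMapping(peptide=rec, antigen_id=antigen_id, peptide_start=start, x=x)
        )
    return mappings, audit
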
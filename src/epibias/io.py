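"""File formats: FASTA proteomes and tab-separated tables.

All tables are plain TSV (header row, UTF-8, '.' decimal, no quoting) with
optional leading ``# key<TAB>value`` provenance lines that readers skip.
Conservation tables follow the convention higher score = more conserved;
tools that emit evolutionary *rates* (higher = faster = LESS conserved)
must be ingested with ``flip_sign=True``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bias import BiasCurve, BinTestResult
from .mapping import Antigen, MappingAudit, PeptideMapping, PeptideRecord


def read_fasta(path) -> list[Antigen]:
    """Read a proteome; ids are the first whitespace token of each header."""
    antigens: list[Antigen] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        antigens.append(Antigen(id=record.id, sequence=str(record.seq)))
    if not antigens:
        raise ValueError(f"no FASTA records found in {path}")
    return antigens


def write_fasta(antigens: list[Antigen], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(a.sequence), id=a.id, description="") for a in antigens],
        str(path),
        "fasta",
    )


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping, for output provenance."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}\t{value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


# --- assay table ------------------------------------------------------------

def write_assay_table(records: list[PeptideRecord], path, header=None) -> None:
    df = pd.DataFrame(
        {
            "peptide": [r.sequence for r in records],
            "label": [r.label for r in records],
            "immunogen": [r.immunogen for r in records],
            "organism_id": [r.organism_id for r in records],
        }
    )
    _write_tsv(df, path, header)


def read_assay_table(path) -> list[PeptideRecord]:
    df = _read_tsv(path, ("peptide", "label", "immunogen"))
    if "organism_id" not in df.columns:
        df["organism_id"] = ""
    return [
        PeptideRecord(
            sequence=row.peptide,
            label=row.label,
            immunogen=row.immunogen,
            organism_id=str(row.organism_id),
        )
        for row in df.itertuples()
    ]


# --- conservation -----------------------------------------------------------

def write_conservation_table(df: pd.DataFrame, path, header=None) -> None:
    _write_tsv(df[["antigen_id", "position_1based", "score"]], path, header)


def read_conservation_table(path, flip_sign: bool = False) -> pd.DataFrame:
    """Per-residue scores. Set flip_sign=True for rate-convention inputs."""
    df = _read_tsv(path, ("antigen_id", "position_1based", "score"))
    df = df.sort_values(["antigen_id", "position_1based"], kind="stable")
    if flip_sign:
        df = df.assign(score=-df["score"])
    return df.reset_index(drop=True)


# --- predictions & supertypes ----------------------------------------------

def write_predictions_table(df: pd.DataFrame, path, header=None) -> None:
    _write_tsv(df[["peptide", "allele", "ic50_nM"]], path, header)


def read_predictions_table(path) -> pd.DataFrame:
    return _read_tsv(path, ("peptide", "allele", "ic50_nM"))


def write_supertype_table(df: pd.DataFrame, path, header=None) -> None:
    _write_tsv(df[["allele", "supertype"]], path, header)


def read_supertype_table(path) -> pd.DataFrame:
    df = _read_tsv(path, ("allele", "supertype"))
    dup = df["allele"][df["allele"].duplicated()]
    if not dup.empty:
        raise ValueError(f"allele(s) mapped to multiple supertypes: {sorted(set(dup))}")
    return df


# --- mappings and curves ----------------------------------------------------

def mappings_frame(mappings: list[PeptideMapping]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [m.peptide.sequence for m in mappings],
            "antigen_id": [m.antigen_id for m in mappings],
            "start_1based": [m.peptide_start for m in mappings],
            "x": [m.x for m in mappings],
            "label": [m.peptide.label for m in mappings],
            "immunogen": [m.peptide.immunogen for m in mappings],
        }
    )


def write_mappings(mappings: list[PeptideMapping], path, header=None) -> None:
    _write_tsv(mappings_frame(mappings), path, header)


def write_audit(audit: MappingAudit, path, header=None) -> None:
    df = pd.DataFrame(
        {
            "category": ["input", "mapped", "unmapped", "ties", "degenerate", "rejected"],
            "count": [
                audit.n_input, audit.mapped, audit.unmapped,
                audit.ties, audit.degenerate, audit.rejected,
            ],
        }
    )
    _write_tsv(df, path, header)


def curve_frame(curve: BiasCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_center": curve.bin_centers,
            "ratio": curve.ratio,
            "boot_p25": curve.boot_p25,
            "boot_p75": curve.boot_p75,
            "whisker_lo": curve.whisker_lo,
            "whisker_hi": curve.whisker_hi,
            "boot_sd": curve.boot_sd,
            "n_undefined_resamples": curve.n_undefined_resamples,
            "defined": curve.defined,
        }
    )


def write_curve(curve: BiasCurve, path, header=None) -> None:
    _write_tsv(curve_frame(curve), path, header)


def bin_tests_frame(result: BinTestResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": range(1, len(result.positives) + 1),
            "positives": result.positives,
            "negatives": result.negatives,
            "expected_fraction": result.expected_fraction,
            "p_value": result.p_values,
            "defined": result.defined,
        }
    )


def write_bin_tests(result: BinTestResult, path, header=None) -> None:
    _write_tsv(bin_tests_frame(result), path, header)
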
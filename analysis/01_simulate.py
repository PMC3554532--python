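"""Generate the four synthetic study scenarios used by the analysis.

Scenarios (written under results/data/<name>/):
  null          uniform placement, flat conservation — calibration baseline
  central       positives placed centrally (direct positional bias)
  recovery      uniform placement; positives arise only via coupling of
                recognition to a centrally-trending conservation field
  dissociation  central placement bias with a flat, uncoupled conservation
                field — the negative control separating the two explanations

Each directory holds proteome.fasta, assay.tsv, conservation.tsv,
predictions.tsv and supertypes.tsv.
"""

import argparse
from pathlib import Path

import epibias as eb
from epibias import io as io_mod

SCENARIOS = {
    "null": eb.scenario_null,
    "central": eb.scenario_central_bias,
    "recovery": eb.scenario_conservation_recovery,
    "dissociation": eb.scenario_dissociation,
}


def main(seed: int = 0, out_root: Path = Path("results/data")) -> None:
    for name, factory in SCENARIOS.items():
        config = factory(seed=seed)
        out = out_root / name
        out.mkdir(parents=True, exist_ok=True)
        antigens = eb.generate_proteome(config)
        records, _ = eb.generate_assay_peptides(antigens, config)
        cons = eb.generate_conservation(antigens, config)
        windows = eb.generate_kmers(antigens, k=config.peptide_length)
        preds = eb.toy_binding_predictor(
            windows["peptide"].drop_duplicates(), n_alleles=24, seed=seed
        )
        header = {"scenario": name, "seed": seed}
        io_mod.write_fasta(antigens, out / "proteome.fasta")
        io_mod.write_assay_table(records, out / "assay.tsv", header)
        io_mod.write_conservation_table(cons, out / "conservation.tsv", header)
        io_mod.write_predictions_table(preds, out / "predictions.tsv", header)
        io_mod.write_supertype_table(
            eb.default_supertype_map(24), out / "supertypes.tsv", header
        )
        n_pos = sum(r.label == "positive" for r in records)
        print(
            f"[{name}] {len(antigens)} proteins, {len(records)} peptides "
            f"({n_pos} positive), {len(windows)} 9-mer windows -> {out}"
        )


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    main(seed=args.seed)
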
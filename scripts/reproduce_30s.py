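#!/usr/bin/env python
"""Reproduce the 30S analyses from local copies of the 2AVY and 1J5E PDB files.

The crystal structures are not bundled; download them yourself, e.g.

    curl -O https://files.rcsb.org/download/2AVY.pdb
    curl -O https://files.rcsb.org/download/1J5E.pdb

then run

    python scripts/reproduce_30s.py --pdb-2avy 2AVY.pdb --pdb-1j5e 1J5E.pdb --out scratch/30s

This writes, per species, the net-charge table, the per-protein contact
pair counts at 3.5 A (with the Total row), and the ANM enrichment factors
with 10,000-draw permutation p-values, plus the overall Lys+Arg
composition percentage.  The tip-effect exclusions reported for the
T. thermophilus structure (S15 Arg88/Gly89; S17 Gly8-Val11) come from the
automatic median + 5*IQR rule unless overridden below.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from riboflex.contact_analysis import composition_stats
from riboflex.pipeline import RunConfig, run_full_pipeline
from riboflex.structure_io import extract_sequence, parse_structure


def run_species(pdb_path: Path, label: str, out_dir: Path, seed: int) -> None:
    structure = parse_structure(pdb_path, structure_id=label)
    rna = [c.chain_id for c in structure.chains_of_class("rna")]
    # the 16S rRNA is the (single) long RNA chain; drop short RNA ligands
    rna16s = [cid for cid in rna if len(structure.chain(cid)) > 1000]
    config = RunConfig(
        structure=structure,
        rna_chains=rna16s or rna,
        n_perm=10_000,
        seed=seed,
        output_dir=out_dir / label,
    )
    bundle = run_full_pipeline(config)
    seqs = [extract_sequence(c) for c in structure.chains_of_class("protein")]
    overall = composition_stats(seqs)
    print(f"[{label}] proteins: {len(seqs)}  16S chains: {rna16s}")
    print(f"[{label}] overall Lys+Arg: {overall.pct_lys_arg:.1f}%  "
          f"Asp+Glu: {overall.pct_asp_glu:.1f}%")
    total = bundle.contact_table[bundle.contact_table['protein'] == 'Total'].iloc[0]
    print(f"[{label}] contact pairs: {total['total_pairs']}  "
          f"positive: {total['pct_pos']}%")
    print(bundle.enrichment_table[['protein', 'ef', 'p_value', 'N', 'C']].to_string(index=False))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb-2avy", type=Path, required=True)
    parser.add_argument("--pdb-1j5e", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("scratch/30s"))
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()
    run_species(args.pdb_2avy, "2AVY", args.out, args.seed)
    run_species(args.pdb_1j5e, "1J5E", args.out, args.seed)


if __name__ == "__main__":
    main()
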
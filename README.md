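# riboflex

Protein–rRNA contact mapping, coarse-grained mobility analysis and
contact-residue enrichment statistics for ribosomal assemblies.

## The problem

During assembly of the bacterial 30S ribosomal subunit, ~20 small-subunit
proteins (S2–S21) bind the 16S rRNA in an ordered, interdependent
sequence.  A recurring structural question is whether the protein
residues that touch the rRNA are *more mobile* than the rest of the
protein — flexible contact regions could adapt to the folding RNA and
help organize later binding sites.  `riboflex` provides the pieces needed
to ask that question of any protein–RNA co-crystal structure:

* **Contact detection.**  A protein residue is a *contact residue* when
  any of its atoms lies within 3.5 Å (inclusive) of any RNA nucleotide
  atom.  A residue touching k nucleotides contributes k contact pairs.
* **Charge census.**  Net charge per protein counting Lys/Arg as +1 and
  Asp/Glu as −1, plus composition percentages; ribosomal proteins are
  strongly enriched in Lys/Arg (≈20% vs ≈10% in typical cytosolic
  proteins) and so are their rRNA contacts.
* **Anisotropic network model (ANM).**  Each protein is coarse-grained to
  its Cα atoms; pairs within 13 Å are joined by identical springs.  The
  3n×3n Hessian has off-diagonal blocks −(γ/d²)·r_ij r_ijᵀ, and the
  per-residue mean-square fluctuation is Σ_k λ_k⁻¹ |v_k,i|² over the
  non-rigid modes (six zero modes for a connected 3-D network).  Highly
  extended terminal nodes show the "tip effect" — exaggerated RMSF — and
  are pruned by an iterative median + 5·IQR rule before statistics.
* **Enrichment factor and permutation test.**  For a protein with N
  usable residues, C of them contacting,

      EF = ⟨RMSF⟩_contacting / ⟨RMSF⟩_non-contacting ,

  and significance comes from drawing random C-subsets (default 10,000
  draws) and recomputing the ratio:
  p = (1 + #{EF_null ≥ EF_obs}) / (1 + n_draws).
* **Ensemble reductions and conservation.**  Kabsch-superposed RMSD
  series, iterative-mean RMSF for multi-model ensembles, B = (8/3)π²·RMSF²,
  profile correlations, Needleman–Wunsch (BLOSUM62) identity /
  side-chain-class conservation and cross-species Cα superposition RMSD.

A synthetic-data module generates toy protein–RNA complexes with planted
contacts at controlled distances, elastic networks with analytically
known spectra, and mobility profiles with planted enrichment, so the
entire pipeline is testable without downloading any structures.

## Worked example

```python
import riboflex as rf

spec = rf.ToyComplexSpec(
    n_protein_res=8, n_rna_nt=4, protein_sequence="KRDSGHKT",
    planted_contacts=frozenset({(1, 0, 3.3), (4, 2, 3.1), (6, 3, 2.9)}),
    seed=23,
)
structure, truth, pdb_text = rf.make_toy_complex(spec)
bundle = rf.run_full_pipeline(
    rf.RunConfig(structure=structure, n_perm=10_000, seed=1, tip_filter=False)
)
print(bundle.enrichment_table[["protein", "ef", "p_value", "N", "C"]])
print(bundle.charge_table)
```

prints

```
protein   ef  p_value  N  C
      A 0.94 0.681432  8  3
protein  length  n_pos  n_neg  net_charge  pct_lys_arg  pct_asp_glu
      A       8      3      1           2         37.5         12.5
```

All three planted contacts are recovered (`C = 3` of `N = 8` residues);
the toy chain is a straight strand, so its contact residues are no more
mobile than the rest (EF ≈ 0.94, p ≈ 0.68) — the permutation test
correctly declines to call an enrichment.  The charge row reflects the
sequence KRDSGHKT: three Lys/Arg, one Asp, net +2.

The same classes drive the bundled worked example on real data: the 27
rRNA-contacting residues of *E. coli* S15 split into 5 basic, 5
histidine, 10 polar, 1 aromatic, 2 acidic and 4 nonpolar:

```python
from riboflex.reference_data import load_s15_contact_residues
from riboflex.contact_analysis import class_census
class_census(load_s15_contact_residues()["residue_name"])
# Counter({'polar': 10, 'histidine': 5, 'basic': 5, 'nonpolar': 4,
#          'acidic': 2, 'aromatic': 1})
```

A console script exposes each stage (`riboflex contacts | charge | anm |
enrich | conserve | synth | run`); `riboflex run --config run.yaml`
executes the whole pipeline and writes TSV/JSON tables.

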
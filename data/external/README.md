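# User-supplied external inputs (not distributed)

Optional real-data cross-checks read from this directory:

- `2kly.pdb` — the multi-model NMR entry 2KLY (Ube2g2), used to check
  that the catalytic cysteine (C89 in Ube2g2 numbering) side chain has a
  mean relative SASA below 15 % across models.
  Obtain with: `curl -O https://files.rcsb.org/download/2KLY.pdb` and
  rename to lower case.
- `cdc34_ube2g2.fasta` — two ungapped UBC-domain sequences (yeast Cdc34
  UBC domain, UniProt P14682 residues 7–170, and human Ube2g2, UniProt
  P60604), used to check that their global sequence identity exceeds 40 %.

The corresponding acceptance tests fail with an explanatory message when
these files are absent.
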
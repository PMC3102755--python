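# Toy mini-family alignments (synthetic)

Hand-constructed miniature E2-family alignments (48/36 columns) that
exercise every conservation operation with known, hand-countable answers.
They are **synthetic fixtures**, not real E2 sequences.

- `family3.fasta` — an acidic-insertion family: reference `cdc34_toy`
  (numbering starts at 1), insertion at positions 15–26, Psite-1 = S33
  (CK2 context D34-D35-E36), Psite-2 = S42 (context G43-D44-E45).
  Designed conservation: Psite-1 S/T 100 %, DE1 100 %, Psite-2 80 %,
  DE2 80 %.
- `family2.fasta` — a close homolog family without the insertion
  (Psite-1 = position 21: 75 % S/T; Psite-2 = position 30: 75 %).
- `family7.fasta` — a distant family: phospho-sites replaced (0 %).
- `cross_family3_vs_family2.fasta` — cross-family pair for insertion
  detection: the comparator row has a 12-column gap at columns 15–26.
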
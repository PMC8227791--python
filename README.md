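# hexamask

Tools for analysing the double-stranded-DNA binding specificity of short
peptides at the level of base-*pair* sequences rather than single-strand
sequences.

Short peptides (the package was built around the neuroprotective
tripeptides EDR, Glu-Asp-Arg, and KED, Lys-Glu-Asp) bind in the minor
groove of B-form dsDNA, where the two strands are not distinguishable
the way they are in major-groove recognition. A useful coordinate system
is therefore the **weak/strong mask**: positionwise, an A·T base pair
(two hydrogen bonds) is written `W` and a G·C pair (three bonds) is
written `S`, following the IUPAC degenerate codes. The mask is a property
of the duplex — complementing a strand leaves it unchanged, reversing a
strand reverses it.

The package provides:

- **Duplex-space enumeration** — all distinct double-stranded k-mers
  under reverse-complement equivalence, with the canonical representative
  chosen as min(s, revcomp(s)). For hexamers the 4⁶ = 4096 strands
  collapse to (4⁶ + 4³)/2 = **2080** duplexes, 64 of them
  reverse-complement palindromes.
- **Mask aggregation** — clustering of per-duplex docking-style affinity
  scores (lower = stronger) by mask: per-cluster count, mean, sample SD,
  best score and best sequence; best-complex lookup; a two-peptide
  comparison; and the mask-coincidence probability (1/2)ᵏ — the chance
  that two independently selected length-k masks agree exactly
  (0.015625 ≈ 0.0156 for hexamers).
- **Promoter scanning** — occurrence counts of exact hexamers or
  degenerate W/S masks in promoter FASTA, computed on four compiled
  variants of each sequence (original, complement, reverse, reverse
  complement), with overlapping matches and a per-variant breakdown.
- **Synthetic data with ground truth** — a calibrated linear score
  simulator (score = β₀ + β_GC·(G+C count) + mask effect + Gaussian
  noise) standing in for a commercial docking engine, and a promoter
  generator that plants motifs at known counts and verifies them against
  an independent brute-force counter.
- **Packaged reference tables** — hand-transcribed per-mask score
  summaries for the EDR and KED tripeptides (48 mask rows each) and
  published occurrence counts of the low-energy masks in promoters of
  Alzheimer's-disease-related genes (CASP3, TP53, SOD2, GPX1, PPARA,
  PPARG, NES, GAP43, SUMO1, APOE, IGF1), checksum-verified on load.

## Worked example

```python
>>> import hexamask as hm
>>> len(hm.enumerate_duplexes(6))
2080
>>> hm.mask_of("GAGTGG")
'SWSWSS'
>>> fx = hm.load_fixtures()
>>> hm.best_complex(fx.table1_edr)
('GAGTGG', -44.71, 'SWSWSS')
>>> hm.best_complex(fx.table1_ked)
('CAGAGG', -26.56, 'SWSWSS')
>>> cmp = hm.compare_peptides(fx.table1_edr, fx.table1_ked)
>>> cmp.best_masks_identical, cmp.shared_masks
(True, 48)
>>> hm.coincidence_probability(6)
0.015625
```

Both tripeptides' best complexes carry the *same* mask, `SWSWSS`, and
highly similar sequences (`GAGTGG` vs `CAGAGG`), even though EDR binds
far more strongly (−44.71 vs −26.56): under the null of independent
mask selection that agreement has probability (1/2)⁶ ≈ 0.0156. Across
all 48 shared mask clusters the EDR mean score is lower than the KED
mean.

The same workflow from the shell:

```sh
hexamask enumerate -k 6 | wc -l        # 2080
hexamask compare --fixtures            # best masks SWSWSS / SWSWSS, identical
hexamask demo --seed 1 --out demo/     # self-contained synthetic inputs
hexamask run-all --fasta demo/promoters.fasta --seed 1 --out run/
```

`run-all` enumerates the duplex space, simulates EDR-like and KED-like
score tables over all 2080 hexamer duplexes, summarises them by mask,
compares the peptides, scans the promoters for each peptide's
best-binding sequence and mask, and writes deterministic TSV/JSON
outputs plus a run log.

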
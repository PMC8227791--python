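# Methods

## The duplex space

A double-stranded DNA word of length k is read off either strand, so the
set of physically distinct duplexes is the quotient of the 4ᵏ strands by
reverse-complement equivalence. The canonical representative is the
lexicographic minimum of a strand and its reverse complement under
A < C < G < T — the convention of standard k-mer tooling, chosen because
it is deterministic and order-stable. Reverse-complement palindromes
(s = revcomp(s), possible only at even k) are their own partner, giving

    |duplexes(k)| = (4^k + 4^(k/2)) / 2   (even k)
    |duplexes(k)| = 4^k / 2               (odd k)

hence 2080 for k = 6 with 4³ = 64 palindromes. Enumeration walks the 4ᵏ
strands and keeps self-canonical ones; a brute-force canonicalization of
the full strand set is the test oracle (set equality, k ≤ 6). The
default enumeration cap is k ≤ 10 (4¹⁰ ≈ 10⁶ strands), overridable.

Scores are attached to duplexes, never to written strands: ingesting a
table that lists both a strand and its reverse complement is a hard
error, because they describe the same molecule.

For structure-based pipelines the k-mer is conventionally embedded in a
longer oligo; `embed_in_flanks` places it centrally between A/T-only
flanks (default four base pairs per side, so a hexamer becomes a
14-mer). Only the base-pair composition of the flank is constrained; the
written flank pattern is a convention, defaulting to alternating `AT`
and overridable (e.g. poly-A), since any A/T-only choice satisfies the
constraint.

## The weak/strong mask

`W` = A·T pair, `S` = G·C pair, positionwise (IUPAC degenerate codes).
Identities used throughout, and enforced by property tests:
mask(complement(s)) = mask(s); mask(reverse(s)) = reverse(mask(s));
hence mask(revcomp(s)) is the reversed mask. A mask is *not* a duplex
invariant — the two strand readings of a non-palindromic duplex give
mutually reversed masks — which motivates the two keying policies below.

## Mask aggregation

`summarize_by_mask` clusters a score table by mask and reports per
cluster: n, mean, sample SD (ddof = 1; size-1 clusters report 0),
minimum score and the sequence achieving it (ties broken by
lexicographically smallest sequence). Rows sort by mean ascending with
mask as tie-break, so output is byte-stable.

Keying policies:

- `as_written` (default when ingesting external tables) keys each record
  by the mask of the strand as reported. Docking engines report one
  strand per complex, and published per-mask tables keyed this way can
  contain more rows than the 36 reversal-equivalence classes of length-6
  W/S strings — the packaged reference tables have 48 rows per peptide.
- `canonical` (default for simulated tables) keys by the canonical
  strand's mask, independent of how a file happened to write each
  strand; over the full hexamer space this yields all 64 W/S strings.

The SD definition in the reference tables is unverifiable from published
information (per-sequence scores are not public); sample SD was chosen
as the common default.

The mask-coincidence probability (1/2)ᵏ is the chance that two
independently chosen length-k masks agree at every position; it
quantifies how surprising it is that two peptides' best complexes carry
the identical mask. Reported rounded to 4 decimals (0.0156 at k = 6).

## The synthetic affinity model

The real scores come from a commercial docking engine and cannot be
recomputed here; the simulator is the package's declared stand-in so
every downstream stage is testable with known ground truth:

    score_i = β₀ + β_GC · gc_i + mask_effect(mask_i) + ε_i,  ε ~ N(0, σ²)

- β₀ (intercept, score units): expected score at zero G+C. EDR-like
  default −31.76, the all-W cluster mean of the EDR reference table.
- β_GC (score per G/C base): the GC-affinity trend. EDR-like default
  −0.925 = (−37.31 − (−31.76))/6, the line through the all-W and all-S
  EDR cluster means. KED-like defaults (β₀ = −12.50, β_GC = −0.047,
  σ = 3.5) are derived the same way from the KED all-W/all-S means,
  reflecting that peptide's much weaker binding and nearly flat GC
  trend.
- σ: homoscedastic Gaussian noise, default 2.5, matching the 2–3.5
  range of the reference tables' per-mask SDs. The simplest model
  consistent with the printed dispersion.
- mask_effects: optional per-mask additive offsets, default empty.

Duplexes are scored in sorted canonical order so the noise stream is
independent of input order; identical seed ⇒ bit-identical table.
`fit_gc_slope` is ordinary least squares of score on G+C count
(scipy.stats.linregress); over the full 2080-duplex space the analytic
slope SE is σ/√(n·Var(gc)) ≈ 0.044 at σ = 2.5, and parameter recovery
within 2 SE per seed is an acceptance check.

What the simulator does *not* emulate: sequence-specific structure
beyond GC count and mask, correlated errors between similar sequences,
and any peptide-pose physics. Passing tests therefore demonstrate the
correctness of the bookkeeping (enumeration, clustering, aggregation,
scanning), not the realism of docking scores.

## Promoter scanning

For each promoter the four variants — original, complement, reverse,
reverse complement — are compiled; published minor-groove searches
compile all four even though complement-only and reverse-only are not
biological reading frames, so all four are implemented, with a
`biological_strands_only` switch restricting totals to original +
reverse complement. Counting needle x on the reverse-complement variant
equals counting revcomp(x) on the original strand (property-tested),
tying the four-variant policy to conventional two-strand scanning.

Needles are exact words or degenerate masks (W → {A,T}, S → {C,G}).
Matches may overlap (default) and are counted as start positions,
1-based in reports. `N` bases load fine and never match. The default
total sums over *deduplicated* variants (an rc-palindromic promoter
would otherwise double-count); the per-variant breakdown is always
emitted so any counting convention can be read off. Whether published
occurrence counts used exact sequences or masks, one strand or several,
is not stated in the source material — both modes are provided, neither
asserted.

On i.i.d. uniform sequence of length L the expected mask-needle count
per strand is (L−5)·(1/2)⁶; the scanner is checked against this within
3 SD over 200 simulations, and against a brute-force sliding-window
counter on random cases.

## Synthetic promoters

Background bases are drawn i.i.d. at a configurable GC fraction
(default 0.5); plants are written at explicit or randomly drawn
non-overlapping positions on a chosen variant. The draw is then verified
with the independent brute-force counter: each planted needle's
four-variant total must equal exactly the planted count (no accidental
background hits, no clobbered plants); failing draws are rejected and
redrawn, up to 100 attempts. Rejection sampling was chosen over
constructive avoidance as simpler and adequate at promoter scale
(~600 bp, hexamer needles: acceptance well above 1/4 per draw). Real
promoter features — CpG islands, TATA boxes, repeat structure,
composition gradients around the TSS — are *not* emulated; planted-count
recovery shows scanner correctness, not expected hit rates in real
promoters.

The demo bundle writes 600 bp promoters named after the eleven
Alzheimer's-disease-related genes of the reference study, with planted
copies of the two best-binding hexamers at gene-dependent known counts,
plus simulated EDR-like/KED-like score tables and a JSON manifest of the
ground truth.

## Reference fixtures

The per-mask summaries for EDR and KED (48 rows each) and the promoter
occurrence table (9 mask entries) are hand-transcribed printed data —
the only bridge to the unpublishable docking output — shipped with
SHA-256 checksums verified on load. One transcription correction: the
occurrence table prints the mean for mask SWSWWS without a minus sign;
it is stored as −37.89, consistent with the same mask's row in the EDR
summary (noted in the file). The occurrence counts depend on an external
promoter database version and window that the source does not state;
they are reference data only and are never treated as a recomputation
target.

Cluster sizes are not printed in the source tables, so fixture rows
carry `n = NA`; computed summaries always carry real n, and conservation
(Σn = record count) is asserted on every summarize call.

## Numerical and policy choices

- Coordinates: 1-based, fully closed in all reports.
- Display rounding: scores 2 decimals, probabilities 4; comparisons use
  full precision.
- Tie-breaks: equal best scores → lexicographically smallest sequence;
  equal cluster means → mask lexicographic order.
- Determinism: every stochastic component takes a seed
  (numpy.random.default_rng); fixed config + seed ⇒ byte-identical
  primary outputs.
- Problem sizes in tests and the acceptance script: the full 2080-duplex
  space (cheap to enumerate and score), 20 seeds for slope recovery,
  200 simulations × 500 bp for the hit-rate check — sizes at which the
  checked statistics are stable.

## Known limitations

- The linear score model cannot reproduce per-sequence docking scores,
  only summary-level behaviour (GC trend, dispersion magnitude).
- `as_written` mask keying depends on which strand an external file
  reports; two files describing the same physical data with different
  strand choices summarize differently under it (use `canonical` for
  strand-choice invariance).
- The scanner is exact-match only (no mismatches, no PWM scoring).
- Odd k is supported throughout (no palindromes exist there), but the
  packaged reference data and default calibrations are hexamer-specific.
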
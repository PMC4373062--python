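# Methods

## The dating model

A provirus integrates with two identical LTRs.  Assuming post-integration
neutrality, each LTR accumulates substitutions independently at rate *R*
(substitutions/site/year), so after *T* years the expected pairwise
divergence is `D = 2·R·T`, and the insertion age is estimated as

    T = (D / R) / 2.

*D* is the Kimura two-parameter (K2P) distance between the 5′ and 3′ LTR
sequences.  With *P* and *Q* the observed proportions of transition (A↔G,
C↔T) and transversion differences over gap- and N-free columns (pairwise
deletion),

    D = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with the standard delta-method variance `[c₁²P + c₃²Q − (c₁P + c₃Q)²]/n`,
`c₁ = 1/(1−2P−Q)`, `c₂ = 1/(1−2Q)`, `c₃ = (c₁+c₂)/2`.  Saturation
(non-positive log argument) raises an explicit error rather than returning
NaN.  Age standard errors propagate through the same linear map,
`SE(T) = SE(D)/(2R)`.

Because LTR substitution rates for felid ERVs are unknown, ages are
reported under a three-rate panel: 2.3×10⁻⁹ and 5×10⁻⁹ (human ERV LTR
studies) and 1.2×10⁻⁸ (felid nuclear DNA).  The uncorrected p-distance
(analytic SE √(p(1−p)/n); seeded site bootstrap available) is used for
within-group summaries and lineage clustering.

## Provirus detection

LTR pairs are direct repeats, so detection is repeat self-matching:

* **Anchoring.** Spaced-seed matching (pattern `1110101101011`, weight 9)
  of the contig against itself, keeping position pairs whose offset is
  compatible with a provirus (repeat length 100–1,500 bp, internal span
  3–12 kb).  A spaced seed rather than a contiguous k-mer because old
  elements (divergence ≥ 0.2) frequently lack any shared exact 15-mer while
  retaining many spaced-seed hits; weight 9 keeps random self-hits to a
  handful per 50 kb.  Anchors sharing an offset are clustered by position;
  a cluster needs ≥ 2 hits (random anchors are almost always isolated).
* **Extension.** Ungapped X-drop extension (drop-off 15) outward from the
  median anchor of the cluster, comparing `seq[x]` against `seq[x+offset]`.
* **Boundary refinement.** X-drop occasionally overruns into unrelated
  flank on a lucky run of matches (flank columns match at ~25%).  Each
  boundary is re-placed by a changepoint rule: minimize the cumulative sum
  of (match − θ) across the boundary, with θ halfway between the flank rate
  (0.25) and the repeat's core identity.  Finally, boundaries snap to
  terminal `TG…CA` motifs when both copies agree within 12 bp; a snap of
  more than 10 bp is flagged as a boundary-convention disagreement.
* **Acceptance.** A candidate is reported iff repeat length, internal span
  and global-alignment identity pass the configured windows.  The identity
  floor is 0.65 (≈ K2P 0.45): high enough that insert-free backbones yield
  nothing (the extension barrier dominates — measured false-positive rate
  on 50 kb random backbones is 0), low enough that elements at divergence
  0.30 with short (200 bp) LTRs are retained despite sampling noise in the
  observed identity.  Overlapping candidates resolve to the highest
  identity, then the longest.

Direct repeats are strand-symmetric, so a single forward scan covers both
orientations; provirus orientation is inferred from ORF strand in the
calling step.  Pairwise global alignment uses Biopython's PairwiseAligner
(affine Needleman–Wunsch; default match 1, mismatch −1, gap open −5,
extend −1, a length-L gap costing `open + L·extend`), with the aligner's
canonical first path as the deterministic tie-break.

A call assembles the LTR pair, the internal region, six-frame ORFs
(≥ 80 aa), a positional gag/pol/env interpretation (first/middle/last ORF),
LTR hallmark flags, the K2P divergence re-computed from the re-extracted
LTR substrings, ages under the rate panel, and target-site-duplication
evidence (4–6 bp identical flanks, searched with ±3 bp boundary slack
because a TSD overlapping the terminal motif can pull the called boundary
a few bases off the integration site; TSDs are evidence only, never a call
requirement).

## Intactness scoring

Coding decay of a *pol* region is scored against an intact reference
protein by a dynamic program over (query nucleotides × reference residues).
Moves consume 3 nt per residue (clean codon), 2 or 4 nt under a frameshift
penalty, a codon with no residue (insertion), or a residue with no codon
(deletion); query ends are free so flanking non-coding sequence is
ignored, while the reference must be covered end to end.  Scoring: residue
match +2, mismatch −1, aligned stop codon −3, frameshift −6, codon
insertion/deletion −5.  Each maximal run of frame disruption is one
frameshift event (adjacent disruptions with no clean codon between them
merge, and merged runs are flagged in the event detail); each aligned stop
codon is one nonsense event, counted independently of frameshifts and also
downstream of them.  Per-lineage summaries report the lower median and
[min–max] of total defect counts.

A caveat: two compensating frameshifts a few codons apart whose
out-of-frame reading happens to part-match the reference admit a cheaper
no-frameshift alignment; the minimal-event parse then undercounts.  At the
benchmark conditions this affects ~0.5% of simulated genes (196/200 exact,
199/200 within ±1).

## Lineage delimitation

Lineages are delimited from a pairwise distance matrix by single-linkage
clustering at a divergence threshold (default 0.15): two sequences share a
lineage iff they are connected by a chain of pairwise distances at or below
the threshold.  Single linkage is the unique linkage for which "no
inter-lineage pair below threshold" is guaranteed.  Neighbor joining
(Saitou–Nei Q-criterion, standard branch-length formulas, lexicographic
tie-break, negative branch estimates clamped to zero and flagged) provides
the accompanying topology; it recovers any additive matrix exactly and is
cross-checked against scikit-bio's implementation in the test suite.

Upstream curation follows common practice: homology-hit tables are
filtered at identity ≥ 30%, coverage ≥ 70%, e-value ≤ 0.001, then
same-species hits at ≥ 95% identity collapse to the lowest-e-value
representative (the table carries no subject–subject identities, so hit
identity is the redundancy proxy).  Alignment columns are trimmed
Gblocks-style: columns with gaps in ≥ 50% of sequences are excluded;
a column is conserved when its majority residue reaches the flank
threshold (default 55% of sequences, absolute counts accepted); runs of
non-conserved columns longer than the limit (default 8) — and any run
containing a gap-excluded column — are removed; surviving stretches are
trimmed to conserved flanks and blocks shorter than 5 columns are dropped.
Re-trimming a trimmed alignment is a no-op.

## The synthetic generator

`simulate_provirus` emulates exactly the data the workflow consumes: a
random host backbone (default 20 kb at GC 0.42, felid-like) containing one
provirus built as TSD + LTR + internal cassette + LTR + TSD.

* The ancestral LTR (default 400 bp, matching the 166–632 bp range of
  reported gammaretroviral LTRs) is constructed with all hallmarks —
  terminal `TG…CA`, a 20 bp ≥ 70%-AT window in the 5′ half, `AATAAA` in the
  3′ half — then duplicated; each copy independently evolves under a
  continuous-time K2P process at branch length R·T (closed-form K80
  transition probabilities; default κ = 2, a conventional mammalian
  transition bias).  Motifs are protected only at age 0 and may decay with
  age, as in real elements.
* The internal cassette (default 7 kb, provirus ≈ 7.8 kb) carries gag, pol
  and env ORFs in order (≈ 23/49/28% of the coding budget, gammaretroviral
  gene proportions), each `ATG` + sense codons + stop, separated by short
  spacers.  The requested numbers of nonsense stops and ±1 nt frameshifts
  are injected into pol at recorded positions (≥ 3 codons apart so the
  injection history is an unambiguous truth table).
* The target-site duplication (default 5 bp) duplicates host sequence at
  the seeded insertion point.

All randomness flows from a single integer seed through a
`numpy.random.SeedSequence` tree; identical parameters and seed give
byte-identical FASTA/TSV output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indel evolution in LTRs (real LTR pairs of
unequal length exist), neutral substitutions outside the LTRs (so defect
counts are exact rather than statistical truth), solo-LTR formation,
nested insertions, insertion polymorphism, host repeat families, and
codon-usage realism.  Detection sensitivity on real genomes with
indel-bearing LTR pairs will be lower than the synthetic benchmarks
because anchor clusters assume a single repeat offset.

## Benchmark problem sizes and numerical choices

The bundled benchmarks use 100 simulated proviruses (600 bp LTRs, true age
10 MY at 1.2×10⁻⁸ — expected divergence 0.24) for parameter recovery,
20–40 insert-free 50 kb backbones for the false-positive rate, 200
simulated pol genes (0–10 defects) for intactness recovery, and 100 random
additive trees of 4–8 taxa for NJ exactness; these sizes put Monte-Carlo
error well below the decision thresholds while keeping the whole suite in
minutes on one core.  Ages are reported to 3 significant figures and
distances to 3 decimals; the pipeline report derives its printed ages from
its printed (rounded) divergence, so re-dating the report's own D column
reproduces them exactly.  Dating arithmetic itself is exact and unrounded
internally.

## Known limitations

* Detection assumes indel-free repeat pairs when grouping anchors by
  offset; a band parameter merges near-identical offsets but true
  indel-tolerant chaining is not implemented.
* Boundary placement is ambiguous when a TSD or a chance flank match
  extends the repeat beyond the integration site; accuracy is a few bp
  (occasionally ~20 bp on a lucky flank run), which is negligible for
  dating 300+ bp LTRs but visible in coordinate comparisons.
* gag/pol/env assignment is positional unless reference proteins are
  supplied; it does not attempt homology classification.
* The K2P estimator's delta-method SE understates uncertainty near
  saturation; dating beyond D ≈ 0.5 should not be trusted regardless.
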
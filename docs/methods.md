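# Methods

## Signal model and coordinate conventions

All coordinates are 1-based, inclusive, and in transcript space (the
convention of CT and SHAPE files). For a CDS-annotated transcript the 5′ UTR
is `[1, cds_start−1]`, the CDS `[cds_start, cds_end]` (stop codon included),
and the 3′ UTR `[cds_end+1, length]`.

An RT stop at position *i* is evidence of a chemical adduct at *i*: reverse
transcription terminates one nucleotide 3′ of the modification, so a read
whose leftmost aligned base is *p* contributes one stop at *p−1*. Reads
starting at position 1 carry no assignable stop, and a stop at the
3′-terminal base would require a read starting past the transcript end;
both terminal positions are therefore masked as unassignable in profiles.
A read's informative coverage is defined as its aligned span plus the
inferred modified base at *p−1*, which guarantees `stops[i] ≤ depth[i]`
everywhere — each stop is backed by the depth of its own read.

## Reactivity

Raw reactivity is the floored log2 ratio of per-transcript-normalized stop
counts, treated (DMS or CMCT) over the non-treated control:

    r_i = max(0, log2( ((t_i + c0)/T) / ((n_i + c0)/N) ))

with pseudocount `c0 = 1` at every position (avoids log of zero at
uncovered positions; configurable) and `T`, `N` the per-transcript totals of
the pseudocounted counts. Per-transcript normalization makes the score
independent of transcript abundance; flooring reflects that positions where
the control exceeds the treatment carry no structural signal, and fixes the
final scale's lower end at 0.

Normalization is 90% Winsorising per transcript per channel: values above
the 90th percentile are capped at it, then all values are divided by it.
The percentile is the sorted-order linear-interpolation estimator (numpy's
default, the common "type 7" rule); the estimator choice is pinned by
tests. A degenerate all-zero profile is left at zero (with a warning)
rather than divided by zero. Channels are normalized before combination so
their dynamic ranges are comparable; the combined track takes the larger
available channel value by default (`max`), exploiting the documented
non-canonical reactivity of both reagents, with a `canonical` mode (A/C
from DMS, G/U from CMCT) as the conservative alternative.

Filters: transcripts are retained when each treated channel averages at
least one RT stop per base (both channels must pass — the conservative
reading); positions require depth strictly greater than 50 in all three
samples, the control included, since the background estimate is equally
depth-limited. Replicates are combined by averaging stop counts (rounded to
integers) before reactivity computation; averaging counts rather than
reactivities preserves count statistics, and differs from pooling by sum
only through the pseudocount scale.

## Folding

The folder maximizes a sum of pair weights (GC 3, AU 2, GU 1; minimum
hairpin loop 3; N never pairs) over all pseudoknot-free structures by
Nussinov-style dynamic programming. This deliberately replaces the full
Turner nearest-neighbor thermodynamic model with a scorer whose optimum can
be verified exactly against exhaustive enumeration; the constraint logic is
preserved, and a SHAPE exporter (two-column text, −999 for missing) serves
users who want an external thermodynamic folder.

Probing data enter as a Deigan-form pseudo-energy `m·ln(ρ+1) + b` added to
the cost of pairing a position with reactivity ρ (missing ρ contributes
nothing), or in hard mode by forbidding pairs at positions with ρ > 0.7.
Defaults `m = 2.0`, `b = −0.6` are expressed in pair-score units, scaled so
that a fully reactive position (ρ = 1) costs about one GU pair and an
unreactive one receives a small stacking-like bonus. Pairs with
non-positive net weight are never taken, which avoids spurious isolated
pairs at zero margin; fully isolated pairs are otherwise permitted (a
`forbid_lonely_pairs` flag prunes them from the output). Traceback is
deterministic: at ties the pair branch wins, then leaving the left end
unpaired, then the right, then the smallest bifurcation point.

## Scoring

PPV = predicted pairs found in the reference / predicted pairs;
sensitivity = reference pairs recovered / reference pairs. Exact pair
matching is the default; `slip=1` lets `(i,j)` match a reference pair
displaced by one nucleotide on either coordinate, each reference pair
consumable once (computed as a maximum bipartite matching, verified against
brute-force enumeration on small inputs). Ratios with zero denominators are
reported as missing, never 0 or 1.

Helix context: helices are maximal runs of stacked pairs; a paired position
is helix-terminal if its pair opens or closes its helix or an immediate
sequence neighbor is unpaired ("adjacent to a bulge/loop" read at
nucleotide granularity — the simplest testable interpretation). The
reactive-site accounting partitions positions with combined reactivity
above 0.7: strict true positives are unpaired, relaxed true positives also
admit helix-terminal positions, which are structurally flexible and
chemically accessible despite being paired.

## Transcriptome aggregation

Region statistics pool position-level values across transcripts rather than
per-transcript means: at transcriptome scale each position is one
observation, which is what gives these contrasts their power. Windows:
Kozak = `cds_start−6 .. cds_start+1` (8 nt, spanning the −6/+1 context
around the AUG including its first two bases); stop-codon window =
`cds_end−5 .. cds_end` (the stop codon plus the 3 nt immediately upstream);
5′ UTR = the 50 nt before the Kozak window; 3′ UTR = the 50 nt after
`cds_end`; the CDS reference region is its first and last 100 nt. Windows
truncate at transcript ends. Codon periodicity assigns frame
`((p − cds_start) mod 3) + 1` inside the CDS and phases UTR control
segments (48 nt) from the UTR/CDS boundary on each side.

The biotype contrast uses base-normalized per-transcript averages: the mean
reactivity is computed within each base identity (A, C, G, U) over unmasked
positions, then the four base means are averaged. This removes
nucleotide-composition differences between RNA classes; transcripts with
fewer than four represented bases use the available means and are flagged.

All tests are two-sided Wilcoxon rank-sum: exact enumeration for tie-free
samples of ≤ 20, otherwise the normal approximation with tie correction.

Summit profiles average combined reactivity at offsets −150..+149 around
binding-site summits (300 positions, summit at 0), truncating at transcript
ends; a duplicated summit counts twice (documented behaviour). Motif
strandedness reports the unpaired fraction of a motif and whether it lies
entirely within a hairpin loop (the unpaired span closed by a pair that
encloses no other pair).

## Simulator

Transcripts are chains of hairpin units (stems 4–10 bp with complementary
strands, G-U wobbles at rate 0.1; loops 4–8 nt) joined by 3–8 nt unpaired
linkers, giving ~30–70% paired positions. mRNA-like transcripts draw a 5′
UTR of 60–90 nt, 70–110 codons and a 3′ UTR of 60–90 nt, then snap AUG and
UAA onto unpaired triples nearest the intended boundaries, so codons never
contradict stem complementarity.

Counts are Poisson per position. Treated channels see rate
`p_natural + p_mod · canonical_scale`, with `p_mod = 0.15` at unpaired and
`0.01` at paired positions, a 0.3 multiplier at non-canonical bases (DMS is
canonical at A/C, CMCT at G/U), and `p_natural = 0.005` shared with the
non-treated control. Depth is Poisson with mean 1000, constant along the
transcript (no 3′ bias, keeping planted-effect recovery interpretable).
Stops are marginal Poisson events, not read-level drop-off along molecules:
the pipeline consumes marginal per-position counts, for which marginal
rates suffice. `simulate_reads` inverts a count table into alignments whose
`count_stops` output reproduces the table exactly.

Planted effects (UTR depression, frame-1 boost, biotype shift, summit bump)
are specified on the normalized 0–1 reactivity scale and planted
structurally: an effect of size *e* flips the pairing-status stop rate of a
fraction `|e| / (gap · eligible_fraction)` of the eligible positions in the
affected region (paired positions take the unpaired rate for boosts, and
vice versa for depressions), where `gap` is the a-priori
normalized-reactivity gap between unpaired and paired canonical positions
implied by the model rates (≈ 0.68 at defaults). A mixture shift of this
size moves the region's mean normalized reactivity by ≈ *e* through the
full pipeline; smooth rate scalings do not survive it, because the
Winsorising cap absorbs upward shifts at near-saturated positions and the
log transform distorts downward ones.

What the simulator does **not** emulate: ligation and PCR bias, sequencing
error, 3′ coverage decay, signal decay along molecules, paired-end
fragments, and real thermodynamic ensembles (structures are ideal hairpin
chains with a binary paired/unpaired rate). Passing tests therefore show
that the pipeline's transforms, statistics and constraint logic behave as
specified under the method's own signal model — not that real libraries are
free of these artefacts.

## Problem sizes and numerical choices

Test and verification scales, chosen to exercise every code path while
keeping runs reproducible on one CPU: folding-oracle equivalence on 500
random sequences of length ≤ 14 in all three modes (exhaustive enumeration
is exact there); constraint benefit on 200 transcripts of 60–120 nt at
depth 1000; signal discrimination (AUROC ≥ 0.9) on 100 transcripts;
planted-effect recovery at 200 transcripts per effect; type-I error of the
biotype test over 200 null replicates of 20 + 20 transcripts. Determinism:
all randomness flows through numpy Generators seeded per run; ties in the
folder are broken by a fixed priority; DP/traceback comparisons use exact
float equality on identically formed expressions.

## Known limitations

- The folder's pair-weight objective is not a free-energy model; absolute
  structures for long, multi-domain RNAs are better obtained by exporting
  SHAPE files to a thermodynamic folder and scoring the result here.
- Mutation-based (mutational-profiling) reactivity, per-nucleotide
  normalization schemes such as the 2–8% rule, and signal-decay correction
  are out of scope.
- Reference-structure accounting depends on the curated structures
  supplied; published per-structure percentages are not reproducible
  without those exact references.
- Genomic coordinates are out of scope; peaks and annotations must already
  be in transcript space.
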
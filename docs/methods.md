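# Methods

This note records the models and procedures `cladeamp` implements, the
parameters that matter, and the choices made where the workflow left the
design open.

## Degenerate sequence algebra

Sequences live on the 15-letter IUPAC nucleotide alphabet.  Degeneracy is
the product over positions of per-symbol base-set sizes — the number of
concrete primers a degenerate primer encodes.  Two symbols are
*compatible* when their base sets intersect, so a template `N` (common in
assemblies) never counts as a mismatch against any primer symbol; this is
deliberately more permissive than treating ambiguity as error.  Input is
case-insensitive, `U` maps to `T`, and gap characters are rejected —
alignment columns are handled before sequences reach this layer.

## Alignment and identity maps

One dynamic-programming engine aligns *profiles* (per-column base
frequency vectors, ambiguity spread uniformly over its base set, gap mass
simply absent) under affine gap costs: a gap of length L costs
`gap_open + (L-1)·gap_extend`, defaults +1/−2/−5/−2
(match/mismatch/open/extend).  Single sequences are one-hot profiles, so
pairwise alignment and progressive profile merging share the code path.
The forward pass is vectorised row-wise; within-row horizontal-gap scores
are a running maximum of `H[k] − extend·k`, which is exact because
opening a gap immediately after another horizontal gap is never optimal
when opening costs at least as much as extending.  Because that
reformulation changes floating-point grouping, the traceback compares
candidates with a 1e-6 tolerance rather than exact equality; ties prefer
diagonal, then up, then left, making output deterministic.

Percent identity of a pair is matches over aligned columns, excluding
terminal-gap-only overhangs (semi-global convention) by default; whether
the external tool the workflow historically used computed global or local
identity is not documented, so `build_identity_map` exposes both
conventions (`semiglobal`, the default, aligns with free end gaps;
`global` penalises and counts end columns).  A pair whose semi-global
alignment has no overlapping columns gets identity 0.  Progressive
alignment takes its merge order from neighbor joining on fractional
shared-6-mer distances and re-sorts rows to input order; every row
degaps back to its input byte-for-byte.  Pairwise scores are
cross-checked in the test suite against biopython's independent
`PairwiseAligner`.  Users with a preferred external aligner can supply a
ready-made MSA or identity map everywhere one is consumed.

## Primer design

The in-group of a family is every taxon whose 16S-like identity to the
reference organism falls within `[idlow, idhigh]`; published settings for
the three gut families are idlow 91/95/92 with idhigh 100.  The scan
slides a `3·codons`-column window (default 7 codons = 21 nt, the length
at which a single primer can still be synthesised cheaply while spanning
whole codons) over the in-group MSA; `greedy` (default) slides by one
column, otherwise starts are restricted to reference codon boundaries.
Column consensus: the top base is used verbatim when its gap-excluded
frequency reaches `consensus`% (default 90); otherwise the minimal IUPAC
code covering all bases with frequency ≥ `min_base_freq` (default 0 —
every observed base enters; raising it is the user's tolerance knob for
sequencing error in the database).  Windows containing any column gappier
than `max_gap_fraction` (default 0) or any reference gap are discarded:
primers cannot span indels, and reference coordinates would be undefined.
Reverse candidates are the reverse complement of the consensus (same
degeneracy, same window).

Pairs are all forward×reverse combinations with both degeneracies at or
under the ceiling (default 96, the published short-list rule) and
predicted size — `reverse.ref_end − forward.ref_start`, both footprints
included — inside the requested range, sorted by descending size then
ascending combined degeneracy.  Off-target ranking amplifies every pair
against an annotated database and sorts by ascending off-target rate
(ties: larger product); pairs that amplify nothing sort last, since a
primer with no on-target product is useless however specific.  Window
coordinates are reported in both alignment and reference frames (the
historical tool's convention is not documented); user-facing tables are
1-based inclusive, everything internal 0-based half-open.  Adapter
overhangs are concatenated at report time only and never enter matching
or degeneracy.  Predicted sizes exclude adapters, which is one reason
published band sizes need not equal predicted insert sizes.

## In-silico PCR

Primer sites require at most `max_mismatch` incompatible positions
(default 2) and zero incompatibilities over the `three_prime_exact`
terminal positions (default 3) — polymerase extension starts at the 3'
end, so mismatches there are the ones that abolish amplification.  The
settings of the external in-silico PCR program used historically are not
published; these defaults are declared, not inferred, and are exposed on
the CLI.  Every forward site paired with every downstream opposite-strand
reverse site whose product length falls in `[size_min, size_max]` yields
a hit; both template strands are scanned, all products are reported (no
shortest-product heuristic — screening wants the complete off-target
picture), and hit sequences are exact template substrings.  Templates
missing from the taxonomy are labelled `Unknown` and counted off-target.

Pseudo-short reads: each long amplicon with exactly one internal
short-primer product is trimmed to that product (primers included);
amplicons with zero or multiple products are dropped and logged
(`no_site` / `multiple_products`).

Off-target accounting supports read-weighted mode (weights = read counts,
the published table convention: rate = 100 × off-target reads / QC reads)
and unweighted ASV mode.

## Classification and concordance

Queries are classified by best infix alignment against an annotated
reference database (edlib backend, IUPAC base sets declared equal);
identity is matched columns over alignment columns, indels included.
Hits below `min_identity` (default 75%) are `Unclassified`.  Ties break
by higher identity, longer alignment, then smaller reference ID.  The
historical pipeline fell back on protein-level search against a remote
database for unclassified reads; a self-contained toolkit cannot call a
remote service, so the default here is nucleotide identity with an
optional 6-frame translated mode — identity values are therefore not
numerically interchangeable with protein-search percent identities, and
the 75% threshold is applied to whichever mode is selected.

Pseudo→parent matching: a unique compatible parent (identity ≥ the
classifier threshold) wins; among several, the parent minimising the
relative count difference `|c_p − c_q| / max(c_p, c_q)`; orphans are
`unassigned`, with a warning when their relative abundance is ≥ the 0.1%
floor.  The floor's denominator is the pooled pseudo-read total across
samples (the per-sample vs pooled choice was undocumented; pooled is used
because parent/pseudo count comparisons are also pooled).

Concordance categories for matched pairs: identical assigned lineages →
`same_species` (agreement at the deepest assigned rank; a consistent but
deeper pseudo lineage also lands here); pseudo lineage a strict ancestor
of the parent's → `less_specific` (an `Unclassified` pseudo read with a
matched parent falls here); any disagreement at a shared rank →
`different_classification`; unmatched reads pass through as
`unassigned`.  Pairs whose parent is `Unclassified` carry nothing to
compare against and are excluded with a log entry.  Counts sum to the
number of categorised pseudo reads.

## Trees

Distances are Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)` over columns where
both rows have concrete bases; saturated pairs (p ≥ 3/4) are capped at
5 substitutions/site and flagged.  Neighbor joining breaks Q-matrix ties
by the lexicographically smallest pair of cluster representative labels,
so the unrooted topology is invariant to input order; negative branch
estimates are clamped to 0.

Likelihood is Felsenstein pruning under JC or GTR with an
invariant-sites mixture: per column,
`L = (1−p_inv)·L_var + p_inv·Σ_b π_b` over bases compatible with every
tip (zero when none).  The rate matrix is normalised to one expected
substitution per unit branch length; branch lengths are therefore in
substitutions per variable site.  Site patterns are compressed and
per-node partials rescaled to avoid underflow.  The exact optimisation
schedule of the GUI package historically used for ML trees is not
published; here base frequencies are fixed empirical, the five free
exchangeabilities (GT ≡ 1) and `p_inv` are fitted by coordinate ascent
with bounded line searches (tolerance 1e-6), and branch lengths by
per-edge line search.  NNI search scores both rearrangements of every
internal edge at current branch lengths, accepts the single best strictly
improving move (> `tol`, default 1e-4), re-optimises branch lengths (and
optionally the model) after each accepted move, and stops when no move
improves; the accepted log-likelihood sequence is non-decreasing by
construction.

Robinson–Foulds compares trees restricted to their shared tips (≥ 4
required): `rf` is the symmetric difference of non-trivial bipartitions;
`max_rf` is the total number of non-trivial splits in the two restricted
trees — `2(n−3)` for binary trees, and a natural generalisation under
multifurcation; `nrf = rf / max_rf`.  Normalisation conventions differ
between toolkits, so externally reported nRF values are only comparable
when the same convention is used.  Tanglegram export reorders the right
tree's children by repeated barycenter passes to reduce crossings and
emits (left tip, right tip, category) rows for plotting.

## Synthetic data

`simulate_gene_family` evolves a gene on a Yule tree (single birth rate —
fewer parameters than full birth–death and sufficient for testing),
calibrated so the **mean pairwise** tip divergence equals
`2 × tree_depth` substitutions/site; defaults (12 in-group taxa,
1,800 nt gene, depth 0.15) give within-family gyrB-like divergence.  The
out-group clade attaches `outgroup_depth_multiplier` (default 4) times
deeper.  A 16S-like marker evolves on the same tree at
`marker_rate_scale` (default 0.1) of the gene rate, so default in-group
marker identities span roughly 95–100% and the out-group falls below 91%
— the identity-map thresholds behave as they would on real 16S data.
Planted windows are copied unchanged from the root haplotype into every
in-group taxon and deterministically disrupted in the out-group.  Because
no indels are simulated, loci are gapless and equal-length, and the
fixture computes its identity map by exact column agreement (verified in
tests to equal the alignment route).  ASV count tables draw lognormal
base abundances, per-sample Gamma(d, 1/d) jitter, and multinomial
sampling at fixed depth — so each sample sums exactly to `depth` and the
d → ∞ limit is plain multinomial sampling.

Not emulated: sequencing error, chimeras, indel evolution, gene-length
variation, copy-number variation.  Green tests on these fixtures
demonstrate algorithmic correctness of every stage, not robustness to
real-data noise — denoising is explicitly upstream of this toolkit, which
consumes ASVs.

## Problem sizes and numerics

The bundled study condition (12+5 taxa, 1.8 kb gene) keeps a full
design→PCR→concordance cycle under a few seconds and an NNI recovery
experiment (6 taxa, 2 kb, one rearrangement from the truth) under ten;
these sizes were chosen so the complete test suite exercises every stage
at desk scale.  Degenerate expansion refuses sets larger than an explicit
limit; alignment scores use float64 with a 1e-6 traceback tolerance;
likelihood partials are max-rescaled per node; all simulators take
explicit integer seeds and are byte-reproducible.

## Known limitations

* Published primer sets for real families cannot be regenerated exactly
  without the deposited reference databases, and window choice is
  sensitive to the upstream alignment; the published primer strings are
  therefore bundled as data and verified by their stated properties
  (length, degeneracy bound) rather than re-derived.
* Classifier identities are nucleotide-level by default and not
  comparable 1:1 with protein-search identities.
* No thermodynamic checks (melting temperature, dimers, secondary
  structure) — window conservation and degeneracy are the only design
  criteria, as in the workflow this implements.
* nRF values depend on the normalisation convention documented above.
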
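# Methods

This note documents the models, numerical choices and limitations behind
`siqchip`, in the order a pipeline run encounters them.

## The scale α and its equivalent forms

The package computes the quantitative scale three ways and treats their
agreement as a standing invariant:

1. the six-parameter form
   `α = (v_in/v_ip)(m_IP/m_in)(R̂_in/R̂)(L_in/L)`;
2. the ratio `c_IP/c_in` of concentration coefficients
   `c_IP = m_IP/(660·L·v_ip·R̂)`, `c_in = m_in/(660·L_in·v_in·R̂_in)`,
   with 660 g/mol/bp the average DNA base-pair weight (`DNA_BP_MW`);
3. the historical bookkeeping chain
   `α = (v_in/v_ip)(ρ_in/ρ)(𝓕ˡ_in/𝓕ˡ)(𝓕_in/𝓕)`.

Units are fixed throughout: masses ng, volumes µL, lengths bp. Forms 1 and 2
are algebraically identical (checked to 1e−12 relative in tests). Form 3
equals form 1 exactly when the chain's intermediate masses are internally
consistent *and* the sequencer's moles-to-reads conversion is shared between
the two libraries; the generator `generate_legacy_bookkeeping` constructs such
chains with randomized intermediates, using one amplification cycle count for
both samples (the chain expression carries no explicit 2^c, so matched
amplification is the regime in which old and new forms coincide exactly — in
practice IP and input libraries are typically amplified together).

Two deliberate conventions: `v_ip` is stored directly (the formulas only ever
use the IP-reaction volume, never the total volume; the metadata parser
accepts `V` and converts), and the library fragment lengths `L`, `L_in` are
used verbatim as reported by the sizing instrument. Whether such instrument
values include adapter length is vendor-dependent; no adapter correction is
applied, and since `L` enters only through the ratio `L_in/L` a common
additive offset largely cancels for similarly prepared libraries.

Depths default to the actual fragment counts of the BED files. Using
requested rather than obtained depth is the single easiest way to corrupt the
scale, so overriding the counts requires an explicit config value.

## Normalized coverage

Coverage is a histogram: fragment *i* of length `L_i` deposits `1/L_i` per
covered base pair, hence exactly 1 in total, and the track sums to the
fragment count R̂. The binned generalization deposits `overlap_bp/L_i` per
bin, which preserves the constraint at every bin size and reduces to the
per-bp rule at bin size 1. Construction is fully vectorized: exact partial
overlaps at the two boundary bins, scatter-add of full interior bins, chunked
to bound memory. No smoothing, no pseudo-counts, no depth-only scaling modes
are offered.

Numerical notes:

- `check_normalization` returns `|Σf − R̂|/R̂`; length-weighted tracks sit at
  ~1e−16 per fragment rounding, far below the 1e−9 assertion used in tests.
  An empty track has residual 0 by definition.
- Disjoint pile-up islands are bit-exactly independent: a bin's value is a sum
  over only the fragments overlapping it.
- Fragments extending past the chromosome end are an error by default;
  `clip=True` truncates the overlap while keeping the original `1/L_i`
  weight (the clipped fragment then contributes < 1, which is reported
  through the normalization residual rather than silently repaired).
- `s(x) = α·f_IP/f_in` is masked (NaN) wherever input coverage is zero —
  fabricated input coverage would corrupt the physical scale. Values above 1
  are kept (with a warning) since clamping would hide bookkeeping errors.
- Default bin size is 30 bp for genome-scale runs (nucleosome-scale
  resolution); tests use bin size 1 where the per-bp definition is the
  oracle. Re-binning by summation is exact, and equals direct construction at
  the coarser size.

Mass projection `m_IP·f(X)/R̂` pro-rates partial bin overlaps so that interval
masses over any partition of the genome sum to m_IP exactly.

## Annotation decomposition

Fragments are assigned to the *first* (lowest start) overlapping annotation
on their chromosome; the segmentation is validated non-overlapping, which
makes the rule deterministic and order-independent. Any-overlap (not
midpoint) is used for the intersection test. An explicit `unannotated` bucket
absorbs misses so the conservation laws hold for gappy segmentations:
counts sum to R̂ (integer-exact), masses to m_IP (≤1e−9 relative), fractions
to 1 (≤1e−12). Per-state efficiency uses the same counts; a state with zero
input count is masked, not imputed.

Metaplots rescale each interval body to a fixed number of bins by averaging
the track bins in each proportional chunk (mean-within-bin preserves area;
interpolation would not), with fixed-bp flanks. Masked bins and
out-of-chromosome flank positions are excluded from every mean. Scaled and
unscaled (IP/input without α) modes differ exactly by the factor α.

## Peaks, responses, shape

The peak caller is intentionally minimal and fully deterministic: maximal
runs of unmasked bins with `s ≥ threshold` (default: 75th percentile of the
unmasked control values), runs separated by ≤ 2 bins merged, merged runs
narrower than 4 bins dropped; all three knobs are exposed. It makes no
statistical claims — it exists to define intervals 𝒳_i on the control track
so that the comparison database is reproducible. Peak "areas" are bare bin
sums of s over the interval (the bin width cancels in the response ratio).

Responses with zero experimental area are flagged and tallied separately,
never binned at infinity. µ(r) uses dr = 0.25 on r ∈ (0, 20] with one
overflow bin; each peak carries exactly one annotation label, so the
per-state histograms sum to the total bin-by-bin as an integer identity.

The shape metric is the *discrete* Fréchet distance (dynamic program,
Euclidean point metric) on the bins where both tracks are unmasked. By
default positions are mapped to [0,1] over the interval and both curves
divided by the control maximum — one shared value scale, so relative shape
rather than amplitude dominates — with a raw-scale mode available. The
continuous Fréchet distance and other normalizations are reasonable
alternatives; the choice is recorded per database via the CLI config stamp.

## The synthetic-experiment generator

The generator embodies the binding model that motivates the scale: each
chromatin fragment in the IP reaction is captured independently with
probability equal to its state's efficiency `e(a)` (a Bernoulli reading of
the Langmuir isotherm; no antibody depletion or competition between species
is simulated).

Construction, for designed per-state efficiencies and genome-wide designed
capture fraction `ē = Σ_a w_a e_a` (w_a = genome fraction of state a):

1. segment the genome into alternating state blocks (uniform lengths,
   5–20 kb by default — broad enough that boundary-spanning fragments are
   rare, narrow enough that every state appears on every chromosome);
2. draw a fragment pool of size `n_input/ē` uniformly over the genome with
   truncated-normal lengths (mean 180 bp, sd 20, range 100–400:
   MNase-digested mono-nucleosome inserts);
3. capture each pool fragment with probability `e(state)` → the IP library;
   the first `n_input` pool fragments → the input library;
4. emit metadata from the physical bookkeeping: `m_in = conc·v_in`,
   `m_ip = (realized mass-capture fraction)·conc·v_ip`, depths and mean
   lengths from the realized files.

Sizing the reaction pool at `n_input/ē` makes the two library depths
comparable — the common laboratory situation of sequencing both libraries to
similar depth — and it is what ties the emitted metadata together: with these
depths, α computed from the metadata telescopes to
`(R̂_in/n_pool)·(L̄_in/L̄_pool) ≈ ē`, and the per-state efficiency estimator
`α·f_IP(a)/f_in(a)` is unbiased for `e(a)`. (With full-pool sequencing on
both sides α would instead telescope to a pure volume ratio and the depth
ratio would carry the efficiency — an equally consistent but less
interpretable regime.) When every state has e = 1 the IP library is
byte-identical to the input library.

All randomness flows through one integer-seeded PCG64 generator: same seed,
same bytes, any platform.

What the generator does **not** emulate — and therefore what passing tests do
not establish about real data: GC / mappability / accessibility bias in
fragment placement, duplicate reads, chimeric or mis-mapped fragments,
antibody off-target binding and depletion, within-state heterogeneity of
efficiency, and chromosome-scale copy-number structure. Tests built on it
verify the *bookkeeping and estimators*, not robustness to these artifacts.

## Problem sizes

Desk-scale defaults keep every check fast while leaving sampling error well
below the assertion margins: a 2 Mb two-chromosome genome, 2·10⁵ input
fragments (≈10⁶-fragment reaction pool), 50 bp analysis bins. At these sizes
the per-state binomial standard error is ~1–3% of e, the efficiency-recovery
check spans 20 seeds (60 state×seed cells), and α matches the designed
capture fraction to ~0.1%. Oracle-equivalence checks run on ≤10 kb genomes
where per-bp brute force is affordable.

## Known limitations

- The peak caller is a reproducibility device, not a detection method; for
  significance-calling use a dedicated caller and import its intervals.
- Upstream processing (alignment, pairing, duplicate handling, BAM→BED) is
  assumed done by standard tools; the package starts at fragment BEDs.
- Efficiencies near or above 1 (bookkeeping error, sampling noise) poison the
  odds transform; they are masked, and the affected states drop out of
  relative-binding-constant tables rather than being clipped.
- Relative binding constants are *apparent*: an annotation aggregates many
  epitope species, and the ratio reflects the mixture.
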
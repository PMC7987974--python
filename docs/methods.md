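# Methods

## The generative model

One ribosome traverses a coding sequence codon by codon. A two-state
process describes drug occupancy: before decoding each codon, a free drug
molecule binds an unoccupied ribosome with probability β (rebinding after
drop-off is allowed, including at the very next codon); after decoding, a
bound drug is retained through the translocation with probability q. While
bound, the codon being decoded is misread into a designated substitution
with probability m·w (w a site/outcome-specific weight, m a drug-level
scale; m·w ≤ 1 per codon is enforced); unbound ribosomes misread with a
small background probability ε₀. The state dynamics are independent of the
decoding outcomes, so the probability that a traversal emits exactly a
given substitution pattern is computed exactly by a forward recursion over
the bound/unbound state — a plain two-state hidden Markov chain
(`pattern_probability`). The test-suite oracle enumerates all 2^L state
paths on proteins of ≤ 8 codons and agrees to 1e-12.

Two errors separated by d correct residues are linked by d + 1
translocation events, so the conditional probability of the second error
given the first is

    E_f^next(d) = m·w · q^(d+1)   (exactly, in the limit β → 0)

At finite β a rebinding correction of order β(1 − q^(d+1)) adds to this;
at the β values used here (≤ 1e-3) it is below 1e-3 relative and invisible
at measurement precision.

Assumptions worth stating: a single occupancy state (no two drugs on one
ribosome); retention q applies to every translocation, including the one
after a misreading event; binding is equally likely at every codon, which
makes first-error frequencies position-independent; premature termination
and drop-off products are not modelled. Background errors (ε₀, and the
elevated `ram_rate` of the error-prone *ram* regime) are only applied at
codons that carry designated substitution weights — this closes the
enumerable outcome space (pattern probabilities sum to one, tested to
1e-12) at the cost of not emitting background errors at unstudied codons,
which no estimator here consumes. The *ram* regime (β = 0, raised
`ram_rate`) therefore produces exactly independent errors: cluster
amplification ≈ 1, which the suite checks by simulation.

## Presets and back-solving

A drug preset pins (q, E_f^next at an anchor distance). The microscopic
bound-state misreading probability is back-solved as
m·w = E_f^next(d_anchor)/q^(d_anchor+1), because experiments report
observables, not microscopic rates. Shipped presets: Str q = 0.97 with
anchors 0.05 (d = 1) and 0.08 (d = 2); Par q = 0.9, 0.09 at d = 1; Apr
q = 0.5, 0.25 at d = 1; Sis 0.40 and KanA 0.36 at d = 0; a generic
group-II preset (q = 0.5, 0.40 at d = 0). q values for Str and Par follow
the near-flat / weakly decaying profiles those drugs show; group-II drugs
use the centre of the 0.3–0.7 bracket obtained by exponential fitting;
preset files mark which values are anchored to published observables and
which are package choices. The first-error site uses the same w as the
following-error site, reflecting the observation that the misreading
preference of a site is conserved between single and in-cluster errors.

## The E_f^1st convention

E_f^next is estimated as E_f^cluster/E_f^1st. Here E_f^1st is the
*marginal* frequency of the first misreading event: the summed intensity
of every species carrying that substitution (the exclusive single-error
peptide plus the cluster peptides) over the parent. With this convention
the ratio is exactly the conditional probability of the next error given
the first, i.e. m·w·q^(d+1); with the exclusive single-species convention
it would be inflated by 1/(1 − E_f^next), an ~9% distortion at
E_f^next = 0.08 and a 67% one at 0.40. At streptomycin-scale values the
two conventions differ by less than replicate scatter.

## Synthetic experiments (study conditions)

The generator's defaults emulate the targeted-MS experiments the
statistics were designed for:

- titrations over 1, 2, 4, 8, 16 µM with β = 5e-5 per µM per codon
  (first-error frequencies span ~1e-4 to ~3e-3, the range seen under
  sub-lethal to maximum-misreading doses);
- N = 1e8 effective ribosome traversals per condition, sampled in
  Poisson-rate mode (counts drawn from Poisson at N × pattern
  probability); an explicit per-ribosome Monte Carlo cross-validates the
  Poisson mode at small N;
- three technical replicates per condition sharing one set of molecule
  counts, each with independent log-normal intensity noise of CV 0.05 —
  the technical scatter typical of targeted PRM with spiked reference
  peptides; intensities are count × 1e3 a.u. with a detection floor of
  1e3 a.u. (below-floor values are missing, and missing missense values
  are imputed at the floor as upper limits, never as zeros);
- ε₀ = 1e-7 background errors per designated codon;
- ionization factors are 1 for all species (the label-free assumption);
  an optional per-species multiplier exists to stress-test the
  estimators.

Replicates aggregate by the median for E_f; distance-profile points
aggregate clusters at one distance as unweighted mean ± SD.

What the generator does *not* emulate: peptide identification and FDR,
chromatographic or ionization drift, isobaric interference (I/L are kept
distinct internally; MS cannot distinguish them), missed-cleavage species,
and position-dependent detectability. Passing recovery tests therefore
shows the estimators are correct and well-calibrated under the model's
noise structure, not that real data are free of those effects.

The benchmark geometry lives on two synthetic proteins (sequences are
generated programmatically, not biological): a 300-residue model protein
with cluster sites at D208/F211 (d = 2), E241/E242 (d = 0) and E242/E244
(d = 1) inside separate tryptic peptides, laid out to mirror the cluster
geometries studied on elongation factor Tu; and a 420-residue profile
protein hosting three E–E pairs per distance d = 0…6, one pair per
20-residue tryptic peptide. Both carry deterministic coding sequences
(single preferred codon per amino acid, E. coli-style high-usage table)
so that every benchmark substitution is a third-position near-cognate
misreading; results that depend on codon identity always carry the codon
assumed.

## Estimators and numerical choices

- E_f: missense/parent intensity ratio per replicate, median across
  replicates; when the parent peptide is undetected the median intensity
  of the correct peptides in that sample stands in (flagged).
- Induction filter: a species is kept only if its intensity exceeds
  `fold` (default 2) times its untreated intensity in every replicate.
- Slope estimator: through-origin least squares of E_f^cluster on
  E_f^1st. The intercept is fixed at zero because translation is
  vectorial — at E_f^1st = 0 no cluster can exist.
- LFQ estimator: direct intensity ratio of cluster to single-first-error
  peptide; refused (with the reason) when the cleavage pattern is altered
  or a following substitution gains/loses His (charge state) or K/R
  (cleavage).
- Distance profiles normalize per-cluster E_f^next to the reference drug
  (default Str) at matched d, then aggregate per d. The exponential fit
  uses exponent d, not d + 1: the ratio to the reference at matched d
  cancels the shared offset, so the fitted q is effectively
  q_drug/q_reference (0.515 for q = 0.5 against a 0.97 reference — still
  inside the 0.3–0.7 bracket the fit is checked against). An alternative
  anchoring that rescales each drug to 1 at its smallest distance is
  available behind `anchor="d0"`.
- Retention fit: `scipy.optimize.curve_fit` of N(d) = c·q^d with q
  constrained to [0, 1]; confidence intervals by parametric bootstrap
  (200 seeded resamples of the points from normal laws at their
  uncertainties; single-cluster points get a 10% nominal uncertainty). A
  perfectly flat profile short-circuits to q = 1 (degenerate flag).
- Group classification: group II iff adjacent E_f^next ≥ 0.2 (midway
  between the group-I maximum ~0.18 and the group-II minimum 0.25),
  otherwise group I if the median single E_f clears a floor; both cutoffs
  configurable; missing or all-zero inputs stay unclassified.
- Imputation of proteome tables: per sample (column), missing values draw
  from N(mean − 1.8·SD, (0.3·SD)²); per-sample rather than global
  application is the standard convention and is an assumption here.
- Non-cognate substitutions (≥ 2 nucleotide changes) are representable
  but flagged and excluded from statistics by default; stop-codon
  outcomes are enumerated but never emitted as substitutions (full-length
  proteins only). Mismatch-position ambiguity resolves 3rd > 1st > 2nd.

## Problem sizes

The recovery experiments run titrations of 5 conditions × 4 species ×
3 replicates on a 300-residue protein (seconds each) and one 21-cluster ×
2-drug profile experiment with a 200-resample bootstrap (~2 s). The whole
test suite runs in ~25 s on one CPU; these sizes were chosen because the
estimator standard errors they give (2–4%) are already far below the
effects being measured, so larger simulations would not change any
conclusion.

## Known limitations

- The retention fit on reference-normalized profiles estimates
  q_drug/q_ref, not q_drug; with a near-flat reference the distinction is
  a few percent.
- Whether a drug remains bound with probability 1 through the first
  misreading event is not empirically constrained; the model applies q to
  every translocation uniformly.
- The induction filter assumes paired replicate ordering between treated
  and untreated runs.
- LFQ-based E_f^next assumes identical ionization of cluster and
  single-error species; the physico-chemical exclusion list (His, K/R) is
  a coarse screen, not a predictor.
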
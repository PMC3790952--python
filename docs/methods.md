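# Methods

## Mining model

The pipeline encodes a neighborhood heuristic: bacterial diterpene
cyclases diverge too fast for direct similarity search, but diterpene
production requires a GGDP synthase, GGDP synthases are conserved
(>30 % identity across characterized producers), and cyclase genes lie
near them in known actinomycete clusters. Mining therefore proceeds
anchor-first.

**ORF calling.** All six frames, bacterial translation table 11, start
codons {ATG, GTG, TTG} (alternative starts translate as M), stops
{TAA, TAG, TGA}. An ORF is maximal start→stop; within one stop-bounded
frame segment alternative starts collapse to the 5′-most (longest) ORF.
ORFs truncated by a contig edge are discarded — their translations are
unreliable on draft assemblies. Default minimum length is 100 aa: the
known targets are 343–371 aa, so the screen cannot lose them, while the
decoy load on high-GC (stop-poor) genomes stays manageable. Coordinates
are 0-based half-open on the forward strand everywhere in memory;
only serialized GFF3 is 1-based inclusive.

**Anchor recognition.** Best local affine-gap alignment (Biopython
`PairwiseAligner`) of each ORF against each query GGDP synthase, with a
BLOSUM62 matrix (X scored 0 against everything) and BLAST-convention gap
cost 11 + k for a gap of length k. Percent identity is computed over
alignment columns, the "X % identity over N amino acids" convention.
An ORF anchors when identity ≥ 30 % over ≥ 0.5 × query length —
thresholds chosen because known anchor homologues sit just above 30 %.
No E-values: identity + aligned-fraction thresholds are deterministic
and database-size independent.

**Motif classification.** Class I terpene synthases are marked by the
Mg²⁺-binding aspartate-rich motif `DDxx[DE]` and/or the NSE/DTE triad;
class II cyclases by the catalytic-acid motif `DxDD`. The NSE/DTE triad
is encoded as the canonical consensus `[ND]Dxx[ST]xxx[ED]`; published
alignments vary in how much degeneracy they accept, so the definitions
live in a plain-text config (`name class pattern`) and can be tightened
or loosened without code changes. All overlapping hits are reported;
the class call uses presence/absence only (call = classI, classII, both
or none).

**Candidate nomination.** For each anchor, every motif-positive ORF on
the same contig whose interval lies within `window_bp` (default
10 000 bp, measured as the gap between feature intervals) is reported,
either side, either strand. 10 kb spans typical actinomycete cluster
gene spacing; the value is configurable. An ORF that itself qualifies
as an anchor is never reported as a candidate (avoids self-pairing).
Ranking uses `anchor_identity − 0.1·(distance_bp/1000)` — a simple
monotone score, documented and replaceable; ties break by candidate
length then coordinates, so reports are byte-deterministic.

## Kinetics model

The coupled pyrophosphate assay converts each PPi released by the
cyclase into oxidation of `nadh_per_ppi` NADH (default 2, the standard
commercial cascade stoichiometry; configurable). In the initial-rate
regime the A340 trace is linear:

    A(t) = A0 − ε·ℓ·n·v·t + N(0, noise_sd),   v = kcat·[E]·[S]/(Km+[S])

with ε = 6220 M⁻¹cm⁻¹, path length ℓ = 1 cm (a standard cuvette; not
otherwise specified), A0 = 1 AU of NADH loaded, time in seconds, v in
μM·min⁻¹. Substrate depletion is ignored over the fit window
(conversion is a few percent at the assay concentrations). Initial
velocity is the least-squares slope over the first 60 s (configurable);
traces are 180 s at 2 s sampling. Michaelis–Menten fitting is
`scipy.optimize.curve_fit` with starts Vmax₀ = max v, Km₀ = median S,
standard errors from the Jacobian, and one perturbed restart before
declaring non-convergence.

**Enzyme molar concentration.** kcat = Vmax/[E] with [E] from the assay
loadings (532 μg DtcycA / 466 μg DtcycB in 800 μL) on a monomer basis
using the SDS-PAGE monomer estimates of 42 and 38 kDa (≈15.8 and
15.3 μM). The enzymes behave as homodimers in solution, but turnover is
conventionally quoted per catalytic monomer; the basis is documented so
users can halve it. Recovery experiments are insensitive to this
choice: the same [E] is used to simulate and to refit, so the recovered
kcat equals the generating kcat regardless of the assumed molar mass.

**Recovery experiment.** For each enzyme, 100 datasets are simulated at
the reported truth (Km 93.7 μM / kcat 2.8 min⁻¹ for DtcycA; 42.1 μM /
1.3 min⁻¹ for DtcycB) over the published design — S ∈ {10, 20, 40, 80,
100, 160, 200} μM, 3 replicates, 0.002 AU per-point noise — and refit
independently; the medians of the fitted Km and kcat are the summary
statistics. At this noise level the medians land well within 1 % of
truth; 100 datasets run in under a second, so no down-scaling was
needed.

## Small-molecule arithmetic

Masses are sums of most-abundant-isotope atomic masses for the
*neutral* formula, with no electron-mass correction — the convention
natural-product HRMS sections print (the "calculated for C20H35O"
value is the neutral protonated-composition sum). Formula search
enumerates heavy-element counts within bounds (defaults C ≤ 50,
H ≤ 100, O ≤ 10 — diterpenoid scope) and solves the H count
analytically per combination, ranking by |ppm error|; for [M+H]⁺ the
neutral composition is reported alongside the ion.

DBE = (2C + 2 + N + P − H)/2. Unsaturation partitioning counts carbons
whose ¹³C shift falls in the olefinic window 100–160 ppm (standard for
di- and trisubstituted alkene carbons; configurable), pairs them into
double bonds (an odd count is an error), and assigns the remaining DBE
to rings. The package ships the transcribed 20-carbon assignment table
of the novel cembrane-type alcohol C20H34O; it yields 3 double bonds +
1 ring, i.e. a monocycle bearing three trisubstituted olefins.

The Mosher caller works at the sign-logic level: protons are labeled by
carbinol side (A/B) in the standard MTPA model, and a configuration is
returned only when the two sides show uniform, opposite Δδ = δ(S)−δ(R)
signs (A positive/B negative ⇒ S); zeros are ignored, mixed signs give
`indeterminate`. The caller does not do CIP priority analysis — side
labeling is the user's structural input.

## Synthetic data: what it does and does not emulate

Planted genomes emulate the *statistical* situation of the real screen:
i.i.d. background DNA at GC 0.72 (Streptomyces-like), an anchor gene
mutated to a target identity (uniform substitutions at positions drawn
without replacement, realized identity within ±2 points, motif spans
frozen), a cyclase gene carrying the class motifs at a controlled
distance, and motif-free decoy genes (rejection-sampled). Reverse
translation uses uniform synonymous codons — the miner is
codon-usage-blind, so no codon-usage model is fitted. Seed proteins are
fully synthetic fixed-seed sequences; no database sequences are
shipped or required.

Two generator interventions keep truth sets exact. An in-frame stop is
written immediately upstream of each planted gene so the ORF caller
reports precisely the planted interval. And because stop-poor high-GC
background occasionally produces long spurious ORFs carrying a class
motif by chance — genuine unlabeled positives that would falsify the
truth set — the generator scrubs them: a background offender gets a
stop codon written over its middle codon; one overlapping a planted
gene (e.g. antisense within its CDS) is removed by re-drawing that
gene's synonymous codons. Scrubbing is deterministic given the seed.

Consequently, passing the planted-recovery tests shows the pipeline's
logic is correct under the generator's assumptions; it does not show
robustness to real-genome phenomena the generator omits: genuine gene
structure and codon bias, pseudogenes, frameshifts, assembly gaps
(N runs), repeated regions, or homologues at the threshold boundary.

Assay simulation adds i.i.d. Gaussian per-point noise; real traces have
correlated drift, lamp noise, and coupled-system lag, none of which are
modeled.

## Numerical choices and degenerate inputs

- Alignment tie-breaks: the aligner's first traceback is taken;
  reports sort on (rank_score, length, coordinates) so equal-score runs
  are byte-stable.
- An empty local alignment (nothing scores positively) has identity 0
  and can never anchor.
- `fit_mm` requires ≥ 4 distinct substrate concentrations;
  `initial_velocity` ≥ 3 points in the window.
- Formula search treats an empty result as a valid empty list, not an
  error; negative DBE and odd olefinic-carbon counts raise.
- Ambiguous bases: N-containing codons translate to X; X scores 0 in
  alignments; FASTA input containing anything outside {A,C,G,T,N} is
  rejected outright rather than coerced.

## Known limitations

- Anchor detection is identity-threshold based; there is no E-value or
  profile (HMM) stage, so very remote GGDP-synthase homologues below
  30 % identity are invisible by design.
- The NSE/DTE consensus is one published degeneracy choice; screens of
  unusual class I enzymes may need a custom motif config.
- The miner inspects single contigs; a cyclase split from its anchor by
  an assembly break is missed.
- Kinetic fits assume the initial-rate linear regime; traces taken into
  substrate depletion will bias Km downward.
- Formula search is CHO(N,S,P)-bounded monoisotopic matching; it does
  not use isotope patterns or ring/double-bond plausibility filters.
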
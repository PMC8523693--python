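# Methods

This note documents the statistical models implemented in GlycoDIA, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Glycan model

Glycans are rooted trees of monosaccharides in canonical parenthesis
notation; children are ordered by the lexical order of their serialized
subtrees so every tree has a unique text form. The default vocabulary is
H = Hex (162.05282 Da), N = HexNAc (203.07937), F = dHex/Fuc (146.05791),
A = NeuAc (291.09542), G = NeuGc (307.09033), X = Xyl (132.04226);
monoisotopic residue masses, extensible via configuration.

Theoretical Y ions are the root-containing connected subtrees plus the
empty set (Y0, the naked peptide). Fragment identity is by monosaccharide
*composition*, not topology, because Y ions of equal composition are
isobaric and indistinguishable in a chromatogram. Two consequences:

* isomeric structures whose Y-fragment sets coincide are merged into one
  glycoform hypothesis;
* Jaccard similarity between glycans — used to rank background glycoforms
  by distinguishability — is computed on the *discriminating* fragment
  sets, excluding Y0 (and the cross-ring Y$), which every glycoform on the
  same peptide shares and which therefore carry no ranking information.
  The same exclusion applies to the generated identification transitions.

The cross-ring ^0,2X0 fragment of the reducing-end HexNAc ("Y$", and the
b$/y$ analogues) is handled as a peptide-mass offset of 83.03711 Da
(composition C4H5NO). Conventions for this ion differ between tools, so
the offset is configuration-overridable.

## Library building

GPSMs of one precursor may be annotated with different plausible glycan
structures; the structure whose summed identification score is largest
wins, with exact ties broken by canonical structure string so the result
is independent of input order. Spectra are annotated against theoretical
fragments (Y at 1+..3+ including Y0/Y$; b/y and the HexNAc-stub and
cross-ring variants at 1+..2+, stubs only for fragments containing the
glycosite) with a ±20 ppm tolerance; the nearest peak claims each
annotation and the *theoretical* m/z is stored.

Consensus building across replicates: (i) replicates with median pairwise
cosine similarity (aligned by annotation identity, not m/z binning) below
0.5 are discarded — if all are mutually dissimilar the single best-scoring
replicate is kept rather than emitting nothing; (ii) peaks present in
strictly more than 60% of survivors are kept (exactly 60% is excluded);
(iii) intensities are identification-score-weighted means.

Transition filters: fragments outside the scan range (default 200–2000
m/z) or inside any isolation window containing the precursor m/z are
excluded; the 10 most intense peptide and glycan transitions are kept
(ties by ascending m/z, for determinism), the top 6 + 6 flagged as
quantifiers; entries with fewer than 3 transitions in either part are
dropped.

RT calibration uses LOWESS (local linear regression, span 0.667, 3
robustness iterations — statsmodels) on anchor pairs, evaluated by
interpolation of the smoothed curve with linear extension outside the
anchor range; at least 10 anchors are required. Anchors can be exported
as TraML for the chromatogram-extraction step.

## Decoys

Peptide decoys reverse the sequence keeping a C-terminal K/R fixed;
modifications travel with their residues. Palindromes and collisions fall
back to seeded shuffles (≤ 20 tries) and are skipped with a warning
otherwise. Glycan decoys add an independent continuous uniform [1, 30) Da
shift to every Y-ion singly-charged fragment mass (divided by charge for
multicharged ions), sparing Y0 and Y$ so the decoy remains anchored to
the same naked-peptide species; precursor m/z and RT are unchanged so the
decoy competes in the same extraction window. The shift is sampled
continuously; an integer-valued convention would work equally and can be
emulated via the registry of mass constants. Both decoys compose the two
operations.
One decoy of each type per target makes the combined library exactly 4×
the target library.

Decoy identification transitions (for glycoform inference) use a random
same-length amino-acid sequence with PTMs kept in place, resampled until
its mass differs from the target peptide by ≥ 1 Da, combined with the
target glycan fragments.

## Two-dimensional FDR

Per axis, the semi-supervised learner mirrors the PyProphet loop:
pseudo-targets are the targets plus the decoy class that is null only on
the *other* axis; pseudo-decoys are the two classes null on this axis.
Starting from the best single sub-score by AUC, 10 iterations of
(decoy-based q < 1% pseudo-positive selection → LDA refit) are run; the
final score is cross-fitted over 3 folds so no peak group is scored by a
model trained on itself, oriented so decoys score lower, and standardized
on the pseudo-decoys. At least 200 pseudo-targets and pseudo-decoys are
required — with a small spectral library the learner and the downstream
density estimates are unreliable and the pipeline refuses to run.

The bivariate mixture is estimated by kernel densities of the four label
classes on a 128×128 grid spanning the observed scores ± 3 bandwidths
(Silverman per axis, n^(−1/6) rate), computed by binning plus Gaussian
smoothing. f00 is the both-decoy density; f01 and f10 are derived by the
subtraction identities with negatives clipped to zero and the result
renormalized to unit mass. π_P = π00+π01 and π_G = π00+π10 come from
Storey's estimator (λ = 0.4, configurable) on decoy-based p-values of the
axis D-scores; π00 from the combined D-scores of targets vs both decoys;
the remaining proportions follow by subtraction, are clipped to [0, 1] and
renormalized so the four proportions sum to one exactly.

PEPs are density ratios evaluated on the grid (points outside the grid use
the nearest boundary cell). Raw, unclipped components are kept so the
inclusion–exclusion identity PEP_P∪G = PEP_P + PEP_G − PEP_P∩G can be
verified to floating-point accuracy; the working values are clipped to
[0, 1] and monotonized by a two-dimensional cumulative-minimum sweep (the
largest function non-increasing in both scores that lies below the
estimate). Grid cells whose target density falls below half the peak
kernel contribution of a single observation contain no data, only kernel
tails; their density ratio is numerically meaningless and occasionally
near zero, which the cumulative-minimum sweep would propagate across the
entire grid. Such cells are therefore set to the conservative PEP = 1
before monotonization.

q-values average the PEPs over the acceptance set: q(t) = mean{PEP ≤ t};
each record receives the q of the smallest acceptance set containing it,
tie groups sharing one value. Run-specific q-values are computed over the
best (highest combined D-score, ties by earlier RT apex) target peak group
per precursor and run; the global context selects the best peak group per
glycopeptide across runs and re-averages on that reduced set. The default
report filter is run q < 5% in every run, < 1% in at least one run, and
global glycopeptide q < 1%.

## Glycoform inference

Background candidates are database glycans on the same peptide whose
precursor m/z at the query charge shares an isolation window with the
target; isomer groups with identical Y sets are merged; groups are ranked
by Jaccard similarity to the target glycan (descending, ties by canonical
string) and capped at n_bg = 50; the target's own group is always kept.
Identification transitions are the union of discriminating Y compositions
over all hypotheses at charges 1–3 within the scan range, each mapped to
the set of hypotheses it can originate from, plus one unfragmented-
precursor transition per hypothesis (MS2 precursor detection).

Transition PEPs come from a univariate two-groups mixture: an LDA
discriminant (or the single score column), kernel densities of the decoy
and target transition scores on a 512-point grid, Storey π0, and
PEP(s) = π0 f_decoy(s)/f_target(s) clipped to [0, 1].

The Bayesian hierarchical model assigns the prior PEP_MS2 to the
incorrect-detection hypothesis A0 and divides 1 − PEP_MS2 equally over the
candidate glycan compositions, then equally over isomer groups within a
composition. The MS1 conditional is 1 − PEP_MS1 for hypotheses whose
precursor m/z lies within 10 ppm (configurable) of the query and PEP_MS1
otherwise; per-hypothesis MS2-precursor conditionals are analogous; each Y
transition contributes 1 − PEP to hypotheses it can originate from and PEP
to the rest. Accumulation is in log space with a 1e-12 per-factor floor.
Posteriors are normalized at both stages (precursor-only and
transition-integrated); composition-level posterior probabilities sum the
isomer-group values. The glycoform PEP is 1 − PP of the library glycan
composition, averaged into per-run glycoform q-values; the default report
filter is glycoform q < 5% per run and < 1% in at least one run.
Peak groups whose best explanation is a background glycan are not
reported as targets.

## Semi-empirical prediction

Peptides are vectorized to amino-acid composition (the glycosite marker
counts as asparagine) and glycans to (Hex, HexNAc, NeuAc, Fuc) counts.
For a target (P, G, n+), the k = 3 same-peptide/same-charge entries with
glycans nearest to G (Euclidean) supply the peptide part and the k
same-glycan/same-charge entries with peptides nearest to P supply the
glycan part, each merged with the library consensus rules; the parts are
scaled so their summed-intensity ratio equals the mean peptide/glycan
ratio over the union of the neighbor spectra (entries in both
neighborhoods counted once). Y-ion and backbone m/z are recomputed for
the target precursor, with intensities aligned by fragment role
(Y composition, b/y ordinal). Distance ties at rank k resolve by library
order. RT is the Gaussian-weighted mean over the k same-peptide entries
with charge states pooled: w_i = exp(−d_i²/(2σ²)) with σ² the mean
squared glycan distance of the neighborhood; σ² = 0 degrades to equal
weights. Predictions pass the standard transition filters before joining
a library, and library extension only considers explicitly listed
peptide–glycan combinations to avoid combinatorial explosion.

## Quantification

Each run is scaled so its median observed intensity equals the grand
median of run medians (idempotent; missing values are never treated as
zero). Glycopeptide and site-specific-glycan levels sum their three most
intense members per sample, with top-3 membership recomputed per column;
the protein-glycosite level sums all members. CVs use the sample standard
deviation (n − 1) over replicates, undefined below two observations.

## Synthetic data

The generators produce the statistical structure the estimators assume,
at desk scale, fully determined by a seed:

* glycan databases grow random trees from the N-glycan core
  (N(N(H(H)(H)))) by leaf attachment (H/N/F/A at weights
  0.5/0.2/0.15/0.15, ≤ 12 nodes), deduplicated canonically;
* libraries use tryptic-like peptides (8–14 residues, C-terminal K/R, one
  J-X-S/T sequon), charges 2–4, precursors inside the 700–1636 m/z DIA
  range, smooth hydrophobicity-based RTs with a glycan-size offset, and
  log-normal fragment reference intensities that depend only on
  (peptide, fragment) for the peptide part and (glycan, fragment) for the
  glycan part — the separability the fragment-swap predictor assumes —
  with per-replicate log-normal noise (σ = 0.2) and ±5 ppm m/z jitter;
* feature tables draw target classes from configurable proportions
  π = (π00, π01, π10, π11) with two of four sub-scores per axis
  informative at a 3σ separation, and decoy classes following the mixture
  identities of the model (peptide decoys peptide-null with the targets'
  glycan-state mixture, etc.);
* the glycan-entrapment benchmark pairs each target (peptide, high-mannose
  glycan, charge) with an entrapment entry whose glycan replaces one
  hexose by a fucose (16 Da lighter, guaranteed disjoint from the sample
  glycome), kept only when both precursors share an isolation window.
  Targets are present with probability 0.9; entrapment glycoforms never.
  Entrapment peak groups receive full peptide evidence and partial (2σ)
  glycan evidence — the shared core Y ions are genuinely present — so
  peak-group scoring alone cannot remove them; their private fucosylated
  Y transitions carry noise-level signal only, which is what the
  transition-level model exploits. MS1 and MS2-precursor evidence is
  simulated as Gaussian scores (3σ separation when the species is truly
  present) converted to PEPs by the same univariate estimator used for
  transitions, against null decoy scores.

What the simulations do *not* emulate: chromatographic peak shapes,
interference between unrelated analytes, correlated sub-scores, intensity-
dependent noise, missed cleavages and charge-state coupling, or realistic
glycome frequency distributions. Passing tests therefore demonstrate the
correctness and calibration of the estimators under their stated
assumptions, not performance on real instrument data.

Default problem sizes — 20,000 precursors for mixture-calibration checks
and 2,000 target + 2,000 entrapment precursors for the benchmark — were
chosen so binomial uncertainty on the reported rates is small (95% CI
half-width below 0.5 percentage points at a 1% rate) while a full
validation run completes in well under a minute.

## Numerical choices and limitations

* Proton 1.00727646688 Da, water 18.0105646863 Da; peptide residue masses
  from pyteomics.
* Mixture grids 128×128 (512 univariate); binned KDE via histogram plus
  Gaussian filter, which matches direct kernel sums to within the bin
  discretization and keeps density estimation O(n + grid).
* The cumulative-minimum monotonization is the largest monotone minorant,
  not the L2 isotonic projection; it is conservative-biased downward in
  noisy regions, which the unsupported-cell rule above counteracts.
* All orderings that affect output (tie-breaks, groupings) are explicit
  and deterministic; every stochastic step takes a seed, and seeds derived
  internally use `numpy.random.SeedSequence` reduced below 2^31.
* Scores far outside the fitted grid are evaluated at the boundary, which
  saturates rather than extrapolates the PEP surface.
* The entrapment benchmark couples one entrapment entry per target; real
  entrapment designs subsample a foreign glycome, so the difficulty of
  the benchmark is controlled by the 16 Da mass offset and shared-core
  construction rather than by glycome diversity.
* O-glycopeptides with multiple candidate sites, glycosite localization,
  and linkage/anomericity distinctions are out of scope.
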
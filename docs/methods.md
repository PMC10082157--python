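# Methods

This note records the models implemented in `bitescreen`, their
assumptions, the defaults and why, and what the synthetic data used by
the test suite does and does not establish.

## Library model

A library member is fully specified by four coordinates: a CD19 scFv
variant, a CD3 scFv, an inter-scFv linker, and a VL/VH orientation pair.
The CD19 arm is always N-terminal; "orientation" is therefore a pair of
domain orders (VL-VH or VH-VL per arm, four combinations), rendered as
`CD19_VL-VH–CD3_VH-VL` style labels.

**Degenerate scanning.** CDRH3 single-site saturation uses an IUPAC
degenerate codon, default NNW. NNW spans 32 codons reaching 18 amino
acids (methionine and tryptophan are unreachable — their only codons end
in G) plus the TAA/TGA stops. Two policies close the gaps the chemistry
leaves open:

* `stop_policy=drop_variant` (default): protein variants requiring a stop
  are not emitted. A stop-containing clone cannot express a full-length
  construct and would never survive the full-length read filter, so the
  enumerated space is the expressible space.
* `parent_policy=collapse_to_parent` (default): synonymous codons
  encoding the parent residue collapse into one parent variant, because
  identity is defined at the protein level throughout (deduplication,
  distribution summaries and composition matrices all operate on
  translated sequences).

**Assembly.** Protein: signal peptide + (domains in CD19 order joined by
the intra-scFv linker) + inter-scFv linker + (CD3 domains likewise) +
His-tag/2A segment. The intra-scFv linker is not part of the published
variable panel; the field-standard (GGGGS)₃ is the default and it is
configurable per library definition. The long flexible inter-scFv linker
is likewise not printed anywhere; it defaults to (GGGGS)₃ to contrast
with the short GGGGS form, alongside the printed rigid pair AEAAAKA and
AEAAAKEAAAKA. DNA: the printed 57-nt signal and 75-nt His-tag/2A
sequences flank a reverse-translated coding region using the most
frequent human codon per residue — deterministic by design, since DNA
realism beyond translatability is not needed by any downstream analysis,
and injectivity makes DNA-level deduplication well defined. Coordinates
are 0-based half-open internally; CDRH3 positions are reported 1-based
(`Y10`-style) in outputs.

## Read classification

Reads are assumed to be consensus reads: substitution-dominated, no
systematic indels. Three consequences:

* **Anchors** are located by a substitution-only Hamming scan on both
  strands (numpy sliding-window), tolerating `max_mismatches` (default 3)
  per anchor. `N` counts as a mismatch. Indel alignment inside anchors is
  deliberately not attempted.
* **Indels between the anchors** are rejected by the frame test (span
  length mod 3) rather than corrected; an in-frame stop fails the read.
* **Domain identity** is ungapped: each scFv half must match a reference
  length exactly and is scored by fractional identity with the
  reference's CDRH3 window masked (threshold 0.85, configurable). The
  library varies only by substitution, so alignment machinery would add
  cost without information.

**Linker calling** must survive the fact that GGGGS is a substring of the
default intra-scFv linker. The panel is searched longest-first, and an
occurrence counts only if the flanking segments each length-match and
assign to a reference scFv — which excludes every occurrence inside an
intra-scFv linker by position. Zero or multiple surviving occurrences →
`ambiguous`.

Classification is per-read and stateless, hence idempotent and
order-independent; the unique-variant table uses the lexicographically
smallest supporting read id as representative so the aggregate is
permutation-invariant. Design-distribution summaries default to
unique-sequence weighting (each unique protein counts once), with
read-count weighting available, since read depth reflects amplification
as much as library composition.

## Droplet and screening statistics

* Occupancy: Poisson, independent between the library and reporter arms;
  monodisperse droplets (volume variation ignored). Unit discipline:
  1 µm³ = 10⁻¹⁵ L, so 1 pL = 1000 µm³; a 77 µm droplet is 239.0 pL.
* Recovery regression: recovery rate (= recovered/spiked) against
  abundance on the raw proportion scale, OLS for the linear family
  (reporting R², slope p-value, Breusch–Pagan and Shapiro diagnostics),
  with 4/5-parameter logistic alternatives via least squares. The
  "lower bound" fed into efficiency curves is the one-sided lower
  confidence limit of the predicted mean at the configured level (90% and
  95% both supported); for the logistic families it is a
  normal-approximation bound from the residual spread, documented as
  approximate.
* Screening efficiency: `P = 1-(1-p)^N` computed via `log1p`/`expm1`; `N`
  is an integer copy count (abundance × cells, floored). The inversion
  `min_copies_for_confidence` uses the closed form and then verifies at
  `N` and `N-1`.
* Dual-reporter false positives multiply under an explicit independence
  assumption; it is an assumption of the model, not a finding.

## Simulator

The simulator reproduces the screen's statistical structure, not its
physics or kinetics: endpoint activation only, per-reporter Bernoulli
with Gaussian signal intensities (no time courses), monodisperse
droplets, independent Poisson arms.

Defaults are the screen's operating point: λ_library = 0.3, λ_reporter =
3 split 1:1 over two orthogonal channels, activation probability 0.40
given a functional co-encapsulated clone, basal (spurious) activation
0.01 per reporter, detection 0.90 per required channel (cell dye plus one
per reporter channel, independent), single-cell PCR success 0.775 (the
midpoint of the reported 75–80% range), gates μ+4σ per channel. A droplet
is sortable only if every channel has ≥1 activated reporter above its
gate — droplets lacking a reporter type can never be dual-positive — and
spurious activations draw genuine activated-level signals, so basal
false positives propagate through gating exactly like real ones.

Genotypes are drawn without replacement from the population; if a Poisson
draw exceeds the remaining pool the trailing droplets receive the
leftover cells. Spiked populations support exact counts
(`round(abundance × size)`, used wherever a titration needs a known
truth) or binomial sampling. `analytic_recovery_probability` gives the
closed-form composition (encapsulation × per-channel activation via
Poisson thinning × detection × PCR) valid for rare single-copy spikes
under ideal gates; tests tie the simulator to it within 3σ.

Every stochastic operation takes a `numpy` Generator or seed;
`run_titration` spawns child seeds with `SeedSequence` so results are
reproducible bit-for-bit and replicates are independent.

## Synthetic reference panel

The real variable-domain sequences of the eight published binders are
proprietary, so `synthetic_panel` generates seeded synthetic stand-in
domains (uniform over the 20 residues, fixed lengths VH=122, VL=108,
CDRH3 window [95, 107)) carrying the real panel structure — binder names,
targets, the four-linker panel, all four orientations, NNW scanning. Two
screening rules make the fixtures sound: no linker motif (GGGGS, EAAAK)
or His-run may occur inside a domain, and uniform domain lengths ensure
no spurious linker occurrence can length-match an scFv block. Its default
theoretical diversity is 52,928 (4 parents × ~205–207 CDRH3 variants × 4
× 4 × 4).

What passing tests show: the classifier inverts the generative model
exactly on clean reads and degrades as designed under substitution noise;
the statistics match their closed forms. What they do not show:
performance on real consensus reads (indel artefacts, chimeras, quality
structure), real binder homology (synthetic domains are far less similar
to each other than real antibody frameworks, which makes domain
assignment easier here than in practice), or the published library's true
per-category counts, which are configuration inputs this package does not
guess.

## Numerical and testing choices

Problem sizes in the suite are chosen to keep the full run near ten
seconds of CPU while leaving Monte-Carlo bands meaningful: 10⁴-read
classifier checks, 10⁵-droplet occupancy checks, 2×10⁶-trial efficiency
simulations (20 aggregated batches of 10⁵), 200-replicate regression
coverage at the 95% CI, 30-replicate end-to-end screens at 2×10⁴ cells.
All stochastic assertions use 3σ bands around the analytic value and
fixed seeds. Tie-breaks are lexicographic everywhere (enumeration order,
domain assignment, representative read ids) so outputs are byte-stable.

## Known limitations

* Anchor matching is substitution-only; a read with an indel inside an
  anchor but a clean coding span is lost (counted `no_anchor`).
* The logistic-family lower confidence bound is a residual-spread normal
  approximation, not a profile or bootstrap interval.
* The regression treats observations as homoscedastic; strongly unequal
  spike copy numbers across abundances violate that and the reported
  Breusch–Pagan p-value is the instrument for noticing.
* Multi-copy droplets are attributed collectively: every library cell in
  a sorted droplet is recovered (subject to PCR), with no intra-droplet
  competition model.
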
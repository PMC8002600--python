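# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `icmaldi`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is an external claim.

## Setting and assumptions

Intact-cell MALDI-TOF profiling of microbial cells yields, after peak
picking, a list of (m/z, intensity) pairs per spectrum in roughly the
m/z 1,000–25,000 window. The package assumes throughout:

* **singly charged ions** — a peak's m/z is read as the [M+H]⁺ mass of
  one protein; charge states ≥ 2 are not modeled;
* **average-mass matching** — above ~1 kDa the isotope envelope is
  unresolved and centroids near the average mass, so assignment and all
  default tolerances work on the average scale;
* **presence/absence semantics for treatment effects** — a treated
  sample differs from its control by which peaks exist, not by intensity
  fold change; intensity enters only normalization, correlation
  distances and the identification score.

## Mass engine

Residue masses are derived at import time from one table of isotope
masses and abundances (standard CODATA/NIST values) and the 20 residue
elemental compositions: monoisotopic = lightest-isotope sums, average =
abundance-weighted sums. Deriving both scales from a single elemental
table means they cannot drift independently. A chain of residues gets
one water added for the termini. Conventions, fixed and deliberate:

* [M+H]⁺ adds the **H atomic weight** (≈1.00794) on the average scale
  and the **proton mass** (1.007276) on the monoisotopic scale. The
  electron-mass distinction is immaterial at Da-level tolerances but the
  convention must be stated; whether a measured peak is compared to the
  neutral or the protonated mass is an explicit `adduct` parameter
  (default `MH`).
* No post-translational modifications, no N-terminal Met excision: the
  mass is that of the full deposited chain.
* Sequences containing B, Z, X, U, O are retained on read but flagged
  non-computable; mass operations skip them with a logged count rather
  than guessing.

Verification: agreement with an independent molecular-formula oracle
(pyteomics, which carries its own isotope table and composition logic)
within 0.01 Da (average) and 0.001 Da (monoisotopic) over 1,000 random
sequences of length 5–300, and exact additivity
`m(A⊕B) = m(A) + m(B) − m(H₂O)` to 1e-9 Da.

## Consensus profiles (MSPs)

Replicate peak lists are pooled and sorted; a new group starts wherever
the gap to the previous peak exceeds `tol` (single-linkage chaining). A
chain spanning more than `2·tol` — possible only in pathological dense
data — is split recursively at its largest internal gap to bound
consensus-peak width. Per group: consensus m/z is the intensity-weighted
mean, mean intensity averages over the replicates containing the peak
(a replicate contributing two peaks to one group counts once, its
intensities summed), and frequency is the fraction of replicates
represented. Groups below `min_frequency` are dropped; if more than
`max_peaks` survive, the most intense are kept.

Defaults: `tol = 2.0` Da (the annotation window reused), `min_frequency
= 0.25`, `max_peaks = 100` (the typical size of a species-characteristic
fingerprint). These are declared assumptions, configurable everywhere;
the commercial software that popularized MSPs does not disclose its
algorithm, so this one is defined from scratch. With 20 replicates and
20% per-peak dropout the occupancy of a true peak is Bin(20, 0.8), so
P(occupancy < 5) < 1e-3 and a 100-peak template is recovered in full
with probability > 0.999 per peak — checked empirically.

## Differential peaks

Matching between a sample and a control profile is greedy over all
cross pairs within `tol`, ascending by |Δm/z|, ties toward the lower
control m/z then lower sample m/z; each peak used once. This is
deterministic, order-independent, and — on instances whose candidate
groups are unambiguous (realized groups separated by more than 2·tol) —
identical to the minimum-total-|Δ| maximum-cardinality assignment, which
the tests verify against a Hungarian-algorithm oracle on 500 random
instances. On deliberately ambiguous instances greedy matching can
differ from the global optimum; this is accepted for transparency and
determinism. Two exact invariants hold always: conservation
(|new| + |shared| = |sample|, |missing| + |shared| = |control|) and role
symmetry (new(S,C) = missing(C,S) as m/z multisets).

Intensity is ignored in the presence/absence call. Counts per
(treatment, concentration, time) condition aggregate into two matrices
(newly appeared, missing) exported as CSV and rendered as heat maps.

## Annotation

A sorted mass index over the proteome supports binary-search window
queries. All index entries within ±tol of a peak are reported, ranked by
|Δ| (ties by accession): assignments are many-to-many by design, since
one mass can fit several proteins and vice versa. Peaks with more than 5
candidates are flagged low-specificity; peaks with none yield an
explicit unassigned marker. Mass-only assignment is a hypothesis, not an
identification — it ignores modifications and cannot substitute for
sequencing.

The package ships the reported (m/z, UniProt accession) worked
assignments for *Synechococcus* sp. UPOC S4 treatment studies as data
(`icmaldi.reported_assignments`) together with a checker that recomputes
average [M+H]⁺ for each accession from a user-supplied UniProt FASTA and
verifies the ±2 Da window. The sequences themselves are not bundled;
`scripts/fetch_reference_proteins.py` retrieves them from UniProtKB when
network access is available, and the corresponding acceptance test fails
until they are present.

## Similarity, clustering, identification

Profiles are aligned by the same one-to-one matching as the differential
step; each union position carries the two base-peak-normalized
intensities (0 for absence). Intensities are square-root transformed
before correlation — MALDI intensities are strongly right-skewed and the
transform stabilizes variance; the distance is 1 − Pearson r (Spearman
optional), in [0, 2]. Degenerate (zero-variance) alignments and
alignments of fewer than 3 positions raise rather than return a value.

UPGMA uses scipy's average linkage on the condensed distance matrix
after reordering leaves lexicographically, which fixes tie-breaking.
The tree is built with node height = merge distance / 2 and branch
length = height difference, so root-to-leaf path lengths are equal by
construction (ultrametric exactly; verified to 1e-9). Newick export via
scikit-bio.

The identification score is
`score = (f_qr · f_rq · max(r, 0))^(1/3) · 3`
with f_qr = fraction of query peaks matched in the reference, f_rq the
reverse, r the Pearson correlation of √-transformed matched intensities.
The 0–3 range imitates the familiar commercial biotyping scale for
readability, but the score is defined entirely by this formula and is
**not** comparable to proprietary scores or their ≥ 2.0 species-level
convention.

## Synthetic-data generator

The generator emulates a treated-vs-control profiling study with the
structure the analysis assumes, at the scale such studies report:

* **Proteome**: random sequences over the 20-letter alphabet, lengths
  8–200, so average [M+H]⁺ spans the instrument window.
* **Control template**: 100 proteins with [M+H]⁺ in m/z 1,000–25,000,
  pairwise ≥ 5 Da apart (so each synthetic peak annotates uniquely at
  rank 1); intensities log-normal (σ = 1).
* **Treatment model**: peak i is lost when its latent vulnerability
  u_i ~ U(0,1) falls below
  `p_loss = logistic(s · (log(dose/d₀) + t/τ))`,
  with steepness s = 1.5, midpoint dose d₀ = 5 µM, time scale τ = 14 d;
  dose 0 gives the dose→0 limit p_loss = 0, so an untreated sample is
  untouched. Vulnerabilities are drawn once per treatment, so harsher
  conditions lose a superset of the peaks lost by milder ones — the
  nested, dose-correlated damage real treatments produce, and the reason
  the harshest conditions cluster together in trees. Marginally each
  peak is still an independent Bernoulli(p_loss), so observed missing
  counts are Binomial(n, p_loss) and recoverable: over 200 simulated
  conditions ≥ 99% lie within 3 binomial SDs of n·p_loss, and expected
  counts are monotone along both grid axes.
* **Stress peaks**: `Poisson(g · (dose/d₀) · (t/τ))` novel peaks with
  g = 12 (≈ 36 expected at 10 µM × 3 weeks, the order reported for harsh
  conditions), drawn from proteome members absent from the template,
  never within the 5 Da spacing margin of template peaks — so
  differential counts are unambiguous and newly appeared peaks annotate
  to "stress proteins". Each pool protein carries one characteristic
  abundance per treatment, shared by all conditions expressing it.
* **Replicates**: per-peak dropout 0.2, m/z jitter N(0, 0.3 Da),
  mean-preserving log-normal intensity noise with CV 0.3, 20 replicates
  per sample. An all-dropout replicate retains its most intense peak
  (instrument software never exports an empty list).

All randomness flows from one integer seed through a spawned
`SeedSequence` hierarchy (seed → condition → replicate); fixed seed
means byte-identical output files.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: baseline/chemical noise and peak-picking
errors, mass-dependent calibration drift, intensity suppression between
co-crystallizing analytes, correlated (biological) replicate structure,
post-translational modifications, and any mechanistic link between a
specific inhibitor and which proteins disappear. Conclusions supported
by the synthetic checks are about the *pipeline's* correctness and
statistical behaviour, not about inhibitor biochemistry.

## Problem sizes and determinism

The default verification runs use a 400-protein proteome with a 100-peak
template (50 peaks / 200 proteins for the 100-run clustering sweep),
20 replicates per sample and a 4-dose × 3-time grid — the scale of the
study design the package targets, and small enough that the whole suite
and the acceptance script each complete in well under a minute. Every
test and the acceptance script are seeded; `scripts/acceptance.py`
derives all child seeds from `--seed`.

## Known limitations

* Greedy matching is optimal only on unambiguous instances (see above).
* Single-linkage MSP grouping can chain in very dense spectra; the
  2·tol split bound is a heuristic, and the "consensus peaks ≥ tol
  apart" guarantee can be violated immediately after a pathological
  split.
* The dose-response form (logistic in log-dose + scaled time) and its
  defaults are modeling choices tuned to the qualitative escalation
  pattern such studies report, not fitted to any measured curve.
* The identification score is transparent but uncalibrated: its values
  have no species-level threshold semantics.
* Annotation trusts the deposited full-length chain mass; proteins
  observed processed (e.g. Met-excised) will mis-assign unless the
  optional Met-excision variant is enabled.
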
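# Methods

This note documents the models, conventions and design choices behind
`hdxmap`, in the order of the pipeline.

## Peptide chemistry and mass conventions

Peptides are intervals of a parent protein with optional residue
substitutions and terminal modifications.  The bench notation is parsed
directly: `Ac-` marks N-terminal acetylation (+C2H2O), `-NH2` C-terminal
amidation (−O +NH), and the inline token `Abu` marks 2-aminobutyric acid
(residue composition C4H7NO), the isosteric thiol-free cysteine
replacement used throughout the synthetic CD160 fragments to prevent
disulfide scrambling.  Linker moieties (penta-glycine, biotinyl
C10H14N2O2S) are supported as composition add-ons for
immobilization-construct bookkeeping.

Masses are summed from pinned atomic-mass tables (`constants.py`):
CODATA/AME monoisotopic masses and IUPAC 2005 standard atomic weights.
Two conventions are exposed deliberately:

* the **isotope-averaged neutral mass** reproduces the tabulated
  "calculated mass" of each synthetic fragment to within ±0.05 Da (the
  panel's printed values match our averages within ~0.01 Da even though
  they are labelled as [M+H]⁺ — they are numerically average neutral
  masses, a common convention of synthesis-lab calculators);
* the **monoisotopic** neutral mass and adduct m/z
  ((M + z·cation)/z with cation masses H⁺ 1.00728, Na⁺ 22.98922, electron
  included) reproduce the observed spectral [M+H]⁺/[M+Na]⁺ values.

The mature-protein numbering is taken at face value from the fragment
intervals; residues 1–133 of the CD160 ectodomain are reconstructed from
the overlapping fragment sequences (every position fixed by at least one
fragment, overlaps consistent).  Coverage is audited as per-residue depth;
*mean redundancy* is defined as the mean depth over covered residues (no
formula is standard; this matches the usual "average redundancy"
reporting).

## Deuteration quantification

The measured quantity is the isotope-envelope centroid mass per peptide,
state, exposure time and replicate.  Deuteration is normalized by the two
control experiments — in-exchange (`Mex0`, minimal labelling) and
out-exchange (`Mex100`, 24 h maximal labelling):

    %D = 100 · (Mex − Mex0) / (Mex100 − Mex0)

Choices:

* **Pooled controls.** Control replicates are averaged per peptide before
  normalization; per-replicate control pairing is not assumed.
* **No clamping.** %D may leave [0, 100] on noisy data; values outside
  [−10, 110] are flagged, never altered, so downstream statistics see the
  raw variance.
* **Sample SD** (n−1) over replicates; singleton points report SD 0.
* **Inclusive filters.** The identification filters (minimum intensity
  3000, minimum products per amino acid 0.3, minimum score 7.0, maximum
  MH⁺ error 10 ppm) are applied with inclusive thresholds; each rejected
  record carries its first failing rule as the reason.
* **Exchange-speed classes.** %D is binned into five classes at
  20/40/60/70%; above 70% is "very fast" (flexible, solvent-exposed
  structure), the only bin edge anchored by the study's wording; the
  remaining edges are configurable.

## Differential exchange and protected regions

Per peptide and exposure time, the difference in fraction exchanged is
ΔFE = (%D_apo − %D_complex)/100 (positive = protected upon binding), with
uncertainty propagated as the square root of the sum of the two variances.
Significance uses Welch's two-sample t-test on the replicate %D values
with Satterthwaite degrees of freedom; degenerate inputs follow explicit
conventions (both variances zero: p = 1 if the means agree, else p = 0).
A peptide is called protected if p ≤ α (default 0.05) **and**
ΔFE ≥ δ_min (default 0.02) at at least one exposure time; both defaults
are configurable, and no multiple-testing correction is applied by default
(an optional Benjamini–Hochberg flag exists).  The ΔFE floor guards
against statistically significant but chemically negligible differences.

**Region calling.** Flagged peptides are condensed in one of two modes:

* *intersection* (default): flagged intervals are taken shortest-first;
  each becomes a region supported by every flagged peptide overlapping
  it, and that evidence is consumed before the next region is chosen.
  When a short fragment is nested inside longer flagged peptides this
  reduces to their common segment — the "shortest region showing a
  significant change".  Resolution is therefore bounded by the shortest
  fragments in the map: with only 20–25-residue fragments the called
  regions cannot be narrower than those fragments, while digest-style
  maps containing short peptides recover planted 5–12-residue epitopes
  exactly (see `tests/test_hdx_differential.py`).
* *union*: the envelope of each connected component of flagged intervals,
  as an upper bound on the perturbed surface.

Per-residue exchange profiles average the fraction exchanged of covering
peptides with weight 1/length (shorter peptides localize better);
uncovered residues are reported as missing, never zero.

## Structure-consistency scoring

Candidate models are scored against three experimentally anchored
criteria; the composite is their weighted mean (equal weights by
default):

1. **Exposure agreement** — the fraction of fast-exchanging residues
   (classes fast/very fast) that are solvent-exposed or lack backbone
   H-bond protection.  Exposure is per-residue Shrake–Rupley SASA (probe
   1.4 Å, 960 fixed Fibonacci quadrature points, Bondi-style radii)
   normalized by Tien-style theoretical maxima, with 0.25 as the
   buried/exposed threshold (the common convention).  H-bond protection
   uses heavy atoms only (models carry no hydrogens): an amide N within
   3.5 Å of a carbonyl O at an N–O–C angle ≥ 90°, excluding own and
   peptide-bond-adjacent carbonyls; prolines are never protected donors.
2. **Binding-fragment exposure** — the fraction of binding-region
   residues that are exposed while the region's Cα trace is contiguous
   (consecutive spacing ≤ 12 Å).
3. **Disulfide topology** — SG–SG ≤ 2.5 Å for each annotated bridge,
   and ≥ 3.0 Å from every other SG for free cysteines.

A fourth plausibility criterion (correct immunoglobulin β-sandwich
topology) is deliberately reduced to the contiguity and disulfide checks;
automated fold classification is out of scope and is documented as a
limitation.  Ranking is by composite, with ties broken by exposure
agreement then model id, so the ordering is deterministic and
input-order independent.

## Interface analysis

Contacts use the dual-cutoff convention of coarse-grained docking
analyses: score 1 at distances ≤ cutoff1 (8 Å), 0 at ≥ cutoff2 (10 Å),
linear in between (a step-at-cutoff2 mode is available).  Distances are
measured between heavy side-chain centroids (the closest all-atom analogue
of a side-chain-centre representation; Cα for glycine), and ensemble maps
average scores over models, so an entry is the fraction-weighted contact
probability.  Interface residues are those whose best score reaches 0.5.

Salt bridges pair acidic side-chain oxygens (Asp OD1/OD2, Glu OE1/OE2)
with basic nitrogens (Lys NZ; Arg NH1/NH2/NE; optionally His ND1/NE2,
off by default) at ≤ 4.0 Å, reporting the minimum distance and the
fraction of ensemble frames in which the bridge is formed.  Hydrophobic
contacts are side-chain-centroid pairs ≤ 5 Å between the apolar residue
types.  RMSD uses Kabsch least-squares superposition (proper rotations
only); RMSF superposes each frame onto the first via Cα (a mean-structure
reference is available), then averages per-atom fluctuations over the
backbone atoms of each residue.

## Synthetic scenarios: what they emulate and what they do not

The generator produces the study's conditions: a 141-residue protein
(the reconstructed CD160 ectodomain residues 1–133 plus a synthetic
Gly/Ser tail), protection planted at residues 16–21, 30–34 and 76–87, the
fragment-panel map (and a digest-style map including the short
HDX-resolved fragments), five exposure times (10 s, 1 min, 5 min, 25 min,
2 h), four replicates, and in-/out-exchange controls.

Exchange follows the Linderstrøm-Lang EX2 limit: each backbone amide is a
single exponential with rate k_int/P, intrinsic rates drawn log-uniformly
over 10⁻³–10¹ s⁻¹ and apo protection factors log-uniformly over 1–100
(a broad, realistic dynamic range reaching from fully solvent-exposed
loops to slow-exchanging core amides within the measured time window);
binding multiplies P by a fold factor (default 10) inside the planted
intervals.  Sequence-dependent intrinsic-rate chemistry, EX1 kinetics and
isotope-envelope shapes are *not* modelled — passing tests demonstrate
correctness of the analysis chain, not instrument realism.

The first residue of each peptide and all prolines carry no exchangeable
amide.  Peptide centroids are the base monoisotopic mass plus
1.00628 Da per exchanged site, with Gaussian noise (default SD 0.1 Da,
a typical centroid precision).  An in-exchange floor (2% of maximal
uptake) and a back-exchange retention (85%) apply *identically* to
samples and controls, so control normalization cancels them exactly:
on noise-free data the pipeline's %D equals the ground-truth mean
exchanged fraction to machine precision, an identity the tests assert at
1e-9.  (Applying floor and retention to controls only would make the
normalized %D an affine rescaling of truth rather than truth itself; the
shared-systematics model is the physically coherent reading, since all
samples pass through the same quench and chromatography.)

Structural fixtures are geometric, not physical: toy complexes place two
chains so that planted interface bands sit inside the inner contact
cutoff with reciprocal Glu/Arg bridge pairs at bonding distance (the
interface's salt-bridge motif), plus rigid per-model jitter; decoy sets
degrade exactly one selection criterion per decoy (burying a binding
region behind an occluding shell, displacing one disulfide SG, or
burying-and-H-bonding a subset of fast residues), with a manifest
recording the perturbation.

## Problem sizes and numerical choices

Simulation-based checks use 1000 peptides for the null false-positive
rate (binomial SE ≈ 0.7% at α = 0.05), 50 seeds for region-recovery and
model-ranking summaries, and 15–20 seeds for the corresponding unit
properties; these sizes put Monte-Carlo error well below the asserted
margins.  SASA uses 960 fixed quadrature points (≈1% accuracy on an
isolated sphere; rotation invariance holds to the quadrature error).
The Welch test is compared against an exhaustive/resampled permutation
oracle; with four replicates per state the permutation null has only 70
atoms, so agreement is asserted within the granularity bound (≈0.03) plus
Monte-Carlo error rather than to arbitrary precision.  All generators are
deterministic given a seed; seeds never influence any threshold.

## Known limitations

* Region resolution is map-limited by construction (no residue-level
  exchange-rate deconvolution from overlapping peptides); under a map of
  only 20–25-mers the shortest callable region is a full fragment.
* The fold-plausibility criterion is a proxy (contiguity + disulfides),
  not a topology classifier.
* Back-exchange is a single global retention factor; no per-residue or
  temperature-dependent correction.
* The contact function is an interpretation of the dual-cutoff
  convention (graded linear ramp); the step variant is provided for
  sensitivity analysis.
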
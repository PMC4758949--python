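# Methods

## Overview

`satsup` implements the computational side of a saturation-suppressor
mutagenesis workflow: it turns deep-mutational-scanning read counts into
per-mutant mutational-sensitivity scores and per-position RankScores,
uses experimentally identified (parent-inactive-mutant, proximal-suppressor)
residue pairs as spatial constraints to score candidate structural models
(ContactScore), complements that with a mutational-sensitivity-derived
depth-correlation score (rdepthscore) and a packing-deviation statistic
(R_s), and applies a differential-contact procedure to decide which of two
rival structures of one protein is the functional conformer in vivo.
A four-parameter sigmoid fitter reports melting temperatures from
thermal-shift fluorescence curves.

## Mutational sensitivity and RankScore

A single-site saturation library screened at increasing expression levels
yields per-mutant read counts across MID-tagged conditions (`mid_<k>`
columns).  **MS_seq** is the first level at which the read count drops
fivefold or more relative to the previous level, i.e. the expression level
at which the mutant first shows an active (lethal) phenotype.  Values span
{0} ∪ [2, 9]: 0 marks a mutant absent from the library, 2 the most active
and 9 the least active class.  Conventions for degenerate counts:

* a drop from positive reads to zero qualifies (complete killing is the
  strongest signal); zero to zero does not;
* a mutant with a positive count somewhere but no qualifying drop scores 9
  (it survived every expression level);
* the reader accepts any ordered set of `mid_<k>` columns.  The bundled
  read simulator emits `mid_1..mid_9`, treating level 1 as the fully
  repressed baseline at which every obtained mutant survives, so the full
  planted range {2..9} round-trips through the drop rule.

**RankScore** aggregates MS_seq to positions.  Each stratum k receives
rank = (cumulative percentage of observed mutants with MS_seq < k) + 1, so
the MS_seq = 2 stratum has rank 1 and the arithmetic is invariant to row
order; cumulative percentages are used unrounded.  A position's RankScore
is the mean rank of its observed mutants, excluding absent mutants and
wild-type self-substitutions.  Depending on the population composition the
maximum attainable value is (100 − a) + 1 for the top stratum (a = percent
of the population below it); the implementation does not clip to 100.

Suppressor positions are classified **distal** when RankScore ≤ 1 (surface
positions sit at the rank floor), **proximal** when RankScore ≥ 25 (only
deeply buried positions reach this), otherwise ambiguous; both cutoffs are
parameters.  Position classing (buried / active-site / exposed) reads the
canonical substitution motifs: buried positions tolerate aliphatic but not
polar/charged substitutions, active-site positions tolerate almost
nothing, exposed positions tolerate almost everything (G and P excluded
from the "everything" count).  The sensitivity threshold (`high_ms = 7`)
and the group agreement fraction (`tol_fraction = 0.5`) are configurable
defaults; the motifs, not the numbers, are the definition.

## Geometry

* **Side-chain centroid**: unweighted mean of heavy side-chain atoms
  (excluding N, CA, C, O, OXT); glycine falls back to CA so that
  glycine-containing pairs still have a defined contact distance.
* **Homo-oligomer convention**: a residue position occurs once per
  protomer; every position-pair distance is minimised over all distinct
  residue pairings within and across chains.
* **Superposition**: Kabsch least squares on N, CA, C (backbone), with
  CA-only and backbone+O variants.  RMSD is reported over the shared
  residue set; missing atoms are skipped with a warning.
* **Ensemble RMSF**: models are superposed onto model 1, the mean
  structure is the reference, and the per-residue CA fluctuation is
  returned.  This identifies mobile segments (e.g. a disordered terminus)
  to exclude from differential-contact analysis.
* **SASA**: an own Shrake–Rupley implementation (deterministic Fibonacci
  sphere points, default 960 per atom, probe 1.4 Å, element vdW radii).
  Relative ASA divides by theoretical Gly-X-Gly maxima, so extended
  termini can exceed 100%.  The implementation is cross-checked in the
  test suite against an independent library implementation of the same
  algorithm.
* **Residue depth**: the solvent-accessible surface is approximated by
  the exposed probe-inflated sphere points from the SASA calculation;
  a residue's depth is the mean (or minimum, by option) over its heavy
  atoms of the distance to the nearest surface point.  An isolated atom
  has depth = atom radius + probe.  This construction is deterministic
  and dependency-free; it is validated by ordering and correlation
  properties (buried > exposed, depth anti-correlates with relative ASA),
  not by exact agreement with explicit-water depth servers.

## Model discrimination

**ContactScore** of a model is the number of constraint pairs whose
side-chain centroid distance (minimised over chain pairings) is strictly
below the cutoff (default 7 Å; the cutoff is a parameter so sensitivity to
the choice can be swept).  With n pairs the score is an integer in [0, n].

**rdepthscore** is the Pearson (optionally Spearman) correlation of
per-position RankScore against model-derived residue depth over shared,
non-active-site positions; active-site positions are excluded because
their sensitivity reflects function rather than burial.

**R_s** sums |ASA_xi − ⟨ASA_x⟩| / ⟨ASA_x⟩ over chain residues, where
⟨ASA_x⟩ is a per-residue-type reference average.  The packaged default
reference is the theoretical maximum scaled by a mean relative
accessibility of 0.35 — a documented approximation, since no curated
structure database is bundled; `refdata.reference_asa_from_models`
computes a bespoke table from any structure collection.  R_s is invariant
to jointly rescaling the profile and the reference.

**Recovery histograms** report, per half-open (lower, upper] RMSD bin of
width 0.5 Å (labelled by upper edge), the fraction of models satisfying a
selection predicate (e.g. ContactScore = n, or rdepthscore ≥ 0.6); empty
bins carry NaN.  `rank_models_by` orders models best-first (R_s ascending,
the other metrics descending; ties broken by model id).

## Differential contacts and structure arbitration

Contacts are side-chain centroid distances ≤ 7 Å, minimised over chain
pairings.  For NMR ensembles pose 1 is the default; a min-over-poses mode
reports the closest distance across the ensemble.  With helix annotations
(taken from PDB HELIX records) pairs within one helix segment can be
removed, restricting the map to inter-helical packing; a residue interval
flagged as mobile by ensemble RMSF can be excluded entirely.

Candidate parent-inactive-mutant positions are residues with contacts in
at least one of the two rival structures but with differing partner sets,
filtered by, in order: (i) the parent must not be charged; (ii) no
side-chain hydrogen bond between parent and partner (side-chain N/O
donor–acceptor distance ≤ 3.5 Å, no angular term — a deliberate,
deterministic simplification); (iii) at least two partners in one
structure; (iv) sequence separation from partners > 30, applied per
structure; (v) the partner sets must be positionally divergent — the
minimum over cross-structure partner combinations of |y_B − y_A| must
exceed 6.  Criterion (v) is read at set level; when the separation filter
leaves partners in only one structure the sets are maximally divergent and
the criterion passes vacuously.

`evaluate_suppressor_support` then judges each experimentally identified
(parent, suppressor) pair: it supports structure A, structure B, both or
neither according to whether the pair is within the contact cutoff in each
structure.  A set of suppressors that are contacts only in one structure
identifies that structure as the functional conformer.

## Thermal melts

The model is y(T) = LL + (UL − LL) / (1 + e^((Tm − T)/a)).  The exponent
is read as (Tm − T)/a — the only reading that yields a sigmoid rising to
UL with temperature.  Fitting is nonlinear least squares initialised from
the data extremes and the steepest-slope temperature; a fitted negative
slope is normalised by the equivalent (LL, UL, a) → (UL, LL, −a)
reparameterisation.  Failure modes (flat signal, inverted plateaus, Tm
outside the data range, non-convergence) raise an error carrying the best
iterate.  Temperatures are °C throughout.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed) and return their
ground truth, so each stage has a closed-loop recovery test without any
external download.

* **Helical bundles** (ring layout; poly-alanine; N, CA, C, O, CB per
  residue) provide contact-rich toys.  The **packed** layout buries a
  central helix; the **compact globule** (jittered cubic lattice,
  ~3.6 Å spacing) is space-filling and provides a genuine depth gradient
  from ~3 Å at the surface to ~8 Å in the core.
* **Decoy sets** displace each residue by window-correlated Gaussian
  noise (default window 5 residues, amplitudes 0.5–8 Å cycling), scaled
  to a per-model amplitude; true backbone RMSD is computed by
  superposition.  Perturbation is Cartesian, not dihedral: it guarantees
  coverage of an RMSD range without a folding engine, at the price of
  unphysical covalent geometry, which none of the scorers consume.
* **Rival conformation pairs** swap two helices between bundle slots, the
  synthetic analogue of a domain-swapped alternative structure; the truth
  list contains inter-helix pairs ≤ 6.5 Å in A and > 8 Å in B, so planted
  pairs satisfy the 7 Å contact definition with margin on both sides.
* **Read tables** keep ~1000 reads per mutant until the planted MS_seq
  level and drop eightfold from there (comfortably past the fivefold
  detection threshold), with negative-binomial noise (default
  overdispersion 0.02, the mild regime typical of amplicon sequencing;
  at this default the drop rule recovers ≳98% of planted scores).
* **Depth-linked sensitivity tables** map normalised depth through a
  linear burial signal with Gaussian noise (default sd 0.1) to per-class
  MS_seq spans: aliphatic substitutions stay tolerated when buried (2–4),
  polar/charged ones reach 9, aromatics intermediate; a deterministic
  per-substitution dither smooths the integer staircase so position means
  vary smoothly with depth.
* **Melt curves** evaluate the sigmoid and add Gaussian noise.

What the generators do **not** emulate: real rotamer packing, sequencing
artefacts beyond overdispersion (no barcode errors or jackpots), loop
regions (bundle "loops" are numbering gaps), physically plausible decoy
energetics, or buffer/dye effects on melt curves.  Passing the synthetic
recovery suite therefore demonstrates the correctness and calibration of
the algorithms under their stated assumptions, not performance on any
particular experimental dataset; the published-geometry checks against
deposited structures (`tests/test_acceptance.py`) cover the latter and
require the reference coordinate files described in
`data/structures/README.md`.

## Numerical choices and problem sizes

Sphere quadrature uses 960 points per atom for SASA (per-residue areas
change < 2% on doubling) and 240 for depth surfaces.  Contact cutoffs are
strict `<` for ContactScore and inclusive `≤` for differential-contact
maps, following their respective definitions.  Recovery bins are
(lower, upper].  Ties in model ranking break by model id; altloc ties
resolve to the first-listed conformer.  Fixed 4-decimal TSV formatting
makes workflow reruns byte-identical.

The default test and acceptance runs use: globules of 60 residues,
bundles of 4×15 or 7×10 residues, decoy sets of 40–120 models, 200
random rank tables (1000 in the test suite), 50 read-simulation seeds,
200 melt replicates, and 20 decoy-monotonicity seeds — sizes chosen so
the whole synthetic battery completes in well under a minute while every
statistical assertion retains a comfortable margin.

## Known limitations

* The depth approximation measures distance to the accessible-surface
  point cloud; it is faithful for ordering and correlation but not
  calibrated to explicit-water depth values.
* The default ⟨ASA_x⟩ table is a scaled-maximum approximation; R_s values
  are comparable within a run, not across reference tables.
* The hydrogen-bond filter is distance-only and operates on side-chain
  N/O heavy atoms.
* Whether published per-residue depth values were atom-minimum or
  residue-mean aggregated is not always stated; both aggregations are
  exposed (`aggregate="mean"` default).
* RankScore's upper range depends on the population composition (see
  above); no clipping is applied.
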
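# Methods

## The contact criterion

`pipistack` detects face-to-face planar pi-pi contacts between sp2 planar
groups in protein structures.  A planar group is one of the nine
sp2-bearing sidechains (Trp, Phe, Tyr, His, Arg, Gln, Asn, Glu, Asp), the
backbone peptide unit spanning residues i/i+1, or the C-terminal carboxyl.
Each group carries a unit plane normal computed as the cross product over a
fixed three-atom triple.  Two groups are in planar pi-pi contact when, with
the default `ContactCriteria`:

* at least **2** heavy-atom pairs lie within the **4.9 Å** van der Waals
  threshold,
* points elevated **1.7 Å** above each plane (per atom, minimized over both
  normal signs of both groups) approach within **1.5 Å**, and
* the absolute dot product of the two unit normals is **≥ 0.8**
  (within ~37° of parallel).

All comparisons are inclusive.  Contacts are classified short range
(sequence separation ≤ 4 residues) or long range (> 4, or different
chains), and intra-chain / inter-chain within the asymmetric unit / crystal
symmetry image.  Symmetry contacts are kept but excluded from default
statistics; symmetry atom pairs closer than 1 Å are tallied as clashes.

Design choices where the construction was genuinely open:

* **Elevated-surface distance** is computed per atom (every member atom
  displaced along the normal), minimized over the four sign combinations.
  A plane-center construction would differ slightly for offset geometries;
  the `ContactCriteria` object keeps the elevation and cutoff swappable.
* **Member-atom tables** are the minimal chemically defensible pi systems
  (e.g. Phe/Tyr ring = CG..CZ with the Tyr OH excluded; Trp treated as one
  nine-atom planar system; Arg = NE,CZ,NH1,NH2).  They ship as editable
  package data (`data/sp2_groups.json`) so alternates are testable.
* **Peptide connectivity**: C(i)–N(i+1) ≤ 1.8 Å defines a bonded unit;
  chain breaks produce no unit.  Groups missing any expected heavy atom are
  skipped and counted, never silently imputed.
* **First-altloc rule**: the first conformation in file order is kept,
  matching a survey convention of taking the first coordinate set.
* Sequence separation between two groups is the minimum index distance
  between their residue-index sets (a peptide unit occupies both flanks),
  measured on a contiguous internal 0-based index.

The accelerated detector prefilters candidate pairs with a KD-tree on group
centroids at radius `cutoff + 2 r_max`; this is conservative, so results
are identical to exhaustive evaluation (enforced by tests against the
all-pairs oracle).

## Survey statistics

Contact frequencies are counts divided by residues considered, with the
annotated chain as the unit of observation.  Involvement counts a residue
when any of its atoms participates in a planar contact; backbone contacts
involve both flanking residues.  Resolution binning groups structures by
exact resolution and rolls bins of fewer than 100 entries into the next bin
within 0.25 Å; regression against bin means uses weighted least squares
(statsmodels WLS) with bin sizes as weights.  Error bars are block
bootstrap standard errors: whole PDB entries are resampled with
replacement (default 10,000 iterations, seeded), never individual residues.
The high-resolution subset is defined as resolution ≤ 1.8 Å and R-factor
≤ 0.18, configurable.  Distances from regular secondary structure use the
DSSP one-letter alphabet with H/G/E as ordered; signed distances cap at ±7
(negative inside elements, positive inside loops).

## The sequence-based frequency predictor (stage 1)

The predictor is an empirical statistical potential.  The frequency table
keys on (group identity, partner residue type, separation class, contacted
category) with 9 sidechain identities and 400 ordered-dipeptide backbone
identities.  Opportunities count every (group, candidate partner residue,
category) pair in a chain, making each cell a proper conditional rate.

**Smoothing.**  Cells are shrunk toward a multiplicative prior,
`mu_identity × (class partner rate / class rate)`, with 50
pseudo-opportunities (the `floor`).  Plain additive count smoothing pulls
rates of order 10⁻³ toward ½ and was rejected; the multiplicative prior
reflects that rates factor approximately into an identity level and a
partner-type preference.

**Context expectation.**  The raw expectation for a group is the mean table
frequency over all residues within ±40 positions (truncated at termini),
with the separation class implied by each offset.  This yields 4 absolute
values per group: {short, long} × {contacted sidechain, contacted
backbone}.

**Calibration.**  Raw expectations are mapped to realized frequencies via
20 equal-population percentile bins whose bin means are post-smoothed with
isotonic regression, so calibration is monotone.  Identities with fewer
than 2,000 calibration groups use the pooled map of their class (sidechain
or backbone); identity means are kept whenever present so the *relative*
channel (prediction minus identity mean) still centers per identity.
Fitting is split-half **cross-fitted** (`fit_predictor`): the table is
tallied on one half of the chains and the calibration on the other,
because calibrating against a table that already contains a group's own
contacts inflates the apparent raw→realized slope and mis-calibrates new
sequences.  At the scale of a full structural database the per-identity
maps would dominate; the pooling threshold and bin count are parameters.

The profile for a sequence contains 8 channels per sp2 group:
{short, long} × {contacted sidechain, contacted backbone} ×
{absolute, relative}.

## The PScore (stage 2)

Profiles are flattened to per-residue tracks: sidechain groups attach to
their own residue, backbone units to both flanking residues, averaging
where several groups attach.  Each scored component is one of the 8
channels, plain or weighted by the carbon count of the contributing group
(16 candidates), aggregated by a window statistic — the maximum mean over
contiguous windows of a component-specific length drawn from
{10, 20, 40, 60, 80, 100, 140}, with a top-60-±5 expansion mode available —
and combined as a weighted sum into a raw score.  The PScore is the raw
score in standard deviations above the mean of the background set; **≥ 4.0**
is the confidence threshold.  Scoring refuses sequences shorter than 140
residues (an explicit error, never a silent zero), matching the length
floor below which the score is unvalidated.

**Training** maximizes `z(lowest-scoring training positive) − z(mean of the
top 1% of the background)` in background z units, by seeded hill climbing:
Gaussian perturbations of one weight (80% of proposals) or a discrete
window-length move (20%), accepting only improvements, stopping after a
plateau of 2,000 consecutive rejections (default), with random restarts.
Aggregates over the window grid are precomputed per sequence, so proposals
are cheap re-weightings.  The accepted-objective trace is stored in the
model and is non-decreasing by construction.  Models serialize as JSON with
seed, plateau, window grid and objective embedded.

## Evaluation

ROC curves are empirical step functions; the AUC is computed from midranks
and equals the normalized Mann–Whitney U with ties counted ½ (the
independent cross-check in the tests uses `scipy.stats.mannwhitneyu`).
Bootstrap AUC errors resample both score sets with replacement.  Sequence
similarity uses L1 distances between normalized 400-cell dipeptide
profiles (range [0, 2]); complexity uses Shannon entropy of the amino-acid
composition in bits.

## Synthetic data: what it emulates and what it does not

All fixtures are generated programmatically and are seed-deterministic.

* **Geometry fixtures** place idealized planar groups (regular hexagon with
  1.39 Å bonds, planar amide with 1.33 Å C–N) at exact gaps, in-plane
  offsets and tilts, embeddable in minimal PDB files; random fields draw
  uniform positions and orientations so pairs straddle every criterion
  boundary.
* **The annotation corpus** emulates the *statistical* shape of a survey of
  folded chains: per-opportunity contact rates
  `(base + slope × flex) × partner_weight`, where `flex` is the G/S/T/P
  fraction within ±40 of the group.  Defaults are scaled so backbone units
  see a few percent involvement and residues ~10–50% across the composition
  range, with short-range rates an order of magnitude above long-range
  per opportunity, as in folded proteins.  Chain compositions mix a
  folded-protein background (UniProt-average frequencies, hard-coded) with
  a flexible composition at chain-specific weights up to 0.6, providing the
  context variance the predictor learns from.
* **Solvation / secondary-structure / interface corpora** draw involvement
  events directly: linearly increasing with per-residue water counts
  (Poisson-distributed), following a sigmoid from 9.5% deep in helices and
  strands to 16% deep in loops, and exchanging non-local intra-chain for
  inter-chain contacts at interface positions with conserved totals.
* **Sequence sets** tile the dipeptide repeats associated with high planar
  pi-contact frequency (Pro-Gly, Phe-Gly, Ser-Arg, Tyr-Gly, Arg-Gly) with a
  configurable mutation fraction for positives, against i.i.d.
  folded-composition backgrounds, all ≥ 140 residues.

What passing these tests shows: the criterion geometry, the bookkeeping of
every statistic, and the end-to-end identifiability of the two-stage
predictor under known generating conditions.  What it does not show:
performance on real structures, which have packing geometry, composition
correlations and redundancy structure the corpus does not model.  The
paper-scale survey numbers require a current non-redundant high-resolution
PDB snapshot, which this repository does not download.

## Problem sizes

Default test and acceptance runs use a 240-chain corpus (chains of 180–300
residues; the binned reliability slope needs roughly this much held-out
data before its sampling error is small relative to the recovery band), 300–1,000 random geometry fields, 50–60-chain profile corpora,
22 positive and 130 background sequences, hill climbing with plateau 1,000
and two restarts, and 200-iteration bootstraps inside tests; these sizes
were chosen so the whole pipeline recomputes in minutes while leaving the
estimators enough data to meet their stated recovery bands.

## Known limitations

* Published predictor weights are not reproduced (the original parameter
  listing is not redistributed); models are versioned artifacts trained by
  the shipped procedure.
* Trp is treated as a single planar system; whether the original split the
  two rings is unknown — the config table makes the alternative testable.
* The backbone-partner bookkeeping counts a contacted peptide unit at both
  of its flanking residues, mirroring the involvement convention; this
  smears partner attribution by one position.
* NMR ensembles (beyond the first model), ligand sp2 perception, hydrogen
  bond and catalytic-site analyses are out of scope.
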
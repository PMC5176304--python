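# Methods

This note documents the models implemented in `uripeg`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Structure model and PDB I/O

`structio` parses fixed-column PDB v3.3 ATOM/HETATM records into a minimal
atoms→residues→chains model. Hydrogens and waters are always dropped: the
surface-area scan is heavy-atom based by convention, and crystallographic
waters are not part of the protein surface being engineered. Alternate
locations are resolved at parse time — highest occupancy wins, ties go to
the alphabetically first conformer — so every downstream number is a
deterministic function of the file. Unparseable records fail loudly with
the line number rather than being skipped.

Subunit correspondence is by residue *number* only. The tetramer files this
pipeline targets share numbering across chains; when residue names disagree
at a shared number the mapper raises instead of guessing an alignment,
because a silent mis-mapping would corrupt the all-subunit criterion.
Positions absent from any chain are excluded and reported. The reader does
not generate biological assemblies from symmetry records: the oligomer must
already be present in the file, and the 2YZB script refuses files with
fewer than four chains.

## Solvent-accessible surface area

SASA is computed by the Shrake–Rupley method: each atom's van der Waals
sphere is inflated by the probe radius (1.4 Å, a water molecule) and covered
with `n_points` quasi-uniform points from a deterministic golden-angle
spiral; the accessible area is the inflated-sphere area times the fraction
of points outside every neighbour's inflated sphere. No random numbers are
used anywhere.

* **Radii.** Element-based: C 1.70, N 1.55, O 1.52, S 1.80 Å (default
  1.70 for anything else), with a Bondi-flavoured alternate set shipped.
  Per-residue totals near the 100 Å² selection threshold can move by a few
  Å² between radii conventions, so the radii-set name is stamped into every
  result.
* **Point count.** 960 by default; the two-sphere closed-form case
  (4πR² − 2πRh) converges through 96/240/960 and is within 2% at 960.
* **Orientation frames.** Each atom's point set is oriented in a local
  frame built from its neighbour geometry (first axis toward the nearest
  neighbour, second from the nearest non-collinear one). Because the frame
  co-rotates with the molecule, computed areas are exactly invariant under
  rigid motion, not merely approximately so; when all neighbours are
  collinear the occlusion pattern is axially symmetric and the azimuthal
  choice cannot affect the result.
* **Occlusion set.** Hetero atoms (the bound substrate) are excluded before
  the computation by default, so candidate conjugation sites are not
  artificially shielded by a ligand that is absent in the product molecule.
  A flag restores ligand occlusion for sensitivity checks.
* **Neighbour search.** A KD-tree prunes the occluder list; a brute-force
  all-pairs path is retained and tested to produce bitwise-identical areas.

## Conjugation-site selection

The three criteria mirror the engineering logic for PEGylating a
homotetramer: (i) exposure — per-subunit total residue SASA strictly
greater than 100 Å²; (ii) active-site protection — Cα strictly more than
25 Å from the C5 atom of *every* bound substrate copy; (iii) mutual
separation — the selected subset's Cα atoms at least 19.5 Å apart, where
the pair distance is the *minimum over all subunit combinations* (same
chain included), since a PEG clash is a whole-oligomer steric constraint.
Criteria (i) and (ii) must hold in every subunit. The distance between
copies of the *same* position on different subunits is reported as a
diagnostic but not used for rejection: every copy of a chosen site is
PEGylated by design, so same-position proximity is evidently tolerated.

Candidate counts are single-digit on a real tetramer, so subset selection
is an exhaustive enumeration (maximum size, then maximum summed
minimum-per-chain SASA, then lexicographically smallest residue numbers).
The tie-break beyond separation is a package convention — the final choice
among feasible sets in practice involves judgment the criteria do not
capture — so the report carries all candidates and the full matrix, not
just the winner.

## Sequence utilities

Pairwise identity uses Needleman–Wunsch global alignment (Biopython,
BLOSUM62, gap open 10, extend 0.5) with identity defined as identical
columns over total alignment length, gaps included. Published identity
tables produced by other programs/definitions can differ by a few
percentage points, so cross-tool comparisons should be treated as soft.
Consensus is per-column majority of non-gap residues; columns with a strict
gap majority are dropped; frequency ties resolve alphabetically (an
arbitrary fixed rule recorded here). Average mass is the standard
average-isotope residue sum plus one water (Biopython); ε₂₈₀ follows the
Gill–von Hippel composition rule 5500·nTrp + 1490·nTyr + 125·n_cystine.

`refseq_synthetic` provides a *synthetic* 302-residue stand-in carrying the
documented landmarks of the native enzyme sequence (single RGD at 49–51,
single Cys inside the C-terminal extension HPIWSNIAGFC); it exercises the
motif/truncation mechanics but is not the real protein, and identities
against it are meaningless.

## Enzyme kinetics

Progress curves are A₂₉₂ readings every 20 s for 10 min. Conversion to
substrate concentration uses Beer–Lambert with ε₂₉₂ = 12,300 M⁻¹cm⁻¹ (a
literature convention for uric acid; configurable). In the synthetic
round trips the same ε maps both directions, so its value cancels and
nothing downstream depends on it.

The initial rate is the OLS slope over an early window: points up to 120 s
or 10% substrate depletion, whichever truncates first, minimum four points.
The window rule is a package convention (the assay software's exact rule is
not public); it is configurable and logged. The slope of a concave
depletion curve estimates the rate near the window midpoint, biasing rates
low by roughly half the fractional depletion over the window — with the
"tiny enzyme" convention used throughout the synthetic studies
(E₀ = 2.95×10⁻⁴ µM ≈ 0.01 µg/mL of a 33.88 kDa monomer) this bias is
below 0.1% and the fit recovers k_cat/K_M to 0.02%/0.09%.

The Michaelis–Menten fit is unweighted nonlinear least squares
(scipy `curve_fit`, trust-region with non-negativity bounds). Convergence
tolerances are tightened to 10⁻¹² because rates are numerically tiny
(nM/s scale) and the solver's default relative-decrease stop fires early
otherwise. k_cat is reported per monomer-equivalent enzyme concentration;
the enzyme-unit basis is a parameter, and k_cat is invariant to jointly
rescaling E₀ and the rates. Under 5% Gaussian rate noise with triplicate
wells at the 7 assay levels (a standard plate design), the median |k_cat|
error over 100 simulations is ≈ 2%.

Serum (quench-mode) assays cannot be read continuously at 292 nm; rates are
instead the slope of acid-quenched readings at 0/1/2/4/6 min and feed the
same fit.

## Pharmacokinetics

IV profiles are fit by OLS of ln(conc) on time over *all* positive samples
— the PEGylated species eliminate mono-exponentially, and using the whole
profile mirrors a single-phase linear fit rather than automated terminal
selection. λ_z = −slope, t½ = ln2/λ_z, c₀ = exp(intercept),
V_d = dose/c₀ (L/kg for an mg/kg dose with µg/mL concentrations — the
dose-to-concentration unit factor is explicit), CL = λ_z·V_d. A log-linear
r² below 0.95 (configurable) raises a lack-of-fit warning: that is the
signature of the atypical fast-initial-elimination profiles seen with
hyper-PEGylated comparators, which this model deliberately does not fit.
For SC dosing, only the terminal half-life is estimated (ln-regression on
the last post-peak points); V_d and CL are absorption-confounded for an
extravascular dose and are omitted rather than reported wrong.

## Stimulation-index statistics

Per donor, an OLS linear model with condition as the only factor estimates
the mean well counts; with a single two-level factor this reduces in closed
form to the group means with a pooled residual variance, which is what the
implementation computes (identical numbers, no per-donor model object).
SI = mean(treated)/mean(reference); its standard error comes from the delta
method, H₀: SI = 1 is tested against a t distribution on n_t + n_r − 2 df,
and the responder rule is SI ≥ 2 *and* p < 0.05 — the SI gate is a
pre-set assay convention, the p-value a supporting screen. No
multiple-testing correction is applied across donors: responder calling is
a per-donor decision by design, and the population summary simply counts.
A log-count formulation is a reasonable alternative the data shapes would
support; the ratio-of-means contrast was chosen because it matches the SI
definition directly.

## Synthetic generators

All generators are pure functions of their parameters and an explicit seed.

* **Toy oligomer.** Pseudo-residues (N/CA/C triads) on a sphere (default
  radius 60 Å) inside one wedge of a Cn rotation (default C4); other chains
  are exact z-rotations, so equivalent positions have identical
  environments and per-chain SASA agrees to machine precision. Buried
  positions are entombed in a 60-atom golden-spiral cage (cage residues
  carry no Cα and are therefore skipped — and reported — by the scan); one
  single-atom "C5" ligand copy per subunit sits near the center, far inside
  the 25 Å criterion for all planted positions. A placement that would let
  planted residues occlude each other raises a geometric-infeasibility
  error rather than producing a wrong planted truth. This toy validates
  criteria logic and selection exactly, but it is not protein-like: no
  side chains, no packing, no partial burial — it says nothing about how
  close a real residue sits to the 100 Å² threshold.
* **Progress curves.** dS/dt = −k_cat·E₀·S/(K_M+S) integrated by
  fixed-step RK4 at 1 s (cross-checked against an adaptive integrator to
  10⁻⁶ relative), sampled on the 20 s grid, mapped to absorbance, optional
  additive Gaussian read noise.
* **PK profiles.** IV: c(t) = c₀·2^(−t/t½). SC: one-compartment
  first-order absorption c(t) = A(e^(−k_e t) − e^(−k_a t)) scaled to a
  requested peak; noise is multiplicative lognormal with a given CV.
* **PBMC counts.** Negative-binomial wells with Var = m + φm² (φ = 0.1 by
  default — an overdispersed, realistic per-well null; φ→0 recovers
  Poisson). Treated wells scale the mean by the planted true SI. The ratio
  of sample means is slightly biased upward (≈ cv²_ref/n ≈ 1.4% at the
  defaults), well inside the 5% recovery tolerance used in tests.

## Problem sizes used in the automated suites

Round trips run at the study conditions: 7 substrate levels × 31 samples;
9 IV timepoints; 7 SC timepoints; 8 replicate wells per condition with
1,000 donors for the null simulation and 200 for planted-SI recovery; 50
randomized toy oligomers (2–4 subunits, 5–7 positions) for the exhaustive
site-selection oracle.

## Known limitations

* The PDB reader handles the fixed-column subset it documents (no mmCIF,
  no symmetry expansion, no chain-break heuristics).
* Identity values depend on the alignment convention; no attempt is made to
  match any specific published alignment program.
* The kinetics model excludes substrate inhibition and cooperativity; the
  PK model is strictly mono-exponential (biphasic data warn, not fit).
* The immunology model treats wells as exchangeable replicates; plate
  layout and batch effects are outside the model.
* The toy oligomer's planted truth concerns the selection *logic*; real
  structures exercise radii sensitivity that the toy cannot.
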
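# Methods

This note documents the models, parameter choices, and numerical
conventions behind each pipeline stage, what the synthetic generators do
and do not emulate, and the known limitations.

## Composition profiling

Constituent concentration is the peak's share of total integrated area,
`100·A_i/ΣA_i`. Percentages are computed at full precision and rounded to
one decimal only for presentation; all downstream arithmetic (sums,
major-component cutoffs) uses the unrounded values. Duplicate compound
names are allowed (isomers elute separately); uniqueness is keyed on peak
index. Input headers are matched case-insensitively and column order is
free. The degenerate case ΣA = 0 is an error rather than a NaN propagation.

The packaged 17-peak guava-leaf table uses all seventeen integrated peaks
as the denominator; the printed shares of the major constituents are
reproduced from the raw areas to within 0.03 percentage points, which is
consistent with that convention.

## Assay statistics and the logarithmic dose–response fit

Percent inhibition and percent viability are the plain ratio formulas of
the two assays. Replicates are summarized as mean ± SEM (sample SD/√n);
a single replicate yields SEM 0 with a warning. Untreated controls define
100% viability by construction.

The dose–response model is `y = a·ln x + b` — a deliberately logarithmic,
two-parameter form rather than a four-parameter logistic: the assay data
this pipeline targets are reported and plotted on that form, it is exactly
solvable, and with typical 6-point designs a 4PL would be under-determined.
The fit is ordinary least squares of response on ln(concentration)
(concentrations strictly positive, µg/mL throughout, no unit inference);
`r²` is the squared Pearson correlation of fitted vs observed. IC50 is
defined at 50% response exactly, `exp((50 − b)/a)`, not at half of the
fitted maximum. A fit with non-positive slope whose responses span 50% is
reported but flagged unreliable rather than rejected.

When replicate columns are available, the pipeline fits each replicate
series separately and reports the mean ± SEM of the per-replicate IC50s;
this is the assumed provenance of published IC50 ± SEM values and is noted
as such in the output.

## Docking post-processing

The pipeline consumes docking outputs; it never runs docking. The grid-box
geometry of the ER-α setup (center 29.944, −1.861, 24.611; size
18 × 14 × 18 Å) is carried as provenance metadata only.

- **Hit filter**: affinity ≤ threshold, inclusive (−8.0 kcal/mol default),
  input order preserved. Known misspellings in published score tables
  ("Copaane", "Limonenel", "Cryophyllene") are normalized to the GC-MS
  constituent names and flagged.
- **Pose RMSD**: atoms are matched by file order, which docking engines
  preserve. No graph-automorphism symmetry correction is applied — for
  molecules with topologically equivalent atoms (e.g. gem-dimethyl) the
  reported RMSD can exceed the symmetry-corrected one. Superimposition is
  the optimal least-squares rotation (Kabsch, via
  `scipy.spatial.transform.Rotation.align_vectors`) after centroid removal.
- **Contacts**: residues with any heavy-atom pair ≤ 4.5 Å (configurable),
  reported with the minimum distance, sorted ascending.
- **Hydrogen bonds**: N/O donor with an attached H (attachment = H within
  1.25 Å), N/O acceptor, D–A ≤ 3.5 Å and D–H···A ≥ 120°, both directions.
  Interaction subtypes (π-alkyl, π-σ, van der Waals) are deliberately not
  assigned; contacts are reported generically.

PDB files are read with gemmi; PDBQT (no reader among the scientific
Python libraries this package builds on) and XYZ use compact fixed-column
parsers, with AutoDock atom types mapped to elements and Vina `REMARK
VINA RESULT` scores extractable from multi-model output files. The first
model of a multi-model file is used unless another is selected. Waters are
stripped by default. Coordinates stay in the source frame.

## Electronic complementarity

### Density model

Each atom contributes a single-exponential outer-shell density

    ρ_a(r) = ρ(CNT)_a · exp(−ζ_a · r)

and a molecule's density at a point is the sum over its atoms. The
per-element defaults are derived, not fitted: ζ is twice the Slater-rule
orbital exponent of the valence shell (density ~ ψ², so it decays twice as
fast; ζ = 2(Z*/n)/a₀), and ρ(CNT) normalizes the shell to the valence
electron count, ρ(CNT) = n_val·ζ³/(8π). For hydrogen this reproduces the
exact 1s density at the nucleus (2.15 e/Å³), a useful sanity anchor.
Values shipped (element, ρ(CNT) e/Å³, ζ Å⁻¹): H 2.148/3.779, C 36.87/6.142,
N 79.64/7.370, O 151.75/8.598, P 43.99/6.047, S 77.27/6.866. The table is
overridable via a TSV (`element, rho_cnt, zeta, atomic_number`), and every
report echoes the table used. This is a declared model of the package:
multi-shell quantum-chemical density parameterizations exist and would
change the absolute regression coefficients, which is why cross-study
coefficient comparisons are only meaningful under the same table.

The "maximal-contribution" atom at a point is the atom with the largest
single term ρ(CNT)·exp(−ζr) — not the nearest atom; across elements the
two can differ. Ties break to the lowest atom index (deterministic).

### Point sampling

A cubic grid (default spacing 0.3 Å) covers the ligand bounding box padded
by 4 Å. A grid point enters the profile when both molecular densities lie
in a band (default 1e-4 to 1e-1 e/Å³ — the thin low-density shell between
the molecules) and the point is at least a clash floor (1.0 Å) from every
atom. The procedure is deterministic; no Monte-Carlo sampling. The band is
the package's declared selection rule for "points of the intermolecular
space"; widening it toward the atomic cores or vacuum degrades the
linearity of the CF1–SUMRLRE relation, which is the intended behaviour of
the filter, not a tuning target. Zero surviving points is a warning (the
profile then refuses to regress fewer than 3 points).

### Regression and selection rules

CF1 is regressed on SUMRLRE by ordinary least squares;
`Rcor²` is the squared Pearson correlation and `Sigma` the residual SD
√(SSR/(n−2)) (the conventional reading of a regression's dispersion
column). The summary row carries (a_CF1, b_CF1, Rcor², Sigma, Npoints,
MIN(SUMRLRE), MAX(CF1)). A complex passes the selection rules when
Rcor² ≥ 0.81 and MAX(CF1) ∈ [−5, −2]; when a reference (experimental)
complex is supplied, the coefficient gaps |a−a_ref|, |b−b_ref| are reported
without a hard cutoff, since "as close as possible" is a ranking criterion,
not a threshold.

Exact closed-form anchor: with one atom per molecule and a shared ζ,
CF1(m) = const − ζ·(R_me + R_ml), so the regression must return slope −ζ
with Rcor² = 1 to machine precision regardless of point placement; this is
enforced in the tests at 1e-9.

## Druglikeness

Violations: MW > 500, MLOGP > 4.15, HBA > 10, HBD > 5; druglike ⇔ ≤ 1
violation. The lipophilicity rule uses the MLOGP-specific 4.15 threshold,
not the generic logP ≤ 5 form. HBA is the count of N and O atoms, HBD the
count of N/O atoms bearing ≥ 1 hydrogen (so water counts one donor group).
A bare molecular formula supports MW and HBA but not HBD — donor counting
demands a structure and says so.

Molecular weights use the 2005 IUPAC standard atomic weights (C 12.0107,
H 1.00794, O 15.9994, ...), pinned as a documented constant table so that
printed two-decimal MWs of the packaged compounds reproduce exactly.

### MLOGP

The Moriguchi 13-descriptor regression, implemented on RDKit graphs:

    MLOGP = 1.244·CX^0.6 − 1.069·NO^0.9 + 0.406·PRX − 0.145·UB^0.8
            + 0.511·HB + 0.268·POL − 2.215·AMP + 0.912·ALK − 0.392·RNG
            − 3.684·QN + 0.474·NO2 + 1.582·NCS + 0.773·BLM − 1.041

Descriptor conventions of this implementation:

- **CX**: carbons weight 1.0; halogens F/Cl/Br/I weight 0.5/1.0/1.5/2.0.
- **NO**: count of N and O atoms. Secondary sources disagree on this
  term's coefficient (−1.017 vs −1.069); this package uses −1.069, which
  reproduces published two-decimal MLOGP values of oxygenated terpenes
  exactly, where −1.017 is systematically 0.05 high.
- **PRX**: N/O proximity — bonded pair 2, 1,3-pair through C/S/P 1.
- **UB**: double/triple bonds of the Kekulé structure (triple counts 2),
  excluding bonds inside nitro groups; aromatic rings contribute their
  Kekulé double bonds.
- **ALK**: 1 for pure hydrocarbons with at most one *aliphatic* multiple
  bond; aromatic bonds do not count against it, so an aromatic hydrocarbon
  with no aliphatic unsaturation (e.g. calamenene) qualifies. This is this
  package's convention, chosen because it reproduces published values for
  aromatic sesquiterpenes; the original descriptor prose ("alkane, alkene,
  cycloalkane, cycloalkene") is ambiguous on aromatics.
- **RNG**: 1 if any ring is not a pure-carbon aromatic ring (saturated,
  heterocyclic, or heteroaromatic rings count; benzene rings do not).
- **HB/POL/AMP/QN/NO2/NCS/BLM**: SMARTS-based flags for intramolecular
  H-bonding (ortho donor/acceptor on an aromatic ring), aromatic polar
  substituents, α-amino acids, quaternary N (1.0) / N-oxide (0.5), nitro,
  iso(thio)cyanate, and β-lactam. For the terpene/terpenoid chemical space
  this pipeline targets these are almost always zero; molecules leaning on
  them (peptides, alkaloid salts) are outside the validated domain.

Molar refractivity uses the Wildman–Crippen atomic-contribution scheme via
RDKit. It is informational: published reference tables list it but never
base a violation on it, and published MR values (from a different
implementation and structure set) differ from RDKit's by ~1–2 cm³/mol.

## Synthetic data

All generators draw from one `numpy.random.default_rng(seed)` per call;
the same seed reproduces tables and files byte-for-byte, and the seed is
recorded in output headers. Defaults are the study conditions the pipeline
targets: six assay concentrations from 3.1 to 100 µg/mL with a = 11.08,
b = 12.68 and 2% Gaussian noise in triplicate; 17-peak chromatograms with
log-normal areas; 17-row affinity tables uniform on [−10, −5] kcal/mol
around the −8 threshold; toy complexes of 50 protein-like atoms (C/N/O/S,
Gaussian cluster, σ = 2 Å, glycine-labelled so contact analysis works) and
10 ligand atoms, with `separation` defined as the closest inter-atomic
gap (solved by bisection on the +x shift) so an intermolecular shell of
known width always exists; and (SUMRLRE, CF1) clouds with a = 6.4,
b = −4.0, σ = 0.3 over SUMRLRE ∈ [2.4, 4.5], the coefficient scale of
experimentally derived complexes.

What the generators do **not** emulate: chromatographic peak overlap and
detector nonlinearity; plate effects and heteroscedastic assay noise;
docking-score correlation with ligand size; real protein topology (the
toy "protein" is an unbonded atom cluster) and real charge distributions.
Passing tests therefore demonstrate the correctness of the arithmetic,
geometry, and statistics on data with the assumed structure — not
robustness to instrument artifacts, nor accuracy of the density model
against quantum-chemical references.

## Problem sizes and numerical conventions

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path: 6-point dose–response fits (500-seed recovery study),
100-point CF1 clouds (200-seed recovery study), toy complexes sampled at
0.3–0.6 Å spacing (tens to hundreds of shell points), and 1,000-configuration
argmax cross-checks. Published per-complex tables with ~5,600 grid points
correspond to finer spacing over a real binding site; the profile machinery
is identical, only the grid is larger.

Ties and degeneracies are deterministic throughout: argmax ties to lowest
index, grid anchored at the padded bounding-box corner, OLS via
`scipy.stats.linregress`. Errors are typed (schema, parse-with-row,
degenerate-input, insufficient-data, unknown-element) so callers can
distinguish bad files from bad science.

## Known limitations

- The density model is a single-exponential valence shell; absolute CF1
  levels and regression coefficients are parameter-table-dependent.
  Published per-complex coefficient values computed with proprietary
  multi-shell parameterizations are reproduced in schema and selection
  logic, not numerically.
- RMSD without symmetry correction over-reports for symmetric ligands.
- MLOGP is validated on hydrocarbon/oxygenated-terpene chemical space;
  the rarely-hit descriptors (AMP, HB, POL) implement minimal SMARTS
  interpretations.
- The bioassay module fits summaries (means or replicate series), not
  raw plate files; blank correction beyond a supplied control is out of
  scope.
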
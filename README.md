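# phytoscreen

A screening pipeline for essential-oil phytochemistry, built around the
workflow used to profile guava (*Psidium guajava*) leaf oil and screen its
constituents against the estrogen receptor α: GC-MS composition profiling,
radical-scavenging and cell-viability assay statistics, docking
post-processing, electronic-complementarity scoring of enzyme–ligand
complexes, and Lipinski/MLOGP druglikeness evaluation. Every stage runs
self-contained — the small reference tables and structures are packaged, and
seeded generators produce synthetic inputs for everything else.

It is aimed at natural-products and molecular-modelling groups who have a
chromatogram, a plate reader export, and a directory of docking outputs, and
want the downstream numbers computed reproducibly instead of by spreadsheet.

## What it computes

**Composition.** A GC-MS peak's area percentage is `100·A_i / ΣA`, the
standard semi-quantitative measure of a constituent's share of the oil.

**Dose–response.** Percent inhibition is `100·(A_ctrl − A_sample)/A_ctrl`
(DPPH) and percent viability `100·OD_sample/OD_ctrl` (MTT). The
dose–response model is logarithmic, `y = a·ln x + b`, fitted by ordinary
least squares on `(ln x, y)`; the half-maximal inhibitory concentration is
solved at exactly 50% response, `IC50 = exp((50 − b)/a)`.

**Docking post-processing.** Hits are ligands with predicted affinity
≤ −8.0 kcal/mol (inclusive). Pose agreement is RMSD with atoms matched by
file order, optionally after Kabsch superimposition; binding-site analysis
is geometric (4.5 Å heavy-atom contacts; hydrogen bonds with D–A ≤ 3.5 Å
and D–H···A ≥ 120°).

**Electronic complementarity.** At grid points *m* of the intermolecular
shell, the complementarity factor

    CF1(m) = ln(ρ_E·ρ_e(CNT)/N_e) + ln(ρ_L·ρ_l(CNT)/N_l)

combines the enzyme and ligand electron densities at *m*, normalized by the
center density and atomic number of the two maximal-contribution atoms
*e*, *l*. With `SUMRLRE = R_me + R_ml` (distances from *m* to those atoms),
a complementary complex shows a tight linear relation
`CF1 = a_CF1 + b_CF1·SUMRLRE` with `Rcor² ≥ 0.81` and `MAX(CF1)` in
[−5, −2]. Atomic densities follow a declared single-exponential outer-shell
model (see `docs/methods.md`).

**Druglikeness.** Rule-of-five violations among {MW > 500,
MLOGP > 4.15, HBA > 10, HBD > 5}; druglike ⇔ at most one violation. MLOGP is
a local implementation of the Moriguchi 13-descriptor regression.

## Worked example

```sh
phytoscreen composition --in src/phytoscreen/data/guava_leaf_peaks.tsv --min-pct 4.0
```

```
peak  rt_min  compound       area       area_pct
3     17.6    Limonene       5248363.0  51.3
4     17.8    Eucalyptol     2177857.0  21.3
...
# major components: Limonene (51.3%), Eucalyptol (21.3%), Caryophyllene oxide (6.2%),
#                   Caryophyllene <(E)-> (5.6%), Nerolidol <(E)-> (4.5%)
```

Five constituents exceed 4% of the chromatogram area; limonene alone is
half the oil.

```sh
phytoscreen dpph --in src/phytoscreen/data/dpph_inhibition.tsv
```

```json
{"a": 11.078967757486275, "b": 12.6779743326791,
 "r2": 0.9520198007641696, "ic50": 29.04155422297015}
```

The scavenging curve rises ~11.1% per ln(µg/mL) and crosses 50% inhibition
at 29.0 µg/mL — the oil's antioxidant IC50.

```sh
phytoscreen dockfilter --in src/phytoscreen/data/er_alpha_affinities.tsv \
    --threshold -8.0 --exclude Hydroxytamoxifen
phytoscreen adme --in src/phytoscreen/data/compounds/caryophyllene_oxide.sdf
```

```
name                 mw      mlogp  hba  hbd  molar_refractivity  druglike
Caryophyllene oxide  220.35  3.67   1    0    66.26               Yes; 0 violation
```

The filter keeps the five ligands at or below −8 kcal/mol; the ADME table
shows caryophyllene oxide passing all four rules. Synthetic fixtures for
any stage come from `phytoscreen simulate dose-response|complex|affinity|peaks
--seed N --out dir/`, each with a machine-readable truth record.

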
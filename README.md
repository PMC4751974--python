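# ccscreen

Design of **heterospecific (mutually orthogonal) coiled-coil peptide pairs**
by virtual library expansion, quantitative interactome scoring and
constraint search.

Parallel dimeric coiled coils are built on a seven-residue repeat
[*abcdefg*]ₙ: the *a*/*d* residues pack the hydrophobic core, the *e*/*g*
residues flank it and form interhelical salt bridges. Within a library that
varies Asn/Ile at *a* and Glu/Lys at *e*/*g*, the stability of any candidate
dimer can be estimated from sequence alone with a bCIPA-style linear model
of the predicted melting temperature,

```
Tm = w_HP · HP + w_CS · CS + w_ES · ES + c
```

where **CS** is the summed *a–a′* core coupling energy (Ile–Ile −9.2,
Asn–Asn −2.4, Asn–Ile −0.5 kcal/mol), **ES** the summed *g–e′*/*e–g′*
electrostatic coupling energy (Glu–Lys −1.2, Glu–Glu +0.4, Lys–Lys
−0.3 kcal/mol) and **HP** the helical propensity of the component chains.
`ccscreen` expands a degenerate template into an explicit peptide library,
predicts the Tm of every pairwise interaction in the resulting interactome
(N peptides → N(N+1)/2 unordered pairs, homodimers included), and then
searches the stored high-affinity candidates for sets of two ("pairs") and
four ("quadruples") coiled coils in which every desired heterodimer is
stable while all off-target pairings — homodimers and cross heterodimers —
stay below user-set Tm ceilings. It is intended for protein engineers and
synthetic biologists assembling orthogonal dimerisation modules.

The package also ships two import-time filters (a homodimer-Tm cutoff and a
filter removing peptides whose *antiparallel* homodimer is fully
charge-complementary), and a utility for the experimental side: simulation
and least-squares fitting of two-state dimer thermal denaturation curves
plus dimer-exchange excess-helicity arithmetic.

> The published regression coefficients of bCIPA are not bundled; the model
> is a pluggable named coefficient set (config key
> `tm_model.coefficients`), and the shipped `demo-linear` placeholder only
> preserves the qualitative regime. Every free-energy identity below is
> independent of the coefficients.

## Worked example

Write the built-in reference inputs (the 27-position degenerate template
`phAALpAphAALpYphAALpAphAALp` with h = {N, I}, p = {E, K}, and the
eight-peptide reference set forming four orthogonal heterodimers):

```sh
ccscreen make-fixtures --outdir fx
```

Score one designed heterodimer:

```sh
$ ccscreen score-pair --a p1.fasta --b p2.fasta
field	value
idA	pep1
idB	pep2
orientation	parallel
tm_pred	73.06
dg_core	-23.20
dg_electro	-9.60
helicity	0.2270
```

The pair makes two Asn–Asn and two Ile–Ile core contacts
(2·(−9.2) + 2·(−2.4) = −23.2 kcal/mol) and eight attractive Glu–Lys flank
contacts (8·(−1.2) = −9.6 kcal/mol); `tm_pred` combines them under the
configured coefficient set. Run the full pipeline on the eight-peptide set:

```sh
$ ccscreen run --config octet_run.yaml --outdir out
{
  "library_size": 8,
  "rejected_homodimer": 0,
  "rejected_antiparallel": 0,
  "retained": 8,
  "evaluated_pairs": 36,
  "stored_interactions": 4,
  "pair_sets": 4,
  "quadruple_sets": 0
}
```

All 36 pairwise interactions are evaluated once; exactly the four designed
heterodimers clear the 70 °C candidate floor and enter the store
(`out/store.tsv`), while the 32 off-target pairings do not. Template
expansion works the same way at library scale: `ccscreen generate-library`
with the shipped template yields 4096 members, or 1536 with
`--constraint "a:N=2,I=2"` (exactly two Asn and two Ile at the four core
positions), whose interactome holds 1,180,416 pairs.

Other subcommands: `screen`, `find-pairs`, `find-quadruples`, `meltfit`.
Everything is also importable (`import ccscreen`); the CLI is a thin layer.

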
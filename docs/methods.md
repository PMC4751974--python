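# Methods

## The design problem

A set of coiled-coil peptides is *heterospecific* (orthogonal) when each
designated heterodimer forms preferentially while every other pairing in
the mixture — each peptide's homodimer and every cross heterodimer — is
destabilised below a working threshold. `ccscreen` searches for such sets
inside a combinatorial sequence library by (i) enumerating the library,
(ii) predicting the melting temperature of every pairwise interaction and
(iii) combining high-affinity candidates under off-target constraints.

## Register model

Peptides are stored with an explicit heptad register: a string over
`gabcdef-` parallel to the sequence, with `-` marking contiguous terminal
cap residues that never enter scoring. Non-cap positions must follow the
cyclic order g→a→b→c→d→e→f without gaps, so the register is fully
determined by a start letter and the cap lengths. The shipped design family
registers chains g-first and e-last: a four-heptad core then exposes all
eight e/g electrostatic contact slots with none dangling at a terminus.

Interhelical contacts are enumerated strictly in register (heptad *n*
against heptad *n*): the intended designs place Asn–Asn core pairs that pin
one axial alignment, so no stagger search is performed.

* parallel: *a(n)–a′(n)* core pairs; *g(n)–e′(n)* and *e(n)–g′(n)* flank
  pairs (the e sits five residues C-terminal of its heptad's g);
* antiparallel: *g(n)–g′(N+1−n)* and *e(n)–e′(N+1−n)* flank pairs; the
  buried contacts become *a–d′* and are enumerable but excluded from
  scoring by default because d is fixed Leu here and carries no
  specificity signal.

Chains of unequal heptad counts are paired over the N-terminal overlap with
a warning; only complete g..e spans produce electrostatic pairs. A peptide
with no complete g..e span is constructible (a warning, not an error, since
single-heptad fragments are legitimate inputs elsewhere) and simply yields
an empty electrostatic pair list.

## Library generation

A template is an ordered list of per-position residue-option sets, written
either as a protein string with user-defined wildcard symbols or as
degenerate IUPAC codons collapsed to residue options through the standard
genetic code (stop translations are flagged and dropped; a codon encoding
only stops is an error). Expansion streams members in lexicographic order
(sorted options fed to a cartesian product), so output is deterministic and
duplicate-free without materialising the library; the shipped 27-position
template (four binary a positions, eight binary e/g positions) expands to
2¹² = 4096 members. An exact-count composition constraint on one register
class filters during enumeration: requiring two Asn and two Ile at the four
a positions keeps C(4,2) = 6 of the 16 core arrangements and 1536 of the
4096 members.

## Scoring

For peptides A, B the predicted melting temperature is the linear form

    Tm(A,B) = w_HP·HP + w_CS·CS + w_ES·ES + c

* **CS** — sum of tabulated free energies over the parallel a–a′ pairs.
  Shipped table (kcal/mol): II −9.2, NN −2.4, NI −0.5.
* **ES** — sum over the orientation's electrostatic pairs. Shipped table:
  EK/KE −1.2, EE +0.4, KK −0.3. Breaking one salt bridge to E–E therefore
  costs exactly +1.6, to K–K +0.9.
* **HP** — mean per-residue helical propensity over the scored residues of
  both chains. The mean (rather than a sum) keeps the term
  length-independent. Per-chain means are memoised on the scored sequence,
  so each peptide is evaluated once per screen.

These tables make the reference octet an exhaustive identity suite: the
four designed pairs score (CS, ES) = (−23.2, −9.6); all eight homodimers
keep CS = −23.2 with ES penalties of +7.2 (all-Lys flanks) to +12.8
(all-Glu); the eight intrapair off-targets (within peptide sets 1–4 and
5–8) carry a core penalty of +21.2 (four Asn–Ile pairs); the sixteen
interpair off-targets +10.6 (one NN, one II, two NI); and all 24
heterodimeric off-targets carry ES penalties of +3.6 to +6.4. The tests
assert all 36 identities.

Missing table entries raise by default — silent zeros usually mean a
register mistake — with an explicit permissive `zero` policy for
exploratory libraries containing untabulated residues.

### Coefficients and helicity table

The regression coefficients of the published bCIPA fit, and its per-residue
helicity scale, are not bundled; absolute predicted-Tm values therefore
depend on what the user configures. The model is a named, pluggable
coefficient set (`tm_model.coefficients` in the config). The default
helicity table is the Pace–Scholtz consensus helix-propensity scale
(kcal/mol relative to Ala; lower = more helical), chosen because it is
public and covers all twenty residues. The default `demo-linear`
coefficients (w_HP = −20, w_CS = −1, w_ES = −9, c = −32) are a documented
placeholder with physically sensible signs, chosen once so the shipped
demo configuration is internally coherent: fully complementary
desired-type pairs clear the default 70 °C candidate floor, and every
Glu/Lys homodimer — including the all-Lys one, whose electrostatic penalty
(+7.2) is the smallest — falls below the default 10 °C import cutoff.
Nothing in the test suite or the acceptance script depends on these
magnitudes; all free-energy results are coefficient-independent.

## Interactome screen

Screening evaluates each unordered pair exactly once (N(N+1)/2 for N
peptides; 1536 → 1,180,416). When all peptides share one register layout —
always true for a template-derived library — the whole Tm matrix is
computed by vectorised 20×20 table-lookup broadcasts per contact slot,
which keeps the 1536-peptide screen at a few seconds on one CPU; mixed
layouts fall back to a per-pair loop, and a test asserts both routes agree.

Two import-time filters discard hopeless peptides before any cross
evaluation:

* homodimer cutoff — predicted homodimer Tm above `max_homodimer_tm`
  (default 10 °C);
* antiparallel filter (off by default) — the peptide's antiparallel
  homodimer makes a fully charge-complementary set of g–g′/e–e′ contacts
  (judged by charge sign, i.e. every contact pairs an acidic with a basic
  residue). Such chains gain stability in a geometry the parallel-only Tm
  model cannot see; in the reference octet exactly peptides 5–8 trip this
  filter. It is off by default because the library-scale pair-count
  milestones predate it.

Only interactions with Tm ≥ `min_desired_tm` (default 70 °C) are persisted
to the interaction store — a plain TSV long table (idA, idB, tm), not a
database server, since nothing in the method needs one. The full matrix
remains exportable on demand; exports are canonically ordered (idA ≤ idB,
rows sorted) and floats are printed with 17 significant digits, so
identical inputs give byte-identical, round-trip-exact files.

## Orthogonal-set search

Candidates are combined exhaustively with pruning. Two candidate
interactions sharing a peptide are skipped without scoring (cross-talk
through the shared chain is certain). For four distinct peptides the
10-pairing mini-interactome is built (2 desired + 4 homodimers + 4 cross);
the set is accepted iff every off-target Tm ≤ `max_offtarget_tm_pairs`
(default 20 °C) and min(desired) − max(off-target) ≥ `min_delta_tm_pairs`
(default 50 °C). Quadruples combine two disjoint 4-peptide sets into a
36-pairing mini-interactome (4 desired + 32 off-targets, homodimers
re-checked so acceptance is self-contained) against the laxer quadruple
thresholds (defaults 30 °C and 40 °C). ΔTm is defined worst-case:
min(desired) − max(all off-targets in the set). Sets are canonicalised
(sorted desired pairs) for deduplication and ranked by highest worst-case
desired Tm, then widest margin, then lexicographic peptide ids. Tests
check the pruned search against unpruned exhaustive enumeration on toy
instances, re-verify every emitted set with an independent checker, and
assert threshold monotonicity.

## Melt-curve utility

Unfolding of a dimer D ⇌ 2M at total monomer concentration Pt has
K_unf = 2·Pt·(1−f)²/f for folded fraction f. With ΔCp = 0 (the default; no
heat-capacity term is exposed because none is needed for the short peptides
this targets) and the midpoint convention f(Tm) = ½ — at which
K_unf = Pt — the Gibbs–Helmholtz expression reduces to
ΔG_unf(T) = ΔH_unf(1 − T/Tm) − RT·ln Pt. The observable interpolates
between linear folded/unfolded baselines. Concentrations are in mol/L
throughout (150 µM is passed as `150e-6`).

The simulator draws Gaussian noise from a seeded generator; the default
grid (−8…95 °C in 1 °C steps) and Pt (150 µM) emulate a stepped CD melt at
222 nm. The fitter runs bounded least squares over (Tm, ΔH, four baseline
parameters) from fixed start values: Tm at the steepest smoothed signal
change, ΔH = −50 kcal/mol, baselines from straight-line fits to the outer
15% of points. Convergence is flagged, never assumed: besides optimizer
failure, a fit is rejected when the Tm variance is non-finite or huge, or
when the fitted folded/unfolded baseline gap at Tm fails to clear 5× the
residual RMS — the signature of a flat curve, which any Tm fits equally
well. Affine rescaling of the signal axis changes only the baselines, so
the fitted Tm is invariant (tested). Parameter recovery on synthetic data:
the tests require a median |Tm_fit − Tm_true| < 0.5 °C at 1% signal-range
noise over 100 seeded curves spanning 40–80 °C.

What the simulator does *not* emulate: baseline curvature, ΔCp ≠ 0,
irreversibility, aggregation, or instrument drift — passing recovery tests
show the fitter inverts its own forward model under noise, not that real
CD data are this clean.

## Problem sizes and determinism

The test suite runs the full 1536-member expansion and its 1,180,416-pair
screen (vectorised, seconds) and keeps search oracles at ≤ 12 peptides
where exhaustive enumeration is affordable; the acceptance script's
quantities are all deterministic, its `--seed` only shuffles evaluation
order. The screen and search contain no randomness at all; the only seeded
component is the melt-curve noise generator.

## Known limitations

* Absolute predicted Tm values (and thus any library-scale pair/quadruple
  counts under the default criteria) are placeholder-coefficient artifacts
  until a calibrated coefficient set and helicity table are configured.
* Alignment is strictly in-register and dimeric: no stagger search, no
  higher oligomers, no 3D structure.
* The antiparallel filter is a charge-complementarity heuristic, not an
  antiparallel stability model.
* Electrostatic scoring covers only residues present in the configured
  tables; the permissive zero policy silently ignores everything else.
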
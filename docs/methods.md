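# Methods

## Model and procedure

The pipeline treats anti-diabetic peptide discovery as four composable
stages.

**Digestion.** A protease is a list of cleavage rules over the two
residues flanking a peptide bond: a rule fires when the P1 residue is in
its P1 set (or the set is a wildcard), the P1′ residue is in its P1′ set
(or wildcard), and the P1′ residue is not in the rule's veto set.
Digestion is *full and simultaneous*: the cut-site set is the union over
all enzymes, every firing rule cuts, and there are no missed cleavages.
Fragments are the maximal substrings between consecutive cuts and carry
1-based inclusive coordinates, so they tile the parent exactly — an
invariant the test suite asserts on thousands of random sequences.

Built-in specificities: trypsin (EC 3.4.21.4) cuts after K/R unless P
follows; chymotrypsin (EC 3.4.21.1) after F/Y/W unless P follows; pepsin
at pH 1.3 (EC 3.4.23.1) at bonds with F or L at P1 *or* P1′ (a second
registry entry broadens this to F/L/W/Y for pH > 2). These are the
conventions of the common cleavage predictors; published rule dialects
differ, which is why the grammar is plain data and fully overridable. A
consequence of the P1′-side pepsin rule worth knowing: a peptide whose
internal bond precedes F or L (e.g. IL) can never survive a digest that
includes this pepsin dialect, so release-frequency results are sensitive
to the chosen dialect.

**Profiling.** For one protein (length `N`) and one activity class, with
class peptides `p_i` occurring `a_i` times (substring occurrences,
overlaps counted — deterministic and oracle-checkable; other tools may
count non-overlapping matches, which only matters for self-overlapping
motifs like AA):

- `A = Σ a_i / N`;
- `B = Σ (a_i / EC50_i) / N` in mM⁻¹, EC50s converted to mM before
  summation; peptides without a known EC50 contribute nothing and are
  counted into a coverage field, and B is reported as *undefined* (not 0)
  when no class peptide has an EC50;
- `A_E = d / N`, where `d` counts released fragments (with multiplicity)
  whose entire sequence is a class member — a bioactive substring inside
  a longer fragment does not count;
- `W = A_E / A`, undefined when `A = 0`.

`W·A = A_E` holds exactly whenever W is defined, and `A_E ≤ A` always (a
peptide cannot be released more often than it occurs).

**Physico-chemistry.** Molecular weight is the sum of average residue
masses plus one water (18.0153 g/mol). Net charge at pH is the
Henderson–Hasselbalch sum: positive groups (N-terminus, His, Lys, Arg)
contribute `1/(1+10^(pH−pKa))`, negative groups (C-terminus, Asp, Glu,
Cys, Tyr) `−1/(1+10^(pKa−pH))`. Cys and Tyr are modelled as weak acids;
at pH 7 their contribution is below 0.01 charge units, so the reported
1-decimal charges are insensitive to that choice. The isoelectric point
is the unique zero of the (strictly decreasing) charge curve, found by
bisection on (0, 14); the iteration stops only when the residual charge
is below the tolerance (default 1e-4) *and* the bracket is narrower than
1e-6 pH units, because between well-separated pKas the titration curve
is nearly flat and the charge criterion alone would leave the pH several
millipH loose. Solubility is a deliberately coarse screen: good iff the
peptide contains at least one charged residue (D/E/K/R). It reproduces
all 54 printed labels of the reference table.

**Reporting.** Pooled amino-acid composition, mean ± sample SD (n−1
denominator), Pearson correlation (scipy), inclusive score-threshold
selection sorted by descending score then sequence, and a length
histogram with exact fractions (integer percentages only in reports).

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| enzyme set | pepsin_ph1.3 + trypsin + chymotrypsin | — | gastric + pancreatic digestion |
| charge pH | 7.0 | pH | physiological, matches the reference table |
| pI tolerance | 1e-4 | charge units | see bisection note above |
| score threshold | 0.93 | — | the published high-bioactivity cutoff |
| mass table | `default` | g/mol | see calibration note below |
| pKa set | `classic` | pH | His 6.00 reproduces the printed His-peptide charges |

Reporting precision mirrors the reference tables: MW 2 dp, pI 2 dp,
charge 1 dp, A/A_E/W 4 dp, B 6 dp.

**Mass-table calibration.** The `default` table is the EMBOSS average
residue-mass set with two residues at the slightly heavier standard
values (K 128.1741, T 101.1051 instead of 128.1723, 101.1039). The pure
EMBOSS set leaves three reference dipeptides (MK, SK, TR) 0.01 g/mol
short of their printed weights; with the adjusted pair, all 53
verifiable rows of the 54-row reference table reproduce to 2 decimals.
The one exception, SW, prints 219.30 where any residue-mass sum gives
291.30 — a typographical error in the source table, which the suite flags
as an expected mismatch rather than asserting. The unmodified EMBOSS
table remains selectable as `emboss`.

**pKa sets.** `classic` (N-term 9.00, C-term 3.55, D 3.65, E 4.25,
H 6.00, C 8.30, Y 10.07, K 10.53, R 12.48) reproduces the printed
1-decimal charges at pH 7 for 53 of the 54 reference peptides; the
exception is HF, printed as 0 while its composition twins HL/HW/HY print
0.1 (any model with His pKa near 6 gives +0.08 for all four) — another
table-internal inconsistency, flagged and not asserted. An EMBOSS-style
set is packaged as `emboss`. The printed *pI* column is not used as a
numerical oracle at all: its values (e.g. 3.70 for side-chain-free
dipeptides) are inconsistent with any standard two-group
Henderson–Hasselbalch model, which puts such peptides near 5.6–6.3, and
the tool that produced them is not identifiable. The column is retained
as fixture data for the correlation analysis only.

## Reference fixtures

The activity database holds the 54 distinct released DPP-IV-inhibitory
sequences and the two glucose-uptake stimulators (IL, VL — themselves
DPP-IV inhibitors, so the GUSP set is a subset of the inhibitor set); a
separate fixture supplies literature EC50s (KA 6.27 mM, AAATP 6.47 mM)
so the affinity statistic B is exercisable. The full DPP-IV reference
set of the original online database is much larger than these 54
released sequences, so the absolute per-protein A/B/A_E/W values of the
original 16-protein screen are *not* regenerable from the packaged
fixture (and the source protein sequences are not bundled); the
reproducible surface is the released-peptide table and its aggregate
statistics. The published candidate count is also internally
inconsistent: the text says 13 peptides score "above 0.93" but the table
holds 14 cells ≥ 0.93 (HW is omitted from the text list). Selection here
is inclusive (≥) and reports what it finds; with threshold 0.99 it
returns exactly the five structure-level candidates (GF, MF, MW, PF, PW).

## Synthetic data

The generator emulates the study design — a panel of muscle-protein-sized
sequences screened for short bioactive motifs — with known truth.
Defaults: 16 proteins of 300 residues, uniform background over the 20
amino acids. Background residues are i.i.d.; planted motifs are placed
at uniform-random non-overlapping positions (bounded rejection sampling;
a placement failure raises). With `flank_released`, each motif is
embedded as `K + motif + X` (X a non-Pro background residue) so a
tryptic digest releases it exactly; this requires the motif itself to be
trypsin-releasable (ends in K/R, does not start with P, no internal
cleavable bond), which is validated. Ground truth is never the planting
bookkeeping: occurrences are recounted by exhaustive scan of the emitted
sequence (accidental background matches included) and releases by an
independent brute-force digest, so the recovery tests are integer-ratio
identities with no tolerance. One RNG stream per study, seeded
explicitly; the same seed is byte-identical.

What the generator does *not* emulate: residue autocorrelation and
domain structure of real proteins, fraction-specific composition
(myofibrillar vs sarcoplasmic), and enzyme kinetics (partial cleavage).
Passing recovery tests therefore validate the bookkeeping and statistics
on sequences of realistic size, not biological realism of the digests.

## Numerical and design notes

- Occurrence scanning, cut-site detection and digestion are all checked
  against brute-force oracles (scan every start, scan every bond) in the
  test suite; the oracles share no code with the implementation.
- Reported values use Python's round-half-even; no reference value sits
  on a half boundary, so the convention is immaterial there.
- Charges rounding to −0.0 are normalised to 0.0.
- Ambiguity codes (B, J, O, U, X, Z) are rejected at parse time, not
  remapped: the mass and pKa tables are defined only for the standard 20
  residues.
- The fraction tag (myofibrillar/sarcoplasmic) is carried as metadata and
  used only for report grouping; no statistic depends on it.
- The pipeline writes per-stage CSVs plus a resolved-config YAML; a stage
  failure removes partial outputs and names the stage.

## Problem sizes

The property suites run on deliberately small inputs — 1,000 random
proteins of up to 80 residues for conservation/oracle equality, 100
seeded synthetic studies of one 150-residue protein for exact frequency
recovery — sizes at which the brute-force oracles are instant while
still exercising every rule path; the whole suite completes in a few
seconds.

## Known limitations

- Cleavage dialects vary between predictors; only the registry defaults
  are validated against the reference fragment vocabulary.
- B depends entirely on EC50 coverage of the activity database; with the
  packaged literature fixture it covers two peptides.
- The solubility rule is a screen, not a solubility model.
- External bioactivity scores are consumed as annotations, never
  recomputed; quantum-chemical (HOMO/LUMO) characterisation of
  candidates is out of scope.
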
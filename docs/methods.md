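# Methods

## Scope and model

`liponom` implements a three-step scheme for annotating lipid fragment ions:

1. **Mass-balanced reactions.** Every detected fragment ion m/z is explained
   by a reaction in which the charged fragment plus all neutral fragments
   reproduce the precursor ion exactly at the level of nuclide multisets.
   Atom balance is structural (the remainder part absorbs whatever the
   explicit parts do not claim), so mass balance holds to float precision
   (< 1e−9 Da, asserted for every enumerated reaction).
2. **Type-specific shorthand.** Charged and neutral fragments are named by
   fragment type: LCFs by class symbol and nominal mass (`PS(153)`), MLFs by
   HCA token plus a signed Hill delta (`FA 22:6(-CO)`), iMLFs by a multi-chain
   moiety reference (`DAG 28:2(+C6H11O9P2)`), DBFs with double-bond positions
   (`FA 18:1(9)(+O -C7H15)`). Neutral losses carry a `-` prefix.
3. **Prioritization.** Each m/z has a dual annotation (charged | neutral
   composite). A decision tree picks one side: fragment type first
   (DBF > MLF > LCF > iMLF), then the side with the lower total fragment
   mass (not m/z), ties to the charged side.

## Chemistry layer

* Nuclide monoisotopic masses come from the NIST table bundled with
  pyteomics; the electron mass is subtracted/added per charge in every m/z
  (m/z = (M − z·mₑ)/|z|). Deprotonation is "remove one H atom, keep its
  electron"; adduct atoms are merged into the ion composition before the
  electron correction.
* Compositions are signed nuclide multisets. Heavy nuclides are first-class
  keys (`("H", 2)`), so isotope labels survive arithmetic, and nominal masses
  count mass numbers (a ²H counts 2 — hence `PC(+[2]H13)(197)` = 184 + 13).
* Display conventions: Hill order (C, H, then alphabetical) with Li/Na/K
  moved last so sodiated deltas print `(+ONa)`/`(+HONa)` as in the field's
  usage rather than strict-Hill `(+NaO)`; mixed-sign deltas print as
  space-separated signed groups (`(+O -C7H15)`); m/z and Da to 4 decimals,
  composite masses to 1 decimal where reported.

## Structural templates

An intact lipid is `backbone + Σ(HCA base − H per binding linkage)`, with the
backbone carrying free OH/NH at every chain slot. HCA bases:

| HCA | base | notes |
|-----|------|-------|
| FA | C_c H_{2c−1−2d} O_{1+h} | `+O` carboxylate, `+HO` fatty acid, `-H` ketene |
| O-alkyl / O-alkenyl | C_c H_{2c+1−2d} | alkenyl (`p`) counts the vinyl-ether DB in d |
| LCB | C_c H_{2c+3−2d} N O_h | free long-chain base |
| ST | C_c H_{2c−6−2d} O | four-ring sterol; 27:1 = cholesterol |

Because every class total formula is linear in (C, DB, OH), species-level
names (`TAG 52:2`, `SM 35:1;2`) have well-defined intact compositions; only
chain-resolved fragments require a molecular-level name. 17 classes are
curated (PC, LPC, PC O-, PE, PE O-, PS, PI, PA, CL, DAG, TAG, SM, Cer, SE,
ACar, ACoA, FA), covering the five lipid categories; the template table
(`data/classes.json`) is data-driven, so further classes need no code change.
The catalogue scope of the original online calculator (hundreds of thousands
of enumerated molecules) depends on unpublished chain ranges and is
explicitly not reproduced; database enumeration ranges default to C16–22
(even), DB 0–6 and are fully configurable.

## Rule table

Rules (`data/rules.json`) are declarative. The vocabulary is deliberately
small: a fixed-composition part, an HCA-slot part with a modification delta
(iterating over matching chains), a double-bond-cleavage part
(`+O −C_kH_{2k+1}`, k = C − position − 2, one reaction per annotated
position), a chain-pair part (for the doubly charged cardiolipin channel,
which charge-separates into two singly charged iMLF-bearing ions; balance is
then checked on atoms *and* charge), and the remainder. Head-group isotope
labels transfer into fixed fragments marked `head_label`; a chain label whose
heavy atoms sit on the lost atoms can be routed into the loss
(`label_to_loss`), which is what produces
`LCB 18:0;3(+[13]C2[15]N)(-[13]CH8[15]NO)`.

Curation covers every fragment family in the worked examples: choline-class
positive (head-group cation 184) and acetate/formate negative channels
(methyl acetate/formate loss, ketene and fatty-acid losses, carboxylates);
PE/PE O- both polarities (141 head-group loss); PS (153/87 LCFs and four MLF
families per chain); PI (241); PA; TAG/DAG ammonium (ammonia loss plus four
MLF families per chain) and sodium (four families incl. `(+ONa)`/`(+HONa)`);
SE ammonium; ACar; ACoA; Cer (incl. formate adduct); CL −1/−2; MS³ acylium
channels for glycerides and the DBF channel for carboxylate anions.
`validate_rules` instantiates every rule on a probe lipid per class and flags
atom-balance or negative-composition violations with the rule id; duplicate
reactions from identical chains collapse to one, keeping the union of chain
slots they evidence (12 MLF reactions for a 3-distinct-chain TAG, 8 when two
chains coincide).

The fourth ammonium-adduct MLF family (loss of the fatty acid with the
ammonium retained, `-FA x(+HO)`) completes the stated count of four families
per chain; the other three are named outright in the reference material.

## Spectrum annotation

Peaks are matched to the nearest theoretical fragment within a ppm or Da
tolerance (defaults 5 ppm for FT-type, 0.3 Da for IT-type data; one
annotation per peak per candidate, closest ppm wins; no arbitration between
isomeric candidates). Identification levels from matched evidence:

* **db_defined** — ≥ 1 DBF matched;
* **molecular** — every chain slot evidenced by ≥ 1 matched MLF. Only parts
  that explicitly carry one chain count as evidence; a single-chain remainder
  is *named* as an MLF but its chain content is implied by the candidate
  hypothesis, not observed. Reactions merged during deduplication keep all
  evidenced slots, so lipids with identical chains (PE 17:0–17:0) reach
  molecular level;
* **species** — ≥ 1 LCF or iMLF matched;
* **none** — otherwise.

No minimum fragment count is imposed beyond these rules (one matched LCF
suffices for a species-level call); stricter policies can be layered on the
returned evidence table.

## Synthetic spectra

The generator emulates FT-type mass error: observed m/z = theoretical ×
(1 + ε), ε ~ N(0, σ ppm) — multiplicative ppm jitter, not additive Da.
Intensities are a 1/rank decay (or uniform); decoy peaks are uniform over a
configurable m/z range, rejected within ±max(3σ, 0.5) ppm of any theoretical
fragment, so at tolerances ≤ 3σ decoys cannot force false annotations (the
0.5 ppm floor keeps the zero-jitter limit collision-free). A seed fixes the
entire output. Expected recall at tolerance t is Φ-based,
erf(t/(σ√2)): ≈ 90.4 % at t = 5 ppm, σ = 3 ppm; ≥ 99.7 % at t = 3σ — the
test suite asserts both against simulation. Not emulated, hence not probed by
passing tests: isotope envelopes, chimeric precursors, intensity physics,
chromatography, real calibration drift.

## Numerical and design choices

* En-dash and hyphen-minus are both accepted as chain separators; output uses
  the hyphen-minus.
* `PE O-18:1p` parses as class `PE O-` with an alkenyl chain; the ether
  distinction exists only at molecular level (`PE O-40:7` at species level).
* Chain order in unordered names is canonical: increasing C, then DB, then
  OH; sn-assigned (`/`) order is preserved; sorting is stable for duplicate
  chains (`TAG 18:1-18:1-18:1` is legal).
* An exact mass tie between the charged and neutral side prioritizes the
  charged side (the reference scheme is silent here). For charge-separated
  reactions (CL²⁻) the observed m/z *is* the charged fragment, so the
  mass tie-break never hands priority to the counter-ion.
* Single-chain classes (LPC, FA, ACar, ACoA) parse a single chain token as a
  molecular-level name: the chain is fully determined.
* Double-bond cleavages with k = C − position − 2 ≤ 0 (bond at the methyl
  end) are structurally impossible and skipped silently rather than flagged.
* For a choline lipid with a head-group label, the acetate-adduct methyl
  loss chemically takes one labeled methyl with it; the packaged rule keeps
  the full label on the lipid-side remainder (the split would need
  atom-level provenance). Mass balance and label conservation still hold.

## Measured-value caveats

Several reference m/z values are measured, with stated accuracies up to
~5 ppm; regression tests assert compositional arithmetic against them at
matching tolerances rather than exactly (e.g. 263.2362, 424.3413, 699.3204,
182.1305, 611.5407). Two reported values (767.4591 for the PS serine-loss
ion; 577.5215 for a TAG fatty-acid+ammonia loss) deviate by > 4 ppm — in the
latter case ~2 Da — from any composition the reaction scheme can produce;
they are treated as measured outliers, excluded from numeric assertions, and
the rules are not tuned toward them. The ammonia neutral loss computes to
17.02655 Da, which rounds to 17.0265 at four decimals although it is usually
quoted as 17.0266.

## Problem sizes

The test suite enumerates fragments for every curated class/adduct pair
(~150 reactions per rule-validation pass), simulates ~125 spectra for the
jitter-recall check (> 1000 fragment draws), and builds PS/PC databases over
C16–22, DB 0–6 (406 PS molecular species, ~4500 records); the whole suite
runs in well under a minute on one CPU with no network access.
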
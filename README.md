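# liponom

Shorthand nomenclature and in-silico CID fragmentation for lipid mass
spectrometry.

Tandem MS (MS², MS³) of lipids produces fragment ions that are essential for
structural elucidation and high-confidence identification, yet — unlike
peptide b/y ions — they have long lacked a consistent shorthand. `liponom`
implements a common fragment-ion nomenclature as a reusable engine for
lipidomics software developers and practitioners: given an intact lipid name,
an adduct and a polarity, it enumerates collision-induced dissociation (CID)
fragments as **mass-balanced chemical reactions**, emits the prescribed
shorthand for both charged and neutral fragments, prioritizes one annotation
per m/z, and annotates MS²/MS³ peak lists — including stable-isotope-labeled
lipids.

## The model

Every fragment ion m/z is represented by a reaction whose parts sum exactly
to the precursor ion, atom by atom:

```
[PC 18:3–18:3 + CH3COO]⁻  →  (charged fragment)  +  Σ (neutral fragments)
```

Fragments fall into four types, keyed to the annotation level of the intact
lipid they can support:

| type | meaning | example | supports |
|------|---------|---------|----------|
| LCF  | lipid class-selective fragment (no chain) | `SM(184)`, `-TAG(17)` | species level |
| MLF  | molecular species-specific fragment (one chain) | `FA 18:2(+O)`, `-FA 17:0(-H)` | molecular level |
| iMLF | intermediate MLF (≥ 2 chains) | `DAG 28:2(+C6H11O9P2)` | species level |
| DBF  | double-bond location-specific fragment | `FA 18:1(9)(+O -C7H15)` | DB-defined level |

Chains are described by *minimal hydrocarbon-chain attributes* (HCA): fatty
acyl `FA c:d;h` with base composition C<sub>c</sub>H<sub>2c−1−2d</sub>O<sub>1+h</sub>,
ether chains (`O-`/`p`), long-chain bases (`LCB`), and sterols (`ST`).
Modifications are signed Hill-notation deltas in parentheses — `(+O)` is the
carboxylate, `(+HO)` the free fatty acid, `(-H)` the ketene. Neutral losses
are prefixed `-`. Each m/z gets a **dual annotation** (charged | composite of
neutral losses); a decision tree prioritizes by fragment type
(DBF > MLF > LCF > iMLF), then by lower total fragment mass (not m/z).
Stable-isotope labels use bracketed nuclides, e.g. `PC(+[2]H13)(197)` or
`-FA 16:0(+[2]H3)(-H)`, and are conserved through every reaction.

All masses are monoisotopic with electron correction (the phosphocholine
cation C₅H₁₅NO₄P comes out at m/z 184.0733). Fragmentation rules and lipid
class templates are data, not code (`src/liponom/data/*.json`), and are
user-extensible; atom balance of every rule is validated on probe lipids
(`liponom validate-rules`).

## Worked example

```
$ liponom calc "PS 20:4-22:6" --adduct "-H"
precursor : [PS 20:4-22:6-H]-
formula   : C48H73NO10P
m/z       : 854.4978  (z = -1)
fragments :
    152.9958  PS(153) | -DAG 42:10(+N -H)
    259.2431  FA 20:4(-CO) | -FA 22:6(+C7H11NO9P)
    283.2431  FA 22:6(-CO) | -FA 20:4(+C7H11NO9P)
    303.2330  FA 20:4(+O) | -FA 22:6(+C6H11NO7P)
    327.2330  FA 22:6(+O) | -FA 20:4(+C6H11NO7P)
    439.2255  -FA 22:6(+HO) -PS(87) | FA 20:4(+C3H5O5P)
    463.2255  -FA 20:4(+HO) -PS(87) | FA 22:6(+C3H5O5P)
    544.2681  -FA 22:6(-H) | FA 20:4(+C6H12NO8P)
    568.2681  -FA 20:4(-H) | FA 22:6(+C6H12NO8P)
    767.4657  -PS(87) | DAG 42:10(+O3P)
```

The deprotonated precursor (m/z 854.4978) yields two head-group LCFs —
`PS(153)`, the glycerophosphate anion, and the serine loss `-PS(87)` — which
identify the lipid at the *species* level (PS 42:10), plus eight MLFs (four
per fatty acyl: carboxylate `(+O)`, decarboxylated carboxylate `(-CO)`,
loss as fatty acid `(+HO)` with the serine head group, and loss as ketene
`(-H)`) which together pin both chains and raise the identification to the
*molecular species* level, PS 20:4–22:6. The text left of each `|` is the
prioritized shorthand; the right side is the redundant dual annotation.

The same engine drives peak-list annotation:

```python
from liponom import Peak, Tolerance, annotate_spectrum

peaks = [Peak(269.2), Peak(448.2), Peak(466.2)]       # ion-trap MS2 of m/z 718.5
res = annotate_spectrum(peaks, [("PE 17:0-17:0", "-H")], Tolerance(0.3, "da"))[0]
print(res.report())
# m/z 269.2 -> FA 17:0(+O), 448.2 -> -FA 17:0(+HO), 466.2 -> -FA 17:0(-H)
# identification level: molecular  (PE 17:0-17:0)
```

Other entry points: `liponom fragments` (TSV fragment lists, `--ms-level 3`
for multi-stage CID), `liponom builddb` / `liponom search` (sqlite + TSV
fragment databases over configurable chain ranges), `liponom simulate`
(synthetic spectra with ppm jitter, decoys and a fixed seed, plus ground
truth), and `liponom annotate` (TSV/MGF peak lists).

## Name grammar (EBNF sketch)

```
name        = class [ "(" label ")" ] sep body
body        = totals | chain { ("-" | "/") chain }        (* "–" accepted on input *)
totals      = C ":" DB [ ";" OH ] [ "(" label ")" ]
chain       = C ":" DB [ "p" ] [ ";" OH ] [ "(" positions ")" ] [ "(" label ")" ]
label       = "+" { "[" massnumber "]" element [ count ] }
```

`-` separates unordered chains (molecular level), `/` sn-assigned chains;
`O-`/`p` mark ether (plasmanyl/plasmenyl) chains; `(9)` gives a double-bond
position. See `docs/methods.md` for the full scheme, the class-template and
rule-table schemas, and known limitations.

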
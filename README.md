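# braferk

Mechanistic, mass-action simulation of BRAF<sup>V600E</sup>–MEK–ERK
signalling under vertical inhibition with dabrafenib (DBF, an ATP-competitive
BRAF inhibitor) and trametinib (TMT, an allosteric MEK inhibitor).

In BRAF<sup>V600E</sup>-mutant melanoma the MAPK cascade is constitutively
switched on: mutant BRAF no longer needs upstream activation, so it steadily
double-phosphorylates MEK, and active ppMEK double-phosphorylates ERK, driving
proliferation. Clinically the cascade is drugged at two tiers at once, and a
central question is *how* the two inhibitors combine — which dose pairs are
synergistic, and how much BRAF amplification or ATP elevation a tumour cell
needs to resist them. This package answers those questions for a fully
mechanistic reaction model, and is aimed at modellers and quantitative
pharmacologists exploring dose–response and resistance in this pathway.

## The model

The cascade is a closed reaction network of **36 elementary reactions over 36
molecular species** (both drugs enabled), built from three ingredients:

* a reduced two-tier phosphorylation cascade (the top tier is the single,
  constitutively active BRAF node), with phosphatases phosph1/phosph2
  reversing MEK and ERK phosphorylation through enzyme–substrate complexes;
* explicit ATP-dependent catalysis — a kinase must carry bound ATP, which is
  converted to ADP as the phosphate is transferred
  (e.g. BRAF·ATP·MEK → BRAF + ADP + pMEK);
* mechanistic drug action: DBF competes with ATP for BRAF's nucleotide
  pocket; TMT occupies a third, distinct MEK site and blocks catalysis
  without excluding ATP or substrate.

By the law of mass action each reversible binding step X + Y ⇌ X·Y with
constants (aᵢ, dᵢ) contributes the flux aᵢ[X][Y] − dᵢ[X·Y], and each
catalytic step contributes k[complex]; the resulting 36 stiff ODEs are
integrated with a BDF method using the analytic Jacobian. All forward
constants are equal (aⱼ = a₁), leaving the Michaelis constants
K<sub>mi</sub> = (dᵢ + kᵢ)/aᵢ as the governing ratios. Seven linear
conservation laws (total BRAF, MEK, ERK, phosph1, phosph2, DBF, TMT across
free, bound and phosphorylated forms) lie exactly in the left null space of
the stoichiometric matrix and are verified on every run to below 10⁻⁶
relative drift.

The treatment readout is the **activated-ERK fraction**

    activated ERK(t) = [ppERK](t) / ERK_tot,   ERK_tot = [ERK](0),

evaluated by default at 8, 16 and 24 h with baselines BRAF = 3 nM and
ATP = 1 mM. On top of the simulator sit the therapy experiments: monotherapy
scans over BRAF/ATP, DBF × TMT combination surfaces, isobole-based synergy
classification (combinations on or below the straight line joining the two
monotherapy doses that reach activated ERK = 0.5, and achieving ≤ 0.5, are
synergistic), minimum-BRAF/ATP resistance thresholds, and the µM ↔ ng/mL
dabrafenib conversion (molecular weight 519.6 g/mol).

The reaction inventory is shipped as an auditable table
(`src/braferk/data/reactions.tsv`) and the kinetic parameters as a
unit-annotated, provenance-flagged config (`src/braferk/data/parameters.yaml`);
both are data, not code. See `docs/methods.md` for the modelling decisions,
parameter provenance and known limitations.

## Worked example

Dabrafenib only delays cascade activation — the response is strongly
time-dependent:

```text
$ braferk simulate --dbf 0.3
activated ERK at    8 h: 0.0416
activated ERK at   16 h: 0.3348
activated ERK at   24 h: 0.4585
```

At 0.3 µM DBF the cascade is almost fully suppressed at 8 h but has rebounded
to about 0.46 by 24 h: BRAF inhibition slows, but does not stop, MEK
activation, so ppERK recovers. Trametinib instead sets a dose-dependent
steady plateau:

```text
$ braferk simulate --tmt 1
activated ERK at    8 h: 0.3057
activated ERK at   16 h: 0.2983
activated ERK at   24 h: 0.2821
```

Resistance thresholds and unit conversion:

```text
$ braferk threshold --dbf 1 --tmt 0 --axis braf
minimum BRAF: 10.08 nM          # BRAF amplification needed to defeat 1 µM DBF
$ braferk convert 2 uM
2.0 uM = 1039.2 ng_per_mL
$ braferk validate
36 reactions, 36 species, 0 violation(s)
```

The same operations are available as library calls (`CascadeModel`,
`combination_grid`, `isobole_synergy`, `min_resistance_threshold`, …) and as
the remaining CLI subcommands `scan`, `grid`, `synergy`, `export-sbml`.

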
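# Methods

## Model

The package simulates the BRAF<sup>V600E</sup>–MEK–ERK cascade as a closed
mass-action reaction network. Its design follows the Huang–Ferrell MAPK
cascade tradition (Huang & Ferrell, PNAS 1996) with three modifications that
matter for drug modelling:

1. **Reduced top tier.** BRAF<sup>V600E</sup> is constitutively active, so
   the MAPKKK tier is a single, always-active enzyme node with no
   activating/deactivating enzymes of its own.
2. **Explicit ATP.** Phosphorylation is ATP-dependent: the kinase must carry
   a bound ATP, which leaves the catalytic step as ADP. This is what makes an
   ATP-competitive inhibitor representable mechanistically, and it makes
   cellular ATP concentration a model variable rather than an absorbed
   constant.
3. **Mechanistic drug action.** Dabrafenib (DBF) binds BRAF's nucleotide
   pocket, mutually exclusively with ATP. Trametinib (TMT) binds a third,
   allosteric site on ppMEK — independent of both the ATP site and the
   substrate site — and any TMT-containing complex is catalytically dead.

### Reaction inventory

The inventory (shipped as `data/reactions.tsv`, one auditable row per
reaction) is generated by a small set of binding-order rules:

* **Substrates bind any enzyme form.** MEK/pMEK bind BRAF, BRAF·ATP and
  BRAF·DBF; ERK/pERK bind ppMEK, ppMEK·ATP, ppMEK·TMT and ppMEK·ATP·TMT.
* **Nucleotide and nucleotide-site drug bind only substrate-free enzyme
  forms.** The productive assembly order is nucleotide first, then
  substrate; substrate-first complexes (BRAF·MEK, ppMEK·ERK, …) exist but
  are dead ends that sequester enzyme and substrate.
* **TMT, being allosteric, binds every ppMEK form**, including ATP- and
  substrate-loaded ones, which is why quaternary complexes such as
  ppMEK·ATP·TMT·ERK appear. TMT is not given affinity for MEK or pMEK.
* **Catalysis** fires only from drug-free kinase·ATP·substrate complexes
  (releasing enzyme, ADP and the phosphorylated substrate) and from
  phosphatase·substrate complexes (phosph1 for pMEK/ppMEK, phosph2 for
  pERK/ppERK).

With both drugs enabled these rules yield exactly 36 reversible-binding and
catalytic reactions over 36 species; dropping DBF removes 3 reactions,
dropping TMT removes 11. Reversible binding is counted as a single reaction
carrying an (a, d) pair, consistent with the mass-action contribution
−a[X][Y] + d[X·Y] of such a step. Complex names use dot notation with the
fixed constituent order *enzyme · ATP · drug · substrate*, so names are
canonical and the moiety bookkeeping (used for balance validation and
conservation laws) can parse them.

The structural validator checks, per reaction, the binding/dissociation/
catalysis arities, exact conservation of the protein/drug constituent
multiset, the ATP→ADP + phosphate bookkeeping of catalysis, and drug-tag/
toggle consistency. These checks are reported, not raised, so broken inputs
can be inspected.

## Parameters

Working units are nM and hours; loaders convert from µM/mM/M. All values
live in `data/parameters.yaml` with a per-value provenance flag — they are
editable configuration, not code. The shipped set:

| group | value | why |
|---|---|---|
| association a₁…a₈ | 3.6 /(nM·h) (= 10⁶ /M/s) | typical protein association rate; all aⱼ equal, so behaviour is governed by the Michaelis constants Kₘᵢ = (dᵢ + kᵢ)/aᵢ |
| substrate/phosphatase steps d₂,d₃,d₆,d₇ | 680 /h | Kₘ = 300 nM with k = 400 /h, the classic Huang–Ferrell cascade Kₘ |
| ATP binding d₁,d₅ | 1.08·10⁵ /h | K_d(ATP) = 30 µM, in the tens-of-µM range typical of kinase nucleotide pockets |
| drug binding d₄,d₈ | 3.6 /h | K_d = 1 nM for both inhibitors (sub-to-low-nM in vitro affinities; slow off-rates) |
| catalytic k₁,₂, k₃, k₅,₆, k₇ | 400 /h (≈ 0.11 /s) | order of magnitude of measured kinase turnover; shared within each tier |
| concentrations | BRAF 3 nM, MEK 1200 nM, ERK 1200 nM, phosph1 0.3 nM, phosph2 120 nM, ATP 1 mM, ADP 0 | BRAF and ATP are the stated study baselines; the protein set is the Huang–Ferrell cascade parameterisation |

The initial condition is the all-free, fully dephosphorylated state; drug
doses enter as free drug at t = 0 (an optional pre-equilibration mode runs
the drug-free system to steady state first, but the default cold start is
what produces the characteristic rise of activated ERK from zero).

This parameterisation reproduces the study conditions' qualitative
pharmacology: the undrugged cascade activates to a sustained high plateau
within a few hours; TMT sets dose-dependent, time-stable plateaus (it
titrates the ppMEK pool at K_d ≪ pool size); DBF merely delays activation
over clinically relevant doses (0.01–1 µM), so its responses differ strongly
between 8 and 24 h and several dose–BRAF–ATP combinations converge to a
common late value by 24 h; raising BRAF to 10 nM or ATP to 5 mM confers
marked resistance. The exact plateau heights and anchor doses (e.g. the
0.5-level monotherapy anchors D* ≈ 0.19 µM, T* ≈ 0.87 µM at 8 h) are
functions of these placeholder constants and should be re-derived after any
re-parameterisation.

## Numerics

* **Integrator.** BDF (scipy `solve_ivp`) with the analytic Jacobian
  assembled from the stoichiometric matrix and flux derivatives; defaults
  rtol = 10⁻⁸, atol = 10⁻¹² nM. The system is stiff: rates span from drug
  off-rates (≈ 3.6/h) to nucleotide dissociation (≈ 10⁵/h) and
  concentrations from sub-nM complexes to mM ATP.
* **Conservation as verification.** The seven moiety totals (plus the pooled
  ATP + ADP count) are exact integer left-null vectors of the stoichiometric
  matrix; an ODE solution of a closed mass-action network satisfies them
  identically, so rather than projecting onto the constraint manifold the
  simulator verifies a posteriori that the relative drift stays below 10⁻⁶
  (observed: ≈ 10⁻¹³). A run that violates the tolerance raises, never
  silently passes. A relative floor of 10⁻⁶ nM keeps zero-dose laws defined.
* **Negative undershoots** larger than −10·atol are an integration failure;
  smaller ones are clipped to zero in the returned trajectory, after the
  conservation check.
* **Isobole anchors** are located on a coarse logarithmic dose scan, guessed
  by monotone (PCHIP) interpolation in log dose, and refined by bisection on
  the simulator to |activated ERK − level| ≤ 10⁻³.
* **Synergy rule tie-break.** "Below the additive segment" is evaluated as
  d/D* + t/T* ≤ 1 (with a 10⁻⁹ relative slack), restricted to true
  combinations (both doses > 0). The on-the-line case matters because the
  exact midpoint (D*/2, T*/2) of the segment is the canonical probe point:
  it is classified synergistic when it achieves the level, while the
  monotherapy anchors — also on the line — never are. A strict inequality
  would exclude the midpoint by construction, which contradicts the intended
  classification, so the closed boundary with the monotherapy exclusion is
  used.
* **Resistance thresholds** are found by bisection on the (numerically
  monotone) response in BRAF or ATP, to 0.01 nM / 0.001 mM, after a coarse
  geometric pre-scan that brackets the crossing and warns if it detects
  non-monotonicity; "never reached below the cap" (default 20 nM BRAF /
  20 mM ATP) returns a tagged sentinel, not a magic number.
* **Determinism.** There is no randomness anywhere in the simulator or the
  experiment drivers; trajectories carry their solver settings and statistics
  as provenance.

## Design choices on genuinely open points

* **ATP dynamics.** ADP is an explicit species and no regeneration reaction
  exists, so the literal closed system slowly consumes ATP; this is the
  default. A `clamp_atp` switch holds free ATP constant instead. Note that
  the phosphorylation/dephosphorylation futile cycle is ATP-expensive: at
  the shipped parameters the ERK tier alone turns over ≈ 5·10⁴ nM/h, so the
  1 mM pool falls to ≈ 0.13 mM by 24 h and is exhausted by ≈ 48 h. Within
  the 24 h study horizon this depresses activated ERK by only a few
  hundredths (e.g. the drug-free plateau eases from 0.82 at 8 h to 0.79 at
  24 h), but conclusions beyond 24 h in the default mode reflect fuel
  exhaustion, not pharmacology; use `clamp_atp` for long-horizon questions.
* **"Late-time convergence" of DBF responses** is therefore read at the
  24 h horizon, where low-to-moderate DBF doses (and elevated-BRAF variants)
  have rebounded to the drug-free value within a few hundredths.
* **Dose grids** default to log spacing over 10⁻³–10 µM (DBF) and
  10⁻³–3.2 µM (TMT). They are configuration: the synergy region between the
  monotherapy anchors is narrow in log space, so a coarse default grid can
  contain no cell that is both below the isobole and at ≤ 0.5 activated ERK
  even when the combination is strongly synergistic (the midpoint probe
  reaches ≈ 0.02). Refine the grid near the anchors to map the region.
* **Rate-constant wiring** (which a/d/k family governs which reaction) is
  kept in the reaction table itself, one source of truth for both structure
  and kinetics.

## What the defaults do and do not show

The shipped parameter set is a literature-informed placeholder
parameterisation (flagged per value), not a fit to any cell line: passing
tests show that the mechanistic structure produces the right pharmacology —
competitive-vs-allosteric asymmetry, time-transient DBF response,
BRAF/ATP-driven resistance, isobole synergy — at realistic constants, not
that predicted doses are quantitatively correct for a given tumour.
Re-measured kinetic constants can be dropped into `parameters.yaml` without
touching code. Further limitations: no ERK-tier inhibitor (the network
builder accepts extended reaction tables, which is the intended extension
hook), no stochasticity, no synthesis/degradation or ATP regeneration, and
no spatial or cell-population structure.
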
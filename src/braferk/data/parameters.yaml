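# Kinetic rate constants and initial concentrations for the BRAFV600E-MEK-ERK
# cascade simulator.
#
# Internal working units are nM and hours; every value here declares its unit and
# the loader normalises.  Each entry carries a `provenance` flag:
#
#   baseline     - value stated directly in the study conditions (BRAF 3 nM and
#                  ATP 1 mM baselines; all forward constants equal, a_j = a_1).
#   huang-ferrell- literature placeholder taken from the Huang & Ferrell (1996)
#                  MAPK cascade parameterisation (Km = 300 nM for every
#                  enzyme-substrate step; the concentration set MAPKKK 3 nM,
#                  MAPKK/MAPK 1.2 uM, phosphatases 0.3 nM / 120 nM).
#   literature   - placeholder informed by published in vitro kinase/inhibitor
#                  data (order-of-magnitude: association 1e6 /M/s, kinase
#                  kcat ~0.1 /s, kinase ATP Kd tens of uM, sub-to-low-nM drug
#                  dissociation constants for dabrafenib and trametinib).
#
# Placeholder values are meant to be overridden if better measurements are
# available; they are configuration, not code.

rate_constants:
  # forward (association) constants, 1/(nM*h); all set equal to a1
  a1: {value: 3.6, unit: "1/(nM*h)", provenance: literature}   # 1e6 /M/s
  a2: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}     # a_j = a_1
  a3: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}
  a4: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}
  a5: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}
  a6: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}
  a7: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}
  a8: {value: 3.6, unit: "1/(nM*h)", provenance: baseline}
  # reverse (dissociation) constants, 1/h
  d1: {value: 1.08e5, unit: "1/h", provenance: literature}     # ATP-BRAF Kd 30 uM
  d2: {value: 680.0, unit: "1/h", provenance: huang-ferrell}   # Km(MEK) 300 nM
  d3: {value: 680.0, unit: "1/h", provenance: huang-ferrell}   # Km(phosphatase-1) 300 nM
  d4: {value: 3.6, unit: "1/h", provenance: literature}        # DBF-BRAF Kd 1 nM
  d5: {value: 1.08e5, unit: "1/h", provenance: literature}     # ATP-ppMEK Kd 30 uM
  d6: {value: 680.0, unit: "1/h", provenance: huang-ferrell}   # Km(ERK) 300 nM
  d7: {value: 680.0, unit: "1/h", provenance: huang-ferrell}   # Km(phosphatase-2) 300 nM
  d8: {value: 3.6, unit: "1/h", provenance: literature}        # TMT-ppMEK Kd 1 nM
  # catalytic constants, 1/h (kcat ~ 0.11 /s)
  k12: {value: 400.0, unit: "1/h", provenance: literature}     # BRAF -> MEK, pMEK
  k3: {value: 400.0, unit: "1/h", provenance: literature}      # phosphatase-1
  k56: {value: 400.0, unit: "1/h", provenance: literature}     # ppMEK -> ERK, pERK
  k7: {value: 400.0, unit: "1/h", provenance: literature}      # phosphatase-2

initial_concentrations:
  # Free, unphosphorylated pools at t = 0; every complex and every phosphorylated
  # form starts at zero; drug pools are set from the dose at run time.
  BRAF: {value: 3.0, unit: nM, provenance: baseline}
  ATP: {value: 1.0, unit: mM, provenance: baseline}
  ADP: {value: 0.0, unit: nM, provenance: baseline}
  MEK: {value: 1200.0, unit: nM, provenance: huang-ferrell}
  ERK: {value: 1200.0, unit: nM, provenance: huang-ferrell}
  phosph1: {value: 0.3, unit: nM, provenance: huang-ferrell}
  phosph2: {value: 120.0, unit: nM, provenance: huang-ferrell}
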
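# Package-authored (synthetic) parameterization of a Sturm-type MAPK/ERK
# cascade: RasGTP input -> Raf -> MEK (two-site, distributive) -> ERK
# (two-site, distributive), four phosphatases, and negative feedback from
# doubly phosphorylated ERK (ppERK) onto Raf activation.
#
# Concentrations and doses are in arbitrary model units; rates are tuned so
# the population activation switch sits inside the dose window 2^9..2^13
# and the terminal-pERK classification threshold of 17 separates the OFF
# (~0) and ON (~70-95) modes.  Downstream analyses of this module are
# ordinal (orderings and shapes), not tied to these particular numbers.
version: 1
species:
  raf_total: 100.0
  mek_total: 120.0
  erk_total: 100.0
  p1: 10.0    # Raf phosphatase
  p2: 10.0    # MEK phosphatase
  p3: 10.0    # ppERK -> pERK phosphatase
  p4: 10.0    # pERK -> ERK phosphatase
rates:
  k1: 2.0       # Raf activation by RasGTP (per dose unit, via km1)
  km1: 1.0e+6
  k2: 1.0       # Raf deactivation by p1
  km2: 200.0
  k3: 0.8       # MEK phosphorylation by active Raf (first site)
  k3b: 0.8      # second site
  km3: 200.0
  k4: 1.0       # MEK dephosphorylation by p2 (both sites)
  km4: 200.0
  k5: 0.55      # ERK phosphorylation by ppMEK (first site)
  k5b: 30.0     # second site (fast, distributive)
  km5: 40.0
  k6: 0.3       # ppERK -> pERK (p3, operating near saturation)
  km6: 0.05
  k7: 0.7       # pERK -> ERK (p4, operating near saturation)
  km7: 0.05
  ki: 300.0     # ppERK feedback inhibition of Raf activation (intact, weak)
  nfb: 1.0
simulation:
  t_end: 240.0
  perk_threshold: 17.0
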
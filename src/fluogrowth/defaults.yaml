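# Default simulation parameters (versioned; loaded by fluogrowth.simulate).
#
# Units: r, m, lysis_rate in h^-1; x0 and K in OD-equivalent units; s in
# A.U. per OD per hour; blank levels in the channel's own units; cvs are
# multiplicative coefficients of variation.
strain:
  r: 1.0            # max specific growth rate; fast grower, ~5 h to plateau
  x0: 0.005         # inoculum: OD 0.05 culture diluted 1:10 into the well
  s: 2300.0         # dark-fluorophore production; puts the signal near
                    # 3.5e4 A.U. by 20 h at K = 1.2
  m: 0.5            # chromophore maturation rate (~1.4 h half-time)
  lysis_rate: 0.0   # biomass loss after resource exhaustion (off by default)
K: 1.2              # carrying capacity at 100%-strength nutrient broth
noise:
  od_cv: 0.05       # OD replicate scatter (larger than fluorescence)
  fluo_cv: 0.01
  od_blank: 0.04    # baseline absorbance of the medium
  blank_autofluorescence:
    red: 120.0
    yellow: 150.0
    green: 150.0
cfu:
  conversion: 8.0e8 # CFU ml^-1 per OD unit
  sigma: 0.1        # lognormal sd of plating/sampling error
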
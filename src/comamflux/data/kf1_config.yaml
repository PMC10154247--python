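# Companion configuration for the KF-1 central-carbon model.
#
# Metabolite roles are inferred from the reaction table (species never
# produced are substrate sources, species never consumed are sinks); entries
# here override or annotate that inference.

symmetric: [SUC, FUM]          # rotationally symmetric: orientation scrambles 50/50

uptake_reaction: UPT_4HB
co2_input_reaction: CO2up      # dissolved-CO2 inflow; its 13C content is a model input

secretion_reactions: [SEC_PCA, SEC_PDC, SEC_PYR, SEC_AKG, SEC_MAL, SEC_GLU]

biomass_reactions: [BM_G6P, BM_F6P, BM_R5P, BM_E4P, BM_GAP, BM_PG3, BM_PEP,
                    BM_PYR, BM_ACA, BM_OAA, BM_AKG]

# Precursor demand, mmol per g_CDW, per unit growth rate (h^-1).  Multiply by
# the measured growth rate to obtain the biomass efflux rate of each
# precursor.  Reconstructed values for a gluconeogenic heterotroph; a
# strain-specific biomass composition is not available, so no numerical
# result in this package depends on these beyond internal consistency.
biomass_efflux:
  G6P: 0.915
  F6P: 0.458
  R5P: 1.831
  E4P: 1.373
  GAP: 0.687
  PG3: 4.119
  PEP: 1.831
  PYR: 5.492
  ACA: 6.865
  OAA: 4.119
  AKG: 4.119

# Full-molecule mass isotopomer distributions of these ten metabolites are
# the default fitting measurements.
measured_metabolites: [MAL, FUM, CIT, AKG, PYR, PEP, PG3, F6P, G6P, S7P]

# Mqo and ME-2 proteins are undetected during growth on 4HB, and each is
# structurally collinear with another reaction (Mdh reverse, ME-1); fixing
# them keeps the flux basis identifiable.
fixed_fluxes:
  Mqo: 0.0
  ME2: 0.0

natural_abundance: 0.0107      # 13C natural abundance applied to measurements
temperature_K: 303.15          # 30 C culture temperature
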
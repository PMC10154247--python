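# Central-carbon metabolic network of Comamonas testosteroni KF-1 (57 reactions)
# for steady-state 13C metabolic flux analysis of gluconeogenic growth on
# 4-hydroxybenzoate (4HB).  Atom maps are lowercase letter strings; carbon
# position 1 is the carboxyl carbon as conventionally drawn.  The ortho and
# 2,3-meta protocatechuate cleavage routes are inactive in KF-1 under these
# conditions and are deliberately not flux-carrying parts of this model.
#
# Reconstruction notes: the 4,5-meta funnel runs PCA -> 4CHMS -> PDC -> OMA
# (enol) -> OMA (keto) -> CHA -> pyruvate + OAA in six enzymatic steps with no
# CO2 loss; the enol/keto tautomerization (PmdU) is kept at equilibrium
# (reversible, unconstrained).  Oxidative TCA reactions from OAA to succinate
# are irreversible; succinate<->fumarate<->malate<->OAA and the three
# cataplerotic reactions are reversible.  Cofactor assignments follow the
# KF-1 enzyme assays (PobA, PmdC, IDH, ME-1: NADPH; Mdh, ME-2: NADH).

# -- uptake and the 4,5-meta cleavage funnel --------------------------------
UPT_4HB: FHBx (abcdefg) -> FHB (abcdefg) [enzyme: PmdK]
PobA: FHB (abcdefg) -> PCA (abcdefg) [cofactors: NADPH=-1] [enzyme: PobA]
PmdAB: PCA (abcdefg) -> CHMS (abcdefg) [enzyme: PmdAB]
PmdC: CHMS (abcdefg) -> PDC (abcdefg) [cofactors: NADPH=1] [enzyme: PmdC]
PmdD: PDC (abcdefg) -> OMAe (abcdefg) [enzyme: PmdD]
PmdU: OMAe (abcdefg) -> OMAk (abcdefg) [reversible] [enzyme: PmdU]
PmdE: OMAk (abcdefg) -> CHA (abcdefg) [enzyme: PmdE]
PmdF: CHA (abcdefg) -> PYR (edc) + OAA (abgf) [enzyme: PmdF]

# -- TCA cycle --------------------------------------------------------------
GltA: OAA (abcd) + ACA (ef) -> CIT (efbcda) [enzyme: GltA]
Acn: CIT (abcdef) -> ICIT (abcdef) [enzyme: AcnA]
IDH: ICIT (abcdef) -> AKG (edcba) + CO2 (f) [cofactors: NADPH=1] [enzyme: IDH1]
SucAB: AKG (abcde) -> SUC (bcde) + CO2 (a) [cofactors: NADH=1,ATP=1] [enzyme: SucABCD]
Sdh: SUC (abcd) -> FUM (abcd) [reversible] [cofactors: FADH2=1] [enzyme: SdhABCD]
FumC: FUM (abcd) -> MAL (abcd) [reversible] [enzyme: FumC]
Mdh: OAA (abcd) -> MAL (abcd) [reversible] [cofactors: NADH=-1] [enzyme: Mdh]
Mqo: MAL (abcd) -> OAA (abcd) [cofactors: FADH2=1] [enzyme: Mqo]

# -- glyoxylate shunt -------------------------------------------------------
AceA: ICIT (abcdef) -> SUC (fcba) + GLX (ed) [enzyme: AceA]
GlcB: GLX (ab) + ACA (cd) -> MAL (abdc) [enzyme: GlcB]

# -- cataplerosis -----------------------------------------------------------
PckG: OAA (abcd) -> PEP (abc) + CO2 (d) [reversible] [cofactors: ATP=-1] [enzyme: PckG]
ME1: MAL (abcd) -> PYR (abc) + CO2 (d) [reversible] [cofactors: NADPH=1] [enzyme: ME-1]
ME2: MAL (abcd) -> PYR (abc) + CO2 (d) [reversible] [cofactors: NADH=1] [enzyme: ME-2]
OadC: OAA (abcd) -> PYR (abc) + CO2 (d) [reversible] [enzyme: PmdF(OAA-decarboxylase)]

# -- acetyl-CoA and PEP synthesis -------------------------------------------
Pdh: PYR (abc) -> ACA (bc) + CO2 (a) [cofactors: NADH=1] [enzyme: PDH]
Pps: PYR (abc) -> PEP (abc) [cofactors: ATP=-2] [enzyme: PEPs]

# -- gluconeogenic EMP chain ------------------------------------------------
Eno: PEP (abc) -> PG2 (abc) [reversible] [enzyme: Eno]
Gpm: PG2 (abc) -> PG3 (abc) [reversible] [enzyme: Gpm]
Pgk: PG3 (abc) -> BPG (abc) [reversible] [cofactors: ATP=-1] [enzyme: Pgk]
GapA: BPG (abc) -> GAP (abc) [reversible] [cofactors: NADH=-1] [enzyme: GapA]
Tpi: GAP (abc) -> DHAP (abc) [reversible] [enzyme: TpiA]
Fba: DHAP (abc) + GAP (def) -> FBP (abcdef) [reversible] [enzyme: Fba]
Fbp: FBP (abcdef) -> F6P (abcdef) [enzyme: Fbp]
Pgi: F6P (abcdef) -> G6P (abcdef) [reversible] [enzyme: Pgi]

# -- non-oxidative pentose phosphate pathway --------------------------------
RpiA: R5P (abcde) -> Ru5P (abcde) [reversible] [enzyme: RpiA]
Rpe: Ru5P (abcde) -> X5P (abcde) [reversible] [enzyme: Rpe]
TktA: X5P (abcde) + R5P (fghij) -> S7P (abfghij) + GAP (cde) [reversible] [enzyme: TktA]
TktB: X5P (abcde) + E4P (fghi) -> F6P (abfghi) + GAP (cde) [reversible] [enzyme: TktB]
Tal: S7P (abcdefg) + GAP (hij) -> F6P (abchij) + E4P (defg) [reversible] [enzyme: TalB]

# -- CO2 exchange -----------------------------------------------------------
# Dissolved CO2 mixes network-produced CO2 with an external pool whose 13C
# content is an input parameter (measurable via N-carbamoyl-aspartate labeling).
CO2up: CO2x (a) -> CO2 (a) [enzyme: CO2-uptake]
CO2out: CO2 (a) -> CO2sink (a) [enzyme: CO2-efflux]

# -- biomass precursor effluxes ---------------------------------------------
BM_G6P: G6P (abcdef) -> bmG6P (abcdef) [enzyme: biomass]
BM_F6P: F6P (abcdef) -> bmF6P (abcdef) [enzyme: biomass]
BM_R5P: R5P (abcde) -> bmR5P (abcde) [enzyme: biomass]
BM_E4P: E4P (abcd) -> bmE4P (abcd) [enzyme: biomass]
BM_GAP: GAP (abc) -> bmGAP (abc) [enzyme: biomass]
BM_PG3: PG3 (abc) -> bmPG3 (abc) [enzyme: biomass]
BM_PEP: PEP (abc) -> bmPEP (abc) [enzyme: biomass]
BM_PYR: PYR (abc) -> bmPYR (abc) [enzyme: biomass]
BM_ACA: ACA (ab) -> bmACA (ab) [enzyme: biomass]
BM_OAA: OAA (abcd) -> bmOAA (abcd) [enzyme: biomass]
BM_AKG: AKG (abcde) -> bmAKG (abcde) [enzyme: biomass]

# -- measured secretions during growth on 4HB -------------------------------
SEC_PCA: PCA (abcdefg) -> PCAx (abcdefg) [enzyme: secretion]
SEC_PDC: PDC (abcdefg) -> PDCx (abcdefg) [enzyme: secretion]
SEC_PYR: PYR (abc) -> PYRx (abc) [enzyme: secretion]
SEC_AKG: AKG (abcde) -> AKGx (abcde) [enzyme: secretion]
SEC_MAL: MAL (abcd) -> MALx (abcd) [enzyme: secretion]
SEC_GLU: AKG (abcde) -> GLUx (abcde) [cofactors: NADPH=-1] [enzyme: GdhA+secretion]

# -- ATP maintenance --------------------------------------------------------
ATPM:  ->  [cofactors: ATP=-1] [enzyme: maintenance]
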
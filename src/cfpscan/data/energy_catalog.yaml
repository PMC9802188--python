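# Default energy-pathway catalog: 34 diagnostic pathways for the oxidation
# of 11 inorganic electron donors, plus the chlorophyll and
# bacteriochlorophyll biosynthesis superpathways used to score
# photosynthetic potential.
#
# These are synthetic fixture pathways exercising the scoring semantics
# (best pathway per compound, strict >cutoff reporting, no genome-
# completeness adjustment).  Users with curated reaction databases can load
# their own catalog through the same schema: per compound, a list of
# pathways, each a list of reaction ids; reference sequences resolve from a
# sidecar FASTA keyed by reaction id, or default to deterministic synthetic
# stand-ins.
version: "1.0"
report_cutoff_pct: 75
compounds:
  hydrogen:
    - pathway_id: H2.NiFe-uptake
      reactions: [H2.NiFe.hyaA, H2.NiFe.hyaB, H2.NiFe.hyaC]
    - pathway_id: H2.FeFe
      reactions: [H2.FeFe.hydA, H2.FeFe.hydB]
    - pathway_id: H2.hox-bidirectional
      reactions: [H2.hox.hoxF, H2.hox.hoxU, H2.hox.hoxY, H2.hox.hoxH]
    - pathway_id: H2.membrane-bound
      reactions: [H2.mbh.mbhL, H2.mbh.mbhS, H2.mbh.mbhM]
  sulfide:
    - pathway_id: S2.sqr
      reactions: [S2.sqr.sqr, S2.sqr.pdo]
    - pathway_id: S2.fcc
      reactions: [S2.fcc.fccA, S2.fcc.fccB]
    - pathway_id: S2.rdsr
      reactions: [S2.rdsr.dsrA, S2.rdsr.dsrB, S2.rdsr.dsrC, S2.rdsr.aprA]
    - pathway_id: S2.sox-extended
      reactions: [S2.sox.soxC, S2.sox.soxD, S2.sox.soxY]
  sulfite:
    - pathway_id: SO3.sorAB
      reactions: [SO3.sor.sorA, SO3.sor.sorB]
    - pathway_id: SO3.apr-reverse
      reactions: [SO3.apr.aprA, SO3.apr.aprB, SO3.apr.sat]
    - pathway_id: SO3.soeABC
      reactions: [SO3.soe.soeA, SO3.soe.soeB, SO3.soe.soeC]
  sulfur:
    - pathway_id: S0.sdo
      reactions: [S0.sdo.sdo, S0.sdo.rhd]
    - pathway_id: S0.sor-disproportionation
      reactions: [S0.sor.sor, S0.sor.tth]
    - pathway_id: S0.hdr-oxidation
      reactions: [S0.hdr.hdrA, S0.hdr.hdrB, S0.hdr.hdrC]
  thiosulfate:
    - pathway_id: TS.soxABXYZ
      reactions: [TS.sox.soxA, TS.sox.soxB, TS.sox.soxX, TS.sox.soxY, TS.sox.soxZ]
    - pathway_id: TS.tsdA
      reactions: [TS.tsd.tsdA, TS.tsd.tsdB]
    - pathway_id: TS.doxAD
      reactions: [TS.dox.doxA, TS.dox.doxD]
  carbon_monoxide:
    - pathway_id: CO.coxLMS
      reactions: [CO.cox.coxL, CO.cox.coxM, CO.cox.coxS]
    - pathway_id: CO.codh-anaerobic
      reactions: [CO.codh.cooS, CO.codh.cooF]
    - pathway_id: CO.coxG-accessory
      reactions: [CO.coxg.coxG, CO.coxg.coxE, CO.coxg.coxF]
  carbon_disulfide:
    - pathway_id: CS2.hydrolase
      reactions: [CS2.hyd.cs2A, CS2.hyd.cs2B]
    - pathway_id: CS2.cos-route
      reactions: [CS2.cos.cosA, CS2.cos.cosB, CS2.cos.cosC]
  nitrite:
    - pathway_id: NO2.nxrAB
      reactions: [NO2.nxr.nxrA, NO2.nxr.nxrB]
    - pathway_id: NO2.nxr-membrane
      reactions: [NO2.nxrm.nxrA2, NO2.nxrm.nxrB2, NO2.nxrm.nxrC]
    - pathway_id: NO2.oxidoreductase-periplasmic
      reactions: [NO2.per.norA, NO2.per.norB]
  ammonia:
    - pathway_id: NH3.amo-hao
      reactions: [NH3.amo.amoA, NH3.amo.amoB, NH3.amo.amoC, NH3.amo.haoA]
    - pathway_id: NH3.archaeal-amo
      reactions: [NH3.aamo.amoA, NH3.aamo.amoB, NH3.aamo.amoX]
    - pathway_id: NH3.hydroxylamine-only
      reactions: [NH3.hao.haoA, NH3.hao.cycA]
  manganese:
    - pathway_id: Mn.mco
      reactions: [Mn.mco.mcoA, Mn.mco.mcoB]
    - pathway_id: Mn.mnx
      reactions: [Mn.mnx.mnxG, Mn.mnx.mnxE, Mn.mnx.mnxF]
    - pathway_id: Mn.peroxidase
      reactions: [Mn.mop.mopA, Mn.mop.mopB]
  iron:
    - pathway_id: Fe.cyc2
      reactions: [Fe.cyc2.cyc2, Fe.cyc2.cyc1]
    - pathway_id: Fe.mto
      reactions: [Fe.mto.mtoA, Fe.mto.mtoB, Fe.mto.mtoD]
    - pathway_id: Fe.fox
      reactions: [Fe.fox.foxE, Fe.fox.foxY, Fe.fox.foxZ]
photosynthesis:
  chlorophyll:
    pathway_id: pigment.chlorophyll
    reactions: [chl.chlH, chl.chlM, chl.chlE, chl.por, chl.chlG, chl.chlP]
  bacteriochlorophyll:
    pathway_id: pigment.bacteriochlorophyll
    reactions: [bchl.bchH, bchl.bchM, bchl.bchE, bchl.bchL, bchl.bchX, bchl.bchF, bchl.bchG, bchl.bchP]
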
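# Canonical physicochemical and tissue-composition defaults for the
# steady-state partitioning model of the three EGFR-TKI PET tracers.
# Units: fractional volumes are dimensionless (mL/mL tissue), acidic
# phospholipid (AP-) concentrations are mg/g tissue, EGFR and Kd are nM.
# Sources per field are listed under `provenance`.

compounds:
  erlotinib:
    log_p: 3.3
    pka: 5.5
    fu_plasma: 0.088
    bp_ratio: 0.95
    kd_egfr_nM: 2164.0
    base_class: weak
  afatinib:
    log_p: 3.6
    pka: 8.2
    fu_plasma: 0.095
    bp_ratio: 1.27
    kd_egfr_nM: 2.0
    base_class: strong
  osimertinib:
    log_p: 3.2
    pka: 9.0
    fu_plasma: 0.017
    bp_ratio: 0.79
    kd_egfr_nM: 155.0
    base_class: strong

# Tissue order follows the whole-body validation table
# (brain, lung, spleen, kidney, bone, tumor).
tissues:
  brain:
    f_nl: 0.039
    f_np: 0.0015
    f_ew: 0.16
    f_iw: 0.61
    ap_conc_mg_g: 0.40
    alb_ratio: 0.048
    egfr_nM: 0.0          # no reliable receptor-density data; assumed absent
    ph_ew: 7.4
    ph_iw: 7.0
    cell_types:
      - {name: residual, fraction: 1.0, f_lys: 0.014, ph_lys: 5.3}
  lung:
    f_nl: 0.0088
    f_np: 0.0030
    f_ew: 0.34
    f_iw: 0.43
    ap_conc_mg_g: 0.57
    alb_ratio: 0.21
    egfr_nM: 31.1
    ph_ew: 7.4
    ph_iw: 7.0
    cell_types:
      - {name: alveolar_macrophages, fraction: 0.041, f_lys: 0.078, ph_lys: 4.75}
      - {name: type_ii_cells, fraction: 0.083, f_lys: 0.03, ph_lys: 5.1}
      - {name: residual, fraction: 0.876, f_lys: 0.01, ph_lys: 5.1}
  spleen:
    f_nl: 0.021
    f_np: 0.017
    f_ew: 0.21
    f_iw: 0.53
    ap_conc_mg_g: 3.18
    alb_ratio: 0.097
    egfr_nM: 54.6
    ph_ew: 7.4
    ph_iw: 7.0
    cell_types:
      - {name: residual, fraction: 1.0, f_lys: 0.053, ph_lys: 5.3}
  kidney:
    f_nl: 0.039
    f_np: 0.012
    f_ew: 0.27
    f_iw: 0.47
    ap_conc_mg_g: 2.44
    alb_ratio: 0.13
    egfr_nM: 177.0
    ph_ew: 7.4
    ph_iw: 7.0
    cell_types:
      - {name: residual, fraction: 1.0, f_lys: 0.017, ph_lys: 5.3}
  bone:
    f_nl: 0.017
    f_np: 0.0017
    f_ew: 0.1
    f_iw: 0.35
    ap_conc_mg_g: 0.67
    alb_ratio: 0.10
    egfr_nM: 0.0          # no reliable receptor-density data; assumed absent
    ph_ew: 7.4
    ph_iw: 7.0
    cell_types: []        # lysosomal volume fraction not determined
  tumor:
    # NSCLC adenocarcinoma, derived from lung by the tumor-hallmark
    # overrides: immune-deprived cell mix (residual cells only), acidic
    # extracellular water; AP- and albumin ratio inherited from lung.
    f_nl: 0.008
    f_np: 0.0030
    f_ew: 0.34
    f_iw: 0.43
    ap_conc_mg_g: 0.57
    alb_ratio: 0.21
    egfr_nM: 299.0
    ph_ew: 6.7
    ph_iw: 7.0
    cell_types:
      - {name: residual, fraction: 1.0, f_lys: 0.01, ph_lys: 5.1}

blood:
  hematocrit: 0.45
  ph_plasma: 7.4
  ph_bc: 7.22
  bc_f_iw: 0.60
  bc_f_nl: 0.0017
  bc_f_np: 0.0029
  bc_ap_mg_g: 0.50

# Source of every numeric default, keyed by `<section>.<field>` with
# tissue- or compound-specific entries overriding the generic ones.
provenance:
  compound.log_p: "octanol/water log partition coefficient, Colclough et al. 2021"
  compound.pka: "basic pKa, Colclough et al. 2021"
  compound.fu_plasma: "fraction unbound in plasma, Colclough et al. 2021"
  compound.bp_ratio: "whole-blood to plasma concentration ratio measured in the PET tracer studies, van de Stadt et al. 2021"
  compound.kd_egfr_nM: "wild-type EGFR dissociation constant, Joly-Tonetti et al. 2021"
  compound.base_class: "classified from pKa: strong base if pKa > 7, else weak"
  tissue.f_nl: "fractional neutral-lipid volume, Rodgers & Rowland 2005/2006 (rat-to-human translation where flagged)"
  tissue.f_np: "fractional neutral-phospholipid volume, Rodgers & Rowland 2005/2006"
  tissue.f_ew: "fractional extracellular-water volume, Rodgers & Rowland 2005/2006"
  tissue.f_iw: "fractional intracellular-water volume, Rodgers & Rowland 2005/2006; lung and tumor use the whole-tissue 0.43, not the 0.45 of the cell-type sub-table"
  tissue.ap_conc_mg_g: "acidic-phospholipid concentration, Rodgers & Rowland 2005/2006; tumor inherits the lung value"
  tissue.alb_ratio: "albumin tissue-to-plasma ratio, Rodgers & Rowland 2006; tumor inherits the lung value"
  tissue.egfr_nM: "tissue EGFR concentration, Glassman & Balthasar 2016; brain and bone assumed receptor-free for lack of data"
  tissue.ph_ew: "extracellular-water pH; 7.4 physiological (a 7.22 lung literature value exists and is selectable via overrides), 6.7 in tumor per tumor-microenvironment acidification literature"
  tissue.ph_iw: "intracellular-water pH 7.0, Rodgers & Rowland 2005/2006"
  tissue.cell_types: "lysosome-bearing cell populations; lung composition from Assmus et al. 2017 (macrophages/type II/residual), tumor immune-deprived residual cells only"
  cell.fraction: "cell-type fraction of tissue cells, Assmus et al. 2017; lung residual 0.876 so fractions sum to 1"
  cell.f_lys: "lysosomal volume fraction, Assmus et al. 2017 / Schmitt et al. 2021"
  cell.ph_lys: "lysosomal pH, Assmus et al. 2017 (4.75 macrophages, 5.1 epithelial/residual); 5.3 default for tissues without a cell-type-resolved composition"
  blood.hematocrit: "hematocrit 0.45, standard physiological value"
  blood.ph_plasma: "plasma pH 7.4, physiological"
  blood.ph_bc: "blood-cell intracellular pH 7.22, Rodgers & Rowland 2005 erythrocyte value; anchors the acidic-phospholipid calibration"
  blood.bc_f_iw: "blood-cell intracellular-water fraction, Rodgers & Rowland 2005"
  blood.bc_f_nl: "blood-cell neutral-lipid fraction, Rodgers & Rowland 2005"
  blood.bc_f_np: "blood-cell neutral-phospholipid fraction, Rodgers & Rowland 2005"
  blood.bc_ap_mg_g: "blood-cell acidic-phospholipid concentration, Rodgers & Rowland 2005"
  scenario.f_vasc: "tumor/lung microvessel-density ratio 0.36 from CD31+ histology of NSCLC adenocarcinoma vs normal lung"
  scenario.f_perf: "tumor perfusion coefficient 1 (tracer uptake shown perfusion-independent)"
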
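# Reference fixture: published screen outcomes for the 11-compound CiPA-style
# panel plus vehicle (DMSO), with FDA-label ground truth.
# Per-threshold columns give the call direction (up/down/none) on the
# Fridericia-corrected FPD percent change and the lowest crossing
# concentration (uM). c_max_uM values are back-derived from the published
# concentration/C_max ratio columns where self-consistent; f_etpc_uM values
# are the free effective therapeutic plasma concentrations reported in the
# CiPA MEA literature for the same compounds.
compound,vehicle,cipa_risk,qt_label,tdp_label,low_direction,low_conc_uM,mid_direction,mid_conc_uM,high_direction,high_conc_uM,arrhythmia,arrhythmia_lowest_uM,arrhythmia_tissue_pct,cessation,cessation_tissue_pct,c_max_uM,f_etpc_uM,max_tested_uM
sotalol,0,H,1,1,up,7.5,up,30,up,30,0,,,0,,15,14.7,30
dofetilide,0,H,1,1,up,0.001,up,0.002,up,0.002,1,0.001,66,1,33,0.002,0.002,0.01
quinidine,0,H,1,1,up,0.06,up,1,up,10,1,0.1,50,0,,0.3,3.237,10
cisapride,0,I,1,1,down,0.0025,down,0.0025,down,0.0025,1,0.001,50,1,25,0.0025,0.0026,0.3
terfenadine,0,I,1,1,up,0.1,up,0.1,up,0.1,1,0.001,60,0,,0.000286,0.00029,0.3
ranolazine,0,L,1,0,up,1,up,2,up,2,1,2,20,0,,1.95,1.95,10
mexiletine,0,L,0,0,up,50,none,,none,,0,,,0,,2.5,2.5,50
nifedipine,0,L,0,0,down,0.001,down,0.005,down,0.01,0,,,0,,0.0077,0.0077,0.1
verapamil,0,L,0,0,down,0.010,down,0.05,down,0.05,0,,,0,,0.045,0.081,1
alfuzosin,0,n.a.,0,0,down,0.3,none,,none,,0,,,0,,0.1,0.139,100
aspirin,0,n.a.,0,0,none,,none,,none,,0,,,0,,10.8,10.8,300
DMSO,1,n.a.,0,0,none,,none,,none,,0,,,0,,,,
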
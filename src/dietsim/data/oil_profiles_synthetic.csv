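# SYNTHETIC per-100 g composition profiles for the oil-substitution
# scenario.  These are package-constructed stand-ins, not survey or food
# database values: sfa_oils approximates a butter / dairy-blend / margarine
# spread mix, healthy_oils an olive / canola / sesame dominant blend.
# Units per 100 g edible portion, as in dietsim.nutrients.UNITS.
nutrient,sfa_oils,healthy_oils
gram_weight,100,100
energy_incl_fibre,3030,3700
protein,0.7,0.0
fat,81,100
carbohydrate,0.6,0.0
sugars,0.6,0.0
added_sugars,0.0,0.0
free_sugars,0.0,0.0
fibre,0.0,0.0
alcohol,0.0,0.0
retinol_equivalents,600,0.0
total_folate_equivalents,3.0,0.0
vitamin_b12,0.1,0.0
calcium,20,1.0
iodine,2.0,0.0
iron,0.1,0.4
sodium,600,1.0
zinc,0.1,0.1
saturated_fat,45,10
monounsaturated_fat,20,60
linoleic_acid,3.0,20
alpha_linolenic_acid,0.5,3.0
lc_omega3,30,0.0
glycaemic_index,0.0,0.0
glycaemic_load,0.0,0.0
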
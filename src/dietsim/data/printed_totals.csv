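# All-food-intake totals as printed in the published intake tables
# (baseline column, and modelled column for the reference combination
# scenario).  Kept as printed, i.e. rounded; used only for cross-checks of
# the aggregation arithmetic, never as computational input.
# The modelled table prints no gram-weight total; the cell is left empty.
nutrient,baseline,modelled
gram_weight,3113,
energy_incl_fibre,7661,7140
protein,79.1,77.7
fat,67.1,70.7
carbohydrate,202,169
sugars,94,94.4
added_sugars,46.5,31.1
free_sugars,53,41.4
fibre,20.6,25.7
alcohol,9.1,4.5
retinol_equivalents,779,1017
total_folate_equivalents,532,461
vitamin_b12,3.8,3.8
calcium,761,670
iodine,153,125
iron,9.6,9.5
sodium,2210,1404
zinc,9.3,9.0
saturated_fat,25.2,20.4
monounsaturated_fat,25.5,28.9
linoleic_acid,8.8,12.2
alpha_linolenic_acid,1.3,1.7
lc_omega3,233.1,1121
glycaemic_index,54.8,52.9
glycaemic_load,110,89.5
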
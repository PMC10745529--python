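# Reference modelled per-group intakes for the combination scenario
# "halve PF, add 150 g/d fruits, 225 g/d vegetables, 30 g/d nuts and
# 40 g/d high-omega-3 fish" (the published modelled-intake table).
# The scenario engine must reproduce these columns from the baseline
# fixture; they are also the source from which the added-food per-100 g
# profiles are derived by differencing against baseline.
# gram_weight rows are derived (baseline grams after the edits), not printed.
nutrient,PF,MP,PCI,fruits,vegetables,nuts,omega3_fish
gram_weight,437,1898,13.6,361,336,33.0,42.2
energy_incl_fibre,2555,1470,245,931,681,788,470
protein,23.3,26.6,0.1,2.9,7.8,5.9,11.1
fat,22.7,13,3.6,1.0,6.0,16.7,7.6
carbohydrate,67.8,30.6,6.8,46,15.6,2.3,0.0
sugars,26.2,11.5,6.8,43.1,5.8,1.1,0.0
added_sugars,18.6,0.6,5.6,6.3,0.0,0.0,0.0
free_sugars,19.3,0.7,6.8,14.6,0.0,0.1,0.0
fibre,5.9,2.1,0.0,7.0,7.0,3.7,0.0
alcohol,4.5,0.0,0.0,0.0,0.0,0.0,0.0
retinol_equivalents,172,120,14.1,147,537,0.9,25.9
total_folate_equivalents,188,72.3,0.2,87.2,90.7,21.7,0.7
vitamin_b12,0.9,1.8,0.0,0.0,0.1,0.0,0.9
calcium,215,268,2.3,46.4,77.2,55.9,5.1
iodine,43.7,59.4,0.4,6.3,5.2,0.4,9.6
iron,3.2,1.7,0.0,1.0,1.7,1.3,0.5
sodium,913,290,32.4,20.8,116,3.6,28
zinc,2.7,2.9,0.0,0.5,1.3,1.3,0.3
saturated_fat,8.9,5.3,1.1,0.1,1.5,1.7,1.7
monounsaturated_fat,8.5,4.9,1.4,0.2,2.8,7.9,3.1
linoleic_acid,3.0,1.2,0.7,0.2,0.8,5.7,0.6
alpha_linolenic_acid,0.5,0.1,0.1,0.0,0.1,0.7,0.2
lc_omega3,57.9,56.9,1.5,0.0,17.9,0.0,987
glycaemic_index,56.0,52.3,63.2,47.2,57.7,21.7,0.0
glycaemic_load,38,16,4.3,21.7,9,0.5,0.0
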
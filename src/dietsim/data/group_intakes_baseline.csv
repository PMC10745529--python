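# Population-average daily intake contributed by each food group (one column
# per group, one row per nutrient; units as in dietsim.nutrients.UNITS).
# Baseline intakes of Australian women of reproductive age (n = 606),
# National Nutrition and Physical Activity Survey 2011-12, grouped by NOVA
# processing level plus the named scenario food groups.
# PF = processed + ultra-processed foods, MP = unprocessed/minimally
# processed, PCI = processed culinary ingredients.
nutrient,PF,MP,PCI,fruits,vegetables,nuts,omega3_fish
gram_weight,874,1898,13.6,211,111,3.0,2.2
energy_incl_fibre,5110,1470,245,451,290,71.6,24.5
protein,46.6,26.6,0.1,1.4,3.3,0.5,0.6
fat,45.5,13,3.6,0.5,2.5,1.5,0.4
carbohydrate,136,30.6,6.8,22.3,6.6,0.2,0.0
sugars,52.3,11.5,6.8,20.9,2.5,0.1,0.0
added_sugars,37.2,0.6,5.6,3.0,0.0,0.0,0.0
free_sugars,38.5,0.7,6.8,7.0,0.0,0.0,0.0
fibre,11.7,2.1,0.0,3.4,3.0,0.3,0.0
alcohol,9.1,0.0,0.0,0.0,0.0,0.0,0.0
retinol_equivalents,344,120,14.1,71.2,229,0.1,1.3
total_folate_equivalents,377,72.3,0.2,42.2,38.6,2.0,0.0
vitamin_b12,1.9,1.8,0.0,0.0,0.1,0.0,0.0
calcium,430,268,2.3,22.5,32.9,5.1,0.3
iodine,87.3,59.4,0.4,3.1,2.2,0.0,0.5
iron,6.5,1.7,0.0,0.5,0.7,0.1,0.0
sodium,1827,290,32.4,10.1,49.5,0.3,1.5
zinc,5.5,2.9,0.0,0.2,0.5,0.1,0.0
saturated_fat,17.9,5.3,1.1,0.0,0.6,0.2,0.1
monounsaturated_fat,17,4.9,1.4,0.1,1.2,0.7,0.2
linoleic_acid,5.9,1.2,0.7,0.1,0.4,0.5,0.0
alpha_linolenic_acid,0.9,0.1,0.1,0.0,0.0,0.1,0.0
lc_omega3,115.7,56.9,1.5,0.0,7.6,0.0,51.4
glycaemic_index,56.1,52.3,63.2,47.1,57.6,0.0,0.0
glycaemic_load,76,16,4.3,10.5,3.8,0.0,0.0
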
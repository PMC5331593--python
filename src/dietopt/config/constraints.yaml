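# Default constraint set for the individual diet-optimization model.
#
# "nutritional" lists the 33 nutrient recommendations enforced at constant
# energy. Bounds are a reconstruction from French adult dietary reference
# values; every row is configuration, not a transcription of an official
# appendix. percent_energy bounds are converted to g/day at the individual's
# (non-alcoholic) observed energy using kcal_per_g.
#
# The free-sugar row is conditional: individuals above 10% of energy from free
# sugars get a 10%-energy ceiling; individuals at or below 10% get a
# "no increase" ceiling at their observed free-sugar intake.

nutritional:
  - {id: protein_min,        kind: nutrient_min, nutrient: protein,       bound: 10,   basis: percent_energy, kcal_per_g: 4}
  - {id: protein_max,        kind: nutrient_max, nutrient: protein,       bound: 20,   basis: percent_energy, kcal_per_g: 4}
  - {id: fat_min,            kind: nutrient_min, nutrient: fat,           bound: 35,   basis: percent_energy, kcal_per_g: 9}
  - {id: fat_max,            kind: nutrient_max, nutrient: fat,           bound: 40,   basis: percent_energy, kcal_per_g: 9}
  - {id: carbohydrate_min,   kind: nutrient_min, nutrient: carbohydrate,  bound: 40,   basis: percent_energy, kcal_per_g: 4}
  - {id: carbohydrate_max,   kind: nutrient_max, nutrient: carbohydrate,  bound: 55,   basis: percent_energy, kcal_per_g: 4}
  - {id: saturated_fat_max,  kind: nutrient_max, nutrient: saturated_fat, bound: 12,   basis: percent_energy, kcal_per_g: 9}
  - {id: free_sugars_max,    kind: nutrient_max, nutrient: free_sugars,   bound: 10,   basis: percent_energy, kcal_per_g: 4,
     condition: fs_conditional}
  - {id: sodium_max,         kind: nutrient_max, nutrient: sodium,        bound: 3150, basis: absolute_per_day}
  - {id: cholesterol_max,    kind: nutrient_max, nutrient: cholesterol,   bound: 300,  basis: absolute_per_day}
  - {id: vitamin_a_max,      kind: nutrient_max, nutrient: vitamin_a,     bound: 3000, basis: absolute_per_day}
  - {id: fiber_min,          kind: nutrient_min, nutrient: fiber,         bound: 25,   basis: absolute_per_day}
  - {id: vitamin_a_min,      kind: nutrient_min, nutrient: vitamin_a,     bound: 750,  basis: absolute_per_day}
  - {id: vitamin_b1_min,     kind: nutrient_min, nutrient: vitamin_b1,    bound: 1.2,  basis: absolute_per_day}
  - {id: vitamin_b2_min,     kind: nutrient_min, nutrient: vitamin_b2,    bound: 1.6,  basis: absolute_per_day}
  - {id: vitamin_b3_min,     kind: nutrient_min, nutrient: vitamin_b3,    bound: 14,   basis: absolute_per_day}
  - {id: vitamin_b5_min,     kind: nutrient_min, nutrient: vitamin_b5,    bound: 5,    basis: absolute_per_day}
  - {id: vitamin_b6_min,     kind: nutrient_min, nutrient: vitamin_b6,    bound: 1.8,  basis: absolute_per_day}
  - {id: vitamin_b9_min,     kind: nutrient_min, nutrient: vitamin_b9,    bound: 330,  basis: absolute_per_day}
  - {id: vitamin_b12_min,    kind: nutrient_min, nutrient: vitamin_b12,   bound: 2.4,  basis: absolute_per_day}
  - {id: vitamin_c_min,      kind: nutrient_min, nutrient: vitamin_c,     bound: 110,  basis: absolute_per_day}
  - {id: vitamin_d_min,      kind: nutrient_min, nutrient: vitamin_d,     bound: 5,    basis: absolute_per_day}
  - {id: vitamin_e_min,      kind: nutrient_min, nutrient: vitamin_e,     bound: 12,   basis: absolute_per_day}
  - {id: calcium_min,        kind: nutrient_min, nutrient: calcium,       bound: 900,  basis: absolute_per_day}
  - {id: iron_min,           kind: nutrient_min, nutrient: iron,          bound: 12.5, basis: absolute_per_day}
  - {id: magnesium_min,      kind: nutrient_min, nutrient: magnesium,     bound: 400,  basis: absolute_per_day}
  - {id: zinc_min,           kind: nutrient_min, nutrient: zinc,          bound: 11,   basis: absolute_per_day}
  - {id: potassium_min,      kind: nutrient_min, nutrient: potassium,     bound: 3500, basis: absolute_per_day}
  - {id: copper_min,         kind: nutrient_min, nutrient: copper,        bound: 1.5,  basis: absolute_per_day}
  - {id: iodine_min,         kind: nutrient_min, nutrient: iodine,        bound: 150,  basis: absolute_per_day}
  - {id: selenium_min,       kind: nutrient_min, nutrient: selenium,      bound: 60,   basis: absolute_per_day}
  - {id: phosphorus_min,     kind: nutrient_min, nutrient: phosphorus,    bound: 750,  basis: absolute_per_day}
  - {id: manganese_min,      kind: nutrient_min, nutrient: manganese,     bound: 2.5,  basis: absolute_per_day}

structural:
  # bounds relative to the individual's observed diet / population statistics
  total_weight_multiplier: 1.1   # total diet weight, energy-free drinks excluded
  total_cost_multiplier: 1.1     # total diet cost
  food_max_quantile: 0.95        # acceptability cap per food (among consumers)
  group_max_quantile: 0.95       # acceptability cap per sub-category

parameters:
  repertoire_increase_weight: 1.0   # w+ on relative increases of repertoire foods
  repertoire_decrease_weight: 2.0   # w- on relative decreases of repertoire foods
  nonrepertoire_penalty: 5.0        # pi on introduced non-repertoire foods
  dual_tolerance: 1.0e-6
  solver_tolerance: 1.0e-8
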
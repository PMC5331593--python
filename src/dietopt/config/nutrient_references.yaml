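# Nutrient reference values for adult diet-quality scoring.
# These lists are a reconstruction from French adult dietary reference values;
# they are configuration data, not a transcription of any single official table.
#
# adequacy nutrients: recommended_intake is the MAR basis (population reference
# intake, per day); ear is the average requirement used by the probabilistic
# adequacy score, with requirement_cv its inter-individual coefficient of
# variation.
# moderation nutrients: max_value is the maximum recommended value, either
# absolute per day or as % of energy (basis: percent_energy, with kcal_per_g
# used to convert to grams at a given energy level).

adequacy:
  protein:      {recommended_intake: 58,   ear: 45,   requirement_cv: 0.125, units: g/day}
  fiber:        {recommended_intake: 25,   ear: 19,   requirement_cv: 0.15,  units: g/day}
  vitamin_a:    {recommended_intake: 750,  ear: 580,  requirement_cv: 0.15,  units: ug/day}
  vitamin_b1:   {recommended_intake: 1.2,  ear: 0.9,  requirement_cv: 0.15,  units: mg/day}
  vitamin_b2:   {recommended_intake: 1.6,  ear: 1.3,  requirement_cv: 0.15,  units: mg/day}
  vitamin_b3:   {recommended_intake: 14,   ear: 11,   requirement_cv: 0.15,  units: mg/day}
  vitamin_b5:   {recommended_intake: 5,    ear: 4,    requirement_cv: 0.15,  units: mg/day}
  vitamin_b6:   {recommended_intake: 1.8,  ear: 1.4,  requirement_cv: 0.15,  units: mg/day}
  vitamin_b9:   {recommended_intake: 330,  ear: 250,  requirement_cv: 0.15,  units: ug/day}
  vitamin_b12:  {recommended_intake: 2.4,  ear: 2.0,  requirement_cv: 0.10,  units: ug/day}
  vitamin_c:    {recommended_intake: 110,  ear: 90,   requirement_cv: 0.10,  units: mg/day}
  vitamin_d:    {recommended_intake: 5,    ear: 4,    requirement_cv: 0.15,  units: ug/day}
  vitamin_e:    {recommended_intake: 12,   ear: 9,    requirement_cv: 0.15,  units: mg/day}
  calcium:      {recommended_intake: 900,  ear: 750,  requirement_cv: 0.125, units: mg/day}
  iron:         {recommended_intake: 12.5, ear: 9,    requirement_cv: 0.15,  units: mg/day}
  magnesium:    {recommended_intake: 400,  ear: 330,  requirement_cv: 0.15,  units: mg/day}
  zinc:         {recommended_intake: 11,   ear: 9,    requirement_cv: 0.125, units: mg/day}
  potassium:    {recommended_intake: 3500, ear: 2800, requirement_cv: 0.15,  units: mg/day}
  copper:       {recommended_intake: 1.5,  ear: 1.1,  requirement_cv: 0.15,  units: mg/day}
  iodine:       {recommended_intake: 150,  ear: 110,  requirement_cv: 0.15,  units: ug/day}
  selenium:     {recommended_intake: 60,   ear: 45,   requirement_cv: 0.15,  units: ug/day}
  phosphorus:   {recommended_intake: 750,  ear: 580,  requirement_cv: 0.15,  units: mg/day}
  manganese:    {recommended_intake: 2.5,  ear: 1.9,  requirement_cv: 0.15,  units: mg/day}

moderation:
  sodium:        {max_value: 3150, basis: absolute,       requirement_cv: 0.15, units: mg/day}
  saturated_fat: {max_value: 12,   basis: percent_energy, kcal_per_g: 9, requirement_cv: 0.15, units: "% energy"}
  free_sugars:   {max_value: 10,   basis: percent_energy, kcal_per_g: 4, requirement_cv: 0.15, units: "% energy"}

# 23 nutrients entering the mean adequacy ratio
mar_nutrients:
  [protein, fiber, vitamin_a, vitamin_b1, vitamin_b2, vitamin_b3, vitamin_b5,
   vitamin_b6, vitamin_b9, vitamin_b12, vitamin_c, vitamin_d, vitamin_e,
   calcium, iron, magnesium, zinc, potassium, copper, iodine, selenium,
   phosphorus, manganese]

# 3 nutrients entering the mean excess ratio
mer_nutrients: [sodium, saturated_fat, free_sugars]

# 25 nutrients entering the probabilistic adequacy score
# (22 adequacy + 3 moderation)
pandiet_adequacy:
  [protein, fiber, vitamin_a, vitamin_b1, vitamin_b2, vitamin_b3, vitamin_b5,
   vitamin_b6, vitamin_b9, vitamin_b12, vitamin_c, vitamin_d, vitamin_e,
   calcium, iron, magnesium, zinc, potassium, copper, iodine, selenium,
   phosphorus]
pandiet_moderation: [sodium, saturated_fat, free_sugars]
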
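# Food taxonomy: 9 categories, 30 sub-categories.
# Fruits are split fresh/processed, milk and yogurts plain/sweet, so that
# intrinsic sugars can be separated from free sugars at the sub-category level.
categories:
  fruits_vegetables_nuts:
    - fresh_fruits
    - processed_fruits
    - vegetables
    - nuts
  starchy_foods:
    - refined_starches
    - unrefined_starches
    - ready_to_eat_cereals
  meats_eggs_fish:
    - meats_eggs_fish
  mixed_dishes_sandwiches:
    - mixed_dishes
    - sandwiches
  dairy_products:
    - plain_milk
    - sweet_milk
    - plain_yogurts
    - sweet_yogurts
    - cheese
  sweet_products:
    - milk_egg_desserts
    - cakes_pastries
    - biscuits
    - croissants
    - confectionery
    - honey_marmalade_spread
    - table_sugar
  beverages:
    - water
    - hot_beverages
    - diet_beverages
    - sugar_sweetened_beverages
    - fruit_juices
  added_fats_sauces:
    - added_fats
    - sauces
  soya_foods:
    - soya_foods
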
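# FIXTURE configuration for the four-step fiber estimation used by the
# DOH- and HCL-style engines (fiber is not a mandatory label nutrient).
# Subcategory lists align with the synthetic generator's taxonomy.
zero_fiber_subcategories:
  - carbonated soft drinks
  - cheese
  - drinking yogurt
  - cooking oils
  - margarine
  - gum jellies
fiber_ingredient_terms:
  - inulin
  - polydextrose
  - oligofructose
  - oat fiber
  - wheat bran
  - psyllium
  - wheat flour
  - whole wheat flour
  - oats
  - almonds
  - peanuts
  - pistachios
  - cashews
  - pumpkin kernels
  - rice
  - corn
  - soybeans
  - mushrooms
  - tomatoes
  - vegetables
  - carrots
  - onion
  - garlic
  - banana
  - mango
  - seaweed
  - coconut
averaging_subcategories:
  - sweet biscuits
  - wet soups
  - instant noodles
  - potato snacks
min_ingredient_overlap: 0.5
fallback_value: 1.0
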
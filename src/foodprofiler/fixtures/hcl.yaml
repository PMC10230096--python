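# SYNTHETIC FIXTURE ruleset for the Healthier Choice Logo style
# front-of-pack eligibility system.  Thresholds are illustrative test
# values, NOT the official criteria.  Semantics: a product is eligible for
# the logo only if EVERY criterion of its category holds; categories the
# scheme does not cover (here: confectionery) are not classifiable.
system: HCL
categories:
  - name: Beverages
    match:
      - category: beverages
  - name: Snacks
    match:
      - category: snacks
  - name: Bakery products
    match:
      - category: bakery
  - name: Dairy products
    match:
      - category: dairy
  - name: Ready meals
    match:
      - category: ready meals
  - name: Seasonings and sauces
    match:
      - category: sauces & seasonings
  - name: Fats and oils
    match:
      - category: fats & oils
criteria:
  Beverages:
    thresholds:
      - {nutrient: total_sugars, comparator: "<=", threshold: 5}
      - {nutrient: energy, comparator: "<=", threshold: 40}
      - {nutrient: sodium, comparator: "<=", threshold: 50}
  Snacks:
    thresholds:
      - {nutrient: fiber, comparator: ">=", threshold: 2}
      - {nutrient: total_fat, comparator: "<=", threshold: 20}
      - {nutrient: sodium, comparator: "<=", threshold: 500}
      - {nutrient: total_sugars, comparator: "<=", threshold: 10}
      - {nutrient: energy, comparator: "<=", threshold: 500}
  Bakery products:
    thresholds:
      - {nutrient: fiber, comparator: ">=", threshold: 1.5}
      - {nutrient: total_sugars, comparator: "<=", threshold: 20}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 8}
      - {nutrient: sodium, comparator: "<=", threshold: 300}
  Dairy products:
    thresholds:
      - {nutrient: protein, comparator: ">=", threshold: 2.5}
      - {nutrient: calcium, comparator: ">=", threshold: 100}
      - {nutrient: total_sugars, comparator: "<=", threshold: 8}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 3}
  Ready meals:
    thresholds:
      - {nutrient: protein, comparator: ">=", threshold: 5}
      - {nutrient: sodium, comparator: "<=", threshold: 600}
      - {nutrient: total_fat, comparator: "<=", threshold: 12}
      - {nutrient: energy, comparator: "<=", threshold: 300}
  Seasonings and sauces:
    thresholds:
      - {nutrient: sodium, comparator: "<=", threshold: 900}
      - {nutrient: total_sugars, comparator: "<=", threshold: 15}
      - {nutrient: total_fat, comparator: "<=", threshold: 15}
  Fats and oils:
    thresholds:
      - {nutrient: saturated_fat, comparator: "<=", threshold: 25}
      - {nutrient: sodium, comparator: "<=", threshold: 90}
      - {nutrient: total_fat, comparator: "<=", threshold: 100}
required_nutrients:
  Beverages: [total_sugars, energy, sodium]
  Snacks: [fiber, total_fat, sodium, total_sugars, energy]
  Bakery products: [fiber, total_sugars, saturated_fat, sodium]
  Dairy products: [protein, calcium, total_sugars, saturated_fat]
  Ready meals: [protein, sodium, total_fat, energy]
  Seasonings and sauces: [sodium, total_sugars, total_fat]
  Fats and oils: [saturated_fat, sodium, total_fat]
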
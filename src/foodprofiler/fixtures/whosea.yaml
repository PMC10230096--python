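# SYNTHETIC FIXTURE ruleset for the WHO South-East Asia style nutrient
# profile model.  Thresholds are illustrative test values, NOT the official
# regional model.  Semantics: a product must not exceed ANY of its
# category's thresholds (per 100 g solids, per 100 ml beverages) for
# marketing to be permitted; a value exactly equal to a threshold passes.
system: WHO_SEA
categories:
  - name: Beverages
    match:
      - category: beverages
  - name: Ready-to-eat savories
    match:
      - category: snacks
  - name: Fine bakery wares
    match:
      - category: bakery
  - name: Dairy products
    match:
      - category: dairy
  - name: Composite foods
    match:
      - category: ready meals
  - name: Sauces dips and dressings
    match:
      - category: sauces & seasonings
  - name: Confectionery
    match:
      - category: confectionery
  - name: Fats and oils
    match:
      - category: fats & oils
criteria:
  Beverages:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 2.5}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 1.25}
      - {nutrient: total_sugars, comparator: "<=", threshold: 6}
      - {nutrient: added_sugars, comparator: "<=", threshold: 0}
      - {nutrient: sodium, comparator: "<=", threshold: 50}
  Ready-to-eat savories:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 10}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 5}
      - {nutrient: total_sugars, comparator: "<=", threshold: 10}
      - {nutrient: added_sugars, comparator: "<=", threshold: 5}
      - {nutrient: sodium, comparator: "<=", threshold: 100}
  Fine bakery wares:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 10}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 5}
      - {nutrient: total_sugars, comparator: "<=", threshold: 15}
      - {nutrient: added_sugars, comparator: "<=", threshold: 10}
      - {nutrient: sodium, comparator: "<=", threshold: 120}
  Dairy products:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 5}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 2}
      - {nutrient: total_sugars, comparator: "<=", threshold: 10}
      - {nutrient: added_sugars, comparator: "<=", threshold: 5}
      - {nutrient: sodium, comparator: "<=", threshold: 100}
  Composite foods:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 10}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 4}
      - {nutrient: total_sugars, comparator: "<=", threshold: 10}
      - {nutrient: added_sugars, comparator: "<=", threshold: 5}
      - {nutrient: sodium, comparator: "<=", threshold: 225}
  Sauces dips and dressings:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 10}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 5}
      - {nutrient: total_sugars, comparator: "<=", threshold: 10}
      - {nutrient: added_sugars, comparator: "<=", threshold: 5}
      - {nutrient: sodium, comparator: "<=", threshold: 350}
  Confectionery:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 15}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 8}
      - {nutrient: total_sugars, comparator: "<=", threshold: 20}
      - {nutrient: added_sugars, comparator: "<=", threshold: 15}
      - {nutrient: sodium, comparator: "<=", threshold: 100}
  Fats and oils:
    thresholds:
      - {nutrient: total_fat, comparator: "<=", threshold: 100}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 20}
      - {nutrient: total_sugars, comparator: "<=", threshold: 5}
      - {nutrient: added_sugars, comparator: "<=", threshold: 0}
      - {nutrient: sodium, comparator: "<=", threshold: 100}
required_nutrients:
  Beverages: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Ready-to-eat savories: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Fine bakery wares: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Dairy products: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Composite foods: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Sauces dips and dressings: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Confectionery: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
  Fats and oils: [total_fat, saturated_fat, total_sugars, added_sugars, sodium]
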
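# SYNTHETIC FIXTURE ruleset for the Thai DOH-style three-group scoring
# system.  Category score tables here are illustrative test values, NOT the
# official Department of Health criteria.  Scoring: for each score rule the
# product earns the points of the first band whose upper bound covers the
# value (above_points beyond the last band); the overall score is
# 100 * earned / maximum, with Group A at >= 80%, Group B at 60-<80%,
# Group C below 60%.  Some categories are automatically prohibited from
# marketing regardless of composition.
system: DOH
cutpoints:
  group_a: 80
  group_b: 60
categories:
  - name: Prohibited products
    auto_prohibited: true
    match:
      - subcategory: carbonated soft drinks
      - category: confectionery
  - name: Beverages
    match:
      - category: beverages
  - name: Snacks
    match:
      - category: snacks
  - name: Bakery products
    match:
      - category: bakery
  - name: Milk and dairy products
    match:
      - category: dairy
  - name: Main meals
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
    scores:
      - {nutrient: total_sugars, bands: [[2, 25], [5, 15], [8, 5]], max_points: 25}
      - {nutrient: sodium, bands: [[20, 25], [60, 15], [120, 5]], max_points: 25}
      - {nutrient: energy, bands: [[25, 25], [45, 15], [70, 5]], max_points: 25}
      - {nutrient: saturated_fat, bands: [[0.5, 25], [1, 15], [2, 5]], max_points: 25}
    marketing:
      - {nutrient: total_sugars, comparator: "<=", threshold: 6}
      - {nutrient: sodium, comparator: "<=", threshold: 100}
  Snacks:
    scores:
      - {nutrient: total_fat, bands: [[8, 25], [15, 15], [25, 5]], max_points: 25}
      - {nutrient: sodium, bands: [[150, 25], [400, 15], [700, 5]], max_points: 25}
      - {nutrient: total_sugars, bands: [[5, 25], [12, 15], [22, 5]], max_points: 25}
      - {nutrient: fiber, bands: [[1, 0], [2.5, 10]], above_points: 25, max_points: 25}
    marketing:
      - {nutrient: total_fat, comparator: "<=", threshold: 12}
      - {nutrient: sodium, comparator: "<=", threshold: 500}
      - {nutrient: total_sugars, comparator: "<=", threshold: 15}
  Bakery products:
    scores:
      - {nutrient: total_sugars, bands: [[8, 25], [18, 15], [30, 5]], max_points: 25}
      - {nutrient: saturated_fat, bands: [[3, 25], [6, 15], [10, 5]], max_points: 25}
      - {nutrient: sodium, bands: [[120, 25], [300, 15], [500, 5]], max_points: 25}
      - {nutrient: fiber, bands: [[0.8, 0], [2, 10]], above_points: 25, max_points: 25}
    marketing:
      - {nutrient: total_sugars, comparator: "<=", threshold: 20}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 8}
  Milk and dairy products:
    scores:
      - {nutrient: total_sugars, bands: [[6, 25], [10, 15], [14, 5]], max_points: 25}
      - {nutrient: saturated_fat, bands: [[1.5, 25], [2.5, 15], [4, 5]], max_points: 25}
      - {nutrient: sodium, bands: [[50, 25], [100, 15], [160, 5]], max_points: 25}
      - {nutrient: protein, bands: [[1.5, 0], [2.8, 10]], above_points: 25, max_points: 25}
    marketing:
      - {nutrient: total_sugars, comparator: "<=", threshold: 8}
      - {nutrient: saturated_fat, comparator: "<=", threshold: 3}
  Main meals:
    scores:
      - {nutrient: sodium, bands: [[120, 25], [300, 15], [600, 5]], max_points: 25}
      - {nutrient: total_fat, bands: [[3, 25], [7, 15], [12, 5]], max_points: 25}
      - {nutrient: energy, bands: [[100, 25], [180, 15], [280, 5]], max_points: 25}
      - {nutrient: protein, bands: [[2.5, 0], [4.5, 10]], above_points: 25, max_points: 25}
    marketing:
      - {nutrient: sodium, comparator: "<=", threshold: 400}
      - {nutrient: total_fat, comparator: "<=", threshold: 10}
  Seasonings and sauces:
    scores:
      - {nutrient: sodium, bands: [[250, 25], [550, 15], [900, 5]], max_points: 25}
      - {nutrient: total_sugars, bands: [[4, 25], [10, 15], [18, 5]], max_points: 25}
      - {nutrient: total_fat, bands: [[2, 25], [6, 15], [12, 5]], max_points: 25}
    marketing:
      - {nutrient: sodium, comparator: "<=", threshold: 600}
  Fats and oils:
    scores:
      - {nutrient: saturated_fat, bands: [[10, 25], [16, 15], [20, 5]], max_points: 25}
      - {nutrient: sodium, bands: [[30, 25], [60, 15], [100, 5]], max_points: 25}
      - {nutrient: total_sugars, bands: [[1, 25], [3, 15], [5, 5]], max_points: 25}
    marketing:
      - {nutrient: saturated_fat, comparator: "<=", threshold: 16}
required_nutrients:
  Beverages: [energy, total_sugars, sodium, saturated_fat]
  Snacks: [total_fat, sodium, total_sugars, fiber]
  Bakery products: [total_sugars, saturated_fat, sodium, fiber]
  Milk and dairy products: [total_sugars, saturated_fat, sodium, protein]
  Main meals: [sodium, total_fat, energy, protein]
  Seasonings and sauces: [sodium, total_sugars, total_fat]
  Fats and oils: [saturated_fat, sodium, total_sugars]
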
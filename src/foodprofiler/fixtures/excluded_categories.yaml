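# Market categories removed at curation stage 3: non-food, alcoholic,
# and special supplementary products.  Fixture list; supply your own via
# curate_products(excluded_categories=...).
excluded_categories:
  - Non-Food Items
  - Alcoholic Beverages
  - Sports & Meal Supplements
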
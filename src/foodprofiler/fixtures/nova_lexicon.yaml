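# SYNTHETIC FIXTURE ingredient lexicon for NOVA classification.  Term
# lists are assembled from standard additive-class names and common
# ingredient vocabulary for testing; they carry no claim of completeness.
# upf_markers: substances of no (or rare) culinary use and cosmetic
#   additive classes whose presence identifies an ultra-processed product.
# pci_substances: processed culinary ingredients (oils, butter, sugar,
#   salt, ...).
# pci_categories: market-category patterns whose products may be PCI.
# preservation_or_added_terms: evidence of group-3 processing (adding
#   salt/sugar/oil, brining, canning, smoking).
# whole_foods: unprocessed/minimally processed ingredient vocabulary,
#   used by the synthetic-data generator to assemble group-1 lists.
upf_markers:
  - maltodextrin
  - dextrose
  - high fructose corn syrup
  - glucose syrup
  - invert sugar
  - protein isolate
  - hydrolyzed vegetable protein
  - modified starch
  - hydrogenated oil
  - interesterified oil
  - flavouring
  - flavoring
  - flavour
  - flavor
  - artificial sweetener
  - aspartame
  - acesulfame
  - sucralose
  - saccharin
  - steviol glycosides
  - emulsifier
  - stabilizer
  - stabiliser
  - thickener
  - gelling agent
  - pectin
  - carrageenan
  - guar gum
  - xanthan gum
  - lecithin
  - colour
  - color
  - colorant
  - anti-caking agent
  - humectant
  - monosodium glutamate
  - msg
e_number_allowlist:
  - e300
  - e330
pci_substances:
  - sugar
  - salt
  - palm oil
  - soybean oil
  - sunflower oil
  - coconut oil
  - rice bran oil
  - olive oil
  - butter
  - lard
  - honey
  - vinegar
  - corn starch
  - tapioca starch
pci_categories:
  - fats & oils
  - fats and oils
  - cooking oils
  - margarine
preservation_or_added_terms:
  - salt
  - sugar
  - oil
  - brine
  - syrup
  - smoked
  - canned
  - vinegar
  - honey
whole_foods:
  - water
  - almonds
  - pistachios
  - peanuts
  - cashews
  - pumpkin kernels
  - rice
  - wheat flour
  - whole wheat flour
  - oats
  - corn
  - soybeans
  - mushrooms
  - tomatoes
  - vegetables
  - carrots
  - onion
  - garlic
  - ginger
  - lemongrass
  - green tea
  - mango
  - banana
  - coconut
  - milk
  - chicken
  - fish
  - shrimp
  - seaweed
  - black pepper
  - chili
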
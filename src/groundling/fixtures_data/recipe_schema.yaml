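name: recipe
entry_class: Recipe
prefixes:
  FOODON: http://purl.obolibrary.org/obo/FOODON_
  UO: http://purl.obolibrary.org/obo/UO_
  WIKIDATA: http://www.wikidata.org/entity/
enums:
  UnitSet:
    permissible_values:
      - UO:9000001
      - UO:9000002
      - UO:9000003
      - UO:9000004
      - UO:9000005
classes:
  Recipe:
    attributes:
      label:
        range: string
        prompt: the name of the recipe
      description:
        range: string
        prompt: a brief description of the recipe
      categories:
        range: string
        multivalued: true
        prompt: the categories of the recipe
      ingredients:
        range: Ingredient
        multivalued: true
        inlined: true
        prompt: the ingredients with quantities
      steps:
        range: Step
        multivalued: true
        inlined: true
        prompt: the steps of the recipe
  Step:
    attributes:
      action:
        range: string
        prompt: the action taken in this step
      utensils:
        range: Utensil
        multivalued: true
        prompt: the utensils used
  Ingredient:
    attributes:
      food_item:
        range: FoodItem
      amount:
        range: Quantity
        inlined: true
        prompt: the quantity of the ingredient
  Quantity:
    attributes:
      value:
        range: string
        prompt: the value of the quantity
      unit:
        range: Unit
  FoodItem:
    id_prefixes: [FOODON]
  Unit:
    id_prefixes: [UO]
    values_from: UnitSet
  Utensil:
    id_prefixes: [WIKIDATA]
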
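name: chemical_to_disease
entry_class: ChemicalToDiseaseDocument
prefixes:
  MESH: http://id.nlm.nih.gov/mesh/
  CHEBI: http://purl.obolibrary.org/obo/CHEBI_
classes:
  ChemicalToDiseaseDocument:
    attributes:
      triples:
        range: ChemicalToDiseaseRelationship
        multivalued: true
        inlined: true
        prompt: chemical to disease relationships, as subject predicate object with qualifiers
  ChemicalToDiseaseRelationship:
    attributes:
      subject:
        range: Chemical
        prompt: the chemical
      predicate:
        range: string
        prompt: the relationship type, for example INDUCES
      object:
        range: Condition
        prompt: the disease or condition
      predicate_qualifier:
        range: string
        prompt: a qualifier on the relationship, for example NOT
      subject_qualifier:
        range: string
        prompt: a qualifier on the chemical
      object_qualifier:
        range: string
        prompt: a qualifier on the disease or condition
  Chemical:
    id_prefixes: [MESH]
  Condition:
    id_prefixes: [MESH]
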
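{
  "_comment": "Illustrative few-shot examples per field, with per-section fallbacks under keys 'section:N'. Synthetic placeholders structured like the EU IDMP Implementation Guide examples.",
  "fields": {
    "container_description": {
      "example_input": "White opaque HDPE bottle with a child-resistant polypropylene cap with an induction seal liner.",
      "example_output": "White opaque HDPE bottle with a child-resistant polypropylene cap with an induction seal liner"
    },
    "container_type": {
      "example_input": "White opaque HDPE bottle with a child-resistant polypropylene cap.",
      "example_output": "bottle"
    },
    "package_item_material": {
      "example_input": "White opaque HDPE bottle with a child-resistant polypropylene cap.",
      "example_output": "HDPE"
    },
    "package_component_value": {
      "example_input": "The green measuring spoon dispenses 100 mg. The blue measuring spoon dispenses 150 mg. The purple measuring spoon dispenses 1 g.",
      "example_output": "[\"100 mg\", \"150 mg\", \"1 g\"]"
    },
    "package_component_component": {
      "example_input": "Each pack contains 1 bottle with 180 g of powder and three polypropylene measuring spoons. The green measuring spoon dispenses 100 mg.",
      "example_output": "[{\"component\": \"green measuring spoon\", \"material\": \"polypropylene\"}]"
    },
    "active_substance_salt_value": {
      "example_input": "Each tablet contains 5.6 mg of aripiprazole hydrochloride equivalent to 5 mg of aripiprazole.",
      "example_output": "aripiprazole hydrochloride"
    },
    "active_substance_salt_dosage": {
      "example_input": "Each tablet contains 5.6 mg of aripiprazole hydrochloride equivalent to 5 mg of aripiprazole.",
      "example_output": "5.6 mg"
    },
    "active_substance_base_value": {
      "example_input": "Each tablet contains 5.6 mg of aripiprazole hydrochloride equivalent to 5 mg of aripiprazole.",
      "example_output": "aripiprazole"
    },
    "active_substance_base_dosage": {
      "example_input": "Each tablet contains 5.6 mg of aripiprazole hydrochloride equivalent to 5 mg of aripiprazole.",
      "example_output": "5 mg"
    }
  },
  "sections": {
    "section:1": {
      "example_input": "1. NAME OF THE MEDICINAL PRODUCT\nPixuvri 29 mg powder for concentrate for solution for infusion",
      "example_output": "Pixuvri 29 mg powder for concentrate for solution for infusion"
    },
    "section:2": {
      "example_input": "8. MARKETING AUTHORISATION NUMBER(S)\nEU/1/22/1646/001, EU/1/22/1646/002-004",
      "example_output": "[\"EU/1/22/1646/001\", \"EU/1/22/1646/002-004\"]"
    },
    "section:3": {
      "example_input": "4.1 Therapeutic indications\nExamplum is indicated for the treatment of major depressive episodes in adults.",
      "example_output": "Examplum is indicated for the treatment of major depressive episodes in adults."
    },
    "section:4": {
      "example_input": "6.5 Nature and contents of container\nPack size: 1 bottle of 180 g of powder.",
      "example_output": "1 bottle of 180 g of powder"
    },
    "section:5": {
      "example_input": "6.1 List of excipients\nLactose monohydrate (54 mg)\nMagnesium stearate (2 mg)",
      "example_output": "[\"Lactose monohydrate\", \"Magnesium stearate\"]"
    },
    "section:6": {
      "example_input": "The administrable dose form is the film-coated tablet, presented as one tablet per dose, for oral use.",
      "example_output": "film-coated tablet"
    }
  }
}
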
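[ROLE]
You are a pharmaceutical regulatory-affairs data specialist who structures
medicinal-product information according to the IDMP standards.

[INPUT]
Question: $question
SmPC excerpt:
<<<CONTEXT
$context
CONTEXT>>>

[STEPS]
1. Read the SmPC excerpt carefully.
2. Identify the passage that answers the question.
3. Extract the answer exactly as stated in the document.$empty_instruction

[EXPECTATION]
$format_instruction
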
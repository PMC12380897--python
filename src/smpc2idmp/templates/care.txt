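[CONTEXT]
You are reading an excerpt of a Summary of Product Characteristics (SmPC) for a
medicinal product. The excerpt below was retrieved as the most relevant context
for one field of the minimal IDMP data model.
<<<CONTEXT
$context
CONTEXT>>>

[ACTION]
Question: $question
Locate the answer in the context above and extract it.$empty_instruction

[RESULT]
$format_instruction

[EXAMPLE]
$examples
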
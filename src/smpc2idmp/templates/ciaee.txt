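[CONTEXT]
You are reading an excerpt of a Summary of Product Characteristics (SmPC) for a
medicinal product, retrieved as relevant context for one minimal-IDMP field.

[INPUT]
Question: $question
SmPC excerpt:
<<<CONTEXT
$context
CONTEXT>>>

[ACTION]
Locate the passage answering the question and extract the answer exactly as
stated in the document.$empty_instruction

[EXPECTATION]
$format_instruction

[EXAMPLE]
$examples
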
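# Default combiner grammar over three layer-1 task outputs x[0..2].
# Extend <idx> with appended demographic slots (e.g. gender, age) when
# those are enabled in the meta-model configuration.
<expr> ::= (<expr> <op> <expr>) | <pre>(<expr>) | <var> | <const>
<op> ::= + | - | *
<pre> ::= tanh | plog | pexp
<var> ::= x[<idx>]
<idx> ::= 0 | 1 | 2
<const> ::= 0.1 | 0.5 | 1.0 | 2.0
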
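# Overlapping CDS intervals excluded from gene assignment (ambiguous)
chrM	8526	8572	ATP8|ATP6	overlap	+
chrM	10759	10766	ND4L|ND4	overlap	+
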
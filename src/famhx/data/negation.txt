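# Pre-entity negation cues (clause-scoped).
no
not
denies
denied
without
never
never had
negative for
no history of
no reports of
no evidence of
free of
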
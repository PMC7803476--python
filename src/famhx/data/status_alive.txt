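# Living-status terms implying the subject is healthy and alive
# (alive=2, healthy=2).
alive
alive and well
doing well
generally healthy
good general health
good health
healthy
living
living and well
otherwise healthy
well
without problems
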
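# Default false-positive list: dictionary hits suppressed after matching.
well
cold
growth
mass
pain
falls
weakness
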
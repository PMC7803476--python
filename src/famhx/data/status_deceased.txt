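# Living-status terms implying the subject is deceased (alive=0, healthy=0).
dead
deceased
died
passed away
stillborn
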
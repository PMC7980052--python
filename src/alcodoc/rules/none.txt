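# Denial / non-drinker phrases. A denial phrase in the same sentence as a
# quantity voids that quantity (simple sentence-window negation).
non-drinker
nondrinker
non drinker
denies
denied
never drinks
never drank
never used alcohol
does not drink
doesn't drink
no alcohol
no etoh
abstains
abstinent
teetotal
teetotaller
none
nil
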
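# Keywords indicating past (former) alcohol use.
# One phrase per line; matching is case-insensitive on word boundaries.
alcoholics anonymous
recovering
recovered
past
quit
sober
in recovery
former drinker
ex-drinker
no longer drinks
stopped drinking
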
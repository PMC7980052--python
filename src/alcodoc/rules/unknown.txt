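# Markers of unquantified / indeterminate documentation. These never decide a
# category on their own; they are recorded as evidence when the note stays
# unclassified.
socially
social drinker
occasional
occasionally
sometimes
discussed
mentioned
reviewed
counselled
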
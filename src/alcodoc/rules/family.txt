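# Family-attribution markers. A sentence containing one of these refers to a
# relative, not the patient: keyword and quantity matches in that sentence are
# ignored and the note (if nothing else fires) is left unclassified.
family history
family hx
fh
father
mother
brother
sister
parent
parents
grandfather
grandmother
husband
wife
son
daughter
uncle
aunt
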
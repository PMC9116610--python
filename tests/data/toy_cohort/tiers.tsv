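gene	tier
BMG001	high
BMG002	moderate_low
BMG003	none
BMG004	none
BMG005	none
BMG006	none
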
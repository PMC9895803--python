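# Restriction enzyme table: IUPAC recognition pattern and 0-based top-strand
# cut offset within the site. Cfr10I cleaves R/CCGGY leaving 4-nt 5' extensions.
Cfr10I:
  recognition: RCCGGY
  cut_offset: 1
EcoRI:
  recognition: GAATTC
  cut_offset: 1
HindIII:
  recognition: AAGCTT
  cut_offset: 1
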
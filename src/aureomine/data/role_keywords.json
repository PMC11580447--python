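{
  "core": ["leaderless bacteriocin", "core peptide", "aureocin"],
  "transport": ["ABC transporter", "ATP-binding", "efflux", "permease", "AcrA", "membrane fusion protein", "ABC-2", "ABC transport"],
  "membrane": ["PH domain", "bPH_2", "Yip1"],
  "regulator": ["transcriptional regulator", "response regulator", "helix-turn-helix", "LacI"],
  "repair": ["excinuclease", "nucleotide excision repair"],
  "hypothetical": ["hypothetical"]
}
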
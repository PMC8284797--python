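# Class I divergence region presets, 1-based mature-protein numbering.
# ARD = antigen-recognition domain (alpha1 + alpha2, exons 2-3);
# pocket definitions follow the standard class I peptide-binding
# pocket assignments.  Edit or supply your own file to override.
ARD:
  start: 1
  end: 182
B_pocket: [7, 9, 24, 25, 33, 34, 45, 60, 63, 66, 67, 70, 99]
F_pocket: [77, 80, 81, 84, 95, 116, 123, 143, 146, 147]
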
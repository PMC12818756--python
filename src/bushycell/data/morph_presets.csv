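# Synthetic relative endbulb sizes for the two morphologically constrained
# conditions (8 convergent inputs each).  The individual reconstructed sizes
# are not published; these vectors are gamma mid-quantiles rescaled so the
# coefficient of variation matches the reported values exactly
# (morph_MED: CV 0.33, morph_HIGH: CV 0.80).  Unit mean by construction.
morph_MED,morph_HIGH
0.5129,0.0535
0.6831,0.2630
0.8029,0.4632
0.9117,0.6796
1.0230,0.9316
1.1488,1.2501
1.3119,1.7101
1.6057,2.6489
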
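# unit=ppm
# analyte=phosphate (as total phosphorus)
# instrument=miniature spectrophotometer, 700 nm
concentration,response
0,0.008
0.2,0.037
0.4,0.059
0.8,0.103
1.2,0.171
1.6,0.253
2,0.321
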
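# unit=ppm
# analyte=vitamin B12
# instrument=miniature spectrophotometer, 550 nm
concentration,response
3,0.030
5,0.056
10,0.081
15,0.109
20,0.158
24,0.189
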
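# unit=uM
# analyte=hydrogen peroxide (enzyme-coupled)
# instrument=miniature spectrophotometer, 600 nm
# note=worked-example fixture; top level (264 uM) lies beyond the linear range
concentration,response
0,0.016
22,0.137
44,0.256
66,0.414
88,0.514
132,0.744
264,1.282
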
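label,lat_deg,lon_deg
NE,66.45,143.22
E,64.17,145.13
SE,63.57,126.50
W,62.25,116.16
NW,66.76,123.37
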
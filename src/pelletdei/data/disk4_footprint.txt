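# Structuring element for the 4-pixel-diameter disk erosion: pixels whose
# Euclidean distance from the centre pixel is <= 2.0 (5x5 box, corners out).
0 0 1 0 0
0 1 1 1 0
1 1 1 1 1
0 1 1 1 0
0 0 1 0 0
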
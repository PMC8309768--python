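# Stylized 7-landmark fish template (synthetic; not asserted as biological truth).
# Centered, unit centroid size. Columns: landmark index (1-based), name, x, y.
# Constructed so the posterior/anterior region-area ratio is 1.6.
1	mouth	-0.507291	0.044450
2	posterior dorsal skull	-0.086942	0.232949
3	anterior dorsal fin	0.189577	0.216190
4	caudal fin	0.566648	0.065362
5	anterior anal fin	0.234461	-0.165713
6	ventral surface	-0.074602	-0.227526
7	ventral anterior skull	-0.321853	-0.165713
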
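# Default gestational-age windows (completed weeks, half-open [low, high))
# for the five scheduled visits after booking.  A declared convention of this
# package: contiguous and non-overlapping, so each contact maps to at most
# one scheduled visit.
wk16: [14, 18]
wk18_22: [18, 23]
wk24_28: [23, 29]
wk32: [29, 34]
wk36: [34, 43]
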
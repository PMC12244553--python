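# SYNTHETIC placeholder score-to-utility mapping.
#
# This is NOT a published QLQ-C30-to-utility algorithm: it is an affine
# stand-in (u = intercept + slope * summary_score) used for examples and
# tests.  To use a published coefficient set, transcribe its intercept /
# slope (or piecewise-linear nodes) into this file; the mapping must be
# monotone non-decreasing in the summary score.
name: synthetic-affine
intercept: 0.2
slope: 0.006
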
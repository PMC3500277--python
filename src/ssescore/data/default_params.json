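{"aa_min_distance": [[4.2, 4.75, 2.25, 3.45, 2.25, 2.25, 3.55, 2.1, 2.25, 4.3, 4.25, 3.05, 2.25, 4.55, 2.25, 2.25, 2.25, 2.25, 2.25, 3.6], [4.75, 4.95, 2.25, 4.5, 2.25, 2.25, 1.25, 4.3, 2.25, 4.4, 1.0, 0.55, 2.25, 4.55, 2.25, 2.25, 2.25, 2.25, 2.25, 4.5], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [3.45, 4.5, 2.25, 4.5, 2.25, 2.25, 3.55, 1.0, 2.25, 2.8, 1.2, 4.55, 2.25, 1.65, 2.25, 2.25, 2.25, 2.25, 2.25, 1.85], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [3.55, 1.25, 2.25, 3.55, 2.25, 2.25, 4.6, 3.5, 2.25, 3.55, 2.9, 0.95, 2.25, 1.4, 2.25, 2.25, 2.25, 2.25, 2.25, 4.1], [2.1, 4.3, 2.25, 1.0, 2.25, 2.25, 3.5, 3.75, 2.25, 4.4, 4.35, 3.9, 2.25, 4.1, 2.25, 2.25, 2.25, 2.25, 2.25, 2.15], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [4.3, 4.4, 2.25, 2.8, 2.25, 2.25, 3.55, 4.4, 2.25, 4.45, 3.55, 3.55, 2.25, 3.7, 2.25, 2.25, 2.25, 2.25, 2.25, 4.15], [4.25, 1.0, 2.25, 1.2, 2.25, 2.25, 2.9, 4.35, 2.25, 3.55, 4.45, 4.5, 2.25, 4.05, 2.25, 2.25, 2.25, 2.25, 2.25, 4.45], [3.05, 0.55, 2.25, 4.55, 2.25, 2.25, 0.95, 3.9, 2.25, 3.55, 4.5, 4.5, 2.25, 3.85, 2.25, 2.25, 2.25, 2.25, 2.25, 2.15], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [4.55, 4.55, 2.25, 1.65, 2.25, 2.25, 1.4, 4.1, 2.25, 3.7, 4.05, 3.85, 2.25, 3.05, 2.25, 2.25, 2.25, 2.25, 2.25, 1.8], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25, 2.25], [3.6, 4.5, 2.25, 1.85, 2.25, 2.25, 4.1, 2.15, 2.25, 4.15, 4.45, 2.15, 2.25, 1.8, 2.25, 2.25, 2.25, 2.25, 2.25, 5.25]], "sse_min_distance": {"HH": 4.0, "HS": 4.0, "SS": 3.0}, "ramp_width": 1.0, "loop_closure_slope": 0.0, "loop_closure_intercept": 23.633541512266373, "loop_closure_exponent": 2.0}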
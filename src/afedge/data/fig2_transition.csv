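interval_s,af_label
0.798185,0
0.819238,0
0.843475,0
0.847546,0
0.807749,0
0.806066,0
0.838713,0
0.788975,0
0.768431,0
0.814373,0
0.879529,0
0.689461,0
0.751486,0
0.744963,0
0.788215,0
0.776601,0
0.783335,0
0.809883,0
0.811647,0
0.835349,0
0.791315,0
0.753147,0
0.702610,0
0.755040,0
0.770408,0
0.771092,0
0.804611,0
0.759443,0
0.764121,0
0.828296,0
0.766539,0
0.762420,0
0.838856,0
0.902025,0
0.743077,0
0.719020,0
0.766069,0
0.788935,0
0.789069,0
0.792078,0
0.521055,1
0.514006,1
0.586347,1
0.580350,1
0.792073,1
0.461952,1
0.787152,1
0.568468,1
0.590410,1
0.804451,1
0.547751,1
0.618793,1
0.634169,1
0.481390,1
0.751650,1
0.666706,1
0.703965,1
0.659858,1
0.639668,1
0.497117,1
0.495053,1
0.661566,1
0.507391,1
0.632941,1
0.637640,1
0.657027,1
0.536588,1
0.805755,1
0.546818,1
0.517866,1
0.688264,1
0.530550,1
0.756685,1
0.630202,1
0.629882,1
0.471681,1
0.640059,1
0.764279,1
0.689195,1
0.395931,1
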